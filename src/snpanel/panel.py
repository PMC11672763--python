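"""Panel assembly: per-population top-K union, capacity allocation, pruning.

Selection runs in three stages.  First the K highest-scoring candidates per
population are united with duplicates collapsed (provenance records every
contributing population and rank).  Capacity allocation then keeps every
autosomal site and fills residual slots with sex-chromosome sites in
descending mean differential.  Finally sites whose detection rate in a test
cohort falls below a threshold are pruned.

Ties at the rank-K and capacity boundaries are broken by (chrom, pos)
ascending, so exports are byte-identical across runs.  Y-chromosome sites
are excluded before selection by a default chromosome blacklist.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .genotypes import GenotypeMatrix, chrom_sort_key
from .probedesign import ProbeContext
from .scoring import DeltaScores

logger = logging.getLogger(__name__)

DEFAULT_K = 1500
DEFAULT_CAPACITY = 6000
DEFAULT_MIN_DETECTION = 0.95
DEFAULT_SEX_CHROMOSOMES = ("X",)
DEFAULT_BLACKLIST = ("Y",)


def _chrom_body(chrom: str) -> str:
    return (chrom[3:] if chrom.lower().startswith("chr") else chrom).upper()


def chrom_class(chrom: str) -> str:
    """Classify a chromosome name as autosome, X, Y or other."""
    body = _chrom_body(chrom)
    if body == "X":
        return "X"
    if body == "Y":
        return "Y"
    if re.fullmatch(r"\d+", body):
        return "autosome"
    return "other"


@dataclass
class Panel:
    """Ordered final site set with per-site provenance.

    ``table`` columns: site_id, chrom, pos, chrom_class, mean_delta,
    source_pops (``pop:rank`` joined by ``;``), stage.  Always sorted by
    (chrom, pos); site ids unique.
    """

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.table["site_id"].duplicated().any():
            raise ValueError("duplicate site ids in panel")
        self.table = _sort_by_position(self.table)

    @property
    def site_ids(self) -> list[str]:
        return list(self.table["site_id"])

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def to_bed(self, path: str | Path) -> None:
        """BED export, 0-based half-open single-base intervals."""
        bed = pd.DataFrame(
            {
                "chrom": self.table["chrom"],
                "start": self.table["pos"] - 1,
                "end": self.table["pos"],
                "name": self.table["site_id"],
            }
        )
        bed.to_csv(path, sep="\t", index=False, header=False)

    def subset_vcf(self, gm: GenotypeMatrix, path: str | Path) -> None:
        gm.subset_site_ids(self.site_ids).to_vcf(path, provenance="panel subset")


def _sort_by_position(df: pd.DataFrame) -> pd.DataFrame:
    key = [(chrom_sort_key(c), p) for c, p in zip(df["chrom"], df["pos"])]
    order = sorted(range(len(df)), key=lambda i: key[i])
    return df.iloc[order].reset_index(drop=True)


def _rank_descending(df: pd.DataFrame, score_col: str) -> pd.DataFrame:
    """Sort by descending score, ties broken by (chrom, pos) ascending."""
    key = [
        (-s, chrom_sort_key(c), p)
        for s, c, p in zip(df[score_col], df["chrom"], df["pos"])
    ]
    order = sorted(range(len(df)), key=lambda i: key[i])
    return df.iloc[order]


def build_candidates(
    gm: GenotypeMatrix,
    scores: DeltaScores,
    probe_results: Mapping[str, ProbeContext] | pd.DataFrame | None = None,
    blacklist: Sequence[str] = DEFAULT_BLACKLIST,
) -> pd.DataFrame:
    """Assemble the candidate table: scoreable, probe-passing, not blacklisted.

    ``probe_results`` may be the DataFrame from
    :func:`snpanel.probedesign.evaluate_probes`, a mapping of site_id to
    :class:`ProbeContext`, or None (all sites treated as probe-feasible,
    e.g. when re-scoring an already probe-vetted list).
    """
    if probe_results is None:
        passed = {sid: True for sid in scores.site_ids}
    elif isinstance(probe_results, pd.DataFrame):
        passed = dict(zip(probe_results["site_id"], probe_results["pass"]))
    else:
        passed = {sid: ctx.passed for sid, ctx in probe_results.items()}

    black = {_chrom_body(c) for c in blacklist}
    rows = []
    for i, site in enumerate(gm.sites):
        if not scores.scoreable[i]:
            continue
        if not passed.get(site.id, False):
            continue
        if _chrom_body(site.chrom) in black:
            continue
        cls = chrom_class(site.chrom)
        row = {
            "site_id": site.id,
            "chrom": site.chrom,
            "pos": site.pos,
            "chrom_class": cls,
            "max_delta": scores.max_delta[i],
            "mean_delta": scores.mean_delta[i],
        }
        for k, p in enumerate(scores.pops):
            row[f"score_{p}"] = scores.pop_score[k, i]
        rows.append(row)
    return pd.DataFrame(rows)


def top_k_union(candidates: pd.DataFrame, k: int = DEFAULT_K) -> pd.DataFrame:
    """Unite the K best candidates per population, collapsing duplicates.

    Per population, candidates are ranked by descending selection score with
    (chrom, pos) ascending as tie-break; ``source_pops`` records each
    contributing population with its 1-based rank.
    """
    if k < 1:
        raise ValueError(f"K must be >= 1, got {k}")
    if candidates.empty:
        raise ValueError("no candidates to select from")
    pops = [c[len("score_") :] for c in candidates.columns if c.startswith("score_")]

    provenance: dict[str, list[str]] = {}
    for p in pops:
        ranked = _rank_descending(candidates, f"score_{p}").head(k)
        for rank, sid in enumerate(ranked["site_id"], 1):
            provenance.setdefault(sid, []).append(f"{p}:{rank}")

    out = candidates[candidates["site_id"].isin(provenance)].copy()
    out["source_pops"] = out["site_id"].map(lambda s: ";".join(provenance[s]))
    out["stage"] = "topK"
    return _sort_by_position(out)


def allocate_capacity(union: pd.DataFrame, capacity: int = DEFAULT_CAPACITY) -> Panel:
    """Keep all autosomal sites; fill remaining slots with the best sex sites.

    Sex-chromosome sites are ranked by descending mean differential with
    (chrom, pos) tie-break.  If autosomal sites alone exceed capacity they
    are all kept and a warning is logged.
    """
    if capacity < 1:
        raise ValueError(f"capacity must be >= 1, got {capacity}")
    if "chrom_class" not in union.columns or "mean_delta" not in union.columns:
        raise ValueError("union table must carry chrom_class and mean_delta")
    auto = union[union["chrom_class"] == "autosome"]
    sex = union[union["chrom_class"] != "autosome"]
    slots = capacity - len(auto)
    if slots < 0:
        logger.warning(
            "allocate_capacity: %d autosomal sites exceed capacity %d; keeping all",
            len(auto),
            capacity,
        )
        slots = 0
    sex_keep = _rank_descending(sex, "mean_delta").head(slots)
    table = pd.concat([auto, sex_keep], ignore_index=True)
    table["stage"] = "capacity"
    return Panel(
        table=table,
        meta={"capacity": capacity, "n_autosomal": len(auto), "n_sex_kept": len(sex_keep)},
    )


def detection_rates(gm: GenotypeMatrix) -> pd.Series:
    """Per-site call rate across a test cohort (fraction of non-missing calls)."""
    from .genotypes import MISSING

    rates = (gm.calls != MISSING).mean(axis=0)
    return pd.Series(rates, index=gm.site_ids)


def prune_by_detection(
    panel: Panel,
    detection: Mapping[str, float] | pd.Series,
    min_rate: float = DEFAULT_MIN_DETECTION,
) -> Panel:
    """Drop panel sites whose detection rate falls below ``min_rate``.

    Every panel site must have a detection value; pruned sites and their
    rates are logged and kept in the returned panel's ``meta['pruned']``.
    """
    if isinstance(detection, pd.Series):
        detection = detection.to_dict()
    missing = [s for s in panel.site_ids if s not in detection]
    if missing:
        raise KeyError(f"no detection rate for panel sites: {missing[:5]}...")
    rates = panel.table["site_id"].map(detection)
    keep = rates >= min_rate
    pruned = panel.table.loc[~keep, ["site_id"]].assign(detection=rates[~keep].values)
    if len(pruned):
        logger.info("prune_by_detection: removed %d sites below %.3f", len(pruned), min_rate)
    table = panel.table[keep].copy()
    table["stage"] = "survived_pruning"
    meta = dict(panel.meta)
    meta["pruned"] = pruned.reset_index(drop=True)
    meta["min_detection"] = min_rate
    return Panel(table=table.reset_index(drop=True), meta=meta)
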