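"""Chip-validation statistics: per-sample call classes and population summaries.

Rate denominators follow the only convention consistent with the published
per-population rows: missing rate over ALL panel sites; het / hom-alt /
reference-consistency rates over CALLED sites (panel minus missing).
Hom-ref calls are the "consistent with the reference genome" class.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .annotate import round_half_up

DEFAULT_MAX_MISSING = 0.90


@dataclass
class SampleCallStats:
    """Per-sample genotype-class counts over the panel.

    The four counts always partition the panel:
    ``n_missing + n_het + n_homalt + n_homref == n_sites``.
    Called-denominator rates are NaN for a sample with no calls at all
    (``failed``).
    """

    sample_id: str
    n_sites: int
    n_missing: int
    n_het: int
    n_homalt: int
    n_homref: int

    def __post_init__(self) -> None:
        if self.n_missing + self.n_het + self.n_homalt + self.n_homref != self.n_sites:
            raise ValueError(f"counts do not partition the panel for {self.sample_id}")

    @property
    def n_called(self) -> int:
        return self.n_sites - self.n_missing

    @property
    def missing_rate(self) -> float:
        return self.n_missing / self.n_sites

    @property
    def call_rate(self) -> float:
        return 1.0 - self.missing_rate

    @property
    def failed(self) -> bool:
        """True when every panel call is missing."""
        return self.n_called == 0

    @property
    def het_rate(self) -> float:
        return self.n_het / self.n_called if self.n_called else float("nan")

    @property
    def homalt_rate(self) -> float:
        return self.n_homalt / self.n_called if self.n_called else float("nan")

    @property
    def consistency_rate(self) -> float:
        """Fraction of called sites homozygous for the reference allele."""
        return self.n_homref / self.n_called if self.n_called else float("nan")


def sample_stats(gm: GenotypeMatrix, sample_id: str) -> SampleCallStats:
    """Tally one sample's calls over the (panel-restricted) matrix."""
    if gm.n_sites == 0:
        raise ValueError("empty panel")
    try:
        j = gm.samples.index(sample_id)
    except ValueError:
        raise KeyError(f"unknown sample {sample_id!r}") from None
    row = gm.calls[j]
    return SampleCallStats(
        sample_id=sample_id,
        n_sites=gm.n_sites,
        n_missing=int((row == MISSING).sum()),
        n_het=int((row == 1).sum()),
        n_homalt=int((row == 2).sum()),
        n_homref=int((row == 0).sum()),
    )


def cohort_stats(gm: GenotypeMatrix) -> list[SampleCallStats]:
    return [sample_stats(gm, s) for s in gm.samples]


def stats_table(stats: Sequence[SampleCallStats]) -> pd.DataFrame:
    """Per-sample companion table (counts plus percent rates)."""
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in stats],
            "n_sites": [s.n_sites for s in stats],
            "n_missing": [s.n_missing for s in stats],
            "missing_rate": [100 * s.missing_rate for s in stats],
            "call_rate": [100 * s.call_rate for s in stats],
            "n_het": [s.n_het for s in stats],
            "het_rate": [100 * s.het_rate for s in stats],
            "n_homalt": [s.n_homalt for s in stats],
            "homalt_rate": [100 * s.homalt_rate for s in stats],
            "n_homref": [s.n_homref for s in stats],
            "consistency_rate": [100 * s.consistency_rate for s in stats],
        }
    )


def population_summary(
    stats: Sequence[SampleCallStats],
    labels: Mapping[str, str],
    include_failed: bool = False,
) -> pd.DataFrame:
    """Per-population means of counts and rates, plus a grand ``Mean`` row.

    Population rows are unweighted means over the population's samples; the
    grand row is the unweighted mean of the population means (not the pooled
    per-sample mean — both conventions exist, this is the tabular one).
    Counts are rounded to integers, rates to 2 decimals (percent,
    half-up).  Samples with zero calls are dropped unless
    ``include_failed``.
    """
    use = [s for s in stats if include_failed or not s.failed]
    if not use:
        raise ValueError("no usable samples")
    missing = [s.sample_id for s in use if s.sample_id not in labels]
    if missing:
        raise KeyError(f"unlabeled samples: {missing[:5]}")

    by_pop: dict[str, list[SampleCallStats]] = {}
    for s in use:
        by_pop.setdefault(labels[s.sample_id], []).append(s)
    for pop, members in by_pop.items():
        if not members:
            raise ValueError(f"population {pop} has no samples")

    def _row(members: Sequence[SampleCallStats]) -> dict[str, float]:
        return {
            "n_samples": len(members),
            "missing_sites": float(np.mean([s.n_missing for s in members])),
            "missing_rate": float(np.mean([100 * s.missing_rate for s in members])),
            "het_sites": float(np.mean([s.n_het for s in members])),
            "het_rate": float(np.mean([100 * s.het_rate for s in members])),
            "hom_sites": float(np.mean([s.n_homalt for s in members])),
            "hom_rate": float(np.mean([100 * s.homalt_rate for s in members])),
            "consistent_sites": float(np.mean([s.n_homref for s in members])),
            "consistency_rate": float(np.mean([100 * s.consistency_rate for s in members])),
        }

    pop_rows = {pop: _row(members) for pop, members in by_pop.items()}
    grand = {
        key: float(np.mean([r[key] for r in pop_rows.values()]))
        for key in next(iter(pop_rows.values()))
    }
    grand["n_samples"] = float(sum(r["n_samples"] for r in pop_rows.values()))

    rows = []
    for pop, r in list(pop_rows.items()) + [("Mean", grand)]:
        rows.append(
            {
                "population": pop,
                "n_samples": int(r["n_samples"]),
                "missing_sites": int(round_half_up(r["missing_sites"])),
                "missing_rate": round_half_up(r["missing_rate"], 2),
                "het_sites": int(round_half_up(r["het_sites"])),
                "het_rate": round_half_up(r["het_rate"], 2),
                "hom_sites": int(round_half_up(r["hom_sites"])),
                "hom_rate": round_half_up(r["hom_rate"], 2),
                "consistent_sites": int(round_half_up(r["consistent_sites"])),
                "consistency_rate": round_half_up(r["consistency_rate"], 2),
            }
        )
    return pd.DataFrame(rows)


def pooled_summary(stats: Sequence[SampleCallStats], include_failed: bool = False) -> dict:
    """Pooled per-sample means across the whole cohort (the prose convention)."""
    use = [s for s in stats if include_failed or not s.failed]
    if not use:
        raise ValueError("no usable samples")
    return {
        "n_samples": len(use),
        "missing_rate": float(np.mean([100 * s.missing_rate for s in use])),
        "call_rate": float(np.mean([100 * s.call_rate for s in use])),
        "het_rate": float(np.mean([100 * s.het_rate for s in use])),
        "homalt_rate": float(np.mean([100 * s.homalt_rate for s in use])),
        "consistency_rate": float(np.mean([100 * s.consistency_rate for s in use])),
    }


def flag_failed_samples(
    stats: Sequence[SampleCallStats], max_missing: float = DEFAULT_MAX_MISSING
) -> list[str]:
    """Sample ids whose missing rate exceeds ``max_missing`` (strict >).

    Flagged samples are excluded from downstream population-structure
    analysis.
    """
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError(f"max_missing must be in [0, 1], got {max_missing}")
    return [s.sample_id for s in stats if s.missing_rate > max_missing]


def write_stats(stats: Sequence[SampleCallStats], path: str | Path) -> None:
    stats_table(stats).to_csv(path, sep="\t", index=False, float_format="%.4f")
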