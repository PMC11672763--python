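"""Genotype matrices: VCF input, site-level QC filters, sample exclusion.

The pipeline's universal currency is :class:`GenotypeMatrix` — a samples x
sites matrix of ALT-allele dosages in ``{0, 1, 2, MISSING}`` with population
labels, optionally carrying per-genotype read depth.

Coordinates are 1-based inclusive throughout (VCF convention); BED exports
convert to 0-based half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for an uncalled genotype in ``GenotypeMatrix.calls`` and for an
#: unreported depth in ``GenotypeMatrix.depth``.
MISSING: int = -1

_NUCS = frozenset("ACGT")


def chrom_sort_key(name: str) -> tuple:
    """Natural sort key for chromosome names: ``2 < 10 < X < Y``.

    A leading ``chr`` prefix is ignored; runs of digits compare numerically
    and sort before alphabetic tokens.
    """
    body = name[3:] if name.lower().startswith("chr") else name
    key = []
    for tok in re.split(r"(\d+)", body):
        if not tok:
            continue
        key.append((0, int(tok)) if tok.isdigit() else (1, tok))
    return tuple(key)


@dataclass(frozen=True, order=False)
class VariantSite:
    """A biallelic SNV locus.

    Attributes
    ----------
    chrom : str
        Chromosome name as spelled in the VCF.
    pos : int
        1-based position.
    ref, alt : str
        Single-nucleotide reference and alternate alleles.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref not in _NUCS or self.alt not in _NUCS:
            raise ValueError(f"alleles must be single A/C/G/T: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")

    @property
    def id(self) -> str:
        """Stable site key ``chrom:pos``."""
        return f"{self.chrom}:{self.pos}"

    def sort_key(self) -> tuple:
        return (chrom_sort_key(self.chrom), self.pos)


@dataclass
class GenotypeMatrix:
    """Samples x sites ALT-dosage calls with population labels.

    ``calls[j, i]`` counts ALT alleles of sample ``j`` at site ``i``;
    ``MISSING`` (-1) marks uncalled genotypes.  Sites are kept sorted by
    (chrom, pos); construction re-sorts columns if needed.
    """

    sites: list[VariantSite]
    samples: list[str]
    populations: list[str]
    calls: np.ndarray
    depth: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)}, {len(self.sites)})"
            )
        if len(self.populations) != len(self.samples):
            raise ValueError("one population label per sample required")
        if self.depth is not None:
            self.depth = np.asarray(self.depth, dtype=np.int32)
            if self.depth.shape != self.calls.shape:
                raise ValueError("depth shape must match calls shape")
        bad = set(np.unique(self.calls)) - {0, 1, 2, MISSING}
        if bad:
            raise ValueError(f"invalid call values {sorted(bad)}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        order = sorted(range(len(self.sites)), key=lambda i: self.sites[i].sort_key())
        if order != list(range(len(self.sites))):
            self.sites = [self.sites[i] for i in order]
            self.calls = self.calls[:, order]
            if self.depth is not None:
                self.depth = self.depth[:, order]
        ids = [s.id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate site ids")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_ids(self) -> list[str]:
        return [s.id for s in self.sites]

    def pop_labels(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    # -- subsetting --------------------------------------------------------

    def take_sites(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = list(idx)
        return GenotypeMatrix(
            sites=[self.sites[i] for i in idx],
            samples=list(self.samples),
            populations=list(self.populations),
            calls=self.calls[:, idx].copy(),
            depth=None if self.depth is None else self.depth[:, idx].copy(),
            meta=dict(self.meta),
        )

    def subset_site_ids(self, keep: Iterable[str]) -> "GenotypeMatrix":
        keep = set(keep)
        return self.take_sites([i for i, s in enumerate(self.sites) if s.id in keep])

    def take_samples(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = list(idx)
        return GenotypeMatrix(
            sites=list(self.sites),
            samples=[self.samples[i] for i in idx],
            populations=[self.populations[i] for i in idx],
            calls=self.calls[idx, :].copy(),
            depth=None if self.depth is None else self.depth[idx, :].copy(),
            meta=dict(self.meta),
        )

    # -- VCF output --------------------------------------------------------

    def to_vcf(self, path: str | Path, provenance: str | None = None) -> None:
        """Write a minimal VCF 4.2 with GT (and DP when depth is present)."""
        path = Path(path)
        has_dp = self.depth is not None
        chrom_max: dict[str, int] = {}
        for s in self.sites:
            chrom_max[s.chrom] = max(chrom_max.get(s.chrom, 0), s.pos)
        lines = ["##fileformat=VCFv4.2"]
        if provenance:
            lines.append(f"##snpanel={provenance}")
        for c in sorted(chrom_max, key=chrom_sort_key):
            lines.append(f"##contig=<ID={c},length={chrom_max[c] + 1000}>")
        lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        if has_dp:
            lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
        lines.append(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(self.samples)
        )
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        fmt = "GT:DP" if has_dp else "GT"
        for i, s in enumerate(self.sites):
            cells = []
            for j in range(self.n_samples):
                g = gt_str[int(self.calls[j, i])]
                if has_dp:
                    d = int(self.depth[j, i])
                    g = f"{g}:{d if d >= 0 else '.'}"
                cells.append(g)
            lines.append(
                f"{s.chrom}\t{s.pos}\t{s.id}\t{s.ref}\t{s.alt}\t.\t.\t.\t{fmt}\t"
                + "\t".join(cells)
            )
        path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# input
# ---------------------------------------------------------------------------


def read_popmap(path: str | Path) -> dict[str, str]:
    """Read a 2-column headerless TSV mapping sample id -> population."""
    popmap: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{ln}: expected 2 tab-separated columns")
        popmap[parts[0]] = parts[1]
    return popmap


def read_vcf(path: str | Path, popmap: str | Path | Mapping[str, str]) -> GenotypeMatrix:
    """Load biallelic SNVs from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic, indel and symbolic records are skipped (count stored in
    ``meta['n_skipped']``).  Half-calls such as ``0/.`` map to MISSING, as
    does ``./.``; phased separators are accepted as unphased.

    Parameters
    ----------
    path : VCF file (plain text or bgzipped).
    popmap : path to a sample->population TSV, or an in-memory mapping.
        Every VCF sample must be covered.
    """
    from cyvcf2 import VCF

    if not isinstance(popmap, Mapping):
        popmap = read_popmap(popmap)

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on bad files
        raise OSError(f"cannot read VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    missing_pop = [s for s in samples if s not in popmap]
    if missing_pop:
        raise KeyError(
            "samples missing from popmap: " + ", ".join(sorted(missing_pop))
        )
    populations = [popmap[s] for s in samples]

    sites: list[VariantSite] = []
    call_rows: list[np.ndarray] = []
    depth_rows: list[np.ndarray] = []
    any_depth = False
    n_skipped = 0
    for v in vcf:
        if (
            len(v.ALT) != 1
            or v.REF not in _NUCS
            or v.ALT[0] not in _NUCS
        ):
            n_skipped += 1
            continue
        sites.append(VariantSite(v.CHROM, v.POS, v.REF, v.ALT[0]))
        row = np.empty(len(samples), dtype=np.int8)
        for j, g in enumerate(v.genotypes):
            a, b = g[0], g[1] if len(g) > 2 else -1
            row[j] = MISSING if (a < 0 or b < 0) else a + b
        call_rows.append(row)
        try:
            d = v.format("DP")
        except KeyError:
            d = None
        if d is not None:
            any_depth = True
            d = np.asarray(d, dtype=np.int64).reshape(len(samples))
            d = np.where(d < 0, MISSING, d)  # htslib encodes missing as INT_MIN
            depth_rows.append(d.astype(np.int32))
        else:
            depth_rows.append(np.full(len(samples), MISSING, dtype=np.int32))
    vcf.close()

    calls = (
        np.stack(call_rows, axis=1)
        if call_rows
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    depth = np.stack(depth_rows, axis=1) if (depth_rows and any_depth) else None
    if n_skipped:
        logger.warning("read_vcf: skipped %d non-biallelic-SNV records", n_skipped)
    return GenotypeMatrix(
        sites=sites,
        samples=samples,
        populations=populations,
        calls=calls,
        depth=depth,
        meta={"n_skipped": n_skipped, "source": str(path)},
    )


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def site_qc_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-site QC statistics: mean depth, missing fraction, het fraction.

    Mean depth averages reported (non-negative) per-genotype depths at the
    site; het fraction is computed over non-missing calls only and is NaN
    when every call is missing.
    """
    calls = gm.calls
    n = gm.n_samples
    called = calls != MISSING
    n_called = called.sum(axis=0)
    missing_fraction = (calls == MISSING).sum(axis=0) / n
    with np.errstate(invalid="ignore"):
        het_fraction = np.where(
            n_called > 0, (calls == 1).sum(axis=0) / np.maximum(n_called, 1), np.nan
        )
    if gm.depth is not None:
        has_d = gm.depth >= 0
        n_d = has_d.sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean_depth = np.where(
                n_d > 0,
                np.where(has_d, gm.depth, 0).sum(axis=0) / np.maximum(n_d, 1),
                np.nan,
            )
    else:
        mean_depth = np.full(gm.n_sites, np.nan)
    return pd.DataFrame(
        {
            "site_id": gm.site_ids,
            "mean_depth": mean_depth,
            "missing_fraction": missing_fraction,
            "het_fraction": het_fraction,
        }
    )


def qc_filter_sites(
    gm: GenotypeMatrix,
    min_depth: float = 5.0,
    max_missing: float = 0.10,
    max_het: float = 0.30,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the site-level quality filters.

    A site is retained iff mean depth >= ``min_depth`` (inclusive), missing
    fraction < ``max_missing`` (strict) and het fraction < ``max_het``
    (strict).  When the matrix carries no depth the depth criterion is
    vacuous (a warning is logged).

    Returns
    -------
    (filtered matrix, report) where the report lists each removed site with
    a ``;``-joined reason string drawn from ``depth``/``missing``/``het``.
    """
    if gm.n_sites == 0:
        raise ValueError("empty genotype matrix")
    for name, v in (("max_missing", max_missing), ("max_het", max_het)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if min_depth < 0:
        raise ValueError(f"min_depth must be >= 0, got {min_depth}")

    stats = site_qc_stats(gm)
    if gm.depth is None:
        logger.warning("qc_filter_sites: no depth data; depth criterion skipped")
        depth_ok = np.ones(gm.n_sites, dtype=bool)
    else:
        depth_ok = stats["mean_depth"].to_numpy() >= min_depth
    miss_ok = stats["missing_fraction"].to_numpy() < max_missing
    het = stats["het_fraction"].to_numpy()
    het_ok = np.where(np.isnan(het), False, het < max_het)
    # an all-missing site has het undefined; it always fails `missing` first
    het_ok |= np.isnan(het) & miss_ok

    keep = depth_ok & miss_ok & het_ok
    reasons = []
    for i in np.flatnonzero(~keep):
        why = []
        if not depth_ok[i]:
            why.append("depth")
        if not miss_ok[i]:
            why.append("missing")
        if miss_ok[i] and not het_ok[i]:
            why.append("het")
        reasons.append((gm.site_ids[i], ";".join(why)))
    report = pd.DataFrame(reasons, columns=["site_id", "reason"])
    return gm.take_sites(np.flatnonzero(keep)), report


def exclude_samples(gm: GenotypeMatrix, ids: Sequence[str]) -> GenotypeMatrix:
    """Drop the named samples; the site list is unchanged.

    Raises ``KeyError`` listing any id not present in the matrix.
    """
    ids = list(ids)
    unknown = [i for i in ids if i not in gm.samples]
    if unknown:
        raise KeyError("unknown sample ids: " + ", ".join(unknown))
    drop = set(ids)
    return gm.take_samples([j for j, s in enumerate(gm.samples) if s not in drop])


def write_filter_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False)
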