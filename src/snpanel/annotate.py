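"""Gene-structure classification, chromosome window density, MAF histogram.

Sites are assigned exactly one of eight categories with fixed precedence:
exonic > UTR5 > UTR3 > intronic > upstream/downstream > intergenic.  A site
that is simultaneously within 1 kb upstream of one gene and 1 kb downstream
of another gets the combined ``upstream;downstream`` label.  Density uses
non-overlapping 1 Mb tiles so window counts sum to the panel size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import VariantSite, chrom_sort_key

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 1000
DEFAULT_WINDOW = 1_000_000

CATEGORIES = (
    "exonic",
    "UTR5",
    "UTR3",
    "intronic",
    "upstream",
    "downstream",
    "upstream;downstream",
    "intergenic",
)

_Interval = tuple[int, int]  # 1-based inclusive


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up, the convention used for printed percentages."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class GeneModel:
    """Union-of-transcripts gene model with 1-based inclusive intervals."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[_Interval] = field(default_factory=list)
    cds: list[_Interval] = field(default_factory=list)
    utr5: list[_Interval] = field(default_factory=list)
    utr3: list[_Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass
class SiteAnnotation:
    site_id: str
    category: str
    genes: tuple[str, ...] = ()


def _in_any(pos: int, intervals: Iterable[_Interval]) -> bool:
    return any(s <= pos <= e for s, e in intervals)


def load_gene_models(gff3: str | Path) -> dict[str, list[GeneModel]]:
    """Read GFF3 gene models into per-chromosome lists (transcripts merged).

    Exons, CDS and UTRs from all transcripts of a gene are pooled; this is
    sufficient for the single-isoform classification used here.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff3),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: dict[str, list[GeneModel]] = {}
    for gene in db.features_of_type("gene"):
        gm = GeneModel(
            gene_id=gene.id,
            chrom=gene.seqid,
            strand=gene.strand,
            start=gene.start,
            end=gene.end,
        )
        for ftype, bucket in (
            ("exon", gm.exons),
            ("CDS", gm.cds),
            ("five_prime_UTR", gm.utr5),
            ("three_prime_UTR", gm.utr3),
        ):
            for f in db.children(gene, featuretype=ftype):
                bucket.append((f.start, f.end))
        models.setdefault(gm.chrom, []).append(gm)
    for lst in models.values():
        lst.sort(key=lambda g: g.start)
    return models


def classify(
    site: VariantSite,
    models: Mapping[str, Sequence[GeneModel]],
    flank: int = DEFAULT_FLANK,
    combine_utr: bool = False,
) -> SiteAnnotation:
    """Assign the single gene-structure category of a site.

    A chromosome absent from the gene models yields ``intergenic`` with a
    warning.  With ``combine_utr`` a site in the 5' UTR of one gene and the
    3' UTR of another is labelled ``UTR5;UTR3`` instead of ``UTR5``.
    """
    genes = models.get(site.chrom)
    if genes is None:
        logger.warning("classify: chromosome %s has no gene models", site.chrom)
        return SiteAnnotation(site.id, "intergenic")

    pos = site.pos
    hits: dict[str, list[str]] = {c: [] for c in CATEGORIES[:6]}
    for g in genes:
        if g.start <= pos <= g.end:
            if _in_any(pos, g.cds):
                hits["exonic"].append(g.gene_id)
            elif _in_any(pos, g.utr5):
                hits["UTR5"].append(g.gene_id)
            elif _in_any(pos, g.utr3):
                hits["UTR3"].append(g.gene_id)
            elif _in_any(pos, g.exons):
                hits["exonic"].append(g.gene_id)  # non-coding exon
            else:
                hits["intronic"].append(g.gene_id)
        else:
            if g.strand == "+":
                up = (g.start - flank, g.start - 1)
                down = (g.end + 1, g.end + flank)
            else:
                up = (g.end + 1, g.end + flank)
                down = (g.start - flank, g.start - 1)
            if up[0] <= pos <= up[1]:
                hits["upstream"].append(g.gene_id)
            if down[0] <= pos <= down[1]:
                hits["downstream"].append(g.gene_id)

    if hits["exonic"]:
        return SiteAnnotation(site.id, "exonic", tuple(hits["exonic"]))
    if hits["UTR5"] and hits["UTR3"] and combine_utr:
        return SiteAnnotation(site.id, "UTR5;UTR3", tuple(hits["UTR5"] + hits["UTR3"]))
    if hits["UTR5"]:
        return SiteAnnotation(site.id, "UTR5", tuple(hits["UTR5"]))
    if hits["UTR3"]:
        return SiteAnnotation(site.id, "UTR3", tuple(hits["UTR3"]))
    if hits["intronic"]:
        return SiteAnnotation(site.id, "intronic", tuple(hits["intronic"]))
    if hits["upstream"] and hits["downstream"]:
        return SiteAnnotation(
            site.id, "upstream;downstream", tuple(hits["upstream"] + hits["downstream"])
        )
    if hits["upstream"]:
        return SiteAnnotation(site.id, "upstream", tuple(hits["upstream"]))
    if hits["downstream"]:
        return SiteAnnotation(site.id, "downstream", tuple(hits["downstream"]))
    return SiteAnnotation(site.id, "intergenic")


def classify_sites(
    sites: Iterable[VariantSite],
    models: Mapping[str, Sequence[GeneModel]],
    flank: int = DEFAULT_FLANK,
    combine_utr: bool = False,
) -> list[SiteAnnotation]:
    return [classify(s, models, flank, combine_utr) for s in sites]


def annotation_summary(annotations: Sequence[SiteAnnotation]) -> pd.DataFrame:
    """Category counts and percentages (to 0.1%) over the whole panel."""
    if not annotations:
        raise ValueError("no annotations to summarize")
    n = len(annotations)
    counts: dict[str, int] = {}
    for a in annotations:
        counts[a.category] = counts.get(a.category, 0) + 1
    cats = [c for c in CATEGORIES if c in counts] + sorted(set(counts) - set(CATEGORIES))
    return pd.DataFrame(
        {
            "category": cats,
            "count": [counts[c] for c in cats],
            "percent": [round_half_up(100.0 * counts[c] / n, 1) for c in cats],
        }
    )


def window_density(
    sites: Iterable[VariantSite],
    chrom_lengths: Mapping[str, int],
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Count sites in non-overlapping tiles [k*W+1, (k+1)*W] per chromosome.

    Every chromosome carrying a site must have a declared length; a site
    beyond that length is an error.  Counts over all windows sum to the
    number of sites.
    """
    sites = list(sites)
    per_chrom: dict[str, list[int]] = {}
    for s in sites:
        if s.chrom not in chrom_lengths:
            raise KeyError(f"no declared length for chromosome {s.chrom}")
        if s.pos > chrom_lengths[s.chrom]:
            raise ValueError(
                f"site {s.id} beyond declared length {chrom_lengths[s.chrom]}"
            )
        per_chrom.setdefault(s.chrom, []).append(s.pos)

    rows = []
    for chrom in sorted(per_chrom, key=chrom_sort_key):
        length = chrom_lengths[chrom]
        n_windows = (length + window - 1) // window
        counts = np.zeros(n_windows, dtype=int)
        for pos in per_chrom[chrom]:
            counts[(pos - 1) // window] += 1
        for w in range(n_windows):
            rows.append(
                {
                    "chrom": chrom,
                    "window_start": w * window + 1,
                    "window_end": min((w + 1) * window, length),
                    "count": int(counts[w]),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class MafHistogram:
    """Folded-MAF histogram over [0, 0.5] plus the share at or above 0.2."""

    bins: pd.DataFrame  # bin_low, bin_high, count
    n: int
    pct_ge_020: float  # percentage of sites with folded MAF >= 0.2 (1 dp)


def maf_histogram(folded_maf: np.ndarray, bin_width: float = 0.05) -> MafHistogram:
    """Bin folded pooled MAF into fixed-width bins covering [0, 0.5].

    The last bin is closed at 0.5; counts sum to the input size.
    """
    maf = np.asarray(folded_maf, dtype=float)
    if np.isnan(maf).any():
        raise ValueError("NaN folded MAF values")
    if (maf < 0).any() or (maf > 0.5 + 1e-12).any():
        raise ValueError("folded MAF must lie in [0, 0.5]")
    edges = np.arange(0.0, 0.5 + bin_width / 2, bin_width)
    counts, _ = np.histogram(maf, bins=edges)
    bins = pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}
    )
    share = 100.0 * float((maf >= 0.2).sum()) / len(maf) if len(maf) else 0.0
    return MafHistogram(bins=bins, n=len(maf), pct_ge_020=round_half_up(share, 1))
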