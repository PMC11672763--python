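"""Per-population allele frequencies and allele-frequency-differential scores.

The marker-informativeness score used for panel selection is the pairwise
allele-frequency differential |f_p - f_q| computed on UNFOLDED ALT-allele
frequencies.  Folding before differencing would send a maximally informative
site (f = 0.9 vs 0.1) to zero; the unfolded differential is invariant under
a ref/alt swap, so nothing is lost.  Folded MAF is still available for
histograms and optional frequency floors.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


@dataclass
class PopulationFrequencies:
    """Per-population and pooled ALT-allele frequencies for each site.

    ``alt_freq[p, i]`` is NaN where population ``p`` has no called genotype
    at site ``i``; such sites are flagged unscoreable.
    """

    site_ids: list[str]
    pops: list[str]
    alt_freq: np.ndarray  # (n_pops, n_sites), NaN where n_p == 0
    called_alleles: np.ndarray  # (n_pops, n_sites) int
    pooled_alt_freq: np.ndarray  # (n_sites,)
    pooled_called_alleles: np.ndarray  # (n_sites,) int

    @property
    def scoreable(self) -> np.ndarray:
        """True where every population has at least one called genotype."""
        return (self.called_alleles > 0).all(axis=0)

    def folded_maf(self, pop: str | None = None) -> np.ndarray:
        """Folded minor-allele frequency, pooled by default."""
        f = (
            self.pooled_alt_freq
            if pop is None
            else self.alt_freq[self.pops.index(pop)]
        )
        return np.minimum(f, 1.0 - f)


@dataclass
class DeltaScores:
    """Pairwise allele-frequency differentials and their aggregates.

    ``delta[k, i]`` holds |f_p - f_q| for unordered pair ``pairs[k]``;
    ``pop_score[p, i]`` is the max differential involving population ``p`` —
    the per-population selection score.  Unscoreable sites carry NaN
    everywhere and are excluded from selection.
    """

    site_ids: list[str]
    pops: list[str]
    pairs: list[tuple[str, str]]
    delta: np.ndarray  # (n_pairs, n_sites)
    max_delta: np.ndarray  # (n_sites,)
    mean_delta: np.ndarray  # (n_sites,)
    pop_score: np.ndarray  # (n_pops, n_sites)
    scoreable: np.ndarray  # (n_sites,) bool

    def pair_delta(self, p: str, q: str) -> np.ndarray:
        key = tuple(sorted((p, q), key=self.pops.index))
        return self.delta[self.pairs.index(key)]  # type: ignore[arg-type]


def population_frequencies(
    gm: GenotypeMatrix, pops: list[str] | None = None
) -> PopulationFrequencies:
    """Compute per-population and pooled ALT frequencies.

    Missing calls are excluded from numerator and denominator.  ``pops``
    defaults to the labels present in the matrix (order of first
    appearance); naming a label with no samples is an error.
    """
    if pops is None:
        pops = gm.pop_labels()
    labels = np.asarray(gm.populations)
    for p in pops:
        if not (labels == p).any():
            raise ValueError(f"population {p!r} has no samples")

    calls = gm.calls
    called = calls != MISSING
    alt = np.where(called, calls, 0)

    n_pops = len(pops)
    alt_freq = np.full((n_pops, gm.n_sites), np.nan)
    called_alleles = np.zeros((n_pops, gm.n_sites), dtype=np.int64)
    for k, p in enumerate(pops):
        rows = labels == p
        n_alleles = 2 * called[rows].sum(axis=0)
        alt_count = alt[rows].sum(axis=0)
        called_alleles[k] = n_alleles
        with np.errstate(invalid="ignore", divide="ignore"):
            alt_freq[k] = np.where(n_alleles > 0, alt_count / np.maximum(n_alleles, 1), np.nan)

    pooled_n = 2 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled_f = np.where(pooled_n > 0, alt.sum(axis=0) / np.maximum(pooled_n, 1), np.nan)
    return PopulationFrequencies(
        site_ids=gm.site_ids,
        pops=list(pops),
        alt_freq=alt_freq,
        called_alleles=called_alleles,
        pooled_alt_freq=pooled_f,
        pooled_called_alleles=pooled_n,
    )


def delta_scores(freqs: PopulationFrequencies) -> DeltaScores:
    """Pairwise |f_p - f_q| with max/mean aggregates and per-population scores."""
    pops = freqs.pops
    idx_pairs = list(combinations(range(len(pops)), 2))
    scoreable = freqs.scoreable

    n_sites = len(freqs.site_ids)
    delta = np.full((len(idx_pairs), n_sites), np.nan)
    for k, (a, b) in enumerate(idx_pairs):
        delta[k] = np.abs(freqs.alt_freq[a] - freqs.alt_freq[b])
    delta[:, ~scoreable] = np.nan

    max_delta = np.full(n_sites, np.nan)
    mean_delta = np.full(n_sites, np.nan)
    max_delta[scoreable] = delta[:, scoreable].max(axis=0)
    mean_delta[scoreable] = delta[:, scoreable].mean(axis=0)

    pop_score = np.full((len(pops), n_sites), np.nan)
    for p in range(len(pops)):
        rows = [k for k, (a, b) in enumerate(idx_pairs) if p in (a, b)]
        pop_score[p, scoreable] = delta[np.ix_(rows, scoreable)].max(axis=0)
    return DeltaScores(
        site_ids=list(freqs.site_ids),
        pops=list(pops),
        pairs=[(pops[a], pops[b]) for a, b in idx_pairs],
        delta=delta,
        max_delta=max_delta,
        mean_delta=mean_delta,
        pop_score=pop_score,
        scoreable=scoreable,
    )


def scores_table(
    gm: GenotypeMatrix, freqs: PopulationFrequencies, scores: DeltaScores
) -> pd.DataFrame:
    """Flat per-site table: frequencies, pairwise deltas and aggregates."""
    rows = {
        "site_id": scores.site_ids,
        "chrom": [s.chrom for s in gm.sites],
        "pos": [s.pos for s in gm.sites],
    }
    for k, p in enumerate(freqs.pops):
        rows[f"f_{p}"] = freqs.alt_freq[k]
    for k, (p, q) in enumerate(scores.pairs):
        rows[f"delta_{p}_{q}"] = scores.delta[k]
    rows["max_delta"] = scores.max_delta
    rows["mean_delta"] = scores.mean_delta
    for k, p in enumerate(scores.pops):
        rows[f"score_{p}"] = scores.pop_score[k]
    rows["scoreable"] = scores.scoreable
    return pd.DataFrame(rows)


def write_scores(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def hudson_fst(gm: GenotypeMatrix, pop_a: str, pop_b: str) -> float:
    """Hudson FST estimator between two populations (ratio of averages).

    Per site: num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1) and
    den = p1(1-p2) + p2(1-p1), with n the called allele counts; the
    estimate is sum(num)/sum(den) over sites with n >= 2 in both
    populations and den > 0.
    """
    freqs = population_frequencies(gm, pops=[pop_a, pop_b])
    p1, p2 = freqs.alt_freq
    n1, n2 = freqs.called_alleles.astype(float)
    ok = (n1 > 1) & (n2 > 1)
    p1, p2, n1, n2 = p1[ok], p2[ok], n1[ok], n2[ok]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    use = den > 0
    if not use.any():
        raise ValueError("no informative sites for FST")
    return float(num[use].sum() / den[use].sum())
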