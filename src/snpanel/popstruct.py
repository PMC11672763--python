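"""Population structure: GRM, PCA, IBS distances, NJ tree, concordance.

The relationship matrix uses the standard frequency-standardized estimator
A_jk = (1/m_jk) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))
with pooled ALT frequencies p_i estimated from the analyzed cohort itself,
pooled-monomorphic sites excluded, and m_jk counting only sites called in
both members of the pair.

The tree distance is allele sharing, d = 1 - IBS, between individuals; the
tree is built with the classic Saitou-Nei neighbor-joining agglomeration
(Q-criterion), negative branch lengths clamped to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# GRM + PCA
# ---------------------------------------------------------------------------


@dataclass
class GRM:
    matrix: np.ndarray  # (n, n)
    m_pairs: np.ndarray  # (n, n) int, markers used per pair
    sample_ids: list[str]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.sample_ids).to_csv(
            path, sep="\t", float_format="%.8g"
        )


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # (k,) descending
    coords: np.ndarray  # (n, k) orthonormal eigenvector columns
    sample_ids: list[str]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.coords,
            index=self.sample_ids,
            columns=[f"PC{i + 1}" for i in range(self.coords.shape[1])],
        )
        df.to_csv(path, sep="\t", float_format="%.8g")


def grm(gm: GenotypeMatrix) -> GRM:
    """Frequency-standardized genomic relationship matrix.

    Missing genotypes contribute nothing; each pair's average runs over the
    markers called in both samples.  Raises if some pair shares no usable
    marker.
    """
    if gm.n_samples < 2:
        raise ValueError("GRM requires at least 2 samples")
    calls = gm.calls.astype(float)
    called = gm.calls != MISSING

    n_alleles = 2 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, calls, 0.0).sum(axis=0) / np.maximum(n_alleles, 1)
    usable = (n_alleles > 0) & (p > 0.0) & (p < 1.0)
    if not usable.any():
        raise ValueError("no polymorphic markers for GRM")

    p = p[usable]
    x = calls[:, usable]
    c = called[:, usable]
    z = np.where(c, (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p)), 0.0)
    m = c.astype(np.float64) @ c.astype(np.float64).T
    if (m == 0).any():
        j, k = np.argwhere(m == 0)[0]
        raise ValueError(
            f"no shared usable markers for pair ({gm.samples[j]}, {gm.samples[k]})"
        )
    a = (z @ z.T) / m
    return GRM(matrix=a, m_pairs=m.astype(np.int64), sample_ids=list(gm.samples))


def pca(relationship: GRM, k: int = 3) -> PCAResult:
    """Top-k eigenpairs of the double-centered relationship matrix.

    Eigenvector signs are fixed so the largest-magnitude loading of each
    component is positive.
    """
    a = relationship.matrix
    n = a.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds sample count {n}")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("GRM must be symmetric")
    j = np.eye(n) - np.ones((n, n)) / n
    ac = j @ a @ j
    vals, vecs = np.linalg.eigh(ac)
    order = np.argsort(vals)[::-1][:k]
    vals = vals[order]
    vecs = vecs[:, order]
    for i in range(k):
        lead = np.argmax(np.abs(vecs[:, i]))
        if vecs[lead, i] < 0:
            vecs[:, i] = -vecs[:, i]
    return PCAResult(eigenvalues=vals, coords=vecs, sample_ids=list(relationship.sample_ids))


# ---------------------------------------------------------------------------
# IBS distance
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    matrix: np.ndarray  # (n, n) in [0, 1]
    m_pairs: np.ndarray  # (n, n) int, co-called sites per pair
    ids: list[str]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", float_format="%.8g"
        )


def ibs_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """Allele-sharing distance d = 1 - IBS over co-called sites.

    d_jk = sum_i |x_ij - x_ik| / (2 m_jk); identical samples are at 0,
    opposite homozygotes at every site are at 1.
    """
    called = gm.calls != MISSING
    ind = [
        ((gm.calls == g) & called).astype(np.float64) for g in (0, 1, 2)
    ]  # one-hot per dosage
    m = called.astype(np.float64) @ called.astype(np.float64).T
    if (m == 0).any():
        j, k = np.argwhere(m == 0)[0]
        if j != k:
            raise ValueError(
                f"no co-called sites for pair ({gm.samples[j]}, {gm.samples[k]})"
            )
    # sum |x_j - x_k| decomposes over dosage classes
    s = (
        ind[0] @ ind[1].T
        + ind[1] @ ind[0].T
        + ind[1] @ ind[2].T
        + ind[2] @ ind[1].T
        + 2.0 * (ind[0] @ ind[2].T + ind[2] @ ind[0].T)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = s / (2.0 * np.maximum(m, 1))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(matrix=d, m_pairs=m.astype(np.int64), ids=list(gm.samples))


def population_distance(dist: DistanceMatrix, labels: Sequence[str]) -> DistanceMatrix:
    """Average inter-population distances from an individual-level matrix."""
    labels = list(labels)
    pops = sorted(set(labels))
    out = np.zeros((len(pops), len(pops)))
    lab = np.asarray(labels)
    for a, p in enumerate(pops):
        for b, q in enumerate(pops):
            if a >= b:
                continue
            block = dist.matrix[np.ix_(lab == p, lab == q)]
            out[a, b] = out[b, a] = float(block.mean())
    return DistanceMatrix(
        matrix=out, m_pairs=np.zeros_like(out, dtype=np.int64), ids=pops
    )


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


class _Node:
    __slots__ = ("name", "children")

    def __init__(self, name: str | None = None):
        self.name = name
        self.children: list[tuple["_Node", float]] = []

    def newick(self) -> str:
        if not self.children:
            return self.name or ""
        inner = ",".join(f"{c.newick()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


@dataclass
class PhyloTree:
    """Unrooted tree serialized as Newick (trifurcating root node)."""

    newick: str
    leaf_names: list[str]

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.newick + "\n")


def nj_tree(dist: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with the Q-criterion.

    Ties in Q are broken by the smaller index pair for determinism.
    Negative branch lengths are clamped to 0 (logged).  The result is an
    unrooted tree written with a trifurcating root.
    """
    d = np.array(dist.matrix, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("NJ requires at least 3 leaves")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")

    nodes: list[_Node] = [_Node(name) for name in dist.ids]
    active = list(range(n))
    clamped = 0

    def _clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(active) > 3:
        na = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (na - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = np.argmin(q)
        i, j = divmod(flat, na)
        if i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = _clamp(0.5 * dij + (r[i] - r[j]) / (2.0 * (na - 2)))
        lj = _clamp(dij - (0.5 * dij + (r[i] - r[j]) / (2.0 * (na - 2))))
        parent = _Node()
        parent.children = [(nodes[ai], li), (nodes[aj], lj)]
        # distances from the new node to all remaining nodes
        new_row = np.zeros(d.shape[0] + 1)
        for t in active:
            if t in (ai, aj):
                continue
            new_row[t] = 0.5 * (d[ai, t] + d[aj, t] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [t for t in active if t not in (ai, aj)] + [d.shape[0] - 1]

    a, b, c = active
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    la = _clamp(0.5 * (dab + dac - dbc))
    lb = _clamp(0.5 * (dab + dbc - dac))
    lc = _clamp(0.5 * (dac + dbc - dab))
    root = _Node()
    root.children = [(nodes[a], la), (nodes[b], lb), (nodes[c], lc)]
    if clamped:
        logger.info("nj_tree: clamped %d negative branch lengths to 0", clamped)
    return PhyloTree(newick=root.newick() + ";", leaf_names=list(dist.ids))


# ---------------------------------------------------------------------------
# cluster concordance
# ---------------------------------------------------------------------------


def cluster_concordance(
    coords: np.ndarray,
    labels: Sequence[str],
    seed: int = 0,
    n_clusters: int | None = None,
) -> tuple[float, float, np.ndarray]:
    """k-means the PCA coordinates and compare clusters to declared labels.

    Returns (adjusted Rand index, purity, cluster assignment).  ``n_clusters``
    defaults to the number of distinct labels.  To score at a coarser
    granularity (e.g. breeds rather than nested types), pass the coarser
    labels.
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import adjusted_rand_score

    labels = list(labels)
    coords = np.asarray(coords, dtype=float)
    k = n_clusters or len(set(labels))
    if coords.shape[0] < k:
        raise ValueError(f"fewer samples ({coords.shape[0]}) than clusters ({k})")
    if coords.shape[0] != len(labels):
        raise ValueError("one label per coordinate row required")
    pred = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(coords)
    ari = float(adjusted_rand_score(labels, pred))
    lab = np.asarray(labels)
    purity = (
        sum(
            int(pd.Series(lab[pred == c]).value_counts().iloc[0])
            for c in np.unique(pred)
        )
        / len(labels)
    )
    return ari, float(purity), pred
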