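"""Synthetic five-population cohorts, reference genomes and gene models.

The cohort follows a hierarchical Balding-Nichols model: each breed's
allele frequency at a site is Beta-distributed around an ancestral
frequency with divergence F_breed, and each type nested inside the first
breed is drawn the same way around its breed frequency with a much smaller
F_type.  This directly reproduces the regime the panel-design method
targets: three weakly diverged types inside one breed plus two well
separated breeds.

Genotypes are Binomial(2, f_pop) with independent per-call missingness and
Poisson read depth.  Everything is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .genotypes import GenotypeMatrix, VariantSite

_DEF_CHROMS = tuple((str(i), 1_000_000) for i in range(1, 30)) + (("X", 500_000),)


@dataclass
class SimConfig:
    """Parameters of the hierarchical cohort simulation.

    ``seed`` is mandatory; every stochastic step derives its stream from it.
    F values are engineering choices reproducing the separable-breed /
    non-separable-type regime, not estimates.
    """

    seed: int
    breeds: tuple[str, ...] = ("IM", "HS", "WZMQ")
    types_in: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {"IM": ("ARBS", "ELS", "ALS")}
    )
    # f_type is small enough that panel-based PCA cannot split the nested
    # types at default cohort sizes, while f_breed keeps breeds separable
    f_breed: float = 0.05
    f_type: float = 0.002
    samples_per_pop: int = 60
    n_sites: int = 20_000
    chroms: tuple[tuple[str, int], ...] = _DEF_CHROMS
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95
    missingness: float = 0.002
    depth_mean: float = 30.0
    n_failed_samples: int = 0
    failed_missingness: float = 0.97
    planted_repeats: tuple[tuple[int, int], ...] = ()  # (site index, total copies)
    edge_margin: int = 60  # keep sites clear of contig ends for probe windows

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for f in (self.f_breed, self.f_type):
            if not 0.0 < f < 1.0:
                raise ValueError(f"divergence F must be in (0, 1), got {f}")
        for name, length in self.chroms:
            if length < 2 * 110:
                raise ValueError(f"chromosome {name} shorter than 2 probe lengths")

    @property
    def populations(self) -> tuple[str, ...]:
        out: list[str] = []
        for b in self.breeds:
            out.extend(self.types_in.get(b, (b,)))
        return tuple(out)

    @property
    def breed_of(self) -> dict[str, str]:
        m: dict[str, str] = {}
        for b in self.breeds:
            for p in self.types_in.get(b, (b,)):
                m[p] = b
        return m


@dataclass
class SimTruth:
    """Ground truth: sites, ancestral and per-population frequencies, labels."""

    sites: list[VariantSite]
    ancestral: np.ndarray  # (n_sites,)
    pops: tuple[str, ...]
    pop_freqs: np.ndarray  # (n_pops, n_sites)
    breed_freqs: dict[str, np.ndarray]
    planted: list[tuple[str, int, str]] = field(default_factory=list)  # chrom, pos, kmer


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    a = p * (1.0 - f) / f
    b = (1.0 - p) * (1.0 - f) / f
    return rng.beta(a, b)


def _site_layout(rng: np.random.Generator, config: SimConfig) -> list[VariantSite]:
    lengths = np.array([l for _, l in config.chroms], dtype=float)
    share = lengths / lengths.sum()
    counts = np.floor(share * config.n_sites).astype(int)
    # largest-remainder top-up to hit n_sites exactly
    rem = config.n_sites - counts.sum()
    order = np.argsort(-(share * config.n_sites - counts))
    counts[order[:rem]] += 1

    nucs = np.array(list("ACGT"))
    sites: list[VariantSite] = []
    for (name, length), k in zip(config.chroms, counts):
        lo, hi = config.edge_margin + 1, length - config.edge_margin
        pos = rng.choice(np.arange(lo, hi + 1), size=k, replace=False)
        pos.sort()
        refs = nucs[rng.integers(0, 4, size=k)]
        for p_, r_ in zip(pos, refs):
            alt = rng.choice([n for n in "ACGT" if n != r_])
            sites.append(VariantSite(name, int(p_), str(r_), str(alt)))
    return sites


def simulate_frequencies(config: SimConfig) -> SimTruth:
    """Draw ancestral and hierarchical per-population allele frequencies."""
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0)))
    sites = _site_layout(rng, config)
    anc = rng.uniform(config.ancestral_low, config.ancestral_high, size=config.n_sites)

    breed_freqs = {
        b: _balding_nichols(rng, anc, config.f_breed) for b in config.breeds
    }
    pops = config.populations
    pop_freqs = np.empty((len(pops), config.n_sites))
    for i, p in enumerate(pops):
        b = config.breed_of[p]
        if p == b:  # breed with no nested types
            pop_freqs[i] = breed_freqs[b]
        else:
            pop_freqs[i] = _balding_nichols(rng, breed_freqs[b], config.f_type)
    return SimTruth(
        sites=sites,
        ancestral=anc,
        pops=pops,
        pop_freqs=pop_freqs,
        breed_freqs=breed_freqs,
    )


def simulate_genotypes(truth: SimTruth, config: SimConfig) -> GenotypeMatrix:
    """Draw genotypes, missingness and depth for the configured cohort.

    The last ``n_failed_samples`` samples of the cohort get the elevated
    ``failed_missingness`` rate (library-failure analogue); their labels are
    unchanged.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    n_per = config.samples_per_pop
    samples: list[str] = []
    labels: list[str] = []
    rows: list[np.ndarray] = []
    for i, p in enumerate(truth.pops):
        g = rng.binomial(2, truth.pop_freqs[i], size=(n_per, config.n_sites))
        rows.append(g)
        samples.extend(f"{p}-{j + 1}" for j in range(n_per))
        labels.extend([p] * n_per)
    calls = np.concatenate(rows, axis=0).astype(np.int8)

    n_total = calls.shape[0]
    miss_rate = np.full(n_total, config.missingness)
    if config.n_failed_samples:
        miss_rate[n_total - config.n_failed_samples :] = config.failed_missingness
    mask = rng.random(calls.shape) < miss_rate[:, None]
    calls[mask] = -1
    depth = rng.poisson(config.depth_mean, size=calls.shape).astype(np.int32)
    return GenotypeMatrix(
        sites=list(truth.sites),
        samples=samples,
        populations=labels,
        calls=calls,
        depth=depth,
        meta={"seed": config.seed},
    )


def write_popmap(gm: GenotypeMatrix, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{s}\t{p}\n" for s, p in zip(gm.samples, gm.populations))
    )


def write_reference(
    config: SimConfig,
    truth: SimTruth,
    fasta_path: str | Path,
    gff3_path: str | Path | None = None,
    gene_every: int = 20_000,
    kmer: int = 31,
) -> SimTruth:
    """Write a seeded random genome consistent with the simulated sites.

    Each variant site's reference base is forced to its ref allele.  Planted
    repeats copy the central k-mer around the named site to extra loci
    (recorded in ``truth.planted``) so homology screens have ground truth.
    Toy gene models (one gene per ``gene_every`` bp, two exons with CDS and
    UTRs, alternating strand) are written as GFF3 when requested.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    nucs = np.array(list("ACGT"))
    contigs: dict[str, np.ndarray] = {
        name: nucs[rng.integers(0, 4, size=length)]
        for name, length in config.chroms
    }
    for s in truth.sites:
        contigs[s.chrom][s.pos - 1] = s.ref

    site_pos: dict[str, set[int]] = {}
    for s in truth.sites:
        site_pos.setdefault(s.chrom, set()).add(s.pos)

    truth.planted = []
    half = kmer // 2
    for site_idx, copies in config.planted_repeats:
        site = truth.sites[site_idx]
        seq = contigs[site.chrom]
        start0 = site.pos - 1 - half
        motif = seq[start0 : start0 + kmer].copy()
        truth.planted.append((site.chrom, site.pos - half, "".join(motif)))
        chrom_names = list(contigs)
        placed = 0
        while placed < copies - 1:
            cname = chrom_names[int(rng.integers(0, len(chrom_names)))]
            target = contigs[cname]
            pos0 = int(rng.integers(0, len(target) - kmer))
            # avoid stamping over variant sites or earlier plants
            span = range(pos0 + 1, pos0 + kmer + 1)
            if any(p in site_pos.get(cname, ()) for p in span):
                continue
            if any(
                c == cname and not (pos0 + kmer + 1 <= p or p + kmer <= pos0 + 1)
                for c, p, _ in truth.planted
            ):
                continue
            target[pos0 : pos0 + kmer] = motif
            truth.planted.append((cname, pos0 + 1, "".join(motif)))
            placed += 1

    with open(fasta_path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            s = "".join(seq)
            for i in range(0, len(s), 80):
                fh.write(s[i : i + 80] + "\n")

    if gff3_path is not None:
        _write_toy_gff3(config, gff3_path, gene_every)
    return truth


def _write_toy_gff3(config: SimConfig, path: str | Path, gene_every: int) -> None:
    lines = ["##gff-version 3"]
    for name, length in config.chroms:
        lines.append(f"##sequence-region {name} 1 {length}")
    g = 0
    for name, length in config.chroms:
        for start in range(5_000, length - 5_000, gene_every):
            g += 1
            gid = f"gene{g}"
            strand = "+" if g % 2 else "-"
            end = start + 3_999
            # two exons of 1 kb separated by a 2 kb intron
            ex1 = (start, start + 999)
            ex2 = (end - 999, end)
            if strand == "+":
                utr5, utr3 = (ex1[0], ex1[0] + 199), (ex2[1] - 199, ex2[1])
                cds = [(ex1[0] + 200, ex1[1]), (ex2[0], ex2[1] - 200)]
            else:
                utr5, utr3 = (ex2[1] - 199, ex2[1]), (ex1[0], ex1[0] + 199)
                cds = [(ex1[0] + 200, ex1[1]), (ex2[0], ex2[1] - 200)]

            def row(ftype: str, s: int, e: int, parent: str, suffix: str) -> str:
                return (
                    f"{name}\tsnpanel_sim\t{ftype}\t{s}\t{e}\t.\t{strand}\t.\t"
                    f"ID={gid}.{suffix};Parent={parent}"
                )

            lines.append(
                f"{name}\tsnpanel_sim\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid}"
            )
            lines.append(
                f"{name}\tsnpanel_sim\tmRNA\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID={gid}.t1;Parent={gid}"
            )
            lines.append(row("exon", *ex1, f"{gid}.t1", "e1"))
            lines.append(row("exon", *ex2, f"{gid}.t1", "e2"))
            lines.append(row("CDS", *cds[0], f"{gid}.t1", "c1"))
            lines.append(row("CDS", *cds[1], f"{gid}.t1", "c2"))
            lines.append(row("five_prime_UTR", *utr5, f"{gid}.t1", "u5"))
            lines.append(row("three_prime_UTR", *utr3, f"{gid}.t1", "u3"))
    Path(path).write_text("\n".join(lines) + "\n")


def simulate_cohort(config: SimConfig) -> tuple[SimTruth, GenotypeMatrix]:
    """Convenience: frequencies then genotypes in one call."""
    truth = simulate_frequencies(config)
    return truth, simulate_genotypes(truth, config)
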