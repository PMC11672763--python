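"""Probe feasibility: flanking context, GC bounds, genome homology count.

A candidate site is probe-feasible when a 110 bp window centred on it can be
extracted from the reference (centre convention: 55 bases left of the site
base, 54 right — the site sits at 1-based offset 56), the window's GC
fraction lies in [0.30, 0.70] (closed interval), and the window's central
31-mer occurs at most 5 times in the genome counting both strands.

The k-mer occurrence count is a documented, reproducible stand-in for the
unstated vendor homology screen; ``k`` and the hit cap are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .genotypes import VariantSite

_IUPAC = frozenset("ACGTRYSWKMBDHVN")
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

DEFAULT_PROBE_LENGTH = 110
DEFAULT_KMER = 31
DEFAULT_GC_LO = 0.30
DEFAULT_GC_HI = 0.70
DEFAULT_MAX_HITS = 5


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ProbeContext:
    """Evaluated probe window for one site.

    ``sequence`` is None when extraction failed; ``fail_reason`` carries the
    first criterion violated (``edge``, ``ref_mismatch``, ``ambiguous_base``,
    ``gc``, ``homology``) or None when all criteria pass.
    """

    site_id: str
    sequence: str | None = None
    gc_fraction: float | None = None
    homology_hits: int | None = None
    gc_ok: bool | None = None
    homology_ok: bool | None = None
    fail_reason: str | None = None

    @property
    def passed(self) -> bool:
        return self.fail_reason is None


class _Genome:
    """Uppercased in-memory contig store built from FASTA or a mapping."""

    def __init__(self, source: str | Path | Mapping[str, str]):
        if isinstance(source, Mapping):
            self.contigs = {k: str(v).upper() for k, v in source.items()}
        else:
            from pyfaidx import Fasta

            fa = Fasta(str(source), sequence_always_upper=True)
            self.contigs = {name: str(fa[name][:]) for name in fa.keys()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.contigs

    def __getitem__(self, chrom: str) -> str:
        return self.contigs[chrom]


def load_genome(source: str | Path | Mapping[str, str]) -> _Genome:
    """Load a reference once for repeated context/homology queries."""
    return source if isinstance(source, _Genome) else _Genome(source)


def extract_context(
    ref: str | Path | Mapping[str, str] | _Genome,
    site: VariantSite,
    length: int = DEFAULT_PROBE_LENGTH,
) -> ProbeContext:
    """Extract the probe window around a site.

    The window covers reference positions [pos - ceil(L/2), pos + floor(L/2) - 1]
    (for L = 110: [pos-55, pos+54]).  Sites too close to a contig end are
    rejected with reason ``edge``; a reference base disagreeing with the
    site's ref allele rejects with ``ref_mismatch``.
    """
    genome = load_genome(ref)
    if site.chrom not in genome:
        raise KeyError(f"chromosome {site.chrom!r} not in reference")
    left = length // 2
    start = site.pos - left  # 1-based
    end = start + length - 1
    contig = genome[site.chrom]
    if start < 1 or end > len(contig):
        return ProbeContext(site_id=site.id, fail_reason="edge")
    seq = contig[start - 1 : end].upper()
    if seq[left] != site.ref:
        return ProbeContext(site_id=site.id, sequence=seq, fail_reason="ref_mismatch")
    return ProbeContext(site_id=site.id, sequence=seq)


def gc_pass(
    seq: str, lo: float = DEFAULT_GC_LO, hi: float = DEFAULT_GC_HI
) -> tuple[float, bool]:
    """GC fraction of a sequence and whether it lies in [lo, hi] (inclusive).

    Sequences containing any ambiguity code (including N) fail regardless of
    their GC fraction; non-IUPAC characters raise ``ValueError``.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    bad = set(seq) - _IUPAC
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    ambiguous = bool(set(seq) - frozenset("ACGT"))
    return gc, (not ambiguous) and lo <= gc <= hi


def _count_overlapping(haystack: str, needle: str) -> int:
    count = 0
    i = haystack.find(needle)
    while i != -1:
        count += 1
        i = haystack.find(needle, i + 1)
    return count


def homology_hits(
    seq: str,
    genome: str | Path | Mapping[str, str] | _Genome,
    k: int = DEFAULT_KMER,
    max_hits: int = DEFAULT_MAX_HITS,
) -> tuple[int, bool]:
    """Count genomic occurrences of the probe's central k-mer, both strands.

    Overlapping occurrences count; the locus itself is one occurrence so the
    count is >= 1 for a window taken from the genome.  Pass iff count <=
    ``max_hits``.
    """
    seq = seq.upper()
    if "N" in seq:
        raise ValueError("probe contains N; homology undefined")
    if k > len(seq):
        raise ValueError(f"k={k} exceeds probe length {len(seq)}")
    center = len(seq) // 2
    half = k // 2
    kmer = seq[center - half : center - half + k]
    rc = reverse_complement(kmer)
    g = load_genome(genome)
    count = 0
    for contig in g.contigs.values():
        count += _count_overlapping(contig, kmer)
        if rc != kmer:  # odd k can never be its own reverse complement
            count += _count_overlapping(contig, rc)
    return count, count <= max_hits


def evaluate_probe(
    genome: _Genome | str | Path | Mapping[str, str],
    site: VariantSite,
    length: int = DEFAULT_PROBE_LENGTH,
    k: int = DEFAULT_KMER,
    gc_lo: float = DEFAULT_GC_LO,
    gc_hi: float = DEFAULT_GC_HI,
    max_hits: int = DEFAULT_MAX_HITS,
) -> ProbeContext:
    """Run all probe criteria for one site; stops at the first failure."""
    genome = load_genome(genome)
    ctx = extract_context(genome, site, length)
    if ctx.sequence is None or ctx.fail_reason is not None:
        return ctx
    if set(ctx.sequence) - frozenset("ACGT"):
        ctx.fail_reason = "ambiguous_base"
        return ctx
    ctx.gc_fraction, ctx.gc_ok = gc_pass(ctx.sequence, gc_lo, gc_hi)
    if not ctx.gc_ok:
        ctx.fail_reason = "gc"
        return ctx
    ctx.homology_hits, ctx.homology_ok = homology_hits(ctx.sequence, genome, k, max_hits)
    if not ctx.homology_ok:
        ctx.fail_reason = "homology"
    return ctx


def evaluate_probes(
    genome: str | Path | Mapping[str, str] | _Genome,
    sites: Iterable[VariantSite],
    **kwargs,
) -> pd.DataFrame:
    """Probe report for many sites: site_id, sequence, gc, hits, pass, reason."""
    genome = load_genome(genome)
    rows = []
    for site in sites:
        ctx = evaluate_probe(genome, site, **kwargs)
        rows.append(
            {
                "site_id": ctx.site_id,
                "sequence": ctx.sequence or "",
                "gc_fraction": ctx.gc_fraction,
                "homology_hits": ctx.homology_hits,
                "pass": ctx.passed,
                "fail_reason": ctx.fail_reason or "",
            }
        )
    return pd.DataFrame(rows)
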