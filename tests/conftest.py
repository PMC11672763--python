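import numpy as np
import pytest

from snpanel.genotypes import GenotypeMatrix, VariantSite
from snpanel.synth import SimConfig


def make_gm(calls, pops=None, depth=None, chrom="1", start_pos=100, spacing=1000):
    """Build a GenotypeMatrix from a (samples x sites) array of dosages.

    -1 encodes MISSING.  Sites are laid on one chromosome with fixed
    spacing; ref/alt alternate A/G.
    """
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_sites = calls.shape
    sites = [
        VariantSite(chrom, start_pos + i * spacing, "A", "G") for i in range(n_sites)
    ]
    samples = [f"S{j}" for j in range(n_samples)]
    if pops is None:
        pops = ["P1"] * n_samples
    return GenotypeMatrix(
        sites=sites, samples=samples, populations=list(pops), calls=calls, depth=depth
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_cfg():
    return SimConfig(
        seed=11,
        samples_per_pop=12,
        n_sites=800,
        chroms=(("1", 300_000), ("2", 300_000), ("3", 200_000), ("X", 150_000), ("Y", 80_000)),
    )


@pytest.fixture
def vcf_writer(tmp_path):
    """Write raw VCF text with a minimal header for the given samples."""

    def _write(name, samples, records, extra_header=()):
        lines = ["##fileformat=VCFv4.2"]
        lines += list(extra_header)
        lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">')
        lines.append(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
        )
        lines += list(records)
        p = tmp_path / name
        p.write_text("\n".join(lines) + "\n")
        return p

    return _write


@pytest.fixture
def popmap_writer(tmp_path):
    def _write(name, mapping):
        p = tmp_path / name
        p.write_text("".join(f"{s}\t{pop}\n" for s, pop in mapping.items()))
        return p

    return _write
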