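import numpy as np
import pytest

from selsig.gio import GenotypeMatrix, Variant


def make_matrix(calls, positions=None, chrom="1", pops=None, samples=None):
    """Build a GenotypeMatrix from a dosage array (variants x samples).

    ``chrom`` may be a single label or one label per variant; ``pops`` one
    population label per sample (default: all "P1").
    """
    calls = np.asarray(calls, dtype=np.int8)
    n_var, n_samp = calls.shape
    if positions is None:
        positions = np.arange(1, n_var + 1) * 1000
    if isinstance(chrom, str):
        chroms = [chrom] * n_var
    else:
        chroms = list(chrom)
    if samples is None:
        samples = [f"S{j + 1}" for j in range(n_samp)]
    if pops is None:
        pops = ["P1"] * n_samp
    variants = [
        Variant(chrom=c, pos=int(p), ref="A", alt="G")
        for c, p in zip(chroms, positions)
    ]
    return GenotypeMatrix(
        variants=variants,
        samples=samples,
        calls=calls,
        pop_of=dict(zip(samples, pops)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230412)
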