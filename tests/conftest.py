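import numpy as np
import pytest

from methylhmm.genome_context import CONTEXTS_6, Methylome


def make_methylome(
    positions,
    m,
    r,
    contexts=None,
    chrom="chr1",
    strands=None,
    context_names=CONTEXTS_6,
):
    """Small hand-built methylome for unit tests."""
    n = len(positions)
    ctx = np.zeros(n, dtype=np.int16) if contexts is None else np.asarray(
        contexts, dtype=np.int16
    )
    chroms = (
        np.full(n, chrom, dtype=object)
        if isinstance(chrom, str)
        else np.asarray(chrom, dtype=object)
    )
    return Methylome(
        chrom=chroms,
        position=np.asarray(positions, dtype=np.int64),
        strand=np.full(n, "+", dtype="<U1") if strands is None else np.asarray(strands),
        context=ctx,
        context_valid=ctx >= 0,
        m=np.asarray(m, dtype=np.int64),
        r=np.asarray(r, dtype=np.int64),
        contexts=context_names,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_simulated():
    """A modest simulated methylome shared by read-only tests."""
    from methylhmm.simulate import simulate_methylome

    return simulate_methylome(20_000, seed=101)
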