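import numpy as np
import pytest

from spliceinfo.infomodel import SiteKind, TrainingAlignment, build_weight_matrix
from spliceinfo.synthetic import CrypticSpec, TruthModel, build_locus


@pytest.fixture(scope="session")
def truth():
    return TruthModel(seed=1)


@pytest.fixture(scope="session")
def locus(truth):
    return build_locus(truth, 42)


@pytest.fixture(scope="session")
def cryptic_locus():
    """Locus with a strong cryptic donor 12 nt into the first intron and a
    weak cryptic donor 100 nt deep (pseudoexon geometry)."""
    truth = TruthModel(
        seed=2,
        cryptic_specs=(
            CrypticSpec(SiteKind.DONOR, junction_index=0, offset=12, target_ri=8.0),
            CrypticSpec(SiteKind.DONOR, junction_index=2, offset=100, target_ri=1.0),
        ),
    )
    return build_locus(truth, 7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_alignment(rng, n=30, length=8, kind=SiteKind.DONOR, window_start=-3):
    seqs = tuple(
        "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
        for _ in range(n)
    )
    return TrainingAlignment(site_kind=kind, window_start=window_start, sequences=seqs)


@pytest.fixture()
def random_matrix(rng):
    aln = random_alignment(rng)
    return build_weight_matrix(aln, pseudocount=0.25), aln
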