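import numpy as np
import pytest

from polydesign import (AlleleFrequencyTable, CleavageModel, Epitope,
                        FlankedEpitope, MhcPssm, RunConfig, TapMatrix)
from polydesign.core import AMINO_ACIDS
from polydesign.fixtures import (make_class1_pssm, make_cleavage_model,
                                 make_tap_matrix, _pattern_on_p1prime)


def make_flanked(seq: str, eid: str = "e1", flank: str = "") -> FlankedEpitope:
    return FlankedEpitope(
        epitope=Epitope(id=eid, sequence=seq),
        flank=flank,
        tap_score_before=0.0,
        tap_score_after=0.0,
    )


def zero_pssm(allele: str = "HLA-A*02:01", length: int = 9, intercept: float = 0.0) -> MhcPssm:
    weights = {(i, aa): 0.0 for i in range(1, length + 1) for aa in AMINO_ACIDS}
    return MhcPssm(allele=allele, length=length, weights=weights, intercept=intercept)


def p1prime_model(kind: str, ranks: dict[str, int], default: int = 6) -> CleavageModel:
    """Cleavage model whose rank depends only on the residue after the bond."""
    patterns = tuple(_pattern_on_p1prime(aa, r) for aa, r in ranks.items())
    return CleavageModel(kind=kind, upstream=4, downstream=2,
                         patterns=patterns, default_rank=default)


@pytest.fixture
def zero_tap() -> TapMatrix:
    return TapMatrix(contributions={(role, aa): 0.0
                                    for role in ("N1", "N2", "N3", "C")
                                    for aa in AMINO_ACIDS})


@pytest.fixture
def neutral_models() -> tuple[CleavageModel, CleavageModel]:
    """Everything cleaves efficiently: empty tables, default rank 1."""
    pr = CleavageModel(kind="proteasome", default_rank=1)
    impr = CleavageModel(kind="immunoproteasome", default_rank=1)
    return pr, impr


@pytest.fixture
def empty_freqs() -> AlleleFrequencyTable:
    return AlleleFrequencyTable()


@pytest.fixture
def config() -> RunConfig:
    return RunConfig(tap_threshold=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20131010)
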