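import numpy as np
import pytest

from polydesign import (AlleleFrequencyTable, MhcPssm, RunConfig, parse_motif,
                        scan_th_cores, select_fragments, join_fragments)
from polydesign.core import AMINO_ACIDS
from polydesign.junctions import enumerate_spacers, evaluate_junction
from polydesign.tap import FlankedEpitope
from polydesign.core import Epitope
from polydesign.thelper import (CORE_LENGTH, EXTENSION, MAX_FRAGMENT,
                                MIN_FRAGMENT, ThFragment, _window_stats)
from tests.conftest import p1prime_model, zero_pssm


def pssm_hitting(window_peptide: str, allele: str = "DRB1*01:01") -> MhcPssm:
    """Class-II matrix that scores exactly `window_peptide` at 9 and others <= 0."""
    weights = {(i, aa): -1.0 for i in range(1, 10) for aa in AMINO_ACIDS}
    for i, aa in enumerate(window_peptide, 1):
        weights[(i, aa)] = 1.0
    return MhcPssm(allele=allele, length=9, weights=weights, intercept=0.0, mhc_class="II")


@pytest.fixture
def antigen(rng):
    return "".join(AMINO_ACIDS[k] for k in rng.integers(0, 20, size=80))


class TestScanThCores:
    def test_zero_matrices_positive_threshold_no_hits(self, antigen):
        panel = [zero_pssm("DRB1*01:01"), zero_pssm("DRB1*04:01")]
        assert scan_th_cores(antigen, panel, 1.0) == {}

    def test_planted_single_window_reported_one_based(self, antigen):
        target = antigen[30:39]
        # guard against chance duplicates of the planted window
        if sum(antigen[i:i + 9] == target for i in range(len(antigen) - 8)) != 1:
            pytest.skip("planted window not unique in random antigen")
        hits = scan_th_cores(antigen, [pssm_hitting(target)], 9.0)
        assert hits == {"DRB1*01:01": [31]}

    def test_hit_positions_invariant_under_panel_order(self, antigen):
        p1 = pssm_hitting(antigen[10:19], "DRB1*01:01")
        p2 = pssm_hitting(antigen[40:49], "DRB1*04:01")
        assert scan_th_cores(antigen, [p1, p2], 9.0) == scan_th_cores(antigen, [p2, p1], 9.0)

    def test_wrong_core_length_rejected(self, antigen):
        with pytest.raises(ValueError, match="9"):
            scan_th_cores(antigen, [zero_pssm("DRB1*01:01", length=10)], 0.0)


def fragment_oracle(antigen: str, hits: dict) -> ThFragment:
    """Independent exhaustive evaluation of every 20-40 window; best single fragment."""
    best = None
    n = len(antigen)
    for length in range(MIN_FRAGMENT, min(MAX_FRAGMENT, n) + 1):
        for start in range(1, n - length + 2):
            end = start + length - 1
            n_alleles, n_eps = _window_stats(hits, start, end)
            if n_eps == 0:
                continue
            key = (-n_alleles, -n_eps, length, start)
            if best is None or key < best[0]:
                best = (key, start, end, n_alleles, n_eps)
    _, start, end, n_alleles, n_eps = best
    return start, end, n_alleles, n_eps


class TestSelectFragments:
    def test_overlapping_hit_cluster_covered_by_minimal_window(self, antigen):
        # three overlapping 9-mer cores spanning positions 31..45 (13-residue offsets)
        hits = {"DRB1*01:01": [31], "DRB1*04:01": [33, 37]}
        frags = select_fragments("ag", antigen, hits)
        assert len(frags) == 1
        f = frags[0]
        assert f.core_length == MIN_FRAGMENT  # 15-residue span padded to the floor
        assert f.core_start <= 31 and f.core_end >= 37 + CORE_LENGTH - 1
        assert (f.n_alleles, f.n_epitopes) == (2, 3)
        start, end, n_alleles, n_eps = fragment_oracle(antigen, hits)
        assert (f.core_start, f.core_end, f.n_alleles, f.n_epitopes) == \
               (start, end, n_alleles, n_eps)

    def test_extension_clamped_at_antigen_start(self):
        antigen = "ACDEFGHIKLMNPQRSTVWYACDEF"  # length 25
        hits = {"DRB1*01:01": [1]}
        (f,) = select_fragments("ag", antigen, hits)
        assert f.extended_start == 1
        assert f.extended_end == min(25, f.core_end + EXTENSION)
        assert f.sequence == antigen[f.extended_start - 1 : f.extended_end]

    def test_no_hits_gives_empty_list(self, antigen):
        assert select_fragments("ag", antigen, {}) == []

    def test_short_antigen_warns_and_returns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            assert select_fragments("ag", "ACDEFGHIKLMNPQR", {"x": [1]}) == []
        assert caplog.records

    def test_accepted_cores_disjoint_and_lengths_in_range(self, rng):
        antigen = "".join(AMINO_ACIDS[k] for k in rng.integers(0, 20, size=200))
        hits = {
            f"DRB1*{i:02d}": sorted(set(int(x) for x in rng.integers(1, 190, size=6)))
            for i in range(4)
        }
        frags = select_fragments("ag", antigen, hits)
        assert frags  # dense hits guarantee at least one window
        for f in frags:
            assert MIN_FRAGMENT <= f.core_length <= MAX_FRAGMENT
            assert f.core_start - f.extended_start <= EXTENSION
            assert f.extended_end - f.core_end <= EXTENSION
        intervals = sorted((f.core_start, f.core_end) for f in frags)
        assert all(a[1] < b[0] for a, b in zip(intervals, intervals[1:]))
        # determinism
        again = select_fragments("ag", antigen, hits)
        assert [(f.core_start, f.core_end) for f in again] == \
               [(f.core_start, f.core_end) for f in frags]


class TestJoinFragments:
    def _frag(self, seq, i=1):
        return ThFragment(antigen_id="ag", core_start=1, core_end=len(seq),
                          extended_start=1, extended_end=len(seq),
                          n_epitopes=1, n_alleles=1, sequence=seq)

    def test_single_fragment_identity(self, neutral_models, empty_freqs, config):
        pr, impr = neutral_models
        f = self._frag("ACDEFGHIKLMNPQRSTVWYACDEF")
        module = join_fragments([f], pr, impr, [], empty_freqs, config)
        assert module.sequence == f.sequence and module.junctions == ()

    def test_junction_drawn_from_kr_motif_candidates(self, empty_freqs, config, rng):
        pr = p1prime_model("proteasome", {"K": 1, "R": 2}, default=10)
        impr = p1prime_model("immunoproteasome", {"K": 2}, default=10)
        f1 = self._frag("".join(AMINO_ACIDS[k] for k in rng.integers(0, 20, size=25)))
        f2 = self._frag("".join(AMINO_ACIDS[k] for k in rng.integers(0, 20, size=25)))
        module = join_fragments([f1, f2], pr, impr, [], empty_freqs, config)
        (junction,) = module.junctions
        assert junction.spacer in {"", "K", "R", "KK", "KR", "RK", "RR"}
        assert module.sequence == f1.sequence + junction.spacer + f2.sequence

    def test_chosen_spacer_is_minimal_weight(self, empty_freqs, config, rng):
        pr = p1prime_model("proteasome",
                           {aa: int(r) for aa, r in zip(AMINO_ACIDS, rng.integers(1, 12, 20))},
                           default=7)
        impr = p1prime_model("immunoproteasome",
                             {aa: int(r) for aa, r in zip(AMINO_ACIDS, rng.integers(1, 12, 20))},
                             default=7)
        f1 = self._frag("".join(AMINO_ACIDS[k] for k in rng.integers(0, 20, size=25)))
        f2 = self._frag("".join(AMINO_ACIDS[k] for k in rng.integers(0, 20, size=25)))
        module = join_fragments([f1, f2], pr, impr, [], empty_freqs, config)
        motif = parse_motif("[KR][KR]")
        left = FlankedEpitope(Epitope(id="th1", sequence=f1.sequence), "", 0.0, 0.0)
        right = FlankedEpitope(Epitope(id="th2", sequence=f2.sequence), "", 0.0, 0.0)
        weights = {
            ss: evaluate_junction(left, right, ss, pr, impr, [], empty_freqs,
                                  config, set()).weight
            for ss in enumerate_spacers(motif)
        }
        assert module.junctions[0].weight == pytest.approx(min(weights.values()))
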