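import math

import numpy as np
import pytest

from barcodegap.best_match import (
    bcm_threshold,
    best_close_match_test,
    best_match_test,
)
from barcodegap.errors import InsufficientDataError, ThresholdError
from conftest import make_dm
from oracles import bcm_oracle, bm_oracle, percentile_oracle, random_labeled_matrix


def _clean_dm():
    ids = ["a1", "a2", "b1", "b2"]
    species = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    v = np.full((4, 4), 0.05)
    np.fill_diagonal(v, 0)
    v[0, 1] = v[1, 0] = 0.001
    v[2, 3] = v[3, 2] = 0.001
    return make_dm(ids, species, v)


class TestBestMatch:
    def test_clean_separation_all_correct(self):
        rep = best_match_test(_clean_dm())
        assert rep.pct_correct == 100.0
        assert rep.pct_unidentified == 0.0  # BM never abstains

    def test_tied_con_and_heterospecific_is_ambiguous(self):
        # a1's nearest neighbors at 0: a2 (conspecific) and b1 (heterospecific)
        ids = ["a1", "a2", "b1", "b2"]
        species = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        v = np.full((4, 4), 0.04)
        np.fill_diagonal(v, 0)
        v[0, 1] = v[1, 0] = 0.0
        v[0, 2] = v[2, 0] = 0.0
        dm = make_dm(ids, species, v)
        rep = best_match_test(dm)
        verdict = {v_.sample_id: v_.verdict for v_ in rep.verdicts}
        assert verdict["a1"] == "ambiguous"
        assert verdict["a2"] == "correct"

    def test_nearest_heterospecific_is_incorrect(self):
        ids = ["a1", "a2", "b1", "b2"]
        species = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        v = np.full((4, 4), 0.05)
        np.fill_diagonal(v, 0)
        v[0, 2] = v[2, 0] = 0.001  # a1 closest to b1
        dm = make_dm(ids, species, v)
        verdict = {v_.sample_id: v_.verdict for v_ in best_match_test(dm).verdicts}
        assert verdict["a1"] == "incorrect"

    def test_query_never_matches_itself(self):
        rep = best_match_test(_clean_dm())
        for v in rep.verdicts:
            assert v.sample_id not in v.best_match_ids

    def test_singletons_are_matches_not_queries(self):
        ids = ["a1", "a2", "x1"]
        species = {"a1": "A", "a2": "A", "x1": "X"}
        v = np.array([[0, 0.03, 0.001], [0.03, 0, 0.04], [0.001, 0.04, 0]])
        rep = best_match_test(make_dm(ids, species, v))
        assert rep.n_queries == 2  # x1 not evaluated
        verdict = {v_.sample_id: v_.verdict for v_ in rep.verdicts}
        assert verdict["a1"] == "incorrect"  # nearest is singleton x1

    def test_all_singletons_error(self):
        ids = ["a", "b"]
        v = np.array([[0, 0.05], [0.05, 0]])
        with pytest.raises(InsufficientDataError):
            best_match_test(make_dm(ids, {"a": "A", "b": "B"}, v))

    def test_percentages_invariant_to_uniform_scaling(self, rng):
        ids, species, values = random_labeled_matrix(rng, 20)
        dm = make_dm(ids, species, values)
        dm2 = make_dm(ids, species, np.asarray(values) * 3.7)
        r1, r2 = best_match_test(dm), best_match_test(dm2)
        assert [v.verdict for v in r1.verdicts] == [v.verdict for v in r2.verdicts]


class TestThreshold:
    def test_all_zero_intra_gives_zero(self):
        ids = ["a1", "a2", "b1", "b2"]
        species = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        v = np.full((4, 4), 0.05)
        np.fill_diagonal(v, 0)
        v[0, 1] = v[1, 0] = 0.0
        v[2, 3] = v[3, 2] = 0.0
        assert bcm_threshold(make_dm(ids, species, v)) == 0.0

    def test_single_pair_distribution(self):
        ids = ["a1", "a2", "b1"]
        species = {"a1": "A", "a2": "A", "b1": "B"}
        v = np.array([[0, 0.02, 0.06], [0.02, 0, 0.06], [0.06, 0.06, 0]])
        assert bcm_threshold(make_dm(ids, species, v)) == pytest.approx(0.02)

    def test_interpolated_percentile_matches_sort_oracle(self):
        intra = [0.01] * 19 + [0.10]
        # wire a dataset whose pooled intraspecific list is exactly `intra`:
        # two species x 5 individuals = 2 x C(5,2) = 20 conspecific pairs
        ids = [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
        species = {**{f"a{i}": "A" for i in range(5)}, **{f"b{i}": "B" for i in range(5)}}
        vals = iter(intra)
        n = 10
        v = np.full((n, n), 0.5)
        np.fill_diagonal(v, 0)
        for grp in (range(0, 5), range(5, 10)):
            grp = list(grp)
            for x in range(len(grp)):
                for y in range(x + 1, len(grp)):
                    val = next(vals)
                    v[grp[x], grp[y]] = v[grp[y], grp[x]] = val
        dm = make_dm(ids, species, v)
        assert sorted(dm.intra_distances()) == sorted(intra)
        got = bcm_threshold(dm, 95)
        assert got == pytest.approx(percentile_oracle(intra, 95), abs=1e-15)

    def test_no_intra_pairs_errors(self):
        ids = ["a", "b"]
        v = np.array([[0, 0.05], [0.05, 0]])
        with pytest.raises(ThresholdError):
            bcm_threshold(make_dm(ids, {"a": "A", "b": "B"}, v))


class TestBestCloseMatch:
    def test_threshold_below_everything_all_unidentified(self):
        dm = _clean_dm()
        rep = best_close_match_test(dm, threshold=0.0001)
        assert rep.pct_unidentified == 100.0

    def test_threshold_above_everything_equals_bm(self):
        dm = _clean_dm()
        bm = best_match_test(dm)
        bcm = best_close_match_test(dm, threshold=1.0)
        assert [v.verdict for v in bcm.verdicts] == [v.verdict for v in bm.verdicts]

    def test_boundary_tie_counts_as_within(self):
        dm = _clean_dm()
        rep = best_close_match_test(dm, threshold=0.001)  # == best distance
        assert rep.pct_unidentified == 0.0
        assert rep.pct_correct == 100.0

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(10):
            ids, species, values = random_labeled_matrix(rng, 22)
            dm = make_dm(ids, species, values)
            try:
                thr = bcm_threshold(dm)
            except ThresholdError:
                continue
            got = {v.sample_id: v.verdict for v in best_close_match_test(dm, thr).verdicts}
            want = {q: verdict for q, (verdict, _) in bcm_oracle(ids, species, values, thr).items()}
            assert got == want

    def test_bcm_never_beats_bm_on_incorrect(self, rng):
        for _ in range(10):
            ids, species, values = random_labeled_matrix(rng, 20)
            dm = make_dm(ids, species, values)
            try:
                thr = bcm_threshold(dm)
            except ThresholdError:
                continue
            bm = best_match_test(dm)
            bcm = best_close_match_test(dm, thr)
            assert bcm.pct_incorrect <= bm.pct_incorrect + 1e-9
            assert bcm.pct_correct <= bm.pct_correct + 1e-9

    def test_report_percentages_sum_to_100(self, rng):
        ids, species, values = random_labeled_matrix(rng, 20)
        dm = make_dm(ids, species, values)
        rep = best_close_match_test(dm, 0.02)
        total = rep.pct_correct + rep.pct_ambiguous + rep.pct_incorrect + rep.pct_unidentified
        assert total == pytest.approx(100.0)
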