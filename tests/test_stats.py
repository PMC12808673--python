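import numpy as np
import pytest

from thermoact.stats import (
    compare_model_errors, compare_params_by_state, dunn_posthoc,
    paired_cohens_d, parameter_separability,
)
from thermoact.state_space import SSParams


class TestCompareModelErrors:
    def test_null_type_one_error_near_nominal(self):
        """Kruskal-Wallis rejects ~5% of the time when all groups share a
        distribution (1000 Monte Carlo replicates)."""
        rejections = 0
        rng = np.random.default_rng(0)
        for _ in range(1000):
            groups = {m: rng.normal(0, 1, 8) for m in ("a", "b", "c")}
            rejections += compare_model_errors(groups).omnibus_p < 0.05
        assert 0.03 < rejections / 1000 < 0.07

    def test_large_shift_all_pairs_significant(self, rng):
        groups = {"a": rng.normal(0, 0.1, 15), "b": rng.normal(2, 0.1, 15),
                  "c": rng.normal(4, 0.1, 15)}
        comp = compare_model_errors(groups)
        assert comp.omnibus_p < 1e-6
        assert all(t.adjusted_p < 0.01 for t in comp.pairwise)

    def test_selective_detection(self, rng):
        groups = {"a": rng.normal(0, 0.3, 20), "b": rng.normal(0, 0.3, 20),
                  "c": rng.normal(3, 0.3, 20)}
        comp = compare_model_errors(groups)
        by_pair = {frozenset(t.pair): t.adjusted_p for t in comp.pairwise}
        assert by_pair[frozenset(("a", "c"))] < 0.01
        assert by_pair[frozenset(("b", "c"))] < 0.01
        assert by_pair[frozenset(("a", "b"))] > 0.05

    def test_degenerate_identical_values_rejected(self):
        with pytest.raises(ValueError):
            compare_model_errors({"a": np.ones(5), "b": np.ones(5)})


class TestDunn:
    def test_bh_adjustment_never_decreases_and_preserves_ranking(self, rng):
        groups = {g: rng.normal(i * 0.4, 1, 12) for i, g in enumerate("abcd")}
        tests = dunn_posthoc(groups)
        raw = np.array([t.raw_p for t in tests])
        adj = np.array([t.adjusted_p for t in tests])
        assert np.all(adj >= raw - 1e-15)
        # weak order preserved (BH may collapse neighbours into ties)
        order = np.argsort(raw)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_invariant_to_group_relabeling(self, rng):
        vals = {g: rng.normal(0, 1, 10) for g in "abc"}
        t1 = {frozenset(t.pair): t.raw_p for t in dunn_posthoc(vals)}
        reordered = {g: vals[g] for g in reversed(list(vals))}
        t2 = {frozenset(t.pair): t.raw_p for t in dunn_posthoc(reordered)}
        for pair in t1:
            assert t1[pair] == pytest.approx(t2[pair])


class TestCompareParamsByState:
    @staticmethod
    def _grouped(rng, male_shift=0.0, e_shift=0.0):
        ids = [f"f{i}" for i in range(13)]
        return {
            "M": rng.normal(35.2 + male_shift, 0.1, 13),
            "NE": {m: rng.normal(35.7, 0.1) for m in ids},
            "E": {m: rng.normal(35.7 + e_shift, 0.1) for m in ids},
        }

    def test_male_shift_detected_in_correct_direction(self, rng):
        comp = compare_params_by_state(self._grouped(rng, male_shift=-0.5))
        report = {frozenset(t.pair): t.raw_p for t in comp.pairwise}
        assert report[frozenset(("M", "NE"))] < 0.001
        assert np.median(comp.groups["M"]) < np.median(comp.groups["NE"])

    def test_identical_ne_e_not_significant(self, rng):
        ps = [compare_params_by_state(self._grouped(np.random.default_rng(s)))
              .pairwise[-1].raw_p for s in range(40)]
        assert np.mean(np.array(ps) < 0.05) < 0.2

    def test_e_shift_detected_by_paired_test(self, rng):
        comp = compare_params_by_state(self._grouped(rng, e_shift=-0.3))
        wilcoxon = [t for t in comp.pairwise if t.test_name == "wilcoxon"][0]
        assert wilcoxon.raw_p < 0.01

    def test_unpaired_input_rejected(self, rng):
        grouped = self._grouped(rng)
        grouped["E"] = {"other": 35.0}
        with pytest.raises(ValueError, match="paired"):
            compare_params_by_state(grouped)


class TestPairedCohensD:
    def test_consistent_difference_gives_large_d(self, rng):
        b = rng.normal(0, 1, 50)
        a = b + 1.0 + rng.normal(0, 0.01, 50)
        assert paired_cohens_d(a, b) > 50

    def test_unit_effect_monte_carlo(self, rng):
        b = rng.normal(0, 1, 10000)
        a = b + rng.normal(1, 1, 10000)
        assert paired_cohens_d(a, b) == pytest.approx(1.0, abs=0.05)

    def test_null_near_zero(self, rng):
        b = rng.normal(0, 1, 5000)
        a = b + rng.normal(0, 1, 5000)
        assert abs(paired_cohens_d(a, b)) < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            paired_cohens_d([1.0, 2.0], [0.0, 1.0])


class TestSeparability:
    def test_separated_clouds_perfect(self, rng):
        pts = ([((35.0 + rng.normal(0, 0.05), 0.0016, -0.02), "M") for _ in range(13)]
               + [((36.5 + rng.normal(0, 0.05), 0.0016, -0.02), "F") for _ in range(13)])
        assert parameter_separability(pts) == 100.0

    def test_identical_distributions_near_chance(self):
        accs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            pts = [((35.5 + r.normal(0, 0.2), r.normal(0.0016, 2e-4),
                     r.normal(-0.02, 2e-3)), s)
                   for s in ("M", "F") for _ in range(13)]
            accs.append(parameter_separability(pts))
        # in-sample quadratic fit overfits above 50%, but stays far from 100%
        assert 50.0 <= np.mean(accs) < 90.0

    def test_accepts_ssparams_objects(self, rng):
        pts = ([(SSParams(0.0016, -0.02, 35.0 + rng.normal(0, 0.05)), "M")
                for _ in range(8)]
               + [(SSParams(0.0016, -0.02, 36.0 + rng.normal(0, 0.05)), "F")
                  for _ in range(8)])
        acc, report = parameter_separability(pts, include_report=True)
        assert acc == 100.0 and report["perfect_separation"]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            parameter_separability([((35.0, 0.001, -0.02), "M")] * 5)
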