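"""C-statistic, DeLong contrast, calibration, NRI, IDI against oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mips.metrics import c_statistic, calibration, delong_test, idi, nri


def brute_force_c(scores, outcomes):
    scores = np.asarray(scores, float)
    y = np.asarray(outcomes, bool)
    pos, neg = scores[y], scores[~y]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestCStatistic:
    def test_perfect_separation(self):
        c, _ = c_statistic([3, 4, 1, 2], [True, True, False, False])
        assert c == 1.0

    def test_worked_micro_example(self):
        # cases {0.9, 0.8}, controls {0.7, 0.9} -> 2.5/4
        c, _ = c_statistic([0.9, 0.8, 0.7, 0.9], [True, True, False, False])
        assert c == pytest.approx(0.625)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(10000)
        y = rng.random(10000) < 0.3
        c, _ = c_statistic(scores, y)
        assert abs(c - 0.5) < 0.02

    def test_matches_pair_counting_oracle_exactly(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = int(rng.integers(20, 200))
            scores = np.round(rng.random(n), 2)  # force ties
            y = rng.random(n) < 0.4
            if y.all() or not y.any():
                continue
            c, (lo, hi) = c_statistic(scores, y)
            assert c == pytest.approx(brute_force_c(scores, y), abs=1e-12)
            assert lo <= c <= hi

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            c_statistic([1, 2], [True, True])

    def test_delong_ci_coverage(self):
        # true AUC for N(1,1) vs N(0,1) scores = Phi(1/sqrt(2))
        from scipy.stats import norm

        true_auc = norm.cdf(1 / np.sqrt(2))
        rng = np.random.default_rng(2)
        covered = 0
        n_sim = 300
        for _ in range(n_sim):
            pos = rng.normal(1, 1, 120)
            neg = rng.normal(0, 1, 380)
            scores = np.concatenate([pos, neg])
            y = np.repeat([True, False], [120, 380])
            _, (lo, hi) = c_statistic(scores, y)
            covered += lo <= true_auc <= hi
        assert covered / n_sim >= 0.92


class TestDeLongTest:
    def test_identical_models(self):
        rng = np.random.default_rng(0)
        s = rng.random(200)
        y = rng.random(200) < 0.5
        res = delong_test(s, s, y)
        assert res["chi2"] == 0.0 and res["p"] == 1.0

    def test_null_p_values_superuniform(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(3)
        ps = []
        for _ in range(200):
            y = np.repeat([True, False], [150, 350])
            base = rng.normal(0, 1, 500) + 0.8 * y
            a = base + rng.normal(0, 0.7, 500)
            b = base + rng.normal(0, 0.7, 500)
            ps.append(delong_test(a, b, y)["p"])
        assert kstest(ps, "uniform", alternative="less").pvalue > 0.01

    def test_detects_genuinely_better_model(self):
        rng = np.random.default_rng(4)
        y = np.repeat([True, False], [400, 600])
        good = 1.5 * y + rng.normal(0, 1, 1000)
        bad = rng.normal(0, 1, 1000)
        res = delong_test(good, bad, y)
        assert res["c_a"] > res["c_b"]
        assert res["p"] < 1e-6


class TestCalibration:
    @staticmethod
    def _simulate(n=40000, seed=0):
        rng = np.random.default_rng(seed)
        lp = rng.normal(-1.5, 1.0, n)
        y = rng.random(n) < 1 / (1 + np.exp(-lp))
        return lp, y

    def test_well_calibrated_model(self):
        lp, y = self._simulate()
        res = calibration(lp, y)
        assert 0.9 <= res.slope <= 1.1
        assert -0.1 <= res.citl <= 0.1

    def test_doubling_lp_halves_slope(self):
        lp, y = self._simulate(seed=1)
        res = calibration(2 * lp, y)
        assert res.slope == pytest.approx(0.5, abs=0.05)

    def test_offset_shifts_citl(self):
        lp, y = self._simulate(seed=2)
        res = calibration(lp + 1.0, y)
        assert res.citl == pytest.approx(-1.0, abs=0.05)

    def test_constant_lp_rejected(self):
        with pytest.raises(ValueError):
            calibration(np.zeros(100), np.zeros(100, bool))


class TestNRI:
    def test_identical_models_zero(self):
        p = np.array([0.1, 0.2, 0.3, 0.4])
        y = np.array([True, True, False, False])
        res = nri(p, p, y, cutpoints=[0.25])
        assert res["continuous"].estimate == 0.0
        assert res["categorical"].estimate == 0.0
        assert res["continuous"].p == 1.0

    def test_three_subject_worked_example(self):
        # events move +0.10 and -0.05; the single non-event moves -0.20
        old = np.array([0.30, 0.40, 0.50])
        new = np.array([0.40, 0.35, 0.30])
        y = np.array([True, True, False])
        res = nri(old, new, y)
        assert res["continuous"].estimate == pytest.approx(1.0)

    def test_categorical_boundary_crossing(self):
        old = np.array([0.10, 0.20])
        new = np.array([0.20, 0.10])
        y = np.array([True, False])
        res = nri(old, new, y, cutpoints=[0.15])
        assert res["categorical"].estimate == pytest.approx(2.0)

    def test_brute_force_tabulation_small(self):
        rng = np.random.default_rng(5)
        old = rng.random(50)
        new = rng.random(50)
        y = rng.random(50) < 0.4
        res = nri(old, new, y)["continuous"]
        ev_up = np.mean(new[y] > old[y]); ev_dn = np.mean(new[y] < old[y])
        ne_up = np.mean(new[~y] > old[~y]); ne_dn = np.mean(new[~y] < old[~y])
        assert res.estimate == pytest.approx((ev_up - ev_dn) + (ne_dn - ne_up), abs=1e-12)

    def test_bounds_and_bad_inputs(self):
        rng = np.random.default_rng(6)
        old, new = rng.random(30), rng.random(30)
        y = rng.random(30) < 0.5
        res = nri(old, new, y)["continuous"]
        assert -2.0 <= res.estimate <= 2.0
        with pytest.raises(ValueError):
            nri(old, new, np.ones(30, bool))
        with pytest.raises(ValueError):
            nri(old, new, y, cutpoints=[0.5, 0.2])


class TestIDI:
    def test_identical_models_zero(self):
        p = np.array([0.2, 0.6, 0.3])
        y = np.array([True, False, False])
        res = idi(p, p, y)
        assert res.estimate == 0.0 and res.p == 1.0

    def test_worked_example(self):
        old = np.array([0.6, 0.8, 0.3])
        new = np.array([0.7, 0.9, 0.2])
        y = np.array([True, True, False])
        assert idi(old, new, y).estimate == pytest.approx(0.2)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_antisymmetric_under_model_swap(self, seed):
        rng = np.random.default_rng(seed)
        old, new = rng.random(40), rng.random(40)
        y = np.concatenate([[True, False], rng.random(38) < 0.5])
        assert idi(old, new, y).estimate == pytest.approx(-idi(new, old, y).estimate)
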