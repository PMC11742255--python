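"""Factorial tests, rank tests, correlation screen and the normality gate."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from soilcue.stats import (
    factorial_test,
    normality_gate,
    scheirer_ray_hare,
    spearman_screen,
    two_way_anova,
    wilcoxon_pair,
)


def factorial_frame(y, m, p):
    return pd.DataFrame({"response": y, "factor_m": m, "factor_p": p})


def two_by_two(rng, n_per_cell=10, shift=0.0):
    cells = [("AM", "non_rhizosphere"), ("AM", "rhizosphere"),
             ("ECM", "non_rhizosphere"), ("ECM", "rhizosphere")]
    frames = []
    for i, (m, p) in enumerate(cells):
        y = rng.normal(shift * (m == "ECM"), 1.0, n_per_cell)
        frames.append(factorial_frame(y, [m] * n_per_cell, [p] * n_per_cell))
    return pd.concat(frames, ignore_index=True)


class TestTwoWayAnova:
    def test_one_factor_collapse_equals_one_way_f(self, rng):
        y = rng.normal(size=24)
        m = ["AM"] * 12 + ["ECM"] * 12
        data = factorial_frame(y, m, ["non_rhizosphere"] * 24)
        table = two_way_anova(data)
        f_ref = sps.f_oneway(y[:12], y[12:])
        row = table[table["effect"] == "mycorrhizal_type"].iloc[0]
        assert row["statistic"] == pytest.approx(f_ref.statistic, rel=1e-9)
        assert row["p"] == pytest.approx(f_ref.pvalue, rel=1e-9)

    def test_location_invariance(self, rng):
        data = two_by_two(rng)
        shifted = data.assign(response=data["response"] + 1000.0)
        a = two_way_anova(data)["statistic"].to_numpy()
        b = two_way_anova(shifted)["statistic"].to_numpy()
        assert np.allclose(a, b)

    def test_detects_planted_main_effect(self, rng):
        data = two_by_two(rng, n_per_cell=20, shift=2.0)
        table = two_way_anova(data).set_index("effect")
        assert table.loc["mycorrhizal_type", "p"] < 1e-6
        assert table.loc["position", "p"] > 0.01

    def test_empty_cells_error(self, rng):
        data = factorial_frame(rng.normal(size=4), ["AM"] * 4, ["rhizosphere"] * 4)
        with pytest.raises(ValueError):
            two_way_anova(data)


class TestScheirerRayHare:
    def test_single_factor_reduction_equals_kruskal_wallis(self, rng):
        for _ in range(5):
            y = rng.normal(size=30)  # tie-free: equivalence is exact
            m = ["AM"] * 14 + ["ECM"] * 16
            data = factorial_frame(y, m, ["rhizosphere"] * 30)
            h_srh = scheirer_ray_hare(data).set_index("effect").loc[
                "mycorrhizal_type", "statistic"
            ]
            h_kw = sps.kruskal(y[:14], y[14:]).statistic
            assert h_srh == pytest.approx(h_kw, abs=1e-10)

    def test_single_factor_reduction_with_ties(self, rng):
        y = rng.integers(0, 4, size=30).astype(float)  # heavy ties
        m = ["AM"] * 15 + ["ECM"] * 15
        data = factorial_frame(y, m, ["rhizosphere"] * 30)
        h_srh = scheirer_ray_hare(data).set_index("effect").loc[
            "mycorrhizal_type", "statistic"
        ]
        h_kw = sps.kruskal(y[:15], y[15:]).statistic
        assert h_srh == pytest.approx(h_kw, abs=1e-10)

    def test_monotone_transform_invariance(self, rng):
        data = two_by_two(rng, shift=1.0)
        data = data.assign(response=data["response"] + 10.0)  # keep positive
        transformed = data.assign(response=np.exp(data["response"] / 5.0))
        a = scheirer_ray_hare(data)["statistic"].to_numpy()
        b = scheirer_ray_hare(transformed)["statistic"].to_numpy()
        assert np.allclose(a, b)

    def test_all_tied_gives_h_zero(self):
        data = two_by_two(np.random.default_rng(0)).assign(response=3.0)
        table = scheirer_ray_hare(data)
        assert (table["statistic"] == 0.0).all()
        assert (table["p"] == 1.0).all()


def exact_rank_sum_p(a, b):
    """Exhaustive-enumeration oracle for the one-sided rank-sum p-value.

    Enumerates all C(n+m, n) assignments of the pooled ranks to group a and
    counts those with a rank sum at least as large as observed.
    """
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n = len(a)
    observed = ranks[:n].sum()
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        total += 1
        if ranks[list(idx)].sum() >= observed - 1e-9:
            count += 1
    return count / total


class TestWilcoxon:
    def test_fully_separated_groups_exact_p(self):
        a = np.array([6.0, 7.0, 8.0, 9.0, 10.0])
        b = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        _, p = wilcoxon_pair(a, b, alternative="greater")
        assert p == pytest.approx(1.0 / 252.0)

    def test_exact_p_matches_enumeration_small_n(self, rng):
        for _ in range(5):
            a = rng.normal(size=4)
            b = rng.normal(0.5, 1.0, size=5)
            _, p = wilcoxon_pair(a, b, alternative="greater")
            assert p == pytest.approx(exact_rank_sum_p(a, b), abs=1e-12)

    def test_identical_groups_p_near_one(self):
        a = np.arange(1.0, 9.0)
        _, p = wilcoxon_pair(a, a.copy())
        assert p > 0.95

    def test_label_swap_symmetry(self, rng):
        a, b = rng.normal(size=8), rng.normal(1.0, 1.0, size=8)
        _, p_ab = wilcoxon_pair(a, b)
        _, p_ba = wilcoxon_pair(b, a)
        assert p_ab == pytest.approx(p_ba)

    def test_paired_mode(self, rng):
        a = rng.normal(size=10)
        stat, p = wilcoxon_pair(a, a + rng.normal(1.0, 0.1, 10), paired=True)
        assert p < 0.01

    def test_too_small_groups(self):
        with pytest.raises(ValueError):
            wilcoxon_pair([1.0, 2.0], [3.0, 4.0, 5.0])


class TestSpearmanScreen:
    def test_monotone_and_antimonotone(self):
        x = pd.DataFrame({"up": np.arange(10.0)})
        y = pd.DataFrame({"mono": np.arange(10.0) ** 2, "anti": -np.arange(10.0)})
        out = spearman_screen(x, y).set_index("response")
        assert out.loc["mono", "rho"] == pytest.approx(1.0)
        assert out.loc["anti", "rho"] == pytest.approx(-1.0)

    def test_constant_column_flagged(self):
        x = pd.DataFrame({"flat": np.ones(8)})
        y = pd.DataFrame({"y": np.arange(8.0)})
        out = spearman_screen(x, y)
        assert np.isnan(out.loc[0, "rho"]) and out.loc[0, "reason"] == "constant_column"

    def test_independent_columns_near_zero_mean_rho(self, rng):
        rhos = []
        for _ in range(300):
            x = pd.DataFrame({"x": rng.normal(size=30)})
            y = pd.DataFrame({"y": rng.normal(size=30)})
            rhos.append(spearman_screen(x, y).loc[0, "rho"])
        assert abs(np.mean(rhos)) < 0.02


class TestNormalityGate:
    def test_normal_sample_routes_parametric(self):
        v = np.random.default_rng(1).normal(size=50)
        assert normality_gate(v).route == "parametric"

    def test_heavy_tailed_routes_nonparametric(self):
        v = np.random.default_rng(2).standard_cauchy(size=80)
        assert normality_gate(v).route == "nonparametric"

    def test_lognormal_routes_parametric_via_log(self):
        v = np.random.default_rng(3).lognormal(0.0, 1.0, size=80)
        decision = normality_gate(v)
        assert decision.route == "parametric" and decision.log_transformed

    def test_route_recorded_in_factorial_output(self, rng):
        data = two_by_two(rng)
        out = factorial_test(data)
        assert out["route"].str.contains("shapiro").all()
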