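"""Tests for the ANOVA battery, including independent oracles.

The mixed-ANOVA oracle here is a sequential model-comparison (regression)
decomposition built from dummy matrices and numpy.linalg.lstsq — a different
computational route from the package's mean-based formulas. Tukey p-values
are checked against a Monte-Carlo studentized-range simulation, and the whole
mixed table against pingouin on random data.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bireach import (
    MixedAnova,
    OneWayAnova,
    generalized_eta_squared,
    huynh_feldt_epsilon,
    independent_t_test,
    tukey_hsd,
)
from bireach.errors import (
    IncompleteDesignError,
    InvalidParameterError,
    UndefinedEffectSizeError,
)


def toy_mixed_data(n_per_group=3, seed=42):
    rng = np.random.default_rng(seed)
    rows = []
    for gi, g in enumerate(["a", "b", "c", "d"]):
        for s in range(n_per_group):
            subj = f"{g}{s}"
            base = rng.normal(gi, 1.0)
            for bi, block in enumerate(["early", "late"]):
                rows.append(
                    dict(subject=subj, group=g, block=block,
                         y=base + 0.5 * bi * (gi - 1.5) + rng.normal(0, 0.7))
                )
    return pd.DataFrame(rows)


def lstsq_ss_decomposition(df):
    """Sequential regression (model-comparison) sums of squares for the
    balanced split-plot design: an oracle independent of the package's
    mean-based formulas."""
    subjects = pd.Categorical(df["subject"])
    groups = pd.Categorical(df["group"])
    blocks = pd.Categorical(df["block"])
    y = df["y"].to_numpy()
    n = len(y)

    def dummies(cat):
        return pd.get_dummies(pd.Series(cat)).to_numpy(dtype=float)

    X_g = dummies(groups)
    X_s = dummies(subjects)
    X_b = dummies(blocks)
    inter = pd.Series(groups.astype(str)) + ":" + pd.Series(blocks.astype(str))
    X_gb = dummies(pd.Categorical(inter))

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    ones = np.ones((n, 1))
    rss0 = rss(ones)
    rss_g = rss(np.hstack([ones, X_g]))
    rss_s = rss(np.hstack([ones, X_s]))
    rss_sb = rss(np.hstack([ones, X_s, X_b]))
    rss_sgb = rss(np.hstack([ones, X_s, X_b, X_gb]))

    return dict(
        ss_group=rss0 - rss_g,
        ss_err_b=rss_g - rss_s,
        ss_block=rss_s - rss_sb,
        ss_int=rss_sb - rss_sgb,
        ss_err_w=rss_sgb,
    )


class TestMixedAnova:
    def test_no_within_variance_gives_zero_f(self):
        rows = []
        for i, g in enumerate(["a", "a", "b", "b"]):
            for block in ("early", "late"):
                rows.append(dict(subject=f"s{i}", group=g, block=block, y=float(i)))
        res = MixedAnova(pd.DataFrame(rows), "y", "group", "block", "subject").fit()
        assert res.table.loc["block", "F"] == 0.0
        assert res.table.loc["block", "p"] == 1.0
        assert res.table.loc["group:block", "F"] == 0.0

    def test_matches_regression_oracle(self):
        df = toy_mixed_data()
        res = MixedAnova(df, "y", "group", "block", "subject").fit()
        oracle = lstsq_ss_decomposition(df)
        t = res.table
        assert t.loc["group", "ss_effect"] == pytest.approx(oracle["ss_group"], rel=1e-10)
        assert t.loc["group", "ss_error"] == pytest.approx(oracle["ss_err_b"], rel=1e-10)
        assert t.loc["block", "ss_effect"] == pytest.approx(oracle["ss_block"], rel=1e-10)
        assert t.loc["group:block", "ss_effect"] == pytest.approx(oracle["ss_int"], rel=1e-10)
        assert t.loc["block", "ss_error"] == pytest.approx(oracle["ss_err_w"], rel=1e-10)
        # F and p recomputed from the oracle SS
        f_group = (oracle["ss_group"] / 3) / (oracle["ss_err_b"] / 8)
        assert t.loc["group", "F"] == pytest.approx(f_group, rel=1e-10)
        assert t.loc["group", "p"] == pytest.approx(sps.f.sf(f_group, 3, 8), rel=1e-10)
        ges_group = oracle["ss_group"] / (
            oracle["ss_group"] + oracle["ss_err_b"] + oracle["ss_err_w"]
        )
        assert t.loc["group", "ges"] == pytest.approx(ges_group, rel=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        df = toy_mixed_data(n_per_group=5, seed=3)
        res = MixedAnova(df, "y", "group", "block", "subject").fit()
        pg = pingouin.mixed_anova(
            data=df, dv="y", within="block", between="group", subject="subject"
        ).set_index("Source")
        assert res.table.loc["group", "F"] == pytest.approx(pg.loc["group", "F"], rel=1e-8)
        assert res.table.loc["block", "F"] == pytest.approx(pg.loc["block", "F"], rel=1e-8)
        assert res.table.loc["group:block", "F"] == pytest.approx(
            pg.loc["Interaction", "F"], rel=1e-8
        )
        assert res.table.loc["group", "p"] == pytest.approx(pg.loc["group", "p_unc"], rel=1e-8)

    def test_ges_in_unit_interval_on_random_data(self, rng):
        for _ in range(10):
            df = toy_mixed_data(seed=int(rng.integers(1 << 30)))
            res = MixedAnova(df, "y", "group", "block", "subject").fit()
            assert ((res.table["ges"] >= 0) & (res.table["ges"] <= 1)).all()

    def test_incomplete_design_rejected(self):
        df = toy_mixed_data()
        broken = df.drop(df[(df["subject"] == "a0") & (df["block"] == "late")].index)
        with pytest.raises(IncompleteDesignError):
            MixedAnova(broken, "y", "group", "block", "subject").fit()

    def test_summary_contains_effects(self):
        res = MixedAnova(toy_mixed_data(), "y", "group", "block", "subject").fit()
        text = res.summary()
        assert "group:block" in text and "ges" in text


class TestGes:
    def test_zero_effect(self):
        assert generalized_eta_squared(0.0, [5.0]) == 0.0

    def test_symmetry_half(self):
        assert generalized_eta_squared(70.0, [50.0, 20.0]) == pytest.approx(0.5)

    def test_substitution(self):
        assert generalized_eta_squared(30.0, [50.0, 20.0]) == pytest.approx(0.3)

    def test_all_zero_denominator(self):
        with pytest.raises(UndefinedEffectSizeError):
            generalized_eta_squared(0.0, [0.0, 0.0])


class TestHuynhFeldt:
    def test_two_levels_exactly_one(self, rng):
        wide = rng.normal(size=(10, 2))
        assert huynh_feldt_epsilon(wide) == 1.0

    def test_identity_covariance_clipped_to_one(self):
        # centered orthonormal columns -> sample covariance proportional to I,
        # a compound-symmetric matrix, so epsilon clips to 1
        h = np.array([
            [1, 1, 1, 1],
            [1, -1, 0, 0],
            [1, 1, -2, 0],
            [1, 1, 1, -3],
        ], dtype=float)
        q, _ = np.linalg.qr(h.T)
        wide = q[:, 1:]  # 4 subjects x 3 levels, centered orthonormal columns
        assert huynh_feldt_epsilon(wide) == 1.0

    def test_matches_brute_force_formulas(self, rng):
        wide = rng.normal(size=(8, 3)) @ np.diag([1.0, 2.0, 0.5])
        k, n = 3, 8
        S = np.cov(wide, rowvar=False)
        Sc = S - S.mean(0, keepdims=True) - S.mean(1, keepdims=True) + S.mean()
        gg = np.trace(Sc) ** 2 / ((k - 1) * (Sc**2).sum())
        hf = (n * (k - 1) * gg - 2) / ((k - 1) * (n - 1 - (k - 1) * gg))
        assert huynh_feldt_epsilon(wide) == pytest.approx(min(hf, 1.0), rel=1e-10)

    def test_single_level_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            huynh_feldt_epsilon(rng.normal(size=(5, 1)))


class TestTukey:
    def test_identical_means_p_one(self):
        out = tukey_hsd({"a": 1.0, "b": 1.0, "c": 1.0}, 2.0, 12, 5)
        assert (out["p_adj"] == 1.0).all()

    def test_monte_carlo_oracle(self, rng):
        means = {"a": 0.0, "b": 1.0, "c": 2.5, "d": 0.5}
        ms, df, n, k = 2.0, 16, 5, 4
        out = tukey_hsd(means, ms, df, n)
        z = rng.standard_normal((1_000_000, k))
        w = rng.chisquare(df, 1_000_000) / df
        q_null = (z.max(axis=1) - z.min(axis=1)) / np.sqrt(w)
        for _, row in out.iterrows():
            p_mc = float(np.mean(q_null >= row["q"]))
            assert row["p_adj"] == pytest.approx(p_mc, abs=0.005)

    def test_p_monotone_in_difference(self):
        out = tukey_hsd({"a": 0.0, "b": 0.5, "c": 3.0}, 1.0, 12, 5)
        by_diff = out.sort_values("diff", key=lambda s: s.abs())
        assert by_diff["p_adj"].is_monotonic_decreasing

    def test_small_cells_rejected(self):
        with pytest.raises(InvalidParameterError):
            tukey_hsd({"a": 0.0, "b": 1.0}, 1.0, 5, 1)


class TestOneWay:
    def test_equal_values_zero_f(self):
        res = OneWayAnova([1.0] * 6, ["a", "a", "b", "b", "c", "c"]).fit()
        assert res.table.loc["group", "F"] == 0.0

    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.7, 1, 8)
        res = OneWayAnova(np.concatenate([a, b]), ["a"] * 8 + ["b"] * 8).fit()
        t, df, p = independent_t_test(a, b)
        assert res.table.loc["group", "F"] == pytest.approx(t**2, rel=1e-10)
        assert res.table.loc["group", "p"] == pytest.approx(p, rel=1e-10)

    def test_hand_computed_toy(self):
        vals = [1, 2, 3, 4, 2, 3, 4, 5, 4, 5, 6, 7]
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        res = OneWayAnova(vals, labels).fit()
        # SS_between = 18.6667, SS_within = 15, F = 9.3333 / 1.6667 = 5.6
        assert res.table.loc["group", "F"] == pytest.approx(5.6, rel=1e-9)
        assert res.table.loc["group", "ges"] == pytest.approx(18.6667 / 33.6667, rel=1e-4)


class TestTTest:
    def test_identical_samples(self):
        t, df, p = independent_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_df_for_15_vs_15(self, rng):
        t, df, p = independent_t_test(rng.normal(size=15), rng.normal(size=15))
        assert df == 28

    def test_matches_scipy_pooled(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.4, 1.3, 9)
        t, df, p = independent_t_test(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_zero_variance_unequal_means_flagged(self):
        t, df, p = independent_t_test([1.0, 1.0], [2.0, 2.0])
        assert np.isinf(t) and p == 0.0
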