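"""Statistics layer: ANOVA decomposition, effect sizes, FDR, outlier rule."""

import numpy as np
import pandas as pd
import pytest

import nf1eeg as nf


# --------------------------------------------------------------------------
# Brute-force oracle: textbook cell-means decomposition for balanced designs
# --------------------------------------------------------------------------


def balanced_mixed_f(Y, groups):
    """Classical mean-based sums of squares for a balanced mixed design.

    Y is (subjects, J, K) with groups balanced; returns {effect: (SS, F)}.
    Written from the cell-means definitions, independently of the package's
    regression-based implementation.
    """
    Y = np.asarray(Y, float)
    N, J, K = Y.shape
    labels = pd.unique(np.asarray(groups))
    G = len(labels)
    n = N // G
    sel = {g: np.asarray(groups) == g for g in labels}

    m = Y.mean()
    m_g = {g: Y[sel[g]].mean() for g in labels}
    m_gs = Y.mean(axis=(1, 2))
    m_j = Y.mean(axis=(0, 2))
    m_k = Y.mean(axis=(0, 1))
    m_jk = Y.mean(axis=0)
    m_gj = {g: Y[sel[g]].mean(axis=(0, 2)) for g in labels}
    m_gk = {g: Y[sel[g]].mean(axis=(0, 1)) for g in labels}
    m_gjk = {g: Y[sel[g]].mean(axis=0) for g in labels}
    m_gsj = Y.mean(axis=2)
    m_gsk = Y.mean(axis=1)

    g_of = np.asarray(groups)
    ss = {}
    ss["group"] = J * K * sum(n * (m_g[g] - m) ** 2 for g in labels)
    ss["subj"] = J * K * sum((m_gs[i] - m_g[g_of[i]]) ** 2 for i in range(N))
    ss["W1"] = N * K * ((m_j - m) ** 2).sum()
    ss["GW1"] = K * sum(n * ((m_gj[g] - m_g[g] - m_j + m) ** 2).sum() for g in labels)
    ss["W1S"] = K * sum(
        (m_gsj[i, j] - m_gs[i] - m_gj[g_of[i]][j] + m_g[g_of[i]]) ** 2
        for i in range(N)
        for j in range(J)
    )
    out = {
        "group": (ss["group"], (ss["group"] / (G - 1)) / (ss["subj"] / (N - G))),
        "W1": (ss["W1"], (ss["W1"] / (J - 1)) / (ss["W1S"] / ((N - G) * (J - 1)))),
        "GW1": (
            ss["GW1"],
            (ss["GW1"] / ((G - 1) * (J - 1))) / (ss["W1S"] / ((N - G) * (J - 1))),
        ),
    }
    if K > 1:
        ss["W2"] = N * J * ((m_k - m) ** 2).sum()
        ss["GW2"] = J * sum(n * ((m_gk[g] - m_g[g] - m_k + m) ** 2).sum() for g in labels)
        ss["W2S"] = J * sum(
            (m_gsk[i, k] - m_gs[i] - m_gk[g_of[i]][k] + m_g[g_of[i]]) ** 2
            for i in range(N)
            for k in range(K)
        )
        ss["W1W2"] = N * ((m_jk - m_j[:, None] - m_k[None, :] + m) ** 2).sum()
        ss["GW1W2"] = sum(
            n
            * (
                (
                    m_gjk[g]
                    - m_gj[g][:, None]
                    - m_gk[g][None, :]
                    - m_jk
                    + m_g[g]
                    + m_j[:, None]
                    + m_k[None, :]
                    - m
                )
                ** 2
            ).sum()
            for g in labels
        )
        total_ws = 0.0
        for i in range(N):
            e = Y[i] - m_gsj[i][:, None] - m_gsk[i][None, :] + m_gs[i]
            ge = (
                m_gjk[g_of[i]]
                - m_gj[g_of[i]][:, None]
                - m_gk[g_of[i]][None, :]
                + m_g[g_of[i]]
            )
            total_ws += ((e - ge) ** 2).sum()
        ss["W1W2S"] = total_ws
        df_e2 = (N - G) * (K - 1)
        df_e3 = (N - G) * (J - 1) * (K - 1)
        out["W2"] = (ss["W2"], (ss["W2"] / (K - 1)) / (ss["W2S"] / df_e2))
        out["GW2"] = (ss["GW2"], (ss["GW2"] / ((G - 1) * (K - 1))) / (ss["W2S"] / df_e2))
        out["W1W2"] = (
            ss["W1W2"],
            (ss["W1W2"] / ((J - 1) * (K - 1))) / (ss["W1W2S"] / df_e3),
        )
        out["GW1W2"] = (
            ss["GW1W2"],
            (ss["GW1W2"] / ((G - 1) * (J - 1) * (K - 1))) / (ss["W1W2S"] / df_e3),
        )
    return out


def _long_frame(Y, groups, within_names=("w1",)):
    rows = []
    N = Y.shape[0]
    J = Y.shape[1]
    K = Y.shape[2] if Y.ndim == 3 else 1
    for i in range(N):
        for j in range(J):
            for k in range(K):
                row = {
                    "subject": f"s{i}",
                    "group": groups[i],
                    within_names[0]: f"a{j}",
                    "value": Y[i, j, k] if Y.ndim == 3 else Y[i, j],
                }
                if len(within_names) == 2:
                    row[within_names[1]] = f"b{k}"
                rows.append(row)
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_two_by_two_matches_brute_force(self):
        rng = np.random.default_rng(10)
        Y = rng.normal(size=(12, 2, 1))
        groups = ["CON"] * 6 + ["NF1"] * 6
        oracle = balanced_mixed_f(Y, groups)
        tab = nf.mixed_anova(_long_frame(Y, groups), "value", "subject",
                             within=("w1",)).set_index("effect")
        assert tab.loc["group", "SS"] == pytest.approx(oracle["group"][0], abs=1e-10)
        assert tab.loc["group", "F"] == pytest.approx(oracle["group"][1], abs=1e-10)
        assert tab.loc["w1", "F"] == pytest.approx(oracle["W1"][1], abs=1e-10)
        assert tab.loc["group x w1", "F"] == pytest.approx(oracle["GW1"][1], abs=1e-10)

    def test_three_way_matches_brute_force(self):
        rng = np.random.default_rng(11)
        Y = rng.normal(size=(8, 3, 2))
        groups = ["CON"] * 4 + ["NF1"] * 4
        oracle = balanced_mixed_f(Y, groups)
        tab = nf.mixed_anova(_long_frame(Y, groups, ("region", "load")), "value",
                             "subject", within=("region", "load")).set_index("effect")
        for effect, key in [
            ("group", "group"), ("region", "W1"), ("group x region", "GW1"),
            ("load", "W2"), ("group x load", "GW2"), ("region x load", "W1W2"),
            ("group x region x load", "GW1W2"),
        ]:
            assert tab.loc[effect, "F"] == pytest.approx(oracle[key][1], abs=1e-9), effect

    def test_matches_pingouin_on_balanced_design(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(12)
        Y = rng.normal(size=(14, 2, 1)) + np.array([[0.0], [0.4]])
        groups = ["CON"] * 7 + ["NF1"] * 7
        df = _long_frame(Y, groups)
        mine = nf.mixed_anova(df, "value", "subject", within=("w1",)).set_index("effect")
        theirs = pg.mixed_anova(data=df, dv="value", within="w1", subject="subject",
                                between="group").set_index("Source")
        assert mine.loc["group", "F"] == pytest.approx(theirs.loc["group", "F"], rel=1e-9)
        assert mine.loc["w1", "F"] == pytest.approx(theirs.loc["w1", "F"], rel=1e-9)
        assert mine.loc["group x w1", "F"] == pytest.approx(
            theirs.loc["Interaction", "F"], rel=1e-9)

    def test_location_invariance(self):
        rng = np.random.default_rng(13)
        Y = rng.normal(size=(10, 2, 1))
        groups = ["CON"] * 5 + ["NF1"] * 5
        a = nf.mixed_anova(_long_frame(Y, groups), "value", "subject", within=("w1",))
        b = nf.mixed_anova(_long_frame(Y + 17.3, groups), "value", "subject", within=("w1",))
        assert np.allclose(a["F"], b["F"], atol=1e-9)

    def test_eta_identity_on_every_row(self):
        rng = np.random.default_rng(14)
        Y = rng.normal(size=(8, 3, 2))
        groups = ["CON"] * 4 + ["NF1"] * 4
        tab = nf.mixed_anova(_long_frame(Y, groups, ("r", "l")), "value", "subject",
                             within=("r", "l"))
        for _, row in tab.iterrows():
            expected = row.F * row.df1 / (row.F * row.df1 + row.df2)
            assert row.eta_p2 == pytest.approx(expected, abs=1e-12)

    def test_missing_cell_listed(self):
        rng = np.random.default_rng(15)
        Y = rng.normal(size=(6, 2, 1))
        groups = ["CON"] * 3 + ["NF1"] * 3
        df = _long_frame(Y, groups).iloc[:-1]
        with pytest.raises(ValueError, match="missing cells"):
            nf.mixed_anova(df, "value", "subject", within=("w1",))

    def test_reported_effect_size_identities(self):
        """Partial eta squared recomputed from reported (F, df) pairs."""
        for F, df1, df2, eta in [(7.135, 1, 28, 0.203), (12.276, 1, 28, 0.305),
                                 (5.023, 2, 54, 0.157), (9.145, 1, 28, 0.246)]:
            assert round(F * df1 / (F * df1 + df2), 3) == eta


class TestPairedT:
    def test_reported_t_to_d_identities(self):
        for t, n, d in [(5.004, 14, 1.34), (4.296, 14, 1.15), (5.291, 14, 1.41)]:
            assert round(t / np.sqrt(n), 2) == d

    def test_hand_computed_example(self):
        res = nf.paired_ttest([1.0, 2.0, 3.0, 4.0])
        assert res.t == pytest.approx(3.873, abs=5e-4)
        assert res.d == pytest.approx(1.936, abs=5e-4)
        assert res.df == 3

    def test_d_equals_t_over_sqrt_n(self):
        rng = np.random.default_rng(16)
        diffs = rng.normal(0.4, 1.0, 14)
        res = nf.paired_ttest(diffs)
        assert res.d == pytest.approx(res.t / np.sqrt(res.n), abs=1e-12)

    def test_sign_flip_antisymmetry(self):
        diffs = np.array([0.3, -0.1, 0.7, 0.2, 0.5])
        a = nf.paired_ttest(diffs)
        b = nf.paired_ttest(-diffs)
        assert b.t == pytest.approx(-a.t, abs=1e-12)
        assert b.d == pytest.approx(-a.d, abs=1e-12)

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError):
            nf.paired_ttest([1.0, 1.0, 1.0])


class TestCompareCorrelations:
    def test_identical_correlations_give_zero(self):
        res = nf.compare_correlations(0.5, 20, 0.5, 20)
        assert res.z == 0.0
        assert res.p == 1.0

    def test_standard_formula_on_reference_pair(self):
        """r=.736 (n=16) vs r=-.241 (n=14) under the standard two-sample
        Fisher transform comparison."""
        res = nf.compare_correlations(0.736, 16, -0.241, 14)
        assert res.z == pytest.approx(2.899, abs=5e-4)

    def test_swap_antisymmetry(self):
        a = nf.compare_correlations(0.6, 18, 0.1, 25)
        b = nf.compare_correlations(0.1, 25, 0.6, 18)
        assert b.z == pytest.approx(-a.z, abs=1e-12)

    def test_degenerate_r_rejected(self):
        with pytest.raises(ValueError):
            nf.compare_correlations(1.0, 10, 0.0, 10)


def _bh_brute_force(p, q):
    """Largest k with p_(k) <= k q / m; reject the k smallest."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    ok = np.flatnonzero(sorted_p <= q * np.arange(1, m + 1) / m)
    k = ok[-1] + 1 if ok.size else 0
    reject = np.zeros(m, bool)
    reject[order[:k]] = True
    return reject


class TestFdrBh:
    def test_worked_family(self):
        flags, _ = nf.fdr_bh([0.001, 0.01, 0.02, 0.04, 0.2], q=0.05)
        assert flags.sum() == 4
        assert not flags[-1]

    def test_all_ones_nothing_significant(self):
        flags, _ = nf.fdr_bh([1.0, 1.0, 1.0])
        assert not flags.any()

    def test_singleton_family_reduces_to_raw_threshold(self):
        flags, _ = nf.fdr_bh([0.04], q=0.05)
        assert flags[0]

    def test_empty_family_is_error(self):
        with pytest.raises(ValueError):
            nf.fdr_bh([])

    def test_matches_step_up_definition_on_random_families(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            m = int(rng.integers(1, 13))
            p = rng.uniform(size=m) ** rng.uniform(0.5, 3.0)
            flags, _ = nf.fdr_bh(p, q=0.05)
            assert np.array_equal(flags, _bh_brute_force(p, 0.05))


class TestOutlierSensitivity:
    @staticmethod
    def _run(values):
        df = pd.DataFrame({
            "subject": [f"s{i}" for i in range(len(values))],
            "cell": "a",
            "value": values,
        })
        return nf.outlier_sensitivity(df, "value", "subject", ["cell"],
                                      analysis=lambda d: d["value"].mean())

    def test_constant_data_has_no_outliers(self):
        res = self._run([5.0] * 8)
        assert len(res.flags) == 0
        assert res.rerun is None

    def test_extreme_value_flagged_and_rerun(self):
        res = self._run(list(range(1, 11)) + [100.0])
        assert list(res.flags["value"]) == [100.0]
        assert res.rerun == pytest.approx(np.mean(range(1, 11)))

    def test_quartiles_use_linear_interpolation(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 30.0]
        q1, q3 = np.percentile(vals, [25, 75])
        bound = q3 + 3 * (q3 - q1)
        res = self._run(vals)
        assert (len(res.flags) == 1) == (30.0 > bound)


class TestFdrProperties:
    from hypothesis import given, settings, strategies as st

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bh_flags_are_step_up_and_q_monotone(self, pvals):
        flags, q = nf.fdr_bh(pvals, q=0.05)
        assert np.array_equal(flags, _bh_brute_force(pvals, 0.05))
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(np.asarray(q)[order]) >= -1e-12)
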