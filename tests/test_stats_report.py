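"""Statistics layer: printed-value recomputation and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from protolearn import (
    build_report,
    chi_square_gof,
    cohens_d_av,
    cohens_d_s,
    eta_squared_from_F,
    generalized_eta_squared,
    independent_t,
    kruskal_wallis,
    mixed_anova_2x2x3,
    one_way_anova,
    paired_t,
)
from protolearn.stats_report import holm_adjust, levene_test, phase_contrasts_by_group

TOL = 1e-10


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementations under test)
# ---------------------------------------------------------------------------


def brute_chi2(observed, proportions):
    n = sum(observed)
    return sum((o - n * p) ** 2 / (n * p) for o, p in zip(observed, proportions))


def brute_t_ind(x, y):
    n1, n2 = len(x), len(y)
    m1, m2 = sum(x) / n1, sum(y) / n2
    v1 = sum((xi - m1) ** 2 for xi in x) / (n1 - 1)
    v2 = sum((yi - m2) ** 2 for yi in y) / (n2 - 1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    return (m1 - m2) / (sp2 * (1 / n1 + 1 / n2)) ** 0.5


def brute_t_paired(x, y):
    d = [a - b for a, b in zip(x, y)]
    n = len(d)
    m = sum(d) / n
    v = sum((di - m) ** 2 for di in d) / (n - 1)
    return m / (v / n) ** 0.5


def brute_F(groups):
    all_vals = [v for g in groups for v in g]
    grand = sum(all_vals) / len(all_vals)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups)
    df1, df2 = len(groups) - 1, len(all_vals) - len(groups)
    return (ssb / df1) / (ssw / df2)


def brute_H(groups):
    all_vals = [v for g in groups for v in g]
    order = sorted(range(len(all_vals)), key=lambda i: all_vals[i])
    ranks = [0.0] * len(all_vals)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and all_vals[order[j + 1]] == all_vals[order[i]]:
            j += 1
        mean_rank = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mean_rank
        i = j + 1
    n = len(all_vals)
    h = 0.0
    start = 0
    for g in groups:
        rsum = sum(ranks[start : start + len(g)])
        h += rsum**2 / len(g)
        start += len(g)
    h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    ties = 0.0
    for v in set(all_vals):
        t = all_vals.count(v)
        ties += t**3 - t
    return h / (1 - ties / (n**3 - n))


def brute_holm(pvals):
    order = sorted(range(len(pvals)), key=lambda i: pvals[i])
    m = len(pvals)
    adj = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(1.0, running)
    return adj


def brute_split_plot(Y, codes):
    """Classical balanced split-plot SS decomposition from cell means.

    Y: (n_subjects, 4) cell means in order (pos,early),(pos,late),
    (neg,early),(neg,late); codes: equal-sized group labels 0..2.
    """
    n_sub = Y.shape[0]
    groups = sorted(set(codes))
    n = n_sub // len(groups)
    # reshape to y[s, v, p]: v in {pos, neg}, p in {early, late}
    y = Y.reshape(n_sub, 2, 2)
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_g = {g: m_s[[i for i in range(n_sub) if codes[i] == g]].mean() for g in groups}
    m_p = y.mean(axis=(0, 1))
    m_v = y.mean(axis=(0, 2))
    m_gp = {g: y[[i for i in range(n_sub) if codes[i] == g]].mean(axis=(0, 1)) for g in groups}
    m_gv = {g: y[[i for i in range(n_sub) if codes[i] == g]].mean(axis=(0, 2)) for g in groups}
    m_pv = y.mean(axis=0)  # (v, p)
    m_gpv = {g: y[[i for i in range(n_sub) if codes[i] == g]].mean(axis=0) for g in groups}

    ss = {}
    ss["intercept"] = 4 * n_sub * grand**2
    ss["strategy"] = 4 * n * sum((m_g[g] - grand) ** 2 for g in groups)
    ss["subj"] = 4 * sum((m_s[i] - m_g[codes[i]]) ** 2 for i in range(n_sub))
    ss["phase"] = 2 * n_sub * ((m_p - grand) ** 2).sum()
    ss["strategy_x_phase"] = 2 * n * sum(
        ((m_gp[g] - m_g[g] - m_p + grand) ** 2).sum() for g in groups
    )
    ss["phase_x_subj"] = 2 * sum(
        ((y[i].mean(axis=0) - m_s[i] - m_gp[codes[i]] + m_g[codes[i]]) ** 2).sum()
        for i in range(n_sub)
    )
    ss["valence"] = 2 * n_sub * ((m_v - grand) ** 2).sum()
    ss["strategy_x_valence"] = 2 * n * sum(
        ((m_gv[g] - m_g[g] - m_v + grand) ** 2).sum() for g in groups
    )
    ss["valence_x_subj"] = 2 * sum(
        ((y[i].mean(axis=1) - m_s[i] - m_gv[codes[i]] + m_g[codes[i]]) ** 2).sum()
        for i in range(n_sub)
    )
    ss["phase_x_valence"] = n_sub * (
        (m_pv - m_v[:, None] - m_p[None, :] + grand) ** 2
    ).sum()
    ss["strategy_x_phase_x_valence"] = n * sum(
        (
            (
                m_gpv[g]
                - m_gp[g][None, :]
                - m_gv[g][:, None]
                - m_pv
                + m_g[g]
                + m_v[:, None]
                + m_p[None, :]
                - grand
            )
            ** 2
        ).sum()
        for g in groups
    )
    ss["pv_x_subj"] = sum(
        (
            (
                y[i]
                - y[i].mean(axis=1)[:, None]
                - y[i].mean(axis=0)[None, :]
                + m_s[i]
                - (
                    m_gpv[codes[i]]
                    - m_gv[codes[i]][:, None]
                    - m_gp[codes[i]][None, :]
                    + m_g[codes[i]]
                )
            )
            ** 2
        ).sum()
        for i in range(n_sub)
    )
    return ss


def _tidy_scores(Y, codes):
    rows = []
    cells = [("positive", "early"), ("positive", "late"),
             ("negative", "early"), ("negative", "late")]
    for i, row in enumerate(Y):
        for (valence, phase), val in zip(cells, row):
            rows.append({"participant_id": i, "feedback_valence": valence,
                         "training_phase": phase, "score": val})
    labels = {i: f"g{codes[i]}" for i in range(len(codes))}
    return pd.DataFrame(rows), labels


# ---------------------------------------------------------------------------
# printed-statistic recomputation
# ---------------------------------------------------------------------------


class TestPrintedStatistics:
    def test_chi_square_on_strategy_counts(self):
        res = chi_square_gof([26, 8, 4], [0.50, 0.42, 0.08])
        assert res.statistic == pytest.approx(6.85, abs=0.005)
        assert res.df == (2,)

    def test_pooled_d_multicue_vs_single_feature(self):
        res = cohens_d_s(80.0, 7.27, 19, 59.2, 10.52, 16)
        assert res.effect_size == pytest.approx(2.34, abs=0.005)
        lo, hi = res.conf_int
        assert lo == pytest.approx(1.46, abs=0.02)
        assert hi == pytest.approx(3.20, abs=0.02)

    def test_pooled_d_multicue_vs_random(self):
        res = cohens_d_s(80.0, 7.27, 19, 59.86, 10.65, 3)
        assert res.effect_size == pytest.approx(2.62, abs=0.005)

    def test_average_sd_d_for_testing_accuracy(self):
        assert cohens_d_av(69.65, 13.67, 73.24, 9.17) == pytest.approx(-0.31, abs=0.005)

    def test_eta_squared_from_reported_F(self):
        assert eta_squared_from_F(25.09, 2, 35) == pytest.approx(0.59, abs=0.005)

    def test_generalized_eta_squared_from_table_ss(self):
        val = generalized_eta_squared(4.03, [39.07, 16.02, 14.94, 7.39])
        assert val == pytest.approx(0.05, abs=0.005)


class TestEffectSizeEdgeCases:
    def test_equal_means_zero_d(self):
        assert cohens_d_s(5.0, 1.0, 10, 5.0, 2.0, 10).effect_size == 0.0
        assert cohens_d_av(3.0, 1.0, 3.0, 2.0) == 0.0

    def test_d_av_equal_sds_reduces_to_simple_form(self):
        assert cohens_d_av(4.0, 2.0, 1.0, 2.0) == pytest.approx(1.5)

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError):
            cohens_d_av(1.0, 0.0, 2.0, 0.0)
        with pytest.raises(ValueError):
            cohens_d_s(1.0, 0.0, 5, 2.0, 0.0, 5)

    def test_eta_squared_limits(self):
        assert eta_squared_from_F(0.0, 2, 30) == 0.0
        assert eta_squared_from_F(1.0, 1, 10**9) < 1e-6


class TestChiSquareValidation:
    def test_proportional_observed_gives_zero(self):
        assert chi_square_gof([25, 21, 4], [0.50, 0.42, 0.08]).statistic == pytest.approx(0.0)

    def test_two_cell_case(self):
        res = chi_square_gof([10, 10], [0.5, 0.5])
        assert res.statistic == 0.0
        assert res.df == (1,)

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError):
            chi_square_gof([10, 10], [0.6, 0.5])
        with pytest.raises(ValueError):
            chi_square_gof([10, 10], [1.0, 0.0])

    def test_raw_count_expectation_option(self):
        by_props = chi_square_gof([26, 8, 4], [0.50, 0.42, 0.08])
        by_counts = chi_square_gof([26, 8, 4], expected_counts=[19.0, 15.96, 3.04])
        assert by_counts.statistic == pytest.approx(by_props.statistic, abs=TOL)
        with pytest.raises(ValueError):
            chi_square_gof([10, 10], [0.5, 0.5], expected_counts=[10, 10])

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            k = rng.integers(2, 6)
            obs = rng.integers(1, 30, size=k)
            props = rng.dirichlet(np.ones(k))
            res = chi_square_gof(obs, props)
            assert res.statistic == pytest.approx(brute_chi2(obs, props), abs=TOL)


class TestTTests:
    def test_paired_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_t(x, x)
        assert res.statistic == 0.0

    def test_paired_df_is_n_minus_one(self, rng):
        x = rng.normal(size=38)
        y = rng.normal(size=38)
        assert paired_t(x, y).df == (37,)

    def test_brute_force_on_small_fixtures(self):
        x = [2.1, 3.4, 1.9, 4.2, 2.8]
        y = [1.5, 2.9, 2.2, 3.1, 2.0]
        assert paired_t(x, y).statistic == pytest.approx(brute_t_paired(x, y), abs=TOL)
        assert independent_t(x, y).statistic == pytest.approx(brute_t_ind(x, y), abs=TOL)

    def test_independent_t_effect_size_and_ci_cover_difference(self, rng):
        x = rng.normal(1.0, 1.0, size=12)
        y = rng.normal(0.0, 1.0, size=10)
        res = independent_t(x, y)
        lo, hi = res.conf_int
        assert lo < np.mean(x) - np.mean(y) < hi


class TestOneWayAnova:
    def test_identical_groups_F_zero(self):
        g = {"a": np.array([1.0, 2, 3]), "b": np.array([1.0, 2, 3]), "c": np.array([1.0, 2, 3])}
        res, _ = one_way_anova(g)
        assert res.statistic == pytest.approx(0.0)

    def test_two_groups_F_equals_t_squared(self, rng):
        x = rng.normal(size=9)
        y = rng.normal(size=7)
        res, _ = one_way_anova({"x": x, "y": y})
        t = brute_t_ind(list(x), list(y))
        assert res.statistic == pytest.approx(t**2, abs=1e-9)

    def test_matches_brute_force_F_and_eta2(self, rng):
        groups = {f"g{i}": rng.normal(i, 1.0, size=4) for i in range(3)}
        res, _ = one_way_anova(groups)
        assert res.statistic == pytest.approx(brute_F(list(groups.values())), abs=TOL)
        # eta2 internally consistent with its own F and dfs
        assert res.effect_size == pytest.approx(
            eta_squared_from_F(res.statistic, *res.df), abs=1e-9
        )

    def test_posthoc_holm_adjustment(self, rng):
        groups = {f"g{i}": rng.normal(i, 1.0, size=6) for i in range(3)}
        _, posthoc = one_way_anova(groups)
        assert np.all(posthoc["p_holm"] >= posthoc["p_raw"] - TOL)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova({"a": np.array([1.0]), "b": np.array([1.0, 2.0])})


class TestKruskalWallis:
    def test_identical_groups(self):
        g = {"a": np.ones(4), "b": np.ones(5)}
        res, _ = kruskal_wallis(g)
        assert res.statistic == pytest.approx(0.0)
        ranks = res.extras["mean_ranks"]
        assert ranks["a"] == pytest.approx(ranks["b"])

    def test_separated_groups_mean_ranks_at_block_midpoints(self):
        g = {
            "low": np.array([1.0, 2, 3, 4]),
            "mid": np.array([10.0, 11, 12]),
            "high": np.array([20.0, 21, 22, 23, 24]),
        }
        res, _ = kruskal_wallis(g)
        assert res.extras["mean_ranks"]["low"] == pytest.approx(2.5)
        assert res.extras["mean_ranks"]["mid"] == pytest.approx(6.0)
        assert res.extras["mean_ranks"]["high"] == pytest.approx(10.0)

    def test_matches_brute_force_with_ties(self, rng):
        for _ in range(10):
            groups = [list(rng.integers(0, 6, size=rng.integers(3, 6))) for _ in range(3)]
            res, _ = kruskal_wallis({f"g{i}": np.array(g, float) for i, g in enumerate(groups)})
            assert res.statistic == pytest.approx(brute_H(groups), abs=TOL)


class TestHolm:
    def test_matches_brute_force(self, rng):
        for _ in range(20):
            p = rng.uniform(size=rng.integers(2, 8))
            assert np.allclose(holm_adjust(list(p)), brute_holm(list(p)), atol=TOL)

    def test_monotone_and_dominating(self, rng):
        p = list(rng.uniform(size=6))
        adj = holm_adjust(p)
        assert all(a >= r - TOL for a, r in zip(adj, p))
        order = np.argsort(p)
        assert np.all(np.diff(np.asarray(adj)[order]) >= -TOL)


class TestLevene:
    def test_mean_centered_matches_scipy(self, rng):
        groups = [rng.normal(0, s, size=8) for s in (1.0, 2.0, 3.0)]
        res = levene_test(groups, center="mean")
        w, p = sps.levene(*groups, center="mean")
        assert res.statistic == pytest.approx(w, abs=TOL)
        assert res.p_value == pytest.approx(p, abs=TOL)


class TestMixedAnova:
    def _balanced_fixture(self, rng, effects=True):
        codes = [0] * 4 + [1] * 4 + [2] * 4
        Y = rng.normal(size=(12, 4))
        if effects:
            Y[:, 2:] -= 1.0  # valence effect
            Y[4:8, 1] += 1.5  # group 1 phase shift
        return Y, codes

    def test_balanced_design_matches_textbook_decomposition(self, rng):
        Y, codes = self._balanced_fixture(rng)
        scores, labels = _tidy_scores(Y, codes)
        table = mixed_anova_2x2x3(scores, labels).set_index("Predictor")
        ss = brute_split_plot(Y, codes)
        pairs = [
            ("(Intercept)", "intercept", "subj"),
            ("Strategy", "strategy", "subj"),
            ("Training phase", "phase", "phase_x_subj"),
            ("Strategy x Training phase", "strategy_x_phase", "phase_x_subj"),
            ("Feedback valence", "valence", "valence_x_subj"),
            ("Strategy x Feedback valence", "strategy_x_valence", "valence_x_subj"),
            ("Training phase x Feedback valence", "phase_x_valence", "pv_x_subj"),
            (
                "Strategy x Training phase x Feedback valence",
                "strategy_x_phase_x_valence",
                "pv_x_subj",
            ),
        ]
        for row_name, eff_key, err_key in pairs:
            assert table.loc[row_name, "SS_num"] == pytest.approx(ss[eff_key], abs=TOL)
            assert table.loc[row_name, "SS_den"] == pytest.approx(ss[err_key], abs=TOL)

    def test_eta2g_recomputes_from_table_rows(self, rng):
        Y, codes = self._balanced_fixture(rng)
        scores, labels = _tidy_scores(Y, codes)
        table = mixed_anova_2x2x3(scores, labels)
        error_ss = table["SS_den"].unique().sum()
        for _, row in table.iterrows():
            assert row["eta2_g"] == pytest.approx(
                row["SS_num"] / (row["SS_num"] + error_ss), abs=1e-9
            )
            assert 0.0 <= row["eta2_g"] <= 1.0

    def test_pure_valence_shift_isolates_valence_row(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=12)
        Y = np.column_stack([base, base, base - 2.0, base - 2.0])
        codes = [0] * 4 + [1] * 4 + [2] * 4
        scores, labels = _tidy_scores(Y, codes)
        table = mixed_anova_2x2x3(scores, labels).set_index("Predictor")
        assert table.loc["Feedback valence", "F"] > 1e6
        for effect in ["Training phase", "Strategy x Training phase",
                       "Training phase x Feedback valence"]:
            assert table.loc[effect, "SS_num"] == pytest.approx(0.0, abs=1e-18)

    def test_unbalanced_groups_supported(self, rng):
        codes = [0] * 6 + [1] * 4 + [2] * 2
        Y = rng.normal(size=(12, 4))
        scores, labels = _tidy_scores(Y, codes)
        table = mixed_anova_2x2x3(scores, labels)
        assert (table["df_den"] == 9).all()

    def test_tiny_group_rejected(self, rng):
        codes = [0] * 6 + [1] * 5 + [2]
        Y = rng.normal(size=(12, 4))
        scores, labels = _tidy_scores(Y, codes)
        with pytest.raises(ValueError):
            mixed_anova_2x2x3(scores, labels)

    def test_incomplete_participant_dropped_with_warning(self, rng):
        codes = [0] * 4 + [1] * 4 + [2] * 4
        Y = rng.normal(size=(12, 4))
        scores, labels = _tidy_scores(Y, codes)
        scores = scores.drop(scores.index[0])  # participant 0 loses a cell
        with pytest.warns(UserWarning, match="incomplete"):
            table = mixed_anova_2x2x3(scores, labels)
        assert (table["df_den"] == 8).all()

    def test_phase_contrasts_share_omnibus_error(self, rng):
        Y, codes = self._balanced_fixture(rng)
        scores, labels = _tidy_scores(Y, codes)
        contrasts = phase_contrasts_by_group(scores, labels)
        assert (contrasts["df"] == 9).all()
        # group 1 received the late-phase shift: its contrast is the largest
        g1 = contrasts.set_index("group").loc["g1", "early_minus_late"]
        assert abs(g1) == contrasts["early_minus_late"].abs().max()


class TestBuildReport:
    def test_partial_report_flags_missing_sections(self, tmp_path):
        sections = build_report(tmp_path)
        text = sections["report_text"]
        assert "ABSENT" in text
        assert (tmp_path / "report.txt").exists()
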