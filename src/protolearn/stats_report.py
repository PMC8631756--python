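"""Group statistics, effect sizes, and the mixed-design ANOVA / report layer.

Implements the full results surface for a simulated cohort: chi-square
goodness of fit on strategy proportions, one-way between-subjects ANOVA with
Holm-adjusted pairwise post-hocs (plus Levene's test), Kruskal-Wallis with
mean ranks and Holm-adjusted rank-sum post-hocs, paired/independent t-tests,
Cohen's d_s (pooled-SD, independent groups, noncentral-t CI) and d_av
(average-SD, paired designs), and a 2 (feedback valence) x 2 (training phase)
x 3 (strategy) split-plot ANOVA with Type III sums of squares and generalized
eta-squared.

The split-plot ANOVA uses the orthonormal-contrast formulation: each
within-subject effect corresponds to a unit-norm contrast over a subject's
four cell means, and the ANOVA of each contrast variable on the
(sum-to-zero-coded) between factor yields exactly the classical split-plot
sums of squares, including for unbalanced groups under Type III tests.
Generalized eta-squared for every effect is SS_effect / (SS_effect + the sum
of all four error-stratum SS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "chi_square_gof",
    "cohens_d_s",
    "cohens_d_av",
    "eta_squared_from_F",
    "generalized_eta_squared",
    "holm_adjust",
    "one_way_anova",
    "kruskal_wallis",
    "mixed_anova_2x2x3",
    "phase_contrasts_by_group",
    "paired_t",
    "independent_t",
    "levene_test",
    "build_report",
]


@dataclass
class StatResult:
    name: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    effect_size_name: str | None = None
    effect_size: float | None = None
    conf_int: tuple[float, float] | None = None
    extras: dict = field(default_factory=dict)


def chi_square_gof(
    observed: np.ndarray,
    expected_proportions: np.ndarray | None = None,
    expected_counts: np.ndarray | None = None,
) -> StatResult:
    """Chi-square goodness of fit.

    Expectations come either from ``expected_proportions`` (scaled to the
    observed total — the convention matching published percentage-based
    comparisons) or from raw ``expected_counts`` (rescaled to the observed
    total if the totals differ).
    """
    obs = np.asarray(observed, dtype=float)
    if np.any(obs < 0):
        raise ValueError("observed counts must be non-negative")
    if (expected_proportions is None) == (expected_counts is None):
        raise ValueError("supply exactly one of expected_proportions / expected_counts")
    if expected_proportions is not None:
        props = np.asarray(expected_proportions, dtype=float)
        if obs.shape != props.shape:
            raise ValueError("observed and expected_proportions must align")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("expected proportions must sum to 1")
        expected = obs.sum() * props
    else:
        counts = np.asarray(expected_counts, dtype=float)
        if obs.shape != counts.shape:
            raise ValueError("observed and expected_counts must align")
        expected = counts * obs.sum() / counts.sum()
    if np.any(expected == 0):
        raise ValueError("expected count of zero")
    chi2, p = stats.chisquare(obs, f_exp=expected)
    return StatResult("chi_square_gof", float(chi2), (len(obs) - 1,), float(p))


def _nct_ci(t_obs: float, df: float, conf: float = 0.95) -> tuple[float, float]:
    """CI for the noncentrality parameter of an observed t statistic."""
    alpha = 1.0 - conf

    def cdf(nc: float) -> float:
        v = stats.nct.cdf(t_obs, df, nc)
        if np.isnan(v):  # extreme noncentrality: use the limiting value
            return 0.0 if nc > t_obs else 1.0
        return float(v)

    def low(nc: float) -> float:
        return cdf(nc) - (1.0 - alpha / 2.0)

    def high(nc: float) -> float:
        return cdf(nc) - alpha / 2.0

    span = max(10.0, 5.0 * abs(t_obs) + 10.0)
    lo = optimize.brentq(low, t_obs - span, t_obs + span)
    hi = optimize.brentq(high, t_obs - span, t_obs + span)
    return lo, hi


def cohens_d_s(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> StatResult:
    """Pooled-SD standardized mean difference with a noncentral-t 95% CI."""
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be non-negative")
    s_pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    if s_pooled == 0:
        if m1 == m2:
            return StatResult("cohens_d_s", 0.0, (n1 + n2 - 2,), np.nan,
                              "d_s", 0.0, (0.0, 0.0))
        raise ValueError("undefined d_s: zero pooled SD with unequal means")
    d = (m1 - m2) / s_pooled
    scale = np.sqrt(1.0 / n1 + 1.0 / n2)
    t_obs = d / scale
    df = n1 + n2 - 2
    nc_lo, nc_hi = _nct_ci(t_obs, df)
    p = 2 * stats.t.sf(abs(t_obs), df)
    return StatResult(
        "cohens_d_s", float(t_obs), (df,), float(p),
        "d_s", float(d), (float(nc_lo * scale), float(nc_hi * scale)),
    )


def cohens_d_av(m1: float, sd1: float, m2: float, sd2: float) -> float:
    """Average-SD standardized mean difference for paired designs."""
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be non-negative")
    denom = (sd1 + sd2) / 2.0
    if denom == 0:
        raise ValueError("undefined d_av: both SDs are zero")
    return (m1 - m2) / denom


def eta_squared_from_F(F: float, df1: float, df2: float) -> float:
    """eta^2 recovered from an F statistic and its degrees of freedom."""
    if F < 0 or df1 < 1 or df2 < 1:
        raise ValueError("require F >= 0 and dfs >= 1")
    return F * df1 / (F * df1 + df2)


def generalized_eta_squared(ss_effect: float, error_ss: list[float]) -> float:
    """eta^2_g = SS_effect / (SS_effect + sum of all subject/error SS)."""
    return ss_effect / (ss_effect + float(np.sum(error_ss)))


def holm_adjust(p_values: list[float]) -> list[float]:
    """Holm step-down adjusted p-values."""
    return list(multipletests(p_values, method="holm")[1])


def levene_test(groups: list[np.ndarray], center: str = "mean") -> StatResult:
    """Levene's test for homogeneity of variance (mean-centered by default;
    center="median" gives the Brown-Forsythe variant)."""
    w, p = stats.levene(*groups, center=center)
    k = len(groups)
    n = sum(len(g) for g in groups)
    return StatResult("levene", float(w), (k - 1, n - k), float(p))


def _pairwise_frame(names, stats_vals, dfs, raw_p, effect_name, effects):
    adj = holm_adjust(raw_p)
    return pd.DataFrame(
        {
            "comparison": names,
            "statistic": stats_vals,
            "df": dfs,
            "p_raw": raw_p,
            "p_holm": adj,
            effect_name: effects,
        }
    )


def one_way_anova(groups: dict[str, np.ndarray]) -> tuple[StatResult, pd.DataFrame]:
    """Between-subjects one-way ANOVA with Holm-adjusted pairwise t post-hocs.

    Returns the omnibus result (eta^2 = SS_between / SS_total, Levene's test
    in ``extras``) and a pairwise post-hoc table.
    """
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with n >= 2 each")
    F, p = stats.f_oneway(*arrays)
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_total = float(((all_vals - grand) ** 2).sum())
    eta2 = ss_between / ss_total if ss_total > 0 else 0.0
    df1, df2 = len(arrays) - 1, len(all_vals) - len(arrays)

    comp_names, tvals, dfs, raw_p, ds = [], [], [], [], []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            a, b = arrays[i], arrays[j]
            t, pt = stats.ttest_ind(a, b)
            comp_names.append(f"{names[i]} vs {names[j]}")
            tvals.append(float(t))
            dfs.append(len(a) + len(b) - 2)
            raw_p.append(float(pt))
            ds.append(
                cohens_d_s(a.mean(), a.std(ddof=1), len(a),
                           b.mean(), b.std(ddof=1), len(b)).effect_size
            )
    posthoc = _pairwise_frame(comp_names, tvals, dfs, raw_p, "d_s", ds)
    omnibus = StatResult(
        "one_way_anova", float(F), (df1, df2), float(p), "eta^2", float(eta2),
        extras={"levene": levene_test(arrays)},
    )
    return omnibus, posthoc


def kruskal_wallis(groups: dict[str, np.ndarray]) -> tuple[StatResult, pd.DataFrame]:
    """Kruskal-Wallis H (tie-corrected) with mean ranks and Holm post-hocs."""
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    all_vals = np.concatenate(arrays)
    if np.all(all_vals == all_vals[0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*arrays)
    ranks = stats.rankdata(all_vals)
    mean_ranks = {}
    start = 0
    for name, a in zip(names, arrays):
        mean_ranks[name] = float(ranks[start : start + len(a)].mean())
        start += len(a)

    comp_names, uvals, dfs, raw_p = [], [], [], []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            z, pz = stats.ranksums(arrays[i], arrays[j])
            comp_names.append(f"{names[i]} vs {names[j]}")
            uvals.append(float(z))
            dfs.append(np.nan)
            raw_p.append(float(pz))
    posthoc = _pairwise_frame(comp_names, uvals, dfs, raw_p, "effect", [np.nan] * len(raw_p))
    omnibus = StatResult(
        "kruskal_wallis", float(h), (len(arrays) - 1,), float(p),
        extras={"mean_ranks": mean_ranks},
    )
    return omnibus, posthoc


# ---------------------------------------------------------------------------
# 2 x 2 x 3 split-plot ANOVA
# ---------------------------------------------------------------------------

# unit-norm within-subject contrasts over the cell order
# (valence, phase): (pos, early), (pos, late), (neg, early), (neg, late)
_CELL_ORDER = [("positive", "early"), ("positive", "late"),
               ("negative", "early"), ("negative", "late")]
_CONTRASTS = {
    "between": np.array([0.5, 0.5, 0.5, 0.5]),
    "phase": np.array([0.5, -0.5, 0.5, -0.5]),  # early - late
    "valence": np.array([0.5, 0.5, -0.5, -0.5]),  # positive - negative
    "phase_x_valence": np.array([0.5, -0.5, -0.5, 0.5]),
}


def _sum_to_zero_design(group_codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Columns: intercept + (n_levels - 1) sum-to-zero group contrasts."""
    n = len(group_codes)
    X = np.ones((n, n_levels))
    for j in range(n_levels - 1):
        X[:, j + 1] = np.where(
            group_codes == j, 1.0, np.where(group_codes == n_levels - 1, -1.0, 0.0)
        )
    return X


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    if X.size == 0:
        return float(y @ y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def mixed_anova_2x2x3(
    scores: pd.DataFrame,
    group_labels: dict | pd.Series,
    dv: str = "score",
) -> pd.DataFrame:
    """Split-plot ANOVA: 3-level between factor, two 2-level within factors.

    ``scores`` is tidy with columns participant_id, feedback_valence,
    training_phase, and the dependent variable; ``group_labels`` maps
    participant_id -> strategy group.  Participants missing any of the four
    cells are dropped with a warning.  Type III sums of squares (sum-to-zero
    coding) accommodate unbalanced groups.  Returns a table with one row per
    effect: df_num, df_den, SS_num, SS_den, F, p, eta2_g.
    """
    wide = scores.pivot_table(
        index="participant_id",
        columns=["feedback_valence", "training_phase"],
        values=dv,
    )
    needed = [c for c in _CELL_ORDER]
    missing = [c for c in needed if c not in wide.columns]
    if missing:
        raise ValueError(f"missing design cells entirely: {missing}")
    complete = wide[needed].dropna()
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        import warnings

        warnings.warn(f"dropped {n_dropped} participants with incomplete cells",
                      stacklevel=2)
    labels = pd.Series(group_labels)
    groups = labels.reindex(complete.index)
    if groups.isna().any():
        raise ValueError("every retained participant needs a group label")
    levels = sorted(groups.unique())
    if len(levels) != 3:
        raise ValueError(f"expected 3 strategy groups, got {levels}")
    if groups.value_counts().min() < 2:
        raise ValueError("each group needs n >= 2")
    codes = groups.map({g: i for i, g in enumerate(levels)}).to_numpy()
    Y = complete.to_numpy()  # (n_subjects, 4) in _CELL_ORDER
    X = _sum_to_zero_design(codes, 3)
    n = len(Y)
    df_den = n - 3

    strata = {}
    for stratum, c in _CONTRASTS.items():
        z = Y @ c
        rss_full = _rss(X, z)
        ss_intercept = _rss(X[:, 1:], z) - rss_full  # Type III intercept
        ss_group = _rss(X[:, :1], z) - rss_full  # Type III group effect
        strata[stratum] = (ss_intercept, ss_group, rss_full)

    error_ss = [strata[s][2] for s in _CONTRASTS]
    effect_rows = [
        ("(Intercept)", "between", 0, 1),
        ("Strategy", "between", 1, 2),
        ("Training phase", "phase", 0, 1),
        ("Strategy x Training phase", "phase", 1, 2),
        ("Feedback valence", "valence", 0, 1),
        ("Strategy x Feedback valence", "valence", 1, 2),
        ("Training phase x Feedback valence", "phase_x_valence", 0, 1),
        ("Strategy x Training phase x Feedback valence", "phase_x_valence", 1, 2),
    ]
    rows = []
    for name, stratum, which, df_num in effect_rows:
        ss_num = strata[stratum][which]
        ss_den = strata[stratum][2]
        F = (ss_num / df_num) / (ss_den / df_den) if ss_den > 0 else np.inf
        p = float(stats.f.sf(F, df_num, df_den))
        rows.append(
            {
                "Predictor": name,
                "df_num": df_num,
                "df_den": df_den,
                "SS_num": ss_num,
                "SS_den": ss_den,
                "F": F,
                "p": p,
                "eta2_g": generalized_eta_squared(ss_num, error_ss),
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["cell_order"] = _CELL_ORDER
    table.attrs["group_levels"] = levels
    table.attrs["n_subjects"] = n
    return table


def phase_contrasts_by_group(
    scores: pd.DataFrame, group_labels: dict | pd.Series, dv: str = "score"
) -> pd.DataFrame:
    """Early-vs-late contrasts within each strategy group.

    Each group's mean early-late difference (valence-averaged) is tested
    against the phase-stratum error term of the split-plot model, so the t
    statistics share the omnibus df_den.
    """
    wide = scores.pivot_table(
        index="participant_id",
        columns=["feedback_valence", "training_phase"],
        values=dv,
    )[_CELL_ORDER].dropna()
    labels = pd.Series(group_labels).reindex(wide.index)
    levels = sorted(labels.unique())
    codes = labels.map({g: i for i, g in enumerate(levels)}).to_numpy()
    z = wide.to_numpy() @ _CONTRASTS["phase"]  # early - late per subject
    X = _sum_to_zero_design(codes, len(levels))
    mse = _rss(X, z) / (len(z) - len(levels))
    rows = []
    for i, g in enumerate(levels):
        zg = z[codes == i]
        se = np.sqrt(mse / len(zg))
        t = zg.mean() / se
        df = len(z) - len(levels)
        rows.append(
            {
                "group": g,
                "early_minus_late": zg.mean(),
                "t": t,
                "df": df,
                "p": 2 * stats.t.sf(abs(t), df),
                "n": len(zg),
            }
        )
    return pd.DataFrame(rows)


def paired_t(x: np.ndarray, y: np.ndarray) -> StatResult:
    """Dependent-samples t-test with CI of the mean difference and d_av."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("paired samples must have equal length >= 2")
    d = x - y
    n = len(d)
    se = d.std(ddof=1) / np.sqrt(n)
    if se == 0:
        if d.mean() == 0:
            return StatResult("paired_t", 0.0, (n - 1,), 1.0, "d_av", 0.0, (0.0, 0.0))
        raise ValueError("undefined t: zero-variance nonzero difference")
    t, p = stats.ttest_rel(x, y)
    ci = stats.t.interval(0.95, n - 1, loc=d.mean(), scale=se)
    d_av = cohens_d_av(x.mean(), x.std(ddof=1), y.mean(), y.std(ddof=1))
    return StatResult("paired_t", float(t), (n - 1,), float(p), "d_av",
                      float(d_av), (float(ci[0]), float(ci[1])))


def independent_t(x: np.ndarray, y: np.ndarray) -> StatResult:
    """Independent-samples t-test with CI of the mean difference and d_s."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    t, p = stats.ttest_ind(x, y)
    n1, n2 = len(x), len(y)
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    ci = stats.t.interval(0.95, n1 + n2 - 2, loc=x.mean() - y.mean(), scale=se)
    ds = cohens_d_s(x.mean(), x.std(ddof=1), n1, y.mean(), y.std(ddof=1), n2)
    return StatResult("independent_t", float(t), (n1 + n2 - 2,), float(p), "d_s",
                      ds.effect_size, (float(ci[0]), float(ci[1])))


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------


def _fmt_stat(r: StatResult) -> str:
    dfs = ", ".join(f"{d:g}" for d in r.df)
    s = f"{r.name}({dfs}) = {r.statistic:.2f}, p = {r.p_value:.3f}"
    if r.effect_size is not None:
        s += f", {r.effect_size_name} = {r.effect_size:.2f}"
    return s


def build_report(
    out_dir,
    strategy_tables: dict[str, pd.DataFrame] | None = None,
    accuracy: pd.DataFrame | None = None,
    condition_scores: pd.DataFrame | None = None,
    exclusions: pd.DataFrame | None = None,
    group_labels: dict | None = None,
) -> dict:
    """Assemble the full results surface as CSV files plus a text summary.

    Sections with missing inputs are flagged as absent rather than failing.
    ``strategy_tables`` maps segment name (e.g. "feedback_testing") to a
    strategy-proportion table; ``accuracy`` is tidy with columns
    participant_id, condition, strategy, accuracy.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sections: dict[str, object] = {}
    lines: list[str] = ["# Analysis report", ""]

    if strategy_tables:
        for segment, table in strategy_tables.items():
            table.to_csv(out / f"strategy_proportions_{segment}.csv", index=False)
        lines.append("## Strategy proportions")
        for segment, table in strategy_tables.items():
            lines.append(f"[{segment}] " + ", ".join(
                f"{r.strategy}: n={r.count} ({r.percent}%)" for r in table.itertuples()
            ))
        if {"observational_testing", "feedback_testing"} <= set(strategy_tables):
            obs = strategy_tables["observational_testing"]
            fb = strategy_tables["feedback_testing"]
            props = obs["count"].to_numpy() / obs["count"].sum()
            if np.all(props > 0):
                chi = chi_square_gof(fb["count"].to_numpy(), props)
                sections["chi_square"] = chi
                lines.append("Feedback vs observational proportions: " + _fmt_stat(chi))
        sections["strategy_tables"] = strategy_tables
        lines.append("")
    else:
        lines.append("## Strategy proportions: ABSENT (no strategy input)\n")

    if accuracy is not None:
        accuracy.to_csv(out / "testing_accuracy.csv", index=False)
        lines.append("## Testing accuracy by strategy")
        for condition, sub in accuracy.groupby("condition"):
            groups = {
                g: s["accuracy"].to_numpy()
                for g, s in sub.groupby("strategy")
                if len(s) >= 2
            }
            if len(groups) >= 2:
                omnibus, posthoc = one_way_anova(groups)
                kw, kw_posthoc = kruskal_wallis(groups)
                posthoc.to_csv(out / f"accuracy_posthoc_{condition}.csv", index=False)
                lines.append(f"[{condition}] ANOVA: " + _fmt_stat(omnibus))
                lines.append(f"[{condition}] Kruskal-Wallis: " + _fmt_stat(kw))
                sections[f"accuracy_anova_{condition}"] = omnibus
                sections[f"accuracy_kw_{condition}"] = kw
        lines.append("")
    else:
        lines.append("## Testing accuracy: ABSENT (no accuracy input)\n")

    if condition_scores is not None and group_labels is not None:
        for component in sorted(condition_scores["component"].unique()):
            sub = condition_scores[condition_scores["component"] == component]
            table = mixed_anova_2x2x3(sub, group_labels)
            table.to_csv(out / f"mixed_anova_{component}.csv", index=False)
            contrasts = phase_contrasts_by_group(sub, group_labels)
            contrasts.to_csv(out / f"phase_contrasts_{component}.csv", index=False)
            sections[f"mixed_anova_{component}"] = table
            lines.append(f"## {component} 2x2x3 mixed ANOVA")
            lines.append(
                table.round(3).to_string(index=False)
            )
            lines.append("")
        condition_scores.to_csv(out / "condition_scores.csv", index=False)
    else:
        lines.append("## ERP mixed ANOVAs: ABSENT (no ERP input)\n")

    if exclusions is not None:
        exclusions.to_csv(out / "exclusion_report.csv", index=False)
        n_exc = int(exclusions["excluded"].sum())
        lines.append(f"## Exclusions: {n_exc} participant(s) excluded "
                     f"(< minimum negative-feedback trials per phase)")
        sections["exclusions"] = exclusions

    (out / "report.txt").write_text("\n".join(lines) + "\n")
    sections["report_text"] = "\n".join(lines)
    return sections
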