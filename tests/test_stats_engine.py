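import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rivalrykit.stats_engine import (
    cohens_d_from_t,
    gg_epsilon,
    gg_epsilon_from_scores,
    independent_t,
    mann_whitney_u,
    mixed_anova,
    paired_t,
    pairwise_comparisons,
    partial_eta_squared,
    pearson_r,
)


# ---------------------------------------------------------------------------
# independent oracles


def split_plot_oracle(df, dv, subject, within, between):
    """Brute-force split-plot ANOVA via projection on the full long-form
    design (intercept | group | condition | group x condition | subjects
    within groups), sum-to-zero coding, Type-III partial sums of squares."""
    subjects = list(pd.unique(df[subject]))
    conds = list(pd.unique(df[within]))
    groups = list(pd.unique(df[between]))
    s_group = df.drop_duplicates(subject).set_index(subject)[between]
    N, k, g = len(subjects), len(conds), len(groups)

    def sum_code(values, levels):
        cols = []
        for lvl in levels[:-1]:
            c = np.where(values == lvl, 1.0, np.where(values == levels[-1], -1.0, 0.0))
            cols.append(c)
        return np.column_stack(cols)

    y = df[dv].to_numpy(dtype=float)
    G = sum_code(df[between].to_numpy(), groups)
    C = sum_code(df[within].to_numpy(), conds)
    GC = np.column_stack([G[:, i] * C[:, j]
                          for i in range(g - 1) for j in range(k - 1)])
    S_cols = []
    for grp in groups:
        members = [s for s in subjects if s_group[s] == grp]
        for s in members[:-1]:
            col = np.where(df[subject].to_numpy() == s, 1.0,
                           np.where(df[subject].to_numpy() == members[-1], -1.0, 0.0))
            col[df[between].to_numpy() != grp] = 0.0
            S_cols.append(col)
    S = np.column_stack(S_cols)
    one = np.ones((len(y), 1))

    def rss(*blocks):
        X = np.column_stack(blocks)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss_full = rss(one, G, C, GC, S)
    ss_c = rss(one, G, GC, S) - rss_full
    ss_gc = rss(one, G, C, S) - rss_full
    ss_g = rss(one, C, GC, S) - rss_full
    ss_s = rss(one, G, C, GC) - rss_full
    df_w = (k - 1) * (N - g)
    return {
        between: ((ss_g / (g - 1)) / (ss_s / (N - g)), (g - 1, N - g)),
        within: ((ss_c / (k - 1)) / (rss_full / df_w), (k - 1, df_w)),
        f"{within} * {between}": (
            (ss_gc / ((g - 1) * (k - 1))) / (rss_full / df_w),
            ((g - 1) * (k - 1), df_w),
        ),
    }


def gg_epsilon_eigen_oracle(cov):
    """Box epsilon via eigenvalues of the contrast-projected covariance."""
    k = cov.shape[0]
    A = np.column_stack([np.ones(k), np.eye(k)[:, : k - 1]])
    Q, _ = np.linalg.qr(A)
    C = Q[:, 1:]
    lam = np.linalg.eigvalsh(C.T @ cov @ C)
    return float(np.sum(lam) ** 2 / ((k - 1) * np.sum(lam ** 2)))


def mwu_enumeration_oracle(x, y):
    """U by direct pair counting; exact two-sided p by enumerating every
    assignment of the pooled sample to the two groups."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)

    def u_min(a, b):
        less = sum((ai < bj) + 0.5 * (ai == bj) for ai in a for bj in b)
        return min(less, len(a) * len(b) - less)

    observed = u_min(x, y)
    pooled = np.concatenate([x, y])
    total = 0
    extreme = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        mask = np.zeros(n1 + n2, dtype=bool)
        mask[list(idx)] = True
        total += 1
        if u_min(pooled[mask], pooled[~mask]) <= observed + 1e-12:
            extreme += 1
    return observed, min(1.0, extreme / total)


# ---------------------------------------------------------------------------
# effect sizes and elementary tests


@pytest.mark.parametrize("F, df1, df2, expected", [
    (232.0, 1.7, 48.2, 0.89),
    (215.0, 1.7, 49.9, 0.88),
    (18.7, 1.0, 29.0, 0.39),
    (245.0, 3.0, 87.0, 0.89),
    (3.87, 2.0, 56.0, 0.12),
    (5.33, 1.0, 28.0, 0.16),
    (5.98, 1.0, 28.0, 0.18),
])
def test_partial_eta_squared_reported_values(F, df1, df2, expected):
    assert round(partial_eta_squared(F, df1, df2), 2) == expected


def test_partial_eta_squared_edge_cases():
    assert partial_eta_squared(0.0, 2, 30) == 0.0
    with pytest.raises(ValueError):
        partial_eta_squared(-1.0, 2, 30)
    # identical for raw and sphericity-corrected dfs (same rescaling)
    eps = 0.71
    assert partial_eta_squared(12.0, 3, 60) == pytest.approx(
        partial_eta_squared(12.0, 3 * eps, 60 * eps)
    )


def test_cohens_d_from_t():
    assert round(cohens_d_from_t(2.55, 17, 14), 2) == 0.92
    assert cohens_d_from_t(0.0, 10, 10) == 0.0
    with pytest.raises(ValueError):
        cohens_d_from_t(1.0, 1, 10)


def test_cohens_d_matches_direct_pooled_sd_formula(rng):
    for _ in range(20):
        x = rng.normal(0.3, 1.0, size=int(rng.integers(5, 30)))
        y = rng.normal(0.0, 1.0, size=int(rng.integers(5, 30)))
        res = independent_t(x, y)
        sp = math.sqrt(((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1))
                       / (len(x) + len(y) - 2))
        d_direct = (x.mean() - y.mean()) / sp
        assert res.d == pytest.approx(d_direct, abs=1e-10)


def test_independent_t_pooled_df(rng):
    x, y = rng.normal(size=17), rng.normal(size=14)
    res = independent_t(x, y)
    assert res.df == 29
    t_ref, p_ref = sps.ttest_ind(x, y, equal_var=True)
    assert (res.t, res.p) == pytest.approx((t_ref, p_ref))
    with pytest.raises(ValueError):
        independent_t([1.0, 1.0], [1.0, 1.0])


def test_paired_t_hand_worked_and_degenerate():
    # differences (1, 2, 3): mean 2, sd 1, t = 2*sqrt(3)
    x, y = np.array([2.0, 4.0, 6.0]), np.array([1.0, 2.0, 3.0])
    res = paired_t(x, y)
    assert res.t == pytest.approx(2 * math.sqrt(3))
    assert res.df == 2
    with pytest.raises(ValueError):
        paired_t(x, x)


def test_pearson_r():
    x = np.array([1.0, 2.0, 4.0, 7.0])
    assert pearson_r(x, x)[0] == pytest.approx(1.0)
    assert pearson_r(x, -2 * x + 5)[0] == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        pearson_r(x, np.zeros_like(x))


def test_pearson_matches_covariance_formula(rng):
    for _ in range(20):
        x = rng.normal(size=12)
        y = 0.4 * x + rng.normal(size=12)
        r, _ = pearson_r(x, y)
        direct = np.cov(x, y)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
        assert r == pytest.approx(direct, abs=1e-12)


# ---------------------------------------------------------------------------
# Mann-Whitney


def test_mwu_known_values():
    u, _ = mann_whitney_u([1, 2], [3, 4])
    assert u == 0
    u, _ = mann_whitney_u([1, 2, 3], [1, 2, 3])
    assert u == 9 / 2
    with pytest.raises(ValueError):
        mann_whitney_u([], [1])


def test_mwu_matches_enumeration(rng):
    for _ in range(15):
        n1, n2 = int(rng.integers(3, 8)), int(rng.integers(3, 8))
        pooled = rng.permutation(100)[: n1 + n2].astype(float)  # distinct values
        x, y = pooled[:n1], pooled[n1:]
        u, p = mann_whitney_u(x, y)
        u_ref, p_ref = mwu_enumeration_oracle(x, y)
        assert u == pytest.approx(u_ref)
        assert p == pytest.approx(p_ref, abs=1e-12)


# ---------------------------------------------------------------------------
# sphericity


def test_gg_epsilon_two_levels_and_compound_symmetry():
    assert gg_epsilon(np.array([[2.0, 0.3], [0.3, 1.0]])) == 1.0
    k = 5
    cs = np.full((k, k), 0.4) + np.eye(k) * 0.6
    assert gg_epsilon(cs) == pytest.approx(1.0, abs=1e-12)


def test_gg_epsilon_matches_eigen_oracle_and_bounds(rng):
    for _ in range(50):
        k = int(rng.integers(3, 7))
        A = rng.normal(size=(k, k))
        S = A @ A.T + 0.1 * np.eye(k)
        eps = gg_epsilon(S)
        assert eps == pytest.approx(gg_epsilon_eigen_oracle(S), abs=1e-10)
        assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12


def test_gg_epsilon_from_scores_needs_two_subjects():
    with pytest.raises(ValueError):
        gg_epsilon_from_scores(np.ones((1, 4)))


# ---------------------------------------------------------------------------
# mixed ANOVA


def _long_table(rng, n_per_group=(6, 5), k=3, group_effect=0.0,
                cond_effect=0.0, subject_sd=1.0, noise_sd=1.0):
    rows = []
    for gi, n in enumerate(n_per_group):
        for s in range(n):
            pid = f"g{gi}s{s}"
            intercept = rng.normal(0, subject_sd) + gi * group_effect
            age = rng.normal(55, 10)
            for c in range(k):
                rows.append({
                    "participant_id": pid,
                    "group": f"grp{gi}",
                    "cond": f"c{c}",
                    "age": age,
                    "y": intercept + c * cond_effect + rng.normal(0, noise_sd),
                })
    return pd.DataFrame(rows)


def test_mixed_anova_matches_projection_oracle(rng):
    for n_per_group, k in (((6, 5), 3), ((4, 4), 2), ((7, 5), 4)):
        df = _long_table(rng, n_per_group, k, group_effect=0.5, cond_effect=0.3)
        table = mixed_anova(df, dv="y", subject="participant_id",
                            within="cond", between="group").set_index("Source")
        oracle = split_plot_oracle(df, "y", "participant_id", "cond", "group")
        for source, (f_ref, dfs_ref) in oracle.items():
            row = table.loc[source]
            assert row["F"] == pytest.approx(f_ref, abs=1e-8, rel=1e-8)
            assert (row["df1"], row["df2"]) == dfs_ref


def test_mixed_anova_matches_pingouin(rng):
    pingouin = pytest.importorskip("pingouin")
    df = _long_table(rng, (6, 6), 3, group_effect=0.8, cond_effect=0.5)
    ours = mixed_anova(df, dv="y", subject="participant_id",
                       within="cond", between="group").set_index("Source")
    ref = pingouin.mixed_anova(df, dv="y", within="cond",
                               subject="participant_id", between="group")
    ref = ref.set_index("Source")
    assert ours.loc["group", "F"] == pytest.approx(ref.loc["group", "F"])
    assert ours.loc["cond", "F"] == pytest.approx(ref.loc["cond", "F"])
    assert ours.loc["cond * group", "F"] == pytest.approx(
        ref.loc["Interaction", "F"])
    assert ours.loc["cond", "np2"] == pytest.approx(ref.loc["cond", "np2"])
    # epsilon uses the within-group pooled covariance (GLM-software
    # convention); check it against the eigenvalue formula on that matrix
    wide = df.pivot(index="participant_id", columns="cond", values="y")
    groups = df.drop_duplicates("participant_id").set_index("participant_id")["group"]
    centered = wide.to_numpy() - np.vstack([
        wide[groups.loc[wide.index] == g].mean().to_numpy()
        for g in groups.loc[wide.index]
    ])
    pooled = centered.T @ centered
    assert ours.loc["cond", "eps"] == pytest.approx(
        gg_epsilon_eigen_oracle(pooled), abs=1e-9)


def test_mixed_anova_two_within_factors_zero_effect_null(rng):
    # pure-noise two-within-factor design: all F finite, eta identity holds
    rows = []
    for gi, n in enumerate((5, 6)):
        for s in range(n):
            pid = f"g{gi}s{s}"
            for c in range(4):
                for p in range(2):
                    rows.append({
                        "participant_id": pid, "group": f"grp{gi}",
                        "cond": f"c{c}", "percept": f"p{p}",
                        "y": rng.normal(),
                    })
    df = pd.DataFrame(rows)
    table = mixed_anova(df, dv="y", subject="participant_id",
                        within=["cond", "percept"], between="group")
    sources = set(table["Source"])
    assert {"group", "cond", "percept", "cond * percept",
            "cond * percept * group"} <= sources
    for _, row in table.iterrows():
        assert row["F"] >= 0
        assert row["np2"] == pytest.approx(
            partial_eta_squared(row["F"], row["df1"], row["df2"]), abs=1e-9
        )
        if not math.isnan(row["eps"]):
            q = row["df1"]  # for main effects q = df1
            assert row["eps"] <= 1.0 + 1e-12


def test_mixed_anova_covariate_adjusts_dfs(rng):
    # 31 subjects (17/14), 3 within levels, age covariate: the between test
    # runs on (1, 28) df and within effects on (2, 56) df
    df = _long_table(rng, (17, 14), 3, group_effect=0.5, cond_effect=0.2)
    table = mixed_anova(df, dv="y", subject="participant_id",
                        within="cond", between="group",
                        covariate="age").set_index("Source")
    assert (table.loc["group", "df1"], table.loc["group", "df2"]) == (1, 28)
    assert (table.loc["cond", "df1"], table.loc["cond", "df2"]) == (2, 56)
    assert "age" in table.index


def test_mixed_anova_covariate_between_matches_ancova_on_subject_means(rng):
    pingouin = pytest.importorskip("pingouin")
    df = _long_table(rng, (9, 8), 3, group_effect=0.7)
    table = mixed_anova(df, dv="y", subject="participant_id",
                        within="cond", between="group",
                        covariate="age").set_index("Source")
    means = df.groupby("participant_id").agg(
        y=("y", "mean"), group=("group", "first"), age=("age", "first")
    ).reset_index()
    ref = pingouin.ancova(means, dv="y", between="group", covar="age")
    ref = ref.set_index("Source")
    assert table.loc["group", "F"] == pytest.approx(ref.loc["group", "F"])
    assert table.loc["age", "F"] == pytest.approx(ref.loc["age", "F"])


def test_mixed_anova_error_cases(rng):
    df = _long_table(rng, (4, 4), 3)
    const = df.assign(y=1.0)
    with pytest.raises(ValueError, match="singular"):
        mixed_anova(const, dv="y", subject="participant_id",
                    within="cond", between="group")
    holed = df[~((df["participant_id"] == "g0s0") & (df["cond"] == "c1"))]
    with pytest.raises(ValueError, match="g0s0"):
        mixed_anova(holed, dv="y", subject="participant_id",
                    within="cond", between="group")


def test_power_on_calibrated_cohorts():
    """With the default calibrated cohort (group difference injected through
    the mean dominance epoch only), the group main effect on the rivalry
    rate is significant in >= 80% of replicate cohorts and the condition
    effect on grouped time in >= 95%."""
    from rivalrykit.event_stream import aggregate_by_condition
    from rivalrykit.pipeline_io import analyze_logs
    from rivalrykit.synthetic_observer import default_cohort_config, simulate_cohort

    sig_rate = sig_cond = 0
    n_reps = 100
    for rep in range(n_reps):
        logs, meta = simulate_cohort(default_cohort_config(seed=50_000 + rep))
        pc = aggregate_by_condition(analyze_logs(logs)).merge(
            meta, on="participant_id")
        rate = pc[pc.condition_id.isin(["MO_SE_SH", "MO_SE_DH"])]
        t_rate = mixed_anova(rate, dv="rivalry_rate", subject="participant_id",
                             within="condition_id", between="group",
                             covariate="age").set_index("Source")
        sig_rate += t_rate.loc["group", "p"] < 0.05
        grouped = pc[pc.condition_id.isin(
            ["MO_SE_SH", "MO_SE_DH", "MO_DE_SH", "MO_DE_DH"])]
        t_cond = mixed_anova(grouped, dv="t_grouped", subject="participant_id",
                             within="condition_id", between="group"
                             ).set_index("Source")
        sig_cond += t_cond.loc["condition_id", "p_gg"] < 0.05
    assert sig_rate >= 0.80 * n_reps, sig_rate
    assert sig_cond >= 0.95 * n_reps, sig_cond


def test_pairwise_comparisons_adjustment(rng):
    df = _long_table(rng, (8, 7), 4, cond_effect=1.0)
    bon = pairwise_comparisons(df, dv="y", within="cond",
                               subject="participant_id", method="bonferroni")
    lsd = pairwise_comparisons(df, dv="y", within="cond",
                               subject="participant_id", method="lsd")
    assert len(bon) == 6
    assert np.allclose(bon["p_adj"], np.minimum(1.0, bon["p_raw"] * 6))
    assert np.allclose(lsd["p_adj"], lsd["p_raw"])
    assert (bon["p_adj"] >= bon["p_raw"] - 1e-15).all()
    assert (bon["p_adj"] <= 1.0).all()
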