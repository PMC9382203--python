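import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoramp.stats import (
    _mixed_anova_arrays,
    ln_transform,
    mann_whitney,
    mixed_anova,
    percent_difference,
    t_test_independent,
)


class TestLnTransform:
    def test_known_values(self):
        out = ln_transform([1.0, math.e, math.e**2])
        assert np.allclose(out, [0.0, 1.0, 2.0])

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ln_transform([1.0, 0.0])

    def test_log_scale_ratio_identity(self):
        # exp(mean log difference) equals the ratio of geometric means.
        rng = np.random.default_rng(0)
        x, y = rng.lognormal(0, 0.3, 50), rng.lognormal(0.2, 0.3, 50)
        lhs = math.exp(np.mean(ln_transform(y)) - np.mean(ln_transform(x)))
        rhs = np.exp(np.mean(np.log(y))) / np.exp(np.mean(np.log(x)))
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestTTest:
    def test_pooled_hand_oracle(self):
        # x={1,2,3}, y={4,5,6}: pooled sp²=1, se=√(2/3), t=−3/0.8165=−3.674.
        t, df, p = t_test_independent([1, 2, 3], [4, 5, 6], equal_var=True)
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == 4
        assert p == pytest.approx(0.0214, abs=5e-4)

    def test_group_swap_negates_t(self):
        t1, _, p1 = t_test_independent([1.0, 2.4, 3.1], [2.0, 4.5, 5.0])
        t2, _, p2 = t_test_independent([2.0, 4.5, 5.0], [1.0, 2.4, 3.1])
        assert t1 == pytest.approx(-t2, rel=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_identical_groups(self):
        t, _, p = t_test_independent([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert t == 0.0 and p == 1.0


def exact_mw_p(x, y):
    """Enumeration oracle: two-sided p over all group relabellings."""
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_of(idx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        return sum((xi > ys).sum() + 0.5 * (xi == ys).sum() for xi in xs)

    u_obs = u_of(range(n1))
    mu = n1 * (len(pooled) - n1) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_of(idx) - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_complete_separation_9v9_exact(self):
        x = np.arange(1.0, 10.0)
        y = np.arange(100.0, 109.0)
        u, p = mann_whitney(x, y)
        assert u == 0.0
        assert p == pytest.approx(2.0 / math.comb(18, 9), rel=1e-9)

    def test_enumeration_oracle_small_samples(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(0, 1, 4), rng.normal(0.8, 1, 5)
        _, p = mann_whitney(x, y)
        assert p == pytest.approx(exact_mw_p(x, y), rel=1e-9)

    def test_identical_single_values_with_ties(self):
        u, p = mann_whitney([3.0], [3.0])
        assert u == 0.5
        assert p == 1.0

    def test_label_swap_complements_u(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 6), rng.normal(0.3, 1, 8)
        u1, p1 = mann_whitney(x, y)
        u2, p2 = mann_whitney(y, x)
        assert u1 + u2 == pytest.approx(len(x) * len(y))
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_exact_and_normal_branch_agree_at_9v9(self):
        rng = np.random.default_rng(30)
        x, y = rng.normal(0, 1, 9), rng.normal(0.9, 1, 9)
        _, p_exact = mann_whitney(x, y, method="exact")
        _, p_norm = mann_whitney(x, y, method="asymptotic")
        assert abs(p_exact - p_norm) < 0.01


def brute_force_split_plot(wide, codes):
    """Independent cell-means sums-of-squares computation (explicit loops)."""
    n, k = wide.shape
    groups = sorted(set(codes))
    grand = wide.mean()
    ss_group = ss_subj = ss_level = ss_inter = ss_err = 0.0
    group_mean = {g: wide[codes == g].mean() for g in groups}
    level_mean = [wide[:, j].mean() for j in range(k)]
    cell = {(g, j): wide[codes == g][:, j].mean() for g in groups for j in range(k)}
    for g in groups:
        ng = (codes == g).sum()
        ss_group += k * ng * (group_mean[g] - grand) ** 2
        for j in range(k):
            ss_inter += ng * (cell[g, j] - group_mean[g] - level_mean[j] + grand) ** 2
    for i in range(n):
        ss_subj += k * (wide[i].mean() - group_mean[codes[i]]) ** 2
        for j in range(k):
            ss_err += (
                wide[i, j] - wide[i].mean() - cell[codes[i], j] + group_mean[codes[i]]
            ) ** 2
    for j in range(k):
        ss_level += n * (level_mean[j] - grand) ** 2
    return {
        "group": (ss_group / (len(groups) - 1)) / (ss_subj / (n - len(groups))),
        "within": (ss_level / (k - 1)) / (ss_err / ((n - len(groups)) * (k - 1))),
        "interaction": (ss_inter / ((len(groups) - 1) * (k - 1)))
        / (ss_err / ((n - len(groups)) * (k - 1))),
    }


def simulate_long(seed, n_per_group=6, k=4, interaction=0.5):
    rng = np.random.default_rng(seed)
    rows = []
    for g, gname in enumerate(["normoxia", "hyperoxia"]):
        for s in range(n_per_group):
            base = rng.normal(0, 1)
            for lvl in range(k):
                rows.append(
                    {
                        "subject": f"{gname}{s}",
                        "group": gname,
                        "level": float(lvl),
                        "value": base + 0.3 * lvl + interaction * g * lvl + rng.normal(0, 1),
                    }
                )
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_matches_brute_force_oracle(self):
        df = simulate_long(21)
        wide = df.pivot(index="subject", columns="level", values="value")
        codes = np.array([0 if s.startswith("h") else 1 for s in wide.index])
        oracle = brute_force_split_plot(wide.to_numpy(), codes)
        for res in mixed_anova(df):
            assert res.F == pytest.approx(oracle[res.effect], rel=1e-8, abs=1e-8)

    def test_matches_pingouin_f_statistics(self):
        pg = pytest.importorskip("pingouin")
        df = simulate_long(22)
        ours = {r.effect: r for r in mixed_anova(df)}
        theirs = pg.mixed_anova(
            data=df, dv="value", within="level", subject="subject", between="group"
        ).set_index("Source")
        assert ours["group"].F == pytest.approx(theirs.loc["group", "F"], rel=1e-9)
        assert ours["within"].F == pytest.approx(theirs.loc["level", "F"], rel=1e-9)
        assert ours["interaction"].F == pytest.approx(
            theirs.loc["Interaction", "F"], rel=1e-9
        )

    def test_two_levels_force_epsilon_one(self):
        df = simulate_long(23, k=2)
        for res in mixed_anova(df):
            assert res.gg_epsilon == 1.0

    def test_all_equal_values_flagged_degenerate(self):
        df = simulate_long(24)
        df["value"] = 5.0
        for res in mixed_anova(df):
            assert res.degenerate
            assert math.isnan(res.F)

    def test_listwise_deletion_of_incomplete_subjects(self):
        df = simulate_long(25)
        dropped = df[~((df.subject == "normoxia0") & (df.level == 3.0))]
        full = mixed_anova(df[df.subject != "normoxia0"])
        partial = mixed_anova(dropped)
        for a, b in zip(full, partial):
            assert a.F == pytest.approx(b.F, rel=1e-12)

    @given(seed=st.integers(0, 500), k=st.integers(3, 5), n=st.integers(3, 7))
    @settings(max_examples=20)
    def test_epsilon_within_theoretical_bounds(self, seed, k, n):
        df = simulate_long(seed, n_per_group=n, k=k)
        for res in mixed_anova(df):
            assert 1.0 / (k - 1) - 1e-12 <= res.gg_epsilon <= 1.0 + 1e-12

    def test_epsilon_near_one_for_compound_symmetric_data(self):
        # Exchangeable covariance satisfies sphericity, so the estimated
        # epsilon should approach its upper bound with many subjects.
        rng = np.random.default_rng(77)
        n, k = 200, 4
        wide = rng.normal(0, 1, (n, 1)) + rng.normal(0, 1, (n, k))
        codes = np.repeat([0, 1], n // 2)
        res = _mixed_anova_arrays(wide, codes)
        assert res[1].gg_epsilon > 0.93

    def test_type_one_error_of_gg_interaction_near_nominal(self):
        # Null simulation: n=9 per group, k=5 exchangeable levels; the
        # GG-adjusted interaction test should reject at close to 5%.
        rng = np.random.default_rng(123)
        reps, n, k = 2000, 18, 5
        codes = np.repeat([0, 1], n // 2)
        rejections = 0
        for _ in range(reps):
            wide = rng.normal(0, 1, (n, 1)) + rng.normal(0, 1, (n, k))
            res = _mixed_anova_arrays(wide, codes)
            if res[2].p_gg < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07


class TestPercentDifference:
    def test_signed_relative_change(self):
        assert percent_difference(200.0, 300.0) == pytest.approx(50.0)
        assert percent_difference(300.0, 200.0) == pytest.approx(-100.0 / 3.0)
        with pytest.raises(ValueError):
            percent_difference(0.0, 1.0)
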