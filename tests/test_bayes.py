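"""Bayes-factor battery against independent quadrature / analytic oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from palmflow import bayes

pg = pytest.importorskip("pingouin")


def grid_oracle_t_bf(t, n, sided="two", scale=math.sqrt(2) / 2):
    """Dense-grid trapezoid integration of the JZS marginal likelihood."""
    df = n - 1
    if sided == "greater":
        delta, mult = np.linspace(0, 15, 150_001), 2.0
    elif sided == "less":
        delta, mult = np.linspace(-15, 0, 150_001), 2.0
    else:
        delta, mult = np.linspace(-15, 15, 300_001), 1.0
    dens = stats.nct.pdf(t, df, delta * math.sqrt(n)) * stats.cauchy.pdf(
        delta, 0, scale
    )
    num = mult * np.trapezoid(dens, delta)
    return num / stats.t.pdf(t, df)


def grid_oracle_corr_bf(r, n):
    """Dense-grid quadrature of the uniform-prior correlation Bayes factor."""
    rho = np.linspace(-1 + 1e-9, 1 - 1e-9, 400_001)
    from scipy.special import hyp2f1

    h = hyp2f1(0.5, 0.5, (2 * n - 1) / 2, (rho * r + 1) / 2)
    h0 = hyp2f1(0.5, 0.5, (2 * n - 1) / 2, 0.5)
    dens = (1 - rho**2) ** ((n - 1) / 2) * (1 - rho * r) ** (1.5 - n) * h / h0
    return np.trapezoid(0.5 * dens, rho)


class TestOneSampleT:
    def test_data_at_null_favor_null(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0] * 8 + [0.0, 0.0])
        res = bayes.bf_one_sample_t(x, 0.0)
        assert res.extra["t"] == 0.0
        assert res.bf10 < 1

    def test_one_and_two_sided_agree_at_t_zero(self):
        x = np.array([-1.0, 1.0, -2.0, 2.0, -0.5, 0.5])
        two = bayes.bf_one_sample_t(x, 0.0, sided="two").bf10
        greater = bayes.bf_one_sample_t(x, 0.0, sided="greater").bf10
        assert greater == pytest.approx(two, rel=1e-8)

    @pytest.mark.parametrize("sided", ["two", "greater", "less"])
    def test_matches_grid_quadrature_oracle(self, sided):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(5, 60))
            x = rng.normal(rng.uniform(-0.8, 0.8), 1.0, n)
            res = bayes.bf_one_sample_t(x, 0.0, sided=sided)
            oracle = grid_oracle_t_bf(res.extra["t"], n, sided=sided)
            assert res.bf10 == pytest.approx(oracle, rel=1e-4)

    def test_two_sided_matches_pingouin(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = int(rng.integers(5, 80))
            x = rng.normal(rng.uniform(-1, 1), 1.0, n)
            res = bayes.bf_one_sample_t(x)
            ref = float(
                pg.bayesfactor_ttest(res.extra["t"], n, paired=True, r=math.sqrt(2) / 2)
            )
            assert res.bf10 == pytest.approx(ref, rel=1e-6)

    def test_monotone_in_t_magnitude(self):
        bfs = [bayes.bf_t_from_stat(t, 30) for t in [0.0, 0.5, 1.0, 2.0, 4.0, 8.0]]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            bayes.bf_one_sample_t([1.0, 1.0, 1.0])

    def test_bf01_is_reciprocal(self):
        res = bayes.bf_one_sample_t([0.1, 0.5, -0.3, 0.8, 0.2])
        assert res.bf01 * res.bf10 == pytest.approx(1.0)


class TestCorrelation:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        res = bayes.bf_correlation(x, 2 * x + 1)
        assert res.extra["r"] == pytest.approx(1.0)
        assert res.extra["r2"] == pytest.approx(1.0)
        assert res.bf10 == math.inf

    def test_independent_data_favor_null_mostly(self):
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(50):
            x, y = rng.normal(size=(2, 42))
            if bayes.bf_correlation(x, y).bf10 < 1:
                hits += 1
        assert hits >= 40  # >= 80% of runs

    def test_matches_grid_quadrature_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            n = int(rng.integers(5, 80))
            x = rng.normal(size=n)
            y = rng.uniform(-0.9, 0.9) * x + rng.normal(size=n)
            res = bayes.bf_correlation(x, y)
            assert res.bf10 == pytest.approx(
                grid_oracle_corr_bf(res.extra["r"], n), rel=1e-3
            )

    def test_matches_exact_closed_form(self):
        # pingouin implements the analytic (hypergeometric) solution
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(6, 60))
            x = rng.normal(size=n)
            y = 0.4 * x + rng.normal(size=n)
            res = bayes.bf_correlation(x, y)
            ref = float(pg.bayesfactor_pearson(res.extra["r"], n))
            assert res.bf10 == pytest.approx(ref, rel=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            bayes.bf_correlation([1, 1, 1, 1], [1, 2, 3, 4])


def make_rm_table(rng, n_subj=20, effect=0.0, n_cond=3, subj_sd=0.08, noise=0.06):
    rows = []
    conds = [f"c{i}" for i in range(n_cond)]
    offs = np.linspace(-effect / 2, effect / 2, n_cond)
    subj = rng.normal(0, subj_sd, n_subj)
    for i in range(n_subj):
        for j, c in enumerate(conds):
            rows.append((i, c, 0.6 + subj[i] + offs[j] + rng.normal(0, noise)))
    return pd.DataFrame(rows, columns=["participant", "condition", "value"])


class TestRmAnova:
    def test_two_level_reduction_equals_paired_t(self):
        """With subjects swept out exactly and matched prior scale, the
        two-level single-factor inclusion BF is the JZS paired t-test."""
        rng = np.random.default_rng(8)
        for _ in range(2):
            tab = make_rm_table(rng, n_subj=18, effect=rng.uniform(0, 0.15), n_cond=2)
            wide = tab.pivot(index="participant", columns="condition", values="value")
            bf_t = bayes.bf_one_sample_t((wide["c0"] - wide["c1"]).to_numpy()).bf10
            res = bayes.bf_rm_anova(
                tab,
                factors=("condition",),
                mc_iterations=120_000,
                seed=9,
                subject_treatment="flat",
                fixed_scale=math.sqrt(2) / 2,
            )
            bf_a = res.per_effect["condition"].bf10
            err = res.per_effect["condition"].mc_error
            assert bf_a == pytest.approx(bf_t, rel=max(5 * err, 0.02))

    def test_strong_condition_effect_detected(self):
        rng = np.random.default_rng(10)
        tab = make_rm_table(rng, n_subj=30, effect=0.12)
        res = bayes.bf_rm_anova(tab, factors=("condition",), mc_iterations=5000, seed=11)
        assert res.per_effect["condition"].bf10 > 100

    def test_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(12)
        tab = make_rm_table(rng)
        a = bayes.bf_rm_anova(tab, factors=("condition",), mc_iterations=2000, seed=13)
        b = bayes.bf_rm_anova(tab, factors=("condition",), mc_iterations=2000, seed=13)
        assert a.per_effect["condition"].bf10 == b.per_effect["condition"].bf10

    def test_seed_dispersion_consistent_with_reported_mc_error(self):
        rng = np.random.default_rng(14)
        tab = make_rm_table(rng, effect=0.05)
        bfs, errs = [], []
        for s in range(12):
            res = bayes.bf_rm_anova(
                tab, factors=("condition",), mc_iterations=4000, seed=s
            )
            bfs.append(math.log(res.per_effect["condition"].bf10))
            errs.append(res.per_effect["condition"].mc_error)
        assert np.std(bfs) < 5 * max(errs)

    def test_missing_cells_trigger_subject_deletion(self):
        rng = np.random.default_rng(15)
        tab = make_rm_table(rng)
        tab.loc[(tab.participant == 0) & (tab.condition == "c0"), "value"] = np.nan
        res = bayes.bf_rm_anova(tab, factors=("condition",), mc_iterations=500, seed=16)
        assert res.n_dropped_subjects == 1

    def test_model_posteriors_sum_to_one(self):
        rng = np.random.default_rng(17)
        rows = [
            (i, c, d, rng.normal(0.6, 0.1))
            for i in range(10)
            for c in range(3)
            for d in range(4)
        ]
        tab = pd.DataFrame(rows, columns=["participant", "condition", "duration", "value"])
        res = bayes.bf_rm_anova(tab, mc_iterations=1000, seed=18)
        assert sum(res.model_posteriors.values()) == pytest.approx(1.0)
        assert set(res.per_effect) == {"condition", "duration", "condition:duration"}

    def test_too_few_subjects_rejected(self):
        tab = pd.DataFrame(
            {"participant": [1, 1], "condition": ["a", "b"], "value": [0.1, 0.2]}
        )
        with pytest.raises(ValueError):
            bayes.bf_rm_anova(tab, factors=("condition",), mc_iterations=100)


class TestPosthocPairs:
    def test_identity_with_one_sample_t_on_differences(self):
        rng = np.random.default_rng(19)
        wide = pd.DataFrame(
            rng.normal(0.6, 0.1, size=(25, 3)), columns=["vertical", "horizontal", "oblique"]
        )
        results = bayes.bf_posthoc_pairs(wide)
        assert len(results) == 3
        for res in results:
            a, b = res.effect.split(" vs ")
            direct = bayes.bf_one_sample_t((wide[a] - wide[b]).to_numpy())
            assert res.bf10 == pytest.approx(direct.bf10, rel=1e-12)

    def test_identical_columns_rejected_as_zero_variance(self):
        wide = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            bayes.bf_posthoc_pairs(wide)

    def test_simulated_oblique_deficit_pattern(self):
        rng = np.random.default_rng(20)
        n = 40
        base = rng.normal(0.63, 0.06, n)
        wide = pd.DataFrame(
            {
                "vertical": base + rng.normal(0, 0.05, n),
                "horizontal": base + rng.normal(0, 0.05, n),
                "oblique": base - 0.08 + rng.normal(0, 0.05, n),
            }
        )
        res = {r.effect: r.bf10 for r in bayes.bf_posthoc_pairs(wide)}
        assert res["vertical vs oblique"] > 10
        assert res["horizontal vs oblique"] > 10
        assert res["vertical vs horizontal"] < 1


@pytest.fixture(scope="module")
def strong_effect_table():
    rng = np.random.default_rng(21)
    rows = []
    for i in range(16):
        base = rng.normal(0.63, 0.05)
        for c, off in (("vertical", 0.0), ("horizontal", 0.0), ("oblique", -0.09)):
            rows.append((i, c, base + off + rng.normal(0, 0.02)))
    return pd.DataFrame(rows, columns=["participant", "condition", "value"])


class TestSequential:
    def test_crossing_at_minimum_sample(self, strong_effect_table):
        seq = bayes.sequential_bf(
            strong_effect_table,
            effect="condition",
            mc_iterations=1500,
            seed=22,
        )
        assert seq.crossing_n == 12

    def test_trajectory_end_matches_direct_recomputation(self, strong_effect_table):
        seq = bayes.sequential_bf(
            strong_effect_table, effect="condition", mc_iterations=1500, seed=23
        )
        n_last, bf_last = seq.trajectory[-1]
        direct = bayes.bf_rm_anova(
            strong_effect_table,
            factors=("condition",),
            mc_iterations=1500,
            seed=(23, n_last),
        )
        assert bf_last == pytest.approx(direct.per_effect["condition"].bf10, rel=1e-12)

    def test_pure_noise_never_crosses_upwards(self):
        rng = np.random.default_rng(24)
        rows = [
            (i, c, rng.normal(0.6, 0.08))
            for i in range(14)
            for c in ("vertical", "horizontal", "oblique")
        ]
        tab = pd.DataFrame(rows, columns=["participant", "condition", "value"])
        seq = bayes.sequential_bf(tab, effect="condition", mc_iterations=1500, seed=25)
        bfs = [bf for n, bf in seq.trajectory if n >= seq.n_min]
        assert all(bf < seq.threshold for bf in bfs)

    def test_unknown_effect_rejected(self, strong_effect_table):
        with pytest.raises(ValueError):
            bayes.sequential_bf(strong_effect_table, effect="nope", mc_iterations=100)


class TestBetweenAnova:
    def test_group_shift_detected_and_null_calibrated(self):
        rng = np.random.default_rng(26)
        groups = np.repeat(["a", "b", "c"], 20)
        null_vals = rng.normal(0, 1, 60)
        shifted = null_vals + np.repeat([0.0, 1.2, 2.4], 20)
        bf_null = bayes.bf_between_anova(null_vals, groups, mc_iterations=4000, seed=27)
        bf_eff = bayes.bf_between_anova(shifted, groups, mc_iterations=4000, seed=27)
        assert bf_eff.bf10 > 100
        assert bf_null.bf10 < 1
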