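"""Synthetic cohort generator: calibration, recovery, pathology injection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import palmflow as pf
from palmflow import io as pio
from palmflow import synthetic as syn
from palmflow.metacognition import type2_aroc


class TestCohortSampling:
    def test_default_population_shows_oblique_deficit(self):
        coh = syn.sample_cohort(42, seed=0)
        p = pd.DataFrame([o.p_by_condition for o in coh.observers.values()])
        assert p["oblique"].mean() < p["vertical"].mean()
        assert p["oblique"].mean() < p["horizontal"].mean()

    def test_zero_population_sd_gives_identical_observers(self):
        pop = syn.PopulationSpec(
            sd_logit_between=0.0,
            sd_logit_condition=0.0,
            aroc_sd=0.0,
            conf_drive_sd=0.0,
        )
        coh = syn.sample_cohort(5, population=pop, seed=1)
        obs = list(coh.observers.values())
        for o in obs[1:]:
            assert o.p_by_condition == obs[0].p_by_condition
            assert o.metacog_m == obs[0].metacog_m
            assert o.conf_drive == obs[0].conf_drive

    def test_large_sample_means_match_population(self):
        """Sample means of the generative parameters sit within 3 SE of the
        population expectations (computed by an independent Monte-Carlo
        oracle for the truncated logit-normal)."""
        pop = syn.PopulationSpec()
        coh = syn.sample_cohort(10_000, population=pop, seed=2)
        p = pd.DataFrame([o.p_by_condition for o in coh.observers.values()])

        # oracle: direct large-sample expectation of clip(expit(l0+N), 0.5, .995)
        rng = np.random.default_rng(99)
        z = rng.normal(0, 1, 400_000)
        for cond, p0 in pop.p_by_condition.items():
            sd = np.hypot(pop.sd_logit_between, pop.sd_logit_condition)
            l0 = np.log(p0 / (1 - p0))
            expected = np.clip(1 / (1 + np.exp(-(l0 + sd * z))), 0.5, 0.995).mean()
            se = p[cond].std() / np.sqrt(len(p))
            assert abs(p[cond].mean() - expected) < 3 * se + 1e-3

        drives = np.array([o.conf_drive for o in coh.observers.values()])
        assert abs(drives.mean() - pop.conf_drive_mean) < 3 * drives.std() / np.sqrt(
            len(drives)
        )

    def test_invalid_population_rejected(self):
        with pytest.raises(ValueError):
            syn.PopulationSpec(p_oblique=0.3)
        with pytest.raises(ValueError):
            syn.PopulationSpec(aroc_sd=-1)
        with pytest.raises(ValueError):
            syn.sample_cohort(0)

    def test_reproducible_from_seed(self):
        a = syn.sample_cohort(4, seed=7)
        b = syn.sample_cohort(4, seed=7)
        assert [o.metacog_m for o in a.observers.values()] == [
            o.metacog_m for o in b.observers.values()
        ]


class TestArocCalibration:
    def test_expected_aroc_at_zero_separation_is_chance(self):
        assert syn.expected_aroc(0.0) == pytest.approx(0.5)

    def test_expected_aroc_increases_with_separation(self):
        vals = [syn.expected_aroc(m) for m in (0.0, 0.3, 0.8, 2.0, 5.0)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert vals[-1] > 0.95

    def test_inversion_roundtrip(self):
        for target in (0.52, 0.57, 0.7, 0.9):
            m = syn.metacog_separation_for_aroc(target)
            assert syn.expected_aroc(m) == pytest.approx(target, abs=1e-8)

    def test_closed_form_matches_simulation(self):
        """The analytic AROC of the ordinal confidence model agrees with a
        brute-force simulated estimate."""
        rng = np.random.default_rng(3)
        m, shift = 0.6, 0.3
        n = 200_000
        correct = rng.random(n) < 0.65
        latent = shift + np.where(correct, m / 2, -m / 2) + rng.normal(size=n)
        conf = 1 + (latent[:, None] > np.array(syn.DEFAULT_THRESHOLDS)).sum(axis=1)
        est = type2_aroc(correct, conf).aroc
        assert est == pytest.approx(
            syn.expected_aroc(m, shifts=[shift]), abs=0.005
        )


class TestSimulateResponses:
    def test_uninformative_observer_is_at_chance(self):
        sched = pf.build_schedule(6, seed=4)
        pop = syn.PopulationSpec(
            p_vertical=0.5, p_horizontal=0.5, p_oblique=0.5,
            sd_logit_between=0.0, sd_logit_condition=0.0,
            aroc_mean=0.5, aroc_sd=0.0,
        )
        coh = syn.sample_cohort(6, population=pop, seed=5,
                                durations_ms=sched.grid.values_ms)
        df = syn.simulate_responses(sched, coh, seed=6)
        n = len(df)
        assert df["correct"].mean() == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(n))
        aroc = type2_aroc(df["correct"], df["confidence"].astype(int)).aroc
        assert aroc == pytest.approx(0.5, abs=0.02)

    def test_perfect_metacognition_limit(self):
        sched = pf.build_schedule(2, seed=7)
        pop = syn.PopulationSpec(aroc_mean=0.95, aroc_sd=0.0,
                                 conf_drive_mean=0.0, conf_drive_sd=0.0)
        coh = syn.sample_cohort(2, population=pop, seed=8,
                                durations_ms=sched.grid.values_ms)
        df = syn.simulate_responses(sched, coh, seed=9)
        aroc = type2_aroc(df["correct"], df["confidence"].astype(int)).aroc
        assert aroc > 0.9

    def test_group_calibration_at_study_scale(self):
        """42 observers x 600 trials at p = 0.65 and target AROC 0.57:
        group means land within 2 SE of the calibrated values."""
        sched = pf.build_schedule(42, seed=10)
        pop = syn.PopulationSpec(
            p_vertical=0.65, p_horizontal=0.65, p_oblique=0.65,
            sd_logit_between=0.0, sd_logit_condition=0.0,
            aroc_mean=0.57, aroc_sd=0.0,
        )
        coh = syn.sample_cohort(42, population=pop, seed=11,
                                durations_ms=sched.grid.values_ms)
        df = syn.simulate_responses(sched, coh, seed=12)
        accs = df.groupby("participant")["correct"].mean()
        se_acc = accs.std() / np.sqrt(len(accs))
        assert abs(accs.mean() - 0.65) < 2 * se_acc + 1e-9
        arocs = df.groupby("participant").apply(
            lambda s: type2_aroc(s["correct"], s["confidence"].astype(int)).aroc,
            include_groups=False,
        )
        se_a = arocs.std() / np.sqrt(len(arocs))
        assert abs(arocs.mean() - 0.57) < 2 * se_a + 1e-9

    def test_accuracy_parameter_recovery(self):
        """Per-condition accuracy on 200 trials recovers the generating p_c
        with RMSE <= 0.04 (pooled over many simulated cohorts)."""
        sched = pf.build_schedule(5, seed=13)
        sq_errs = []
        for rep in range(20):
            coh = syn.sample_cohort(5, seed=100 + rep,
                                    durations_ms=sched.grid.values_ms)
            df = syn.simulate_responses(sched, coh, seed=200 + rep)
            est = df.groupby(["participant", "condition"])["correct"].mean()
            for (pid, cond), phat in est.items():
                sq_errs.append((phat - coh.observers[pid].p_by_condition[cond]) ** 2)
        assert np.sqrt(np.mean(sq_errs)) <= 0.04

    def test_missing_observer_rejected(self):
        sched = pf.build_schedule(3, seed=14)
        coh = syn.sample_cohort(2, seed=15)
        with pytest.raises(ValueError):
            syn.simulate_responses(sched, coh, seed=16)

    def test_roundtrip_through_csv(self, tmp_path, cohort_records):
        path = tmp_path / "trials.csv"
        pio.write_trials(cohort_records, path)
        back = pio.read_trials(path)
        pd.testing.assert_frame_equal(
            back, cohort_records.reset_index(drop=True), check_dtype=False
        )


class TestExclusionInjection:
    def test_single_key_mode(self, cohort_records):
        df = syn.inject_exclusion_case(cohort_records, "single-key", seed=17)
        shares = df.groupby("participant")["response_interval"].agg(
            lambda r: r.value_counts(normalize=True).iloc[0]
        )
        flagged = shares[shares >= 0.95]
        assert len(flagged) == 1
        # correctness stays consistent with the rewritten responses
        sub = df[df.participant == flagged.index[0]]
        assert (sub["correct"] == (sub["response_interval"] == sub["correct_interval"])).all()

    def test_none_mode_is_identity(self, cohort_records):
        out = syn.inject_exclusion_case(cohort_records, "none")
        pd.testing.assert_frame_equal(out, cohort_records)

    def test_mapping_flip_inverts_accuracy(self, cohort_records):
        pid = int(cohort_records["participant"].min())
        before = cohort_records[cohort_records.participant == pid]["correct"].mean()
        out = syn.inject_exclusion_case(cohort_records, "mapping-flip")
        after = out[out.participant == pid]["correct"].mean()
        assert after == pytest.approx(1 - before)

    def test_unknown_mode_rejected(self, cohort_records):
        with pytest.raises(ValueError):
            syn.inject_exclusion_case(cohort_records, "gibberish")
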