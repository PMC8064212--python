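"""Generator consistency: known ground truth must survive the pipeline."""

import numpy as np
import pandas as pd
import pytest

import aaci
from aaci.simulate import ground_truth


class TestIntakes:
    def test_zero_deviation_scores_exactly_at_reference(self, ratios):
        cfg = aaci.SimulationConfig(n_subjects=300, seed=0, deviation_scale=0.0)
        intakes = aaci.simulate_intakes(cfg)
        res = aaci.compute_aaci(intakes, ratios)
        assert np.allclose(res["aaci"], 0.0, atol=1e-12)

    def test_degenerate_exposure_refused_downstream(self):
        cohort, _ = aaci.simulate_cohort(
            aaci.SimulationConfig(n_subjects=300, seed=0, deviation_scale=0.0)
        )
        with pytest.raises(ValueError, match="degenerate"):
            aaci.assign_tertiles(cohort["aaci"])
        with pytest.raises(Exception, match="variance"):
            aaci.fit_mediation(cohort, aaci.MediationSpec(outcome_link="logit"))

    def test_mean_aaci_monotone_in_deviation_scale(self, ratios):
        means = []
        for scale in (0.1, 0.3, 0.6):
            vals = []
            for seed in range(25):
                cfg = aaci.SimulationConfig(n_subjects=200, seed=seed, deviation_scale=scale)
                vals.append(aaci.compute_aaci(aaci.simulate_intakes(cfg), ratios)["aaci"].mean())
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_fixed_seed_reproduces_dataset(self):
        cfg = aaci.SimulationConfig(n_subjects=100, seed=5)
        c1, _ = aaci.simulate_cohort(cfg)
        c2, _ = aaci.simulate_cohort(cfg)
        pd.testing.assert_frame_equal(c1, c2)


class TestSerum:
    def fitted_beta(self, slopes, seed=0, n=20000):
        cfg = aaci.SimulationConfig(n_subjects=n, seed=seed, serum_slopes=slopes)
        cohort, _ = aaci.simulate_cohort(cfg)
        ladder = aaci.ModelLadder(models={"m1": ["age", "sex"]})
        return {
            aa: aaci.fit_linear_std(cohort, f"serum_{aa}", ladder)["m1"]
            for aa in slopes
        }

    def test_null_slope_gives_null_beta(self):
        beta, _ = self.fitted_beta({"valine": 0.0})["valine"]
        assert abs(beta) < 0.02

    def test_negative_slope_recovered_with_sign(self):
        beta, p = self.fitted_beta({"histidine": -0.15})["histidine"]
        assert beta == pytest.approx(-0.15, abs=0.02)
        assert p < 1e-3

    def test_default_sign_structure(self, sim_cohort):
        cohort, _, _ = sim_cohort
        ladder = aaci.ModelLadder(models={"m1": ["age", "sex"]})
        betas = {
            aa: aaci.fit_linear_std(cohort, f"serum_{aa}", ladder)["m1"][0]
            for aa in ("valine", "isoleucine", "glutamic_acid", "phenylalanine",
                       "glycine", "histidine")
        }
        for aa in ("valine", "isoleucine", "glutamic_acid", "phenylalanine"):
            assert betas[aa] > 0
        for aa in ("glycine", "histidine"):
            assert betas[aa] < 0

    def test_noiseless_single_predictor_beta_is_unity(self):
        # a slope of ~1 leaves no residual variance: standardized beta -> 1
        cfg = aaci.SimulationConfig(n_subjects=2000, seed=3,
                                    serum_slopes={"valine": 0.999999})
        cohort, _ = aaci.simulate_cohort(cfg)
        z = lambda s: (s - s.mean()) / s.std(ddof=0)
        beta = float(np.polyfit(z(cohort["aaci"]), z(cohort["serum_valine"]), 1)[0])
        assert beta == pytest.approx(1.0, abs=1e-2)


class TestOutcome:
    def test_generated_glucose_reproduces_flags_exactly(self, sim_cohort):
        cohort, _, _ = sim_cohort
        flags = aaci.ascertain_t2dm(cohort)
        assert (flags.astype(int).to_numpy() == cohort["t2dm_incident"].to_numpy()).all()

    def test_null_effects_give_flat_tertile_rrs(self):
        cfg = aaci.SimulationConfig(
            n_subjects=8000, seed=21, direct_logodds=0.0,
            mediator_logodds={"valine": 0.0, "glutamic_acid": 0.0, "histidine": 0.0},
        )
        cohort, truth = aaci.simulate_cohort(cfg)
        assert truth.total_effect == 0.0
        cohort, _ = aaci.score_and_cut(cohort, cohort["aaci"])
        res = aaci.fit_tertile_logistic(
            cohort, aaci.ModelLadder(models={"m1": ["age", "sex"]})
        )["m1"]
        assert np.all(np.abs(np.log(res.table["rr"].to_numpy()[1:])) < 0.4)

    def test_ground_truth_percentages_sum_to_target(self):
        truth = ground_truth(aaci.SimulationConfig())
        assert truth.total_percent_mediated == pytest.approx(30.0, abs=1e-9)
        assert sum(truth.indirect.values()) / truth.total_effect == pytest.approx(0.30)

    def test_extreme_incidence_warns(self):
        with pytest.warns(UserWarning, match="incidence"):
            aaci.simulate_cohort(
                aaci.SimulationConfig(n_subjects=500, seed=2, outcome_intercept=-7.0)
            )


class TestFFQ:
    def test_round_trip_non_negative_and_scoreable(self, ratios):
        cfg = aaci.SimulationConfig(n_subjects=80, seed=4)
        records, table = aaci.simulate_ffq(cfg)
        intakes = aaci.ffq_to_intake(records, table)
        assert (intakes.to_numpy() >= 0).all()
        res = aaci.compute_aaci(intakes, ratios)
        assert (res["aaci"] > 0).all()

    def test_fixed_seed_determinism(self):
        cfg = aaci.SimulationConfig(n_subjects=30, seed=6)
        r1, t1 = aaci.simulate_ffq(cfg)
        r2, t2 = aaci.simulate_ffq(cfg)
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_more_rice_raises_aaci_on_average(self, ratios):
        diffs = []
        for seed in range(12):
            cfg = aaci.SimulationConfig(n_subjects=150, seed=seed)
            lo_rec, table = aaci.simulate_ffq(cfg, rice_multiplier=0.5)
            hi_rec, _ = aaci.simulate_ffq(cfg, rice_multiplier=3.0)
            lo = aaci.compute_aaci(aaci.ffq_to_intake(lo_rec, table), ratios)["aaci"].mean()
            hi = aaci.compute_aaci(aaci.ffq_to_intake(hi_rec, table), ratios)["aaci"].mean()
            diffs.append(hi - lo)
        assert np.mean(diffs) > 0
        assert sum(d > 0 for d in diffs) >= 9  # sign consistent across seeds

    def test_rice_items_are_lysine_threonine_poor(self, pattern):
        _, table = aaci.simulate_ffq(aaci.SimulationConfig(n_subjects=1, seed=7))
        rice = table[table["food_group"] == "rice"]
        other = table[table["food_group"] != "rice"]
        ratio = lambda df: (df["lysine_mg"] / df["leucine_mg"]).mean()
        assert ratio(rice) < 0.5 * ratio(other)
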