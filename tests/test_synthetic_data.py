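"""Generator correctness: determinism, kinetics, mixtures, surfaces, tumors."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from celsignal.errors import ValidationError
from celsignal.plate_io import Antagonist, WellCondition
from celsignal.synthetic_data import (
    DEFAULT_COHORT_MIXTURE,
    DEFAULT_DRUGS,
    DrugSpec,
    MixtureSpec,
    PatientProfile,
    default_plate_layout,
    generate_cohort_profiles,
    generate_cohort_scores,
    generate_combination_surface,
    generate_plate,
    generate_trace,
    generate_xenograft,
    kinetic_kernel,
    median_effect_fa,
    solve_surface_fa,
    well_amplitude,
)
from celsignal.scoring import signaling_score


class TestCohortScores:
    def test_standard_normal_sample_mean(self):
        spec = MixtureSpec((1.0,), (0.0,), (1.0,))
        df, _ = generate_cohort_scores(spec, 10_000, seed=3)
        assert abs(df["score"].mean()) < 4 / np.sqrt(10_000)

    def test_default_cohort_row_count(self):
        df, labels = generate_cohort_scores(DEFAULT_COHORT_MIXTURE, 79, seed=1)
        assert len(df) == 79
        assert labels.shape == (79,)
        assert set(df["pathway"]) == {"cMet"}

    def test_determinism(self):
        a, la = generate_cohort_scores(DEFAULT_COHORT_MIXTURE, 50, seed=11)
        b, lb = generate_cohort_scores(DEFAULT_COHORT_MIXTURE, 50, seed=11)
        pd.testing.assert_frame_equal(a, b)
        np.testing.assert_array_equal(la, lb)

    def test_component_proportions_converge(self):
        n = 50_000
        _, labels = generate_cohort_scores(DEFAULT_COHORT_MIXTURE, n, seed=5)
        for k, pi in enumerate(DEFAULT_COHORT_MIXTURE.weights):
            se = np.sqrt(pi * (1 - pi) / n)
            assert abs(np.mean(labels == k) - pi) < 3 * se

    @pytest.mark.parametrize("bad", [
        {"weights": (0.5, 0.6), "means": (0, 1), "sds": (1, 1)},
        {"weights": (1.0,), "means": (0,), "sds": (0.0,)},
        {"weights": (1.0,), "means": (0, 1), "sds": (1,)},
    ])
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(ValidationError):
            MixtureSpec(**bad)


class TestTraces:
    def test_control_well_is_pure_baseline(self, noiseless_profile, c_condition):
        tr = generate_trace(noiseless_profile, c_condition, seed=0)
        np.testing.assert_allclose(tr.cell_index,
                                   noiseless_profile.baseline_ci)

    def test_noiseless_score_matches_kernel_integral(self, noiseless_profile,
                                                     cf3_condition):
        # saturating agonist: occupancy ~ 1, so the score equals capacity
        cond = WellCondition("DRUG", "P0001", agonist="HGF",
                             agonist_dose_molar=1.0)
        treated = generate_trace(noiseless_profile, cond, seed=0)
        control = generate_trace(noiseless_profile,
                                 WellCondition("C", "P0001"), seed=0)
        score = signaling_score(treated, control)
        a_eff = well_amplitude(noiseless_profile, cond)
        assert score == pytest.approx(a_eff, abs=1e-9)
        assert a_eff == pytest.approx(noiseless_profile.capacity["cMet"],
                                      rel=1e-9)
        # and the discrete normalizer agrees with quadrature of the kernel
        tau_r, tau_d = noiseless_profile.tau_rise, noiseless_profile.tau_decay
        integral, _ = quad(lambda t: kinetic_kernel(t, tau_r, tau_d), 0, 240)
        grid_sum = kinetic_kernel(np.arange(241.0), tau_r, tau_d).sum()
        assert grid_sum == pytest.approx(integral, rel=0.01)

    def test_score_linear_in_amplitude(self, cf3_condition):
        scores = []
        for a in (100.0, 200.0, 400.0):
            prof = PatientProfile("P0001", {"cMet": a}, noise_sd=0.0)
            tr = generate_trace(prof, cf3_condition, seed=0)
            c = generate_trace(prof, WellCondition("C", "P0001"), seed=0)
            scores.append(signaling_score(tr, c))
        assert scores[1] == pytest.approx(2 * scores[0], rel=1e-12)
        assert scores[2] == pytest.approx(4 * scores[0], rel=1e-12)

    def test_occupancy_half_at_dm(self):
        drug = DrugSpec("x", 1e-8, 3.7)
        assert drug.occupancy(1e-8) == pytest.approx(0.5)
        assert median_effect_fa(1e-8, 1e-8, 0.3) == pytest.approx(0.5)

    def test_unknown_drug_rejected(self, noiseless_profile):
        cond = WellCondition("DRUG", "P0001", agonist="HGF",
                             antagonists=(Antagonist("nosuchdrug", 1e-8),))
        with pytest.raises(ValidationError):
            generate_trace(noiseless_profile, cond, seed=0)

    def test_on_target_antagonist_reduces_amplitude(self, noiseless_profile):
        free = WellCondition("DRUG", "P0001", agonist="HGF")
        drugged = WellCondition(
            "DRUG", "P0001", agonist="HGF",
            antagonists=(Antagonist("tepotinib", 14.7e-9),))
        a0 = well_amplitude(noiseless_profile, free)
        a1 = well_amplitude(noiseless_profile, drugged)
        # occupancy at Dm is exactly 0.5 with full on-target coupling
        assert a1 == pytest.approx(0.5 * a0)

    def test_enhancement_coupling_raises_amplitude(self):
        prof = PatientProfile(
            "P1", {"HER3_4": 100.0}, noise_sd=0.0,
            crosstalk={"tepotinib": {"HER3_4": -0.98}})
        free = WellCondition("CF1", "P1")
        drugged = WellCondition(
            "DRUG", "P1", agonist="NRG1b",
            antagonists=(Antagonist("tepotinib", 1.0),))  # saturating
        assert well_amplitude(prof, drugged) == pytest.approx(
            1.98 * well_amplitude(prof, free), rel=1e-6)


class TestPlates:
    def test_one_trace_per_well(self, noiseless_profile):
        layout = default_plate_layout("P0001", n_replicates=1)
        traces = generate_plate(noiseless_profile, layout, seed=2)
        assert len(traces) == 6
        assert {t.well_id for t in traces} == set(layout.wells)

    def test_cdf_wells_lose_her2_contribution(self, noiseless_profile):
        layout = default_plate_layout("P0001", n_replicates=1)
        traces = {t.well_id: t for t in
                  generate_plate(noiseless_profile, layout, seed=2)}
        by_code = {layout.wells[w].condition_code: t for w, t in traces.items()}
        cf1 = by_code["CF1"].cell_index.sum()
        cdf1 = by_code["CDF1"].cell_index.sum()
        assert cf1 > cdf1  # HER2 coupling > 0 in the profile

    def test_seed_reproducibility(self, duplicate_layout):
        prof = PatientProfile("P0001", {"cMet": 300.0}, noise_sd=0.1)
        a = generate_plate(prof, duplicate_layout, seed=9)
        b = generate_plate(prof, duplicate_layout, seed=9)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.cell_index, tb.cell_index)

    def test_planted_cohort_profiles_deterministic(self):
        a = generate_cohort_profiles(10, seed=4, n_combined_positive=3)
        b = generate_cohort_profiles(10, seed=4, n_combined_positive=3)
        assert [p.capacity for p in a] == [p.capacity for p in b]


class TestCombinationSurface:
    drug1 = DrugSpec("a", 10e-9, 1.5)
    drug2 = DrugSpec("b", 20e-9, 1.0)

    def test_sham_combination_is_single_agent_dose_sum(self):
        # identical drugs, any split: fa must equal fa(d1 + d2) of one agent
        d = self.drug1
        fa = solve_surface_fa(3e-9, 5e-9, d, d, alpha=0.0)
        assert fa == pytest.approx(median_effect_fa(8e-9, d.dm_molar, d.m),
                                   abs=1e-12)

    def test_alpha_sign_shifts_effect(self):
        grid = [(4e-9, 8e-9)]
        base = generate_combination_surface(self.drug1, self.drug2, 0.0, grid)
        syn = generate_combination_surface(self.drug1, self.drug2, 2.0, grid)
        ant = generate_combination_surface(self.drug1, self.drug2, -0.5, grid)
        assert syn["fa"][0] > base["fa"][0] > ant["fa"][0]

    def test_non_positive_doses_rejected(self):
        with pytest.raises(ValidationError):
            generate_combination_surface(self.drug1, self.drug2, 0.0,
                                         [(0.0, 1e-9)])

    def test_alpha_below_minus_one_rejected(self):
        with pytest.raises(ValidationError):
            solve_surface_fa(1e-9, 1e-9, self.drug1, self.drug2, -1.5)

    def test_noise_is_seeded(self):
        grid = [(4e-9, 8e-9), (8e-9, 16e-9)]
        a = generate_combination_surface(self.drug1, self.drug2, 0.0, grid,
                                         seed=7, noise_sd=0.02)
        b = generate_combination_surface(self.drug1, self.drug2, 0.0, grid,
                                         seed=7, noise_sd=0.02)
        pd.testing.assert_frame_equal(a, b)


class TestXenograft:
    def test_full_effect_flattens_growth(self):
        df = generate_xenograft(
            [{"name": "t", "n_mice": 3, "effect": 1.0}],
            g=0.1, v0=150.0, days=21, noise_cv=0.0, seed=1)
        np.testing.assert_allclose(df["volume_mm3"], 150.0)

    def test_zero_effect_zero_reduction(self):
        arms = [{"name": "control", "n_mice": 5, "effect": 0.0},
                {"name": "t", "n_mice": 5, "effect": 0.0}]
        df = generate_xenograft(arms, noise_cv=0.0, seed=1)
        end = df[df["day"] == 21.0]
        mc = end[end["arm"] == "control"]["volume_mm3"].mean()
        mt = end[end["arm"] == "t"]["volume_mm3"].mean()
        assert mt == pytest.approx(mc)

    def test_effect_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            generate_xenograft([{"name": "t", "n_mice": 3, "effect": 1.2}])

    def test_single_mouse_arm_rejected(self):
        with pytest.raises(ValidationError):
            generate_xenograft([{"name": "t", "n_mice": 1, "effect": 0.5}])

    def test_noise_is_mean_preserving(self):
        df = generate_xenograft(
            [{"name": "c", "n_mice": 400, "effect": 0.0}],
            g=0.0, v0=100.0, days=3, noise_cv=0.3, seed=8, measure_every=3)
        end = df[df["day"] == 3.0]["volume_mm3"]
        se = 100.0 * 0.3 / np.sqrt(len(end))
        assert abs(end.mean() - 100.0) < 3 * se
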