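"""Generator and choice-simulation tests, with brute-force sampling oracles."""

import numpy as np
import pytest
from scipy.stats import chisquare

import dsschoice as d


class TestMonkeyGenerator:
    def test_all_pulses_integer_and_seven_samples(self):
        t = d.gen_monkey_stimuli(d.MonkeyDesign(trials_per_session=500), seed=1)
        assert np.array_equal(t.evidence, np.rint(t.evidence))
        assert (t.n_samples == 7).all()

    def test_rounded_gaussian_moments_match_sampling_oracle(self):
        # oracle: brute-force sampling of round(N(0, 0.25)) with 10x draws
        design = d.MonkeyDesign(conditions=[(0.0, 0.25)],
                                trials_per_session=1000)
        t = d.gen_monkey_stimuli(design, seed=2)
        r = np.random.default_rng(99)
        oracle = np.rint(r.normal(0.0, 0.5, size=70_000))
        sd_o = oracle.std()
        se = sd_o / np.sqrt(t.evidence.size)
        assert abs(t.evidence.std() - sd_o) < 3 * se
        assert abs(t.evidence.mean()) < 3 * se

    def test_degenerate_variance_gives_constant_pulses(self):
        t = d.gen_monkey_stimuli(
            d.MonkeyDesign(conditions=[(3.0, 1e-20)], trials_per_session=50),
            seed=3)
        assert np.all(t.evidence == 3.0)
        assert np.all(t.category == 1)

    def test_zero_mean_condition_categorized_by_empirical_sign(self):
        t = d.gen_monkey_stimuli(
            d.MonkeyDesign(conditions=[(0.0, 1.0)], trials_per_session=400),
            seed=4)
        tot = t.total_evidence()
        nonzero = tot != 0
        assert np.array_equal(t.category[nonzero], (tot[nonzero] > 0))

    def test_sessions_in_blocks_with_gains_in_range(self):
        des = d.MonkeyDesign(n_sessions=4, trials_per_session=10,
                             session_gain_range=(0.5, 2.0))
        t = d.gen_monkey_stimuli(des, seed=5)
        assert t.n_sessions == 4
        assert np.array_equal(t.session, np.repeat(np.arange(4), 10))
        g = t.meta["session_gains"]
        assert np.all((g >= 0.5) & (g <= 2.0))


class TestHumanGenerator:
    def test_evidence_formula_at_reference_angles(self):
        # the printed evidence formula forces S = +/- 2 kappa at the poles
        kappa = 0.3
        a0 = np.radians(45.0)
        assert 2 * kappa * np.cos(2 * (a0 - a0)) == pytest.approx(0.6)
        assert 2 * kappa * np.cos(2 * (a0 + np.pi / 2 - a0)) == pytest.approx(-0.6)

    def test_evidence_bounded_by_2kappa(self):
        t = d.gen_human_stimuli(d.HumanDesign(trials=2000), seed=6)
        assert np.abs(t.evidence[t.mask]).max() <= 0.6 + 1e-12

    def test_sequence_lengths_uniform(self):
        t = d.gen_human_stimuli(d.HumanDesign(trials=10_000), seed=7)
        lengths, counts = np.unique(t.n_samples, return_counts=True)
        assert lengths.tolist() == [5, 6, 7, 8, 9, 10]
        assert chisquare(counts).pvalue > 0.001

    def test_category_drives_evidence_sign(self):
        t = d.gen_human_stimuli(d.HumanDesign(trials=4000), seed=8)
        mean_cw = t.evidence[t.category == 1].sum() / t.mask[t.category == 1].sum()
        mean_ccw = t.evidence[t.category == 0].sum() / t.mask[t.category == 0].sum()
        assert mean_cw > 0 > mean_ccw

    def test_invalid_kappa_rejected(self):
        with pytest.raises(ValueError, match="kappa"):
            d.HumanDesign(kappa=0.0)


class TestRatGenerator:
    def test_condition_grid_has_35_conditions(self):
        assert len(d.rat_conditions(d.RatDesign())) == 35

    def test_envelopes_sum_to_one_exactly(self):
        t = d.gen_rat_stimuli(d.RatDesign(trials_per_condition=30), seed=9)
        aL, aR = d.rat_envelopes(t.evidence)
        assert np.abs(aL + aR - 1.0).max() == 0.0

    def test_point_mass_condition(self):
        des = d.RatDesign(means=(1.0,), sds=(0.0,), trials_per_condition=20)
        t = d.gen_rat_stimuli(des, seed=10)
        assert np.all(t.evidence == 1.0)
        aL, aR = d.rat_envelopes(t.evidence)
        assert np.all(aL == 1.0) and np.all(aR == 0.0)

    def test_infeasible_condition_names_offender(self):
        des = d.RatDesign(means=(0.9,), sds=(0.8,), trials_per_condition=5)
        with pytest.raises(ValueError, match="0.9"):
            d.gen_rat_stimuli(des, seed=11)

    def test_moments_match_condition_within_mc_error(self):
        des = d.RatDesign(means=(0.15,), sds=(0.25,), trials_per_condition=500)
        t = d.gen_rat_stimuli(des, seed=12)
        n = t.evidence.size
        assert abs(t.evidence.mean() - 0.15) < 3 * 0.25 / np.sqrt(n)
        assert abs(t.evidence.std() - 0.25) < 0.02

    def test_constrained_sampling_tightens_empirical_means(self):
        des = d.RatDesign(means=(0.0, 0.5), sds=(0.57,),
                          trials_per_condition=100, constrained=True)
        t = d.gen_rat_stimuli(des, seed=13)
        nominal = np.array([des.means[c // len(des.sds)]
                            for c in t.meta["condition"]])
        tol = 0.5 * 0.5  # half the grid spacing of the means
        assert np.abs(t.evidence.mean(axis=1) - nominal).max() < tol


class TestSimulateChoices:
    def test_flat_integration_model_gives_half(self, gaussian_trials):
        params = d.IntegrationParams(beta0=0.0, beta=np.zeros(7))
        y = d.simulate_choices(params, gaussian_trials, seed=1)
        se = 0.5 / np.sqrt(gaussian_trials.n_trials)
        assert abs(y.mean() - 0.5) < 3 * se

    def test_saturated_bias_forces_rightward(self, gaussian_trials):
        params = d.IntegrationParams(beta0=10.0, beta=np.zeros(7))
        y = d.simulate_choices(params, gaussian_trials, seed=2)
        assert y.mean() >= 0.999

    def test_extrema_low_noise_first_sample_triggers(self):
        S = np.column_stack([np.ones(200), np.random.default_rng(3).normal(
            size=(200, 6))])
        t = d.TrialTable(evidence=S, choice=np.zeros(200, dtype=int))
        params = d.ExtremaParams(theta=0.5, sigma=1e-9)
        y = d.simulate_choices(params, t, seed=3)
        assert np.all(y == 1)

    def test_bit_reproducible_under_seed(self, integration_dataset):
        trials, params = integration_dataset
        a = d.simulate_choices(params, trials, seed=77)
        b = d.simulate_choices(params, trials, seed=77)
        assert np.array_equal(a, b)

    def test_generators_bit_reproducible(self):
        a = d.gen_rat_stimuli(d.RatDesign(trials_per_condition=5), seed=42)
        b = d.gen_rat_stimuli(d.RatDesign(trials_per_condition=5), seed=42)
        assert a == b


class TestDesignConfig:
    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "design.yaml"
        path.write_text("species: rat\nn_samples: 20\n"
                        "trials_per_condition: 3\n")
        des = d.design_from_file(path)
        assert isinstance(des, d.RatDesign)
        assert des.n_samples == 20
        t = d.gen_rat_stimuli(des, seed=1)
        assert t.n_max == 20

    def test_json_monkey_design(self, tmp_path):
        path = tmp_path / "design.json"
        path.write_text('{"species": "monkey", "n_sessions": 2, '
                        '"trials_per_session": 5, '
                        '"conditions": [[0.5, 1.0], [-0.5, 1.0]]}')
        des = d.design_from_file(path)
        assert des.conditions == [(0.5, 1.0), (-0.5, 1.0)]
        assert d.gen_monkey_stimuli(des, seed=2).n_trials == 10

    def test_missing_species_rejected(self, tmp_path):
        path = tmp_path / "design.yaml"
        path.write_text("n_samples: 10\n")
        with pytest.raises(ValueError, match="species"):
            d.design_from_file(path)
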