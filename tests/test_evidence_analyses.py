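"""Disagree-trial detection/alignment and subjective-weight estimation."""

import numpy as np
import pytest
from scipy.special import expit

import dsschoice as d


class TestFindDisagree:
    def test_definition_examples(self):
        t = d.TrialTable(evidence=[[2, 2, -3], [1, 1, -3], [3, -3, 1]],
                         choice=[0, 0, 0])
        idx, n_excluded = d.find_disagree_trials(t)
        assert idx.tolist() == [0]      # total +1, largest -3 -> disagree
        assert n_excluded == 1          # tied maxima of conflicting signs

    def test_agree_trial(self):
        t = d.TrialTable(evidence=[[1, 1, -3]], choice=[0])
        idx, _ = d.find_disagree_trials(t)
        assert idx.size == 0            # total -1, largest -3: same sign

    def test_zero_total_excluded(self):
        t = d.TrialTable(evidence=[[2, -1, -1]], choice=[0])
        idx, n_excluded = d.find_disagree_trials(t)
        assert idx.size == 0 and n_excluded == 1

    def test_matches_exhaustive_per_trial_check(self):
        r = np.random.default_rng(1)
        S = np.rint(r.normal(0, 1.5, size=(500, 5)))
        t = d.TrialTable(evidence=S, choice=np.zeros(500, dtype=int))
        idx, _ = d.find_disagree_trials(t)
        flag = set()
        for i, s in enumerate(S):
            tot = s.sum()
            if tot == 0:
                continue
            mx = np.abs(s).max()
            if mx == 0:
                continue
            top_signs = {np.sign(v) for v in s if abs(v) == mx}
            if len(top_signs) != 1:
                continue
            if top_signs.pop() != np.sign(tot):
                flag.add(i)
        assert set(idx.tolist()) == flag


class TestDisagreeAlignment:
    def test_total_follower_fully_aligned(self):
        r = np.random.default_rng(2)
        S = r.normal(0, 1.5, size=(3000, 7))
        y = (S.sum(axis=1) > 0).astype(int)
        rep = d.disagree_alignment(d.TrialTable(evidence=S, choice=y))
        assert rep.observed_alignment == 1.0

    def test_largest_sample_follower_never_aligned(self):
        r = np.random.default_rng(3)
        S = r.normal(0, 1.5, size=(3000, 7))
        largest = S[np.arange(3000), np.abs(S).argmax(axis=1)]
        y = (largest > 0).astype(int)
        rep = d.disagree_alignment(d.TrialTable(evidence=S, choice=y))
        assert rep.observed_alignment == 0.0

    def test_integrator_above_half_extrema_below(self):
        r = np.random.default_rng(4)
        S = r.normal(0, 1.5, size=(5000, 7))
        t = d.TrialTable(evidence=S, choice=np.zeros(5000, dtype=int))
        y_int = d.simulate_choices(
            d.IntegrationParams(beta0=0.0, beta=np.full(7, 0.8)), t, seed=5)
        y_ed, _ = d.simulate_extrema_process(
            d.ExtremaParams(theta=1.5, sigma=0.2), t, seed=6)
        assert d.disagree_alignment(
            t, choices=y_int).observed_alignment > 0.5
        assert d.disagree_alignment(
            t, choices=y_ed).observed_alignment < 0.5

    def test_parametric_bootstrap_ci_brackets_model(self):
        r = np.random.default_rng(7)
        S = r.normal(0, 1.5, size=(4000, 7))
        t = d.TrialTable(evidence=S, choice=np.zeros(4000, dtype=int))
        y = d.simulate_choices(
            d.IntegrationParams(beta0=0.0, beta=np.full(7, 0.8)), t, seed=8)
        t = t.with_choices(y)
        fit = d.fit_integration(t)
        rep = d.disagree_alignment(t, models=[fit], n_boot=40, seed=9)
        lo, hi = rep.model_ci[fit.variant]
        assert lo <= rep.observed_alignment <= hi or \
            abs(rep.observed_alignment - np.clip(
                rep.observed_alignment, lo, hi)) < 0.1
        assert len(rep.model_boot[fit.variant]) == 40

    def test_model_without_cov_flagged(self):
        r = np.random.default_rng(10)
        S = r.normal(0, 1.5, size=(500, 7))
        y = (S.sum(axis=1) > 0).astype(int)
        t = d.TrialTable(evidence=S, choice=y)
        bare = d.FittedModel(model_id="snapshot", variant="snap",
                             params={"pi": np.r_[np.full(7, 0.98 / 7),
                                                 0.01, 0.01]},
                             loglik=-1.0, n_params=8,
                             fit_meta={"rule": "deterministic", "K": 1})
        rep = d.disagree_alignment(t, models=[bare], n_boot=10, seed=11)
        assert "snap" in rep.flags
        assert "snap" in rep.model_alignment


class TestSubjectiveWeights:
    @pytest.fixture(scope="class")
    @staticmethod
    def integer_trials():
        r = np.random.default_rng(12)
        S = np.rint(r.normal(0, 1.5, size=(20_000, 7)))
        return d.TrialTable(evidence=S, choice=np.zeros(20_000, dtype=int)), r

    def test_linear_transfer_recovered(self, integer_trials):
        t, r = integer_trials
        beta = np.array([1.3, 1.1, 1.0, 0.9, 0.8, 1.0, 0.9])
        beta = beta / beta.mean()
        y = (r.random(t.n_trials) < expit(0.1 + (t.evidence @ beta) * 0.6)
             ).astype(int)
        c = d.fit_subjective_weights(t.with_choices(y), mode="discrete")
        assert np.corrcoef(c.f, c.points)[0, 1] > 0.99
        assert c.beta.mean() == pytest.approx(1.0, abs=1e-9)

    def test_saturating_transfer_detected(self, integer_trials):
        t, r = integer_trials
        cut = 2.0
        fS = np.sign(t.evidence) * np.minimum(np.abs(t.evidence), cut)
        y = (r.random(t.n_trials) < expit((fS.sum(axis=1)) * 0.8)).astype(int)
        c = d.fit_subjective_weights(t.with_choices(y), mode="discrete")
        pos = c.points > 0
        x, f = c.points[pos], c.f[pos]
        below = (f[x == 2.0] - f[x == 1.0]) / 1.0
        above = (f[x == x[x > 2.0].max()] - f[x == 2.0]) / (x[x > 2.0].max() - 2.0)
        assert above < 0.5 * below

    def test_oddness_exact(self, integer_trials):
        t, r = integer_trials
        y = (r.random(t.n_trials) < expit(t.evidence.sum(axis=1))).astype(int)
        c = d.fit_subjective_weights(t.with_choices(y), mode="discrete")
        np.testing.assert_array_equal(c.f, -c.f[::-1])
        if 0 in c.points:
            assert c.f[c.points == 0][0] == 0.0
        assert c(np.array([0.0]))[0] == 0.0

    def test_too_few_levels_rejected(self):
        S = np.random.default_rng(13).choice([-1.0, 1.0], size=(500, 4))
        t = d.TrialTable(evidence=S, choice=(S.sum(axis=1) > 0).astype(int))
        with pytest.raises(ValueError, match="levels"):
            d.fit_subjective_weights(t, mode="discrete")

    def test_gp_mode_linear_on_continuous_evidence(self):
        r = np.random.default_rng(14)
        t = d.gen_human_stimuli(d.HumanDesign(trials=20_000), seed=15)
        y = (r.random(t.n_trials) < expit(t.evidence.sum(axis=1) * 4.0)
             ).astype(int)
        c = d.fit_subjective_weights(t.with_choices(y), mode="gp")
        assert np.corrcoef(c.f, c.points)[0, 1] > 0.99
        slope = np.polyfit(c.points, c.f, 1)[0]
        assert slope == pytest.approx(4.0, rel=0.15)

    def test_session_gains_normalized(self):
        r = np.random.default_rng(16)
        S = np.rint(r.normal(0, 1.5, size=(12_000, 7)))
        sess = np.repeat(np.arange(3), 4000)
        g = np.array([0.6, 1.0, 1.4])
        y = (r.random(12_000) < expit(
            g[sess] * S.sum(axis=1) * 0.5)).astype(int)
        t = d.TrialTable(evidence=S, choice=y, session=sess)
        c = d.fit_subjective_weights(t, mode="discrete",
                                     use_session_gain=True)
        assert c.gamma.mean() == pytest.approx(1.0, abs=1e-9)
        assert np.corrcoef(c.gamma, g)[0, 1] > 0.9
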