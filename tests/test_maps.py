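"""Integration-map tests: split identity, smoothing, isolines, conditionals."""

import numpy as np
import pytest
from scipy.special import expit

import dsschoice as d
from dsschoice.maps import EvidenceSplit


@pytest.fixture(scope="module")
def uniform_split():
    """Dense synthetic (E, L) cloud with uniform coverage of the plane."""
    r = np.random.default_rng(21)
    n = 120_000
    E = r.uniform(-4.5, 4.5, n)
    L = r.uniform(-4.5, 4.5, n)
    return EvidenceSplit(E=E, L=L), r


class TestSplit:
    def test_seven_samples_split_three_four(self, integration_dataset):
        trials, _ = integration_dataset
        fit = d.fit_integration(trials)
        split = d.split_evidence(trials, fit)
        beta = fit.params["beta"]
        expect_E = trials.evidence[:, :3] @ beta[:3]
        np.testing.assert_allclose(split.E, expect_E, atol=1e-12)

    def test_equal_weights_arithmetic(self):
        t = d.TrialTable(evidence=np.ones((1, 7)), choice=[1])
        fit = d.FittedModel(model_id="integration", variant="integration",
                            params={"beta0": 0.0, "beta": np.full(7, 2.0)},
                            loglik=-1.0, n_params=8,
                            fit_meta={"fit_bias": True})
        split = d.split_evidence(t, fit)
        assert split.E[0] == pytest.approx(6.0)   # 3 early samples * 2
        assert split.L[0] == pytest.approx(8.0)   # 4 late samples * 2

    def test_partition_identity_exact(self, integration_dataset):
        trials, _ = integration_dataset
        fit = d.fit_integration(trials)
        split = d.split_evidence(trials, fit)
        T = d.weighted_evidence(trials, fit)
        np.testing.assert_array_equal(split.E + split.L, split.T)
        np.testing.assert_allclose(split.T, T, atol=1e-12)

    def test_ragged_split_per_trial(self, ragged_trials):
        fit = d.fit_integration(ragged_trials)
        split = d.split_evidence(ragged_trials, fit)
        # 5-sample trials: early = first 2 samples
        i = np.flatnonzero(ragged_trials.n_samples == 5)[0]
        beta = fit.params["beta"]
        assert split.E[i] == pytest.approx(
            ragged_trials.evidence[i, :2] @ beta[:2])


class TestComputeMap:
    def test_integration_rule_gives_equal_p_on_diagonals(self, uniform_split):
        split, r = uniform_split
        p = expit(split.E + split.L)
        m = d.compute_map(split, p, density_min=20)
        # nodes with equal E+L share the smoothed value (away from the
        # support boundary, where one-sided smoothing biases the estimate)
        total = m.E_nodes[None, :] + m.L_nodes[:, None]
        interior = (np.abs(m.E_nodes[None, :]) < 4.0) & \
            (np.abs(m.L_nodes[:, None]) < 4.0)
        sel = (np.abs(total - 1.0) < 1e-9) & interior & m.mask
        vals = m.p[sel]
        assert vals.size > 5
        assert vals.max() - vals.min() < 0.02

    def test_nonintegration_rule_node_value(self, uniform_split):
        # attend early or late with probability 1/2:
        # at L = 0 and strongly rightward E the map sits at 0.75
        split, _ = uniform_split
        r = np.random.default_rng(22)
        p = 0.5 * expit(split.E) + 0.5 * expit(split.L)
        y = (r.random(split.E.size) < p).astype(int)
        m = d.compute_map(split, y, density_min=20)
        j = np.argmin(np.abs(m.L_nodes))
        k = np.argmin(np.abs(m.E_nodes - 4.0))
        assert m.mask[j, k]
        assert m.p[j, k] == pytest.approx(0.75, abs=0.03)

    def test_coin_flip_choices_give_half_everywhere(self, uniform_split):
        split, _ = uniform_split
        r = np.random.default_rng(23)
        y = r.integers(0, 2, size=split.E.size)
        m = d.compute_map(split, y, density_min=200)
        dev = np.abs(m.p[m.mask] - 0.5)
        # smoothed binomial noise: bound by 3 SEs at the effective count
        assert np.quantile(dev, 0.99) < 0.2
        assert np.abs(np.mean(m.p[m.mask]) - 0.5) < 0.01

    def test_permutation_invariance(self, uniform_split):
        split, _ = uniform_split
        idx = np.arange(20_000)
        r = np.random.default_rng(24)
        y = r.integers(0, 2, size=idx.size)
        sub = split.subset(idx)
        perm = r.permutation(idx.size)
        m1 = d.compute_map(sub, y, density_min=5)
        m2 = d.compute_map(sub.subset(perm), y[perm], density_min=5,
                           E_nodes=m1.E_nodes, L_nodes=m1.L_nodes)
        np.testing.assert_allclose(m1.p, m2.p, equal_nan=True, atol=1e-10)

    def test_empty_support_raises(self):
        split = EvidenceSplit(E=np.zeros(3), L=np.zeros(3))
        with pytest.raises(ValueError, match="density"):
            d.compute_map(split, np.array([0, 1, 0]), density_min=1000)

    def test_noiseless_integration_isolines_straight(self, uniform_split):
        split, _ = uniform_split
        p = expit(split.E + split.L)
        m = d.compute_map(split, p, density_min=20)
        assert d.isoline_straightness(m) < 2.0


class TestConditionalPsychometrics:
    def test_integration_data_linear_bias_null_lapses(self, uniform_split):
        split, _ = uniform_split
        r = np.random.default_rng(25)
        y = (r.random(split.E.size) < expit(split.E + split.L)).astype(int)
        fits = [c for c in d.conditional_psychometrics(
            split, y, min_trials_per_bin=2000) if abs(c.L_center) < 2.5]
        L = np.array([c.L_center for c in fits])
        B = np.array([c.beta for c in fits])
        A = np.vstack([L, np.ones_like(L)]).T
        coef, res, *_ = np.linalg.lstsq(A, B, rcond=None)
        r2 = 1 - res[0] / ((B - B.mean()) ** 2).sum()
        assert r2 > 0.95
        assert coef[0] == pytest.approx(1.0, abs=0.15)
        assert max(max(c.pi_L, c.pi_R) for c in fits) < 0.05

    def test_nonintegration_data_grows_lapses(self, uniform_split):
        split, _ = uniform_split
        r = np.random.default_rng(26)
        p = 0.5 * expit(split.E) + 0.5 * expit(split.L)
        y = (r.random(split.E.size) < p).astype(int)
        fits = d.conditional_psychometrics(split, y, min_trials_per_bin=2000)
        lapse = {c.L_center: max(c.pi_L, c.pi_R) for c in fits}
        Ls = np.array(sorted(lapse))
        inner = np.mean([lapse[x] for x in Ls if abs(x) < 1.0])
        outer = np.mean([lapse[x] for x in Ls if abs(x) > 3.0])
        assert outer > inner + 0.15
        assert outer > 0.2    # attending the other stream half of the time

    def test_zero_late_bin_recovers_sensitivity(self):
        r = np.random.default_rng(27)
        E = r.uniform(-4, 4, 10_000)
        split = EvidenceSplit(E=E, L=np.zeros(10_000))
        y = (r.random(10_000) < expit(E)).astype(int)
        fits = d.conditional_psychometrics(split, y, min_trials_per_bin=100)
        assert len(fits) == 1
        assert fits[0].beta == pytest.approx(0.0, abs=0.1)
        assert fits[0].alpha == pytest.approx(1.0, rel=0.1)


class TestMapCorrelation:
    def test_self_correlation_is_one(self, uniform_split):
        split, _ = uniform_split
        r = np.random.default_rng(28)
        y = (r.random(split.E.size) < expit(split.E + split.L)).astype(int)
        m = d.compute_map(split, y, density_min=20)
        assert d.map_pearson(m, m) == pytest.approx(1.0)

    def test_mirrored_antisymmetric_map_is_minus_one(self):
        m = d.IntegrationMapGrid(
            E_nodes=np.arange(5.0), L_nodes=np.arange(4.0),
            p=np.add.outer(np.arange(4.0), np.arange(5.0)),
            density=np.full((4, 5), 100), mask=np.ones((4, 5), bool),
            spacing=1.0)
        flipped = d.IntegrationMapGrid(
            E_nodes=m.E_nodes, L_nodes=m.L_nodes, p=-m.p,
            density=m.density, mask=m.mask, spacing=1.0)
        assert d.map_pearson(m, flipped) == pytest.approx(-1.0)

    def test_disjoint_support_rejected(self):
        mask1 = np.zeros((3, 3), bool)
        mask1[0] = True
        mask2 = np.zeros((3, 3), bool)
        mask2[2] = True
        a = d.IntegrationMapGrid(np.arange(3.0), np.arange(3.0),
                                 np.ones((3, 3)), np.ones((3, 3), int),
                                 mask1, 1.0)
        b = d.IntegrationMapGrid(np.arange(3.0), np.arange(3.0),
                                 np.ones((3, 3)), np.ones((3, 3), int),
                                 mask2, 1.0)
        with pytest.raises(ValueError, match="disjoint"):
            d.map_pearson(a, b)

    def test_generating_model_correlates_best(self):
        # choices from an integrator: its simulated map should correlate
        # with the data map better than a snapshot simulation does
        r = np.random.default_rng(29)
        n = 60_000
        S = r.normal(0, 1.2, size=(n, 7))
        t = d.TrialTable(evidence=S, choice=np.zeros(n, dtype=int))
        gen = d.IntegrationParams(beta0=0.0, beta=np.full(7, 0.6))
        y = d.simulate_choices(gen, t, seed=30)
        t = t.with_choices(y)
        fit = d.fit_integration(t)
        split = d.split_evidence(t, fit)
        y_int = d.simulate_choices(fit, t, seed=31)
        pi = np.zeros(9)
        pi[:7] = 1 / 7 * 0.98
        pi[7:] = 0.01
        y_snap = d.simulate_choices(d.SnapshotParams(pi=pi), t, seed=32)
        kw = dict(density_min=50)
        r_int, _ = d.bootstrap_map_correlation(split, y, y_int, n_boot=0,
                                               seed=33, **kw)
        r_snap, _ = d.bootstrap_map_correlation(split, y, y_snap, n_boot=0,
                                                seed=34, **kw)
        assert r_int > r_snap

    def test_bootstrap_distribution_brackets_point_estimate(self):
        r = np.random.default_rng(35)
        n = 20_000
        E = r.uniform(-3, 3, n)
        L = r.uniform(-3, 3, n)
        split = EvidenceSplit(E=E, L=L)
        y = (r.random(n) < expit(E + L)).astype(int)
        y2 = (r.random(n) < expit(E + L)).astype(int)
        r0, boot = d.bootstrap_map_correlation(split, y, y2, n_boot=20,
                                               seed=36, density_min=10)
        assert boot.shape == (20,)
        assert np.percentile(boot, 1) < r0 < np.percentile(boot, 99) + 0.05
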