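"""Disagree-trial analysis and subjective evidence weighting.

**Disagree trials** are trials where the sign of the largest-magnitude
evidence sample conflicts with the sign of the summed evidence.  They
dissociate integration from extrema detection: an integrator follows the
total more often than not, an extrema detector follows the dominant
sample.  The analysis reports the observed proportion of choices aligned
with the total evidence on that subset, plus parametric-bootstrap
confidence intervals per candidate model (parameters drawn from the
Laplace posterior, choices re-simulated).

**Subjective weights** relax the linear read-out of the integration
model to p = sigma(beta0 + gamma_t sum_i beta_i f(S_ti)) with an odd
transfer function f estimated from the data: f is linear under pure
integration and saturating when large samples are under-weighted.  f is
estimated at the discrete evidence levels when the design uses finitely
many values, or on a grid under a squared-exponential Gaussian-process
prior (length scale 0.1, variance 1, fixed) for continuous evidence.
The scale degeneracy between f, beta and gamma is removed by fixing
mean(beta) = 1 and mean(gamma) = 1 exactly; f carries the scale and
stays in evidence units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import FittedModel, TrialTable
from .integration import IntegrationParams, fit_integration
from .synthetic import simulate_choices
from . import extrema as _extrema

__all__ = ["DisagreeReport", "SubjectiveWeightCurve", "find_disagree_trials",
           "disagree_alignment", "fit_subjective_weights"]


# ---------------------------------------------------------------------------
# Disagree trials
# ---------------------------------------------------------------------------

@dataclass
class DisagreeReport:
    indices: np.ndarray
    n_excluded: int
    observed_alignment: float
    model_alignment: dict = field(default_factory=dict)   # variant -> point est
    model_ci: dict = field(default_factory=dict)          # variant -> (lo, hi)
    model_boot: dict = field(default_factory=dict)        # variant -> samples
    flags: dict = field(default_factory=dict)


def find_disagree_trials(trials: TrialTable) -> tuple[np.ndarray, int]:
    """Indices of trials whose largest-|S| sample opposes the summed evidence.

    Raw (not gain-scaled) evidence defines both the dominant sample and
    the total.  Ambiguous trials — exact-zero totals, or tied maxima with
    conflicting signs — are excluded and counted separately.
    """
    absS = np.where(trials.mask, np.abs(trials.evidence), -np.inf)
    amax = absS.max(axis=1)
    total = trials.total_evidence()
    sign_total = np.sign(total)
    is_max = absS == amax[:, None]
    signs = np.sign(trials.evidence)
    pos_max = (is_max & (signs > 0)).any(axis=1)
    neg_max = (is_max & (signs < 0)).any(axis=1)
    ambiguous = (pos_max & neg_max) | (sign_total == 0) | (amax == 0)
    sign_max = np.where(pos_max, 1.0, -1.0)
    disagree = ~ambiguous & (sign_max != sign_total)
    return np.flatnonzero(disagree), int(ambiguous.sum())


def _alignment(trials: TrialTable, choices: np.ndarray,
               idx: np.ndarray) -> float:
    total = trials.total_evidence()[idx]
    return float(np.mean((np.asarray(choices)[idx] == 1) == (total > 0)))


def _sample_fit_params(fit: FittedModel, rng: np.random.Generator):
    """Draw one parameter set from a fit's Laplace posterior (or None)."""
    if fit.posterior_cov is None:
        return None
    if fit.model_id == "integration":
        mean = np.concatenate([[fit.params.get("beta0", 0.0)],
                               np.atleast_1d(fit.params["beta"])]) \
            if fit.fit_meta.get("fit_bias", True) else \
            np.atleast_1d(fit.params["beta"])
        draw = rng.multivariate_normal(mean, fit.posterior_cov,
                                       method="cholesky")
        if fit.fit_meta.get("fit_bias", True):
            b0, beta = float(draw[0]), draw[1:]
        else:
            b0, beta = 0.0, draw
        return IntegrationParams(beta0=b0, beta=beta,
                                 gamma=fit.params.get("gamma"),
                                 link=fit.fit_meta.get("link", "logit"))
    if fit.model_id == "extrema":
        p = _extrema.params_from_fit(fit)
        theta = np.atleast_1d(p.theta)
        mean = np.concatenate([theta, [p.sigma],
                               [p.pi_L, p.pi_R]
                               if fit.fit_meta.get("fit_lapses", True) else []])
        for _ in range(100):
            draw = rng.multivariate_normal(mean, fit.posterior_cov,
                                           method="cholesky")
            th = draw[: theta.size]
            sig = draw[theta.size]
            if fit.fit_meta.get("fit_lapses", True):
                pl, pr = draw[theta.size + 1], draw[theta.size + 2]
            else:
                pl = pr = 0.0
            if np.all(th >= 0) and sig > 0 and 0 <= pl <= 0.5 \
                    and 0 <= pr <= 0.5 and pl + pr < 1:
                return _extrema.ExtremaParams(
                    theta=th if theta.size > 1 else float(th[0]),
                    sigma=float(sig), pi_L=float(pl), pi_R=float(pr),
                    default_rule=p.default_rule)
        return None  # posterior mass concentrated outside the valid region
    return None


def disagree_alignment(trials: TrialTable, choices: np.ndarray | None = None,
                       models: list[FittedModel] | None = None,
                       n_boot: int = 100, seed: int = 0,
                       gains: np.ndarray | None = None) -> DisagreeReport:
    """Alignment with total evidence on disagree trials, with model CIs.

    Per model: parametric bootstrap — sample parameters from the Laplace
    posterior, simulate choices for all trials, recompute the alignment
    proportion on the disagree subset — and a percentile 95% CI.  Models
    without a posterior covariance get a point simulation and a flag.
    """
    if choices is None:
        choices = trials.choice
    idx, n_excluded = find_disagree_trials(trials)
    if idx.size == 0:
        raise ValueError("no disagree trials in this dataset")
    report = DisagreeReport(indices=idx, n_excluded=n_excluded,
                            observed_alignment=_alignment(trials, choices, idx))
    rng = np.random.default_rng(seed)
    for fit in models or []:
        key = fit.variant
        sim = simulate_choices(fit, trials,
                               seed=int(rng.integers(2 ** 31)), gains=gains)
        report.model_alignment[key] = _alignment(trials, sim, idx)
        boots = []
        for _ in range(n_boot):
            params = _sample_fit_params(fit, rng)
            if params is None:
                break
            sim_b = simulate_choices(params, trials,
                                     seed=int(rng.integers(2 ** 31)),
                                     gains=gains)
            boots.append(_alignment(trials, sim_b, idx))
        if boots:
            boots = np.asarray(boots)
            report.model_boot[key] = boots
            report.model_ci[key] = (float(np.percentile(boots, 2.5)),
                                    float(np.percentile(boots, 97.5)))
        else:
            report.flags[key] = "no posterior covariance; point estimate only"
    return report


# ---------------------------------------------------------------------------
# Subjective weighting
# ---------------------------------------------------------------------------

@dataclass
class SubjectiveWeightCurve:
    """Estimated odd transfer function f with its companion linear fit."""

    points: np.ndarray          # evaluation points (signed, symmetric)
    f: np.ndarray               # f at the points (odd by construction)
    f_se: np.ndarray            # Laplace SEs (mirrored on the negative side)
    beta0: float
    beta: np.ndarray            # per-position weights, mean(beta) = 1
    gamma: np.ndarray | None    # per-session gains, mean(gamma) = 1
    mode: str
    loglik: float

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """Evaluate f by odd linear interpolation."""
        x = np.asarray(x, dtype=float)
        pos = self.points[self.points > 0]
        fpos = self.f[self.points > 0]
        xp = np.r_[0.0, pos]
        fp = np.r_[0.0, fpos]
        return np.sign(x) * np.interp(np.abs(x), xp, fp)


def _interp_weights(a: np.ndarray, xpos: np.ndarray):
    """Linear-interpolation scatter of |S| values onto [0, xpos] nodes.

    Returns (lower node index into f-vector or -1 for the virtual zero
    node, upper index, upper fraction)."""
    xp = np.r_[0.0, xpos]
    idx = np.clip(np.searchsorted(xp, a, side="right") - 1, 0, xp.size - 2)
    frac = (a - xp[idx]) / (xp[idx + 1] - xp[idx])
    return idx - 1, idx, frac


def _se_kernel_odd(x: np.ndarray, length: float, variance: float) -> np.ndarray:
    """Covariance of the odd part of a squared-exponential GP."""
    d = x[:, None] - x[None, :]
    s = x[:, None] + x[None, :]
    k = variance * (np.exp(-d ** 2 / (2 * length ** 2))
                    - np.exp(-s ** 2 / (2 * length ** 2)))
    return k


def fit_subjective_weights(trials: TrialTable,
                           choices: np.ndarray | None = None,
                           mode: str = "discrete",
                           use_session_gain: bool = False,
                           gp_length_scale: float = 0.1,
                           gp_variance: float = 1.0,
                           n_grid: int = 50,
                           min_level_count: int = 10,
                           max_rounds: int = 50,
                           tol: float = 1e-6,
                           seed: int = 0) -> SubjectiveWeightCurve:
    """Joint MAP estimate of (beta0, gamma, beta, f) by coordinate ascent.

    Alternates (a) a logistic step in f at its evaluation points, holding
    the linear weights fixed, with (b) an integration-model refit on the
    f-transformed evidence, renormalizing mean(beta) = 1 and
    mean(gamma) = 1 after every sweep so that f carries the scale.

    ``mode='discrete'`` estimates f at each observed evidence magnitude
    (requires at least 3 distinct positive levels); ``mode='gp'`` uses a
    grid of ``n_grid // 2`` positive nodes under the odd projection of a
    squared-exponential GP prior with fixed hyperparameters.
    """
    if choices is not None:
        trials = trials.with_choices(choices)
    y = trials.choice.astype(float)
    S = trials.evidence
    valid = trials.mask
    a = np.abs(S[valid])
    if mode == "discrete":
        # estimate f only at magnitudes seen often enough to pin it;
        # samples beyond the top retained level extrapolate linearly
        lev, cnt = np.unique(a[a > 0], return_counts=True)
        xpos = lev[cnt >= min_level_count]
        if xpos.size == 0:
            xpos = lev
        if xpos.size < 3:
            raise ValueError(
                "need >= 3 distinct positive evidence levels for discrete f "
                "(f is unidentifiable beyond linearity otherwise)")
        prior_prec = np.full(xpos.size, 1e-4)   # weak ridge
        prior_cov_inv = np.diag(prior_prec)
    elif mode == "gp":
        m = max(n_grid // 2, 5)
        xpos = np.linspace(a.max() / m, a.max(), m)
        K = _se_kernel_odd(xpos, gp_length_scale, gp_variance)
        prior_cov_inv = np.linalg.inv(K + 1e-8 * np.eye(m))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    nu = xpos.size
    lo_idx, up_idx, frac = _interp_weights(np.abs(S).ravel(), xpos)
    sgn = np.sign(S).ravel()
    vmask = valid.ravel()
    n, n_max = S.shape
    trial_of = np.repeat(np.arange(n), n_max)

    # state
    beta = np.ones(n_max)
    beta0 = 0.0
    gamma = np.ones(trials.n_sessions) if use_session_gain else None
    u = xpos.copy()          # start from f = identity
    sess = trials.session_index

    def f_of_S() -> np.ndarray:
        xp = np.r_[0.0, xpos]
        fp = np.r_[0.0, u]
        return np.sign(S) * np.interp(np.abs(S), xp, fp) * valid

    def build_design() -> np.ndarray:
        g = np.ones(n) if gamma is None else gamma[sess]
        coef = (g[:, None] * beta[None, :]).ravel() * sgn * vmask
        B = np.zeros((n, nu))
        lower_ok = lo_idx >= 0
        np.add.at(B, (trial_of[lower_ok], lo_idx[lower_ok]),
                  coef[lower_ok] * (1.0 - frac[lower_ok]))
        np.add.at(B, (trial_of, up_idx), coef * frac)
        return B

    def loglik() -> float:
        from scipy.special import log_expit
        g = np.ones(n) if gamma is None else gamma[sess]
        eta = beta0 + g * (f_of_S() @ beta)
        return float(np.sum(log_expit(np.where(y == 1, eta, -eta))))

    prev = -np.inf
    for _ in range(max_rounds):
        # (a) f-step: penalized logistic in (beta0, u)
        B = build_design()
        X = np.column_stack([np.ones(n), B])
        if mode == "discrete":
            P = np.diag(np.r_[1e-6, prior_prec])
        else:
            P = np.zeros((nu + 1, nu + 1))
            P[0, 0] = 1e-6
            P[1:, 1:] = prior_cov_inv
        w_hat = _newton_map(X, y, P, w0=np.r_[beta0, u])
        beta0, u = float(w_hat[0]), w_hat[1:]
        # (b) linear step: integration refit on f-transformed evidence
        ft = TrialTable(evidence=f_of_S(), choice=trials.choice,
                        session=trials.session, mask=trials.mask)
        lin = fit_integration(ft, use_session_gain=use_session_gain,
                              prior_sd=10.0)
        beta0 = float(lin.params["beta0"])
        beta = np.asarray(lin.params["beta"])
        gamma = np.asarray(lin.params["gamma"]) if use_session_gain else None
        # renormalize: mean(beta) = 1 exactly, f carries the scale
        scale = beta.mean()
        if abs(scale) > 1e-12:
            beta = beta / scale
            u = u * scale
        cur = loglik()
        if cur - prev < tol:
            break
        prev = cur

    # Laplace SEs of f from the final f-step Hessian
    B = build_design()
    X = np.column_stack([np.ones(n), B])
    from scipy.special import expit
    g = np.ones(n) if gamma is None else gamma[sess]
    eta = beta0 + g * (f_of_S() @ beta)
    p = expit(eta)
    H = (X * (p * (1 - p))[:, None]).T @ X
    if mode == "discrete":
        H += np.diag(np.r_[1e-6, prior_prec])
    else:
        H[1:, 1:] += prior_cov_inv
        H[0, 0] += 1e-6
    try:
        se_u = np.sqrt(np.diag(np.linalg.inv(H)))[1:]
    except np.linalg.LinAlgError:
        se_u = np.full(nu, np.nan)

    pts = np.r_[-xpos[::-1], xpos] if 0 not in np.unique(S[valid]) else \
        np.r_[-xpos[::-1], 0.0, xpos]
    fv = np.r_[-u[::-1], u] if pts.size == 2 * nu else np.r_[-u[::-1], 0.0, u]
    fse = np.r_[se_u[::-1], se_u] if pts.size == 2 * nu else \
        np.r_[se_u[::-1], 0.0, se_u]
    return SubjectiveWeightCurve(points=pts, f=fv, f_se=fse, beta0=beta0,
                                 beta=beta, gamma=gamma, mode=mode,
                                 loglik=prev if prev > -np.inf else loglik())


def _newton_map(X, y, prior_prec_mat, w0=None, max_iter=100, tol=1e-10):
    """Penalized logistic MAP with a full prior precision matrix."""
    from scipy.special import expit, log_expit
    n, d = X.shape
    w = np.zeros(d) if w0 is None else np.asarray(w0, dtype=float).copy()

    def obj(w):
        eta = X @ w
        return float(np.sum(log_expit(np.where(y == 1, eta, -eta)))
                     - 0.5 * w @ prior_prec_mat @ w)

    cur = obj(w)
    for _ in range(max_iter):
        eta = X @ w
        p = expit(eta)
        grad = X.T @ (y - p) - prior_prec_mat @ w
        H = (X * (p * (1 - p))[:, None]).T @ X + prior_prec_mat
        H[np.diag_indices(d)] += 1e-10
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(30):
            new = obj(w + scale * step)
            if new >= cur - 1e-12:
                break
            scale *= 0.5
        if new < cur:
            break
        w = w + scale * step
        if new - cur < tol:
            cur = new
            break
        cur = new
    return w
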