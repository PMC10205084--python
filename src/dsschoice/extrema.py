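"""Extrema-detection model: commit to the first threshold-crossing sample.

Each sample's evidence is corrupted by Gaussian sensory noise,
m_ti = S_ti + eps_ti with eps ~ N(0, sigma^2).  The observer commits to a
rightward (leftward) choice at the first sample whose noisy evidence
exceeds +theta (falls below -theta); later samples are ignored.  If no
sample crosses, a default rule resolves the trial: respond at random
('random_guess') or follow the sign of the noisy last sample
('last_sample').  Writing Phi for the standard normal CDF, the crossing
and survival probabilities at sample i are

    c+_i = Phi((S_ti - theta) / sigma)
    c-_i = Phi((-S_ti - theta) / sigma)
    surv_i = 1 - c+_i - c-_i

and the rightward-choice probability is the first-passage sum-product

    p_core = sum_i c+_i prod_{j<i} surv_j  +  default term.

Left/right lapses enter as an outer mixture
p = pi_R + (1 - pi_L - pi_R) * p_core.  A varying-threshold variant
substitutes a per-position theta_i.  Fitting is bounded maximum
likelihood (L-BFGS-B on (theta, log sigma, pi_L, pi_R)) with multiple
random initializations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr
from scipy.stats import norm

from .core_data import FittedModel, TrialTable

__all__ = ["ExtremaParams", "extrema_choice_prob", "extrema_path_probs",
           "fit_extrema", "simulate_extrema_process"]


@dataclass
class ExtremaParams:
    theta: float | np.ndarray          # scalar, or vector theta_i
    sigma: float
    pi_L: float = 0.0
    pi_R: float = 0.0
    default_rule: str = "random_guess"  # or "last_sample"

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if np.any(self.theta < 0):
            raise ValueError("threshold theta must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sensory noise sigma must be > 0")
        if not (0 <= self.pi_L <= 0.5 and 0 <= self.pi_R <= 0.5):
            raise ValueError("lapse rates must lie in [0, 0.5]")
        if self.pi_L + self.pi_R >= 1:
            raise ValueError("pi_L + pi_R must be < 1")
        if self.default_rule not in ("random_guess", "last_sample"):
            raise ValueError(f"unknown default rule {self.default_rule!r}")


def _crossing_terms(params: ExtremaParams, trials: TrialTable,
                    gains: np.ndarray | None):
    S = trials.scaled_evidence(gains)
    theta = params.theta
    if theta.ndim == 1 and theta.size not in (1, trials.n_max):
        raise ValueError("varying threshold needs one theta per position")
    th = np.broadcast_to(theta, (trials.n_max,)) if theta.ndim else \
        np.full(trials.n_max, float(theta))
    cpos = ndtr((S - th[None, :]) / params.sigma)
    cneg = ndtr((-S - th[None, :]) / params.sigma)
    surv = np.clip(1.0 - cpos - cneg, 0.0, 1.0)
    # masked samples can never cross and always survive
    cpos = np.where(trials.mask, cpos, 0.0)
    cneg = np.where(trials.mask, cneg, 0.0)
    surv = np.where(trials.mask, surv, 1.0)
    return S, cpos, cneg, surv


def _path_probs(S, cpos, cneg, surv):
    before = np.cumprod(np.concatenate(
        [np.ones((S.shape[0], 1)), surv[:, :-1]], axis=1), axis=1)
    right = cpos * before
    left = cneg * before
    through = before[:, -1] * surv[:, -1]
    return right, left, through


def extrema_path_probs(params: ExtremaParams, trials: TrialTable,
                       gains: np.ndarray | None = None):
    """Per-trial path probabilities (decide at sample i; survive to the end).

    Returns ``(right, left, through)`` where ``right``/``left`` are
    (n_trials, n_max) matrices of committing right/left at sample i and
    ``through`` is the probability that no sample crosses.  These n+1
    outcomes sum to 1 for every trial (total probability over first-
    passage paths).
    """
    S, cpos, cneg, surv = _crossing_terms(params, trials, gains)
    return _path_probs(S, cpos, cneg, surv)


def extrema_choice_prob(params: ExtremaParams, trials: TrialTable,
                        gains: np.ndarray | None = None) -> np.ndarray:
    """Closed-form P(rightward) per trial, lapses included."""
    S, cpos, cneg, surv = _crossing_terms(params, trials, gains)
    right, left, through = _path_probs(S, cpos, cneg, surv)
    if params.default_rule == "random_guess":
        p_core = right.sum(axis=1) + 0.5 * through
    else:
        # replace the last sample's contribution: on reaching sample n the
        # decision follows the sign of the noisy last sample (no threshold)
        n_t = trials.n_samples
        last = n_t - 1
        tr = np.arange(trials.n_trials)
        before_last = np.where(
            last > 0,
            np.cumprod(np.where(trials.mask, surv, 1.0), axis=1)[tr, last - 1],
            1.0)
        S_last = S[tr, last]
        p_core = right.sum(axis=1) - right[tr, last] \
            + ndtr(S_last / params.sigma) * before_last
    return params.pi_R + (1.0 - params.pi_L - params.pi_R) * p_core


def simulate_extrema_process(params: ExtremaParams, trials: TrialTable,
                             seed: int = 0,
                             gains: np.ndarray | None = None):
    """Monte-Carlo generative simulation (noise draws + first-crossing rule).

    Independent of the closed-form likelihood; used as its oracle in
    tests.  Returns ``(choices, crossing_sample)`` with crossing_sample =
    -1 on trials resolved by the default rule.  Lapses are applied as an
    outer mixture, consistent with :func:`extrema_choice_prob`.
    """
    rng = np.random.default_rng(seed)
    S = trials.scaled_evidence(gains)
    n, m = S.shape
    noisy = S + rng.normal(0.0, params.sigma, size=(n, m))
    th = np.broadcast_to(params.theta, (m,)) if params.theta.ndim else \
        np.full(m, float(params.theta))
    crossed = (np.abs(noisy) >= th[None, :]) & trials.mask
    first = np.where(crossed.any(axis=1), crossed.argmax(axis=1), -1)
    choices = np.empty(n, dtype=int)
    tr = np.arange(n)
    hit = first >= 0
    choices[hit] = (noisy[tr[hit], first[hit]] > 0).astype(int)
    if params.default_rule == "random_guess":
        choices[~hit] = rng.integers(0, 2, size=(~hit).sum())
    else:
        last = trials.n_samples - 1
        # fresh noise draw on the last sample (threshold-free readout)
        relook = S[tr[~hit], last[~hit]] + rng.normal(
            0.0, params.sigma, size=(~hit).sum())
        choices[~hit] = (relook > 0).astype(int)
    lapse = rng.random(n)
    choices = np.where(lapse < params.pi_R, 1, choices)
    choices = np.where(lapse > 1.0 - params.pi_L, 0, choices)
    return choices, first


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_extrema(trials: TrialTable, default_rule: str = "random_guess",
                varying_threshold: bool = False, fit_lapses: bool = True,
                n_starts: int = 10, seed: int = 0,
                gains: np.ndarray | None = None) -> FittedModel:
    """Bounded multi-start MLE of (theta, sigma, pi_L, pi_R).

    The varying-threshold variant fits one theta per sample position
    (n + 3 parameters).  sigma is optimized on a log scale for
    conditioning; bounds are theta in [0, 10 max|S|], sigma in
    [1e-3, 10 sd(S)], lapses in [0, 0.3].
    """
    rng = np.random.default_rng(seed)
    y = trials.choice
    S = trials.scaled_evidence(gains)
    absmax = float(np.abs(S[trials.mask]).max())
    sd = float(S[trials.mask].std()) or 1.0
    n_theta = trials.n_max if varying_threshold else 1

    def unpack(x):
        theta = x[:n_theta] if varying_threshold else float(x[0])
        sigma = float(np.exp(x[n_theta]))
        pl, pr = (float(x[n_theta + 1]), float(x[n_theta + 2])) \
            if fit_lapses else (0.0, 0.0)
        return ExtremaParams(theta=theta, sigma=sigma, pi_L=pl, pi_R=pr,
                             default_rule=default_rule)

    # fold gains once up front into a scaled view of the trials
    scaled = TrialTable(evidence=S, choice=y, session=trials.session,
                        mask=trials.mask, category=trials.category)

    def negll(x):
        p = np.clip(extrema_choice_prob(unpack(x), scaled), 1e-12, 1 - 1e-12)
        return -float(np.sum(np.where(y == 1, np.log(p), np.log1p(-p))))

    bounds = [(0.0, 10.0 * absmax)] * n_theta + \
        [(np.log(1e-3), np.log(10.0 * sd))] + \
        ([(0.0, 0.3)] * 2 if fit_lapses else [])

    best = None
    diagnostics = []
    for s in range(n_starts):
        x0 = np.concatenate([
            rng.uniform(0.1 * sd, 2.0 * sd, size=n_theta),
            [np.log(rng.uniform(0.2 * sd, 2.0 * sd))],
            rng.uniform(0.0, 0.1, size=2) if fit_lapses else [],
        ])
        res = minimize(negll, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 500})
        diagnostics.append({"start": s, "loglik": -float(res.fun),
                            "success": bool(res.success),
                            "message": str(res.message)})
        if best is None or -res.fun > best["loglik"]:
            best = {"x": res.x, "loglik": -float(res.fun),
                    "success": bool(res.success)}

    params = unpack(best["x"])
    n_params = n_theta + 1 + (2 if fit_lapses else 0)
    any_converged = any(d["success"] for d in diagnostics)
    cov, cov_names = _laplace_cov(params, scaled, varying_threshold, fit_lapses)
    return FittedModel(
        model_id="extrema",
        variant="extrema." + default_rule
        + (".varying_threshold" if varying_threshold else ""),
        params={"theta": params.theta if varying_threshold
                else float(params.theta),
                "sigma": params.sigma,
                "pi_L": params.pi_L, "pi_R": params.pi_R},
        loglik=best["loglik"], n_params=n_params,
        posterior_cov=cov, cov_param_names=cov_names,
        fit_meta={"default_rule": default_rule,
                  "varying_threshold": varying_threshold,
                  "fit_lapses": fit_lapses, "n_starts": n_starts,
                  "seed": seed, "converged": any_converged,
                  "starts": diagnostics, "used_gains": gains is not None},
    )


def _laplace_cov(params: ExtremaParams, trials: TrialTable,
                 varying_threshold: bool, fit_lapses: bool):
    """Inverse numerical Hessian of the negative log-likelihood at the MLE.

    Natural scale (theta, sigma, pi_L, pi_R); supplies the sampling
    distribution for parametric bootstraps.  Returns (None, None) when
    the Hessian is not positive definite (e.g. a bound-pinned optimum).
    """
    theta = np.atleast_1d(params.theta)
    x0 = np.concatenate([theta, [params.sigma],
                         [params.pi_L, params.pi_R] if fit_lapses else []])
    names = [f"theta{i + 1}" for i in range(theta.size)] if varying_threshold \
        else ["theta"]
    names += ["sigma"] + (["pi_L", "pi_R"] if fit_lapses else [])
    y = trials.choice

    def nll(x):
        th = x[: theta.size] if varying_threshold else float(x[0])
        pl, pr = (x[theta.size + 1], x[theta.size + 2]) if fit_lapses \
            else (0.0, 0.0)
        if np.any(np.atleast_1d(th) < 0) or x[theta.size] <= 0 or \
                not (0 <= pl <= 0.5 and 0 <= pr <= 0.5):
            return np.inf
        p = extrema_choice_prob(
            ExtremaParams(theta=th, sigma=float(x[theta.size]), pi_L=float(pl),
                          pi_R=float(pr), default_rule=params.default_rule),
            trials)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -float(np.sum(np.where(y == 1, np.log(p), np.log1p(-p))))

    d = x0.size
    h = np.maximum(1e-4, 1e-3 * np.abs(x0))
    H = np.empty((d, d))
    f0 = nll(x0)
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = h[i]
            ej = np.zeros(d); ej[j] = h[j]
            if i == j:
                val = (nll(x0 + ei) - 2 * f0 + nll(x0 - ei)) / h[i] ** 2
            else:
                val = (nll(x0 + ei + ej) - nll(x0 + ei - ej)
                       - nll(x0 - ei + ej) + nll(x0 - ei - ej)) \
                    / (4 * h[i] * h[j])
            H[i, j] = H[j, i] = val
    if not np.isfinite(H).all():
        return None, None
    try:
        cov = np.linalg.inv(H)
        cov = (cov + cov.T) / 2.0
        if np.linalg.eigvalsh(cov).min() <= 0:
            return None, None
        return cov, names
    except np.linalg.LinAlgError:
        return None, None


def params_from_fit(fit: FittedModel) -> ExtremaParams:
    return ExtremaParams(
        theta=fit.params["theta"], sigma=float(fit.params["sigma"]),
        pi_L=float(fit.params.get("pi_L", 0.0)),
        pi_R=float(fit.params.get("pi_R", 0.0)),
        default_rule=fit.fit_meta.get("default_rule", "random_guess"),
    )
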