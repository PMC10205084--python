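"""Temporal-integration choice model.

The model treats the choice as a logistic (or probit) function of the
weighted sum of sample evidence,

    p(r_t = right) = sigma(beta0 + gamma_{s(t)} * sum_i beta_i S_ti),

with a lateral bias beta0, per-position sensory weights beta_i (the
psychophysical kernel of the fitted model) and an optional per-session
multiplicative gain gamma capturing slow performance drift.  The per-
position weights are a first-order statistical stand-in for any generative
accumulator (leak, attractors, bounds show up as kernel shape), which is
what makes the model cheap to fit and robust to overfitting.

Fitting is penalized maximum likelihood (independent Gaussian priors on
all weights) with a Laplace approximation to the posterior at the mode.
With gains enabled the problem is bilinear; we alternate two convex
penalized logistic sub-problems (beta with gamma fixed, gamma with beta
fixed), renormalizing to mean(gamma) = 1 after every sweep to pin the
scale degeneracy.  The reported log-likelihood excludes the prior so AIC
stays likelihood-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, log_expit
from scipy.stats import norm

from .core_data import FittedModel, SessionGains, TrialTable

__all__ = ["IntegrationParams", "predict_integration", "fit_integration"]


@dataclass
class IntegrationParams:
    beta0: float
    beta: np.ndarray
    gamma: SessionGains | np.ndarray | None = None
    link: str = "logit"

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if isinstance(self.gamma, SessionGains):
            self.gamma = self.gamma.gamma
        if self.gamma is not None:
            self.gamma = np.asarray(self.gamma, dtype=float)


def _link_cdf(x: np.ndarray, link: str) -> np.ndarray:
    if link == "logit":
        return expit(x)
    if link == "probit":
        return norm.cdf(x)
    raise ValueError(f"unknown link {link!r}")


def linear_predictor(params: IntegrationParams, trials: TrialTable) -> np.ndarray:
    beta = params.beta
    if beta.size < trials.n_max:
        raise ValueError(
            f"kernel length {beta.size} < max sample count {trials.n_max}")
    drive = trials.evidence @ beta[: trials.n_max]
    if params.gamma is not None:
        if params.gamma.shape != (trials.n_sessions,):
            raise ValueError("need one gain per session present in the data")
        drive = drive * params.gamma[trials.session_index]
    return params.beta0 + drive


def predict_integration(params: IntegrationParams,
                        trials: TrialTable) -> np.ndarray:
    """Per-trial P(rightward) under the integration model."""
    return _link_cdf(linear_predictor(params, trials), params.link)


# ---------------------------------------------------------------------------
# Penalized logistic solver (Newton with step-halving)
# ---------------------------------------------------------------------------

def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray, link: str) -> float:
    if link == "logit":
        # log sigma(eta) for y=1, log sigma(-eta) for y=0; stable
        return float(np.sum(log_expit(np.where(y == 1, eta, -eta))))
    p = np.clip(norm.cdf(eta), 1e-12, 1 - 1e-12)
    return float(np.sum(np.where(y == 1, np.log(p), np.log1p(-p))))


def _penalized_logistic(X: np.ndarray, y: np.ndarray, prior_prec: np.ndarray,
                        prior_mean: np.ndarray, w0: np.ndarray | None = None,
                        link: str = "logit", max_iter: int = 100,
                        tol: float = 1e-10) -> tuple[np.ndarray, bool]:
    """MAP weights of y ~ link(X w) with w ~ N(prior_mean, diag(1/prior_prec)).

    Newton ascent on the log posterior with step-halving; prior_prec of 0
    yields plain maximum likelihood.  Returns (w_hat, converged).
    """
    n, d = X.shape
    w = np.zeros(d) if w0 is None else w0.astype(float).copy()

    def objective(w):
        eta = X @ w
        pen = -0.5 * np.sum(prior_prec * (w - prior_mean) ** 2)
        return _bernoulli_loglik(eta, y, link) + pen

    obj = objective(w)
    converged = False
    for _ in range(max_iter):
        eta = X @ w
        if link == "logit":
            p = expit(eta)
            score = y - p
            wts = p * (1 - p)
        else:
            p = np.clip(norm.cdf(eta), 1e-10, 1 - 1e-10)
            phi = norm.pdf(eta)
            score = phi * (y - p) / (p * (1 - p))
            wts = phi ** 2 / (p * (1 - p))
        grad = X.T @ score - prior_prec * (w - prior_mean)
        H = (X * wts[:, None]).T @ X
        H[np.diag_indices(d)] += prior_prec + 1e-12
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = grad / np.diag(H)
        scale = 1.0
        for _ in range(30):
            w_new = w + scale * step
            obj_new = objective(w_new)
            if obj_new >= obj - 1e-12:
                break
            scale *= 0.5
        if obj_new < obj:
            converged = True  # no ascent direction left
            break
        delta = obj_new - obj
        w, obj = w_new, obj_new
        if delta < tol:
            converged = True
            break
    return w, converged


def fit_integration(trials: TrialTable, use_session_gain: bool = False,
                    prior_sd: float | None = 1.0, fit_bias: bool = True,
                    link: str = "logit", seed: int = 0,
                    max_sweeps: int = 200, tol: float = 1e-9) -> FittedModel:
    """Fit the integration model by penalized ML with Laplace covariance.

    Parameters
    ----------
    use_session_gain:
        Fit one multiplicative gain per session (identified by fixing
        mean(gamma) = 1 exactly).  With a single session the constraint
        forces gamma = 1 and the fit equals the no-gain fit.
    prior_sd:
        SD of the independent Gaussian prior on beta0 and beta (and of the
        N(1, prior_sd^2) prior on gains).  ``None`` or ``inf`` -> flat
        prior (plain logistic regression; separation is then possible and
        reported through the convergence flag).
    fit_bias:
        Include the lateral bias beta0 (set False for the snapshot K=n
        equivalence form).

    Returns a :class:`FittedModel` whose ``posterior_cov`` is the inverse
    Hessian of the negative log posterior over (beta0, beta) at the mode
    (gains held at their estimate).
    """
    y = trials.choice.astype(float)
    if np.unique(y).size < 2:
        import warnings
        warnings.warn("all choices identical; bias-only fit is degenerate")
    S = trials.evidence  # masked entries are exactly 0, so they drop out
    n, m = S.shape
    prec = 0.0 if (prior_sd is None or not np.isfinite(prior_sd)) \
        else 1.0 / prior_sd ** 2

    d = m + (1 if fit_bias else 0)
    prior_prec = np.full(d, prec)
    prior_mean = np.zeros(d)

    sess = trials.session_index
    n_sess = trials.n_sessions
    gamma = np.ones(n_sess)
    w = np.zeros(d)

    def design(gamma):
        Xg = S * gamma[sess][:, None]
        if fit_bias:
            return np.column_stack([np.ones(n), Xg])
        return Xg

    def data_loglik(w, gamma):
        eta = design(gamma) @ w
        return _bernoulli_loglik(eta, y, link)

    def log_post(w, gamma):
        lp = data_loglik(w, gamma)
        lp -= 0.5 * np.sum(prior_prec * w ** 2)
        if use_session_gain:
            lp -= 0.5 * prec * np.sum((gamma - 1.0) ** 2)
        return lp

    converged = True
    if not use_session_gain or n_sess == 1:
        w, converged = _penalized_logistic(
            design(gamma), y, prior_prec, prior_mean, link=link)
        use_gains_effective = use_session_gain  # single session -> gamma = 1
    else:
        prev = -np.inf
        for _ in range(max_sweeps):
            w, _ = _penalized_logistic(design(gamma), y, prior_prec,
                                       prior_mean, w0=w, link=link)
            # gamma-step: per-session 1-D penalized logistic with offset
            beta = w[1:] if fit_bias else w
            b0 = w[0] if fit_bias else 0.0
            u = S @ beta
            for s in range(n_sess):
                sel = sess == s
                ys = y[sel]
                # 1-D Newton on gamma_s alone (bias held fixed as offset)
                g = gamma[s]
                for _ in range(25):
                    eta = b0 + g * u[sel]
                    if link == "logit":
                        p = expit(eta)
                        grad = np.dot(u[sel], ys - p) - prec * (g - 1.0)
                        hess = np.dot(u[sel] ** 2, p * (1 - p)) + prec + 1e-12
                    else:
                        p = np.clip(norm.cdf(eta), 1e-10, 1 - 1e-10)
                        phi = norm.pdf(eta)
                        grad = np.dot(u[sel] * phi, (ys - p) / (p * (1 - p))) \
                            - prec * (g - 1.0)
                        hess = np.dot(u[sel] ** 2 * phi ** 2,
                                      1.0 / (p * (1 - p))) + prec + 1e-12
                    step = grad / hess
                    if abs(step) < 1e-12:
                        break
                    g = g + step
                gamma[s] = g
            # remove the bilinear scale degeneracy: mean(gamma) = 1 exactly
            scale = gamma.mean()
            gamma = gamma / scale
            if fit_bias:
                w[1:] *= scale
            else:
                w *= scale
            cur = log_post(w, gamma)
            if cur - prev < tol:
                break
            prev = cur
        else:
            converged = False
        use_gains_effective = True

    # exact renormalization guarantee (single-session case included)
    if use_session_gain:
        gamma = gamma / gamma.mean()

    beta = w[1:] if fit_bias else w.copy()
    beta0 = float(w[0]) if fit_bias else 0.0
    loglik = data_loglik(w, gamma)

    # Laplace covariance over (beta0?, beta) at the mode, gains fixed
    X = design(gamma)
    eta = X @ w
    if link == "logit":
        p = expit(eta)
        wts = p * (1 - p)
    else:
        p = np.clip(norm.cdf(eta), 1e-10, 1 - 1e-10)
        phi = norm.pdf(eta)
        wts = phi ** 2 / (p * (1 - p))
    H = (X * wts[:, None]).T @ X
    H[np.diag_indices(d)] += prior_prec
    try:
        cov = np.linalg.inv(H)
        cov = (cov + cov.T) / 2.0
    except np.linalg.LinAlgError:
        cov = None

    separation = bool(np.abs(w).max() > 50.0)
    n_params = d + (n_sess - 1 if use_session_gain else 0)
    params = {"beta0": beta0, "beta": beta}
    if use_session_gain:
        params["gamma"] = gamma
    names = (["beta0"] if fit_bias else []) + \
        [f"beta{i + 1}" for i in range(m)]
    return FittedModel(
        model_id="integration",
        variant="integration" + (".session_gain" if use_session_gain else "")
        + ("" if link == "logit" else f".{link}"),
        params=params, loglik=loglik, n_params=n_params,
        posterior_cov=cov, cov_param_names=names,
        fit_meta={"converged": converged and not separation,
                  "separation": separation, "link": link,
                  "prior_sd": prior_sd, "fit_bias": fit_bias, "seed": seed},
    )


def params_from_fit(fit: FittedModel) -> IntegrationParams:
    return IntegrationParams(
        beta0=float(fit.params.get("beta0", 0.0)),
        beta=np.asarray(fit.params["beta"]),
        gamma=fit.params.get("gamma"),
        link=fit.fit_meta.get("link", "logit"),
    )
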