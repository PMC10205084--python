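"""Snapshot mixture model: choices driven by a single attended sample.

On each trial the observer attends one sample (or a window of K
consecutive samples) drawn from a stimulus-independent multinomial
attention policy (pi_1..pi_n, pi_L, pi_R); pi_L and pi_R are lapse
components that answer left/right regardless of the stimulus.  Given the
attended component, the response probability is H_i:

* deterministic rule:  H_i = 1, 0 or 0.5 by the sign of the attended
  evidence (guess on exactly-zero evidence);
* probabilistic rule:  H_i = sigma(beta_i * S_ti) with a per-position
  sensitivity; for windows, sigma of the beta-weighted window sum.

The marginal choice probability is the mixture p(r_t) = sum_c pi_c H_c.
The deterministic rule is the beta -> +inf limit of the probabilistic
one.  With K = n, no lapses and the probabilistic rule the model is
exactly the bias-free integration model — a useful identity for testing.

Fitting is by Expectation-Maximization over the attention policy (and
sensitivities): the E-step computes responsibilities z_tc (posterior
attention probabilities), the M-step re-estimates pi in closed form and
applies one safeguarded Newton-Raphson update per sensitivity parameter.
A step-halving guard keeps the observed log-likelihood non-decreasing on
every iteration (generalized EM); convergence is an increment below
``tol`` (default 1e-9), best of ``n_starts`` random initializations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .core_data import FittedModel, TrialTable

__all__ = ["SnapshotParams", "snapshot_choice_prob", "em_fit_snapshot",
           "snapshot_component_probs"]


@dataclass
class SnapshotParams:
    """Attention policy + response-rule parameters.

    ``pi`` is ordered (window starts 1..n-K+1, then L, then R).  ``beta``
    is a ``(K, n_windows)`` matrix for the probabilistic rule (a vector is
    accepted for K=1); ignored by the deterministic rule.
    """

    pi: np.ndarray
    beta: np.ndarray | None = None
    K: int = 1
    rule: str = "deterministic"          # or "probabilistic"
    lapse_mode: str = "free"             # free | fixed | none

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.beta is not None:
            self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        if np.any(self.pi < -1e-12):
            raise ValueError("mixture weights must be non-negative")
        if abs(self.pi.sum() - 1.0) > 1e-12:
            raise ValueError("mixture weights must sum to 1 (to 1e-12)")
        if self.rule not in ("deterministic", "probabilistic"):
            raise ValueError(f"unknown rule {self.rule!r}")

    @property
    def n_windows(self) -> int:
        return self.pi.size - 2


def _n_windows(n: int, K: int) -> int:
    if not 1 <= K <= n:
        raise ValueError(f"window length K={K} out of range [1, {n}]")
    return n - K + 1


def _component_matrix(S: np.ndarray, n_t: np.ndarray, K: int, rule: str,
                      beta: np.ndarray | None) -> np.ndarray:
    """H matrix (n_trials, n_windows + 2): P(right | attended component).

    Components attending a window that starts beyond a trial's own sample
    count contribute H = 0.5 (attending a nonexistent sample is a guess).
    The last two columns are the left (H=0) and right (H=1) lapses.
    """
    n = S.shape[1]
    nw = _n_windows(n, K)
    H = np.full((S.shape[0], nw + 2), 0.5)
    for i in range(nw):
        if rule == "deterministic":
            # window sum over samples that exist; start beyond n_t -> guess
            h = 0.5 + 0.5 * np.sign(S[:, i:i + K].sum(axis=1))
        else:
            if beta is None:
                raise ValueError("probabilistic rule requires sensitivities beta")
            if beta.shape != (K, nw):
                raise ValueError(f"beta must have shape ({K}, {nw})")
            h = expit(S[:, i:i + K] @ beta[:, i])
        h[n_t <= i] = 0.5
        H[:, i] = h
    H[:, nw] = 0.0       # left lapse
    H[:, nw + 1] = 1.0   # right lapse
    return H


def snapshot_component_probs(params: SnapshotParams, trials: TrialTable,
                             gains: np.ndarray | None = None) -> np.ndarray:
    """Per-component response probabilities H for every trial."""
    nw = _n_windows(trials.n_max, params.K)
    if params.pi.size != nw + 2:
        raise ValueError(
            f"pi has {params.pi.size} entries, expected {nw + 2} for K={params.K}")
    return _component_matrix(trials.scaled_evidence(gains), trials.n_samples,
                             params.K, params.rule, params.beta)


def snapshot_choice_prob(params: SnapshotParams, trials: TrialTable,
                         gains: np.ndarray | None = None) -> np.ndarray:
    """Mixture probability of a rightward choice, p = sum_c pi_c H_c."""
    H = snapshot_component_probs(params, trials, gains)
    return H @ params.pi


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

def _loglik(pi, H, y, w=None):
    p = np.clip(H @ pi, 1e-300, 1.0)
    q = np.clip(1.0 - H @ pi, 1e-300, 1.0)
    ll = np.where(y == 1, np.log(p), np.log(q))
    return float(np.sum(ll if w is None else w * ll))


def em_fit_snapshot(trials: TrialTable, rule: str = "deterministic",
                    K: int = 1, lapse_mode: str = "free",
                    n_starts: int = 10, tol: float = 1e-9,
                    max_iter: int = 3000, seed: int = 0,
                    gains: np.ndarray | None = None,
                    allow_full_window: bool = False) -> FittedModel:
    """Fit the snapshot model by (generalized) EM, best of ``n_starts``.

    ``lapse_mode``: 'free' fits pi_L, pi_R inside the multinomial; 'fixed'
    clamps them to 0.01 each; 'none' removes them.  The strict snapshot
    family has K <= n-1; pass ``allow_full_window=True`` for the K = n
    integration-equivalence form.
    """
    n = trials.n_max
    if not allow_full_window and not 1 <= K <= max(n - 1, 1):
        raise ValueError(f"K={K} out of the snapshot range [1, {n - 1}]")
    nw = _n_windows(n, K)
    y = trials.choice
    rng = np.random.default_rng(seed)
    S = trials.scaled_evidence(gains)
    n_t = trials.n_samples
    fixed_lapse = 0.01

    w = None
    H_det = None
    if rule == "deterministic":
        # H is parameter-free; collapsing to unique (H-row, choice)
        # patterns with counts makes EM cost independent of n_trials
        H_det = _component_matrix(S, n_t, K, rule, None)
        patt, counts = np.unique(np.column_stack([H_det, y]), axis=0,
                                 return_counts=True)
        H_det, y = patt[:, :-1], patt[:, -1].astype(int)
        w = counts.astype(float)

    best = None
    start_logs = []
    for s in range(n_starts):
        pi = rng.dirichlet(np.ones(nw + 2))
        if lapse_mode == "fixed":
            pi[:nw] = pi[:nw] / pi[:nw].sum() * (1 - 2 * fixed_lapse)
            pi[nw:] = fixed_lapse
        elif lapse_mode == "none":
            pi[:nw] = pi[:nw] / pi[:nw].sum()
            pi[nw:] = 0.0
        beta = rng.standard_normal((K, nw)) if rule == "probabilistic" else None
        H = H_det if rule == "deterministic" else \
            _component_matrix(S, n_t, K, rule, beta)
        ll = _loglik(pi, H, y, w)
        history = [ll]
        monotone = True
        for _ in range(max_iter):
            # E-step: responsibilities
            Hy = np.where(y[:, None] == 1, H, 1.0 - H)
            num = Hy * pi[None, :]
            z = num / np.clip(num.sum(axis=1, keepdims=True), 1e-300, None)
            # M-step: closed-form pi under the simplex constraint
            if w is None:
                zbar = z.mean(axis=0)
            else:
                zbar = (z * w[:, None]).sum(axis=0) / w.sum()
            if lapse_mode == "free":
                pi_new = zbar
            elif lapse_mode == "fixed":
                pi_new = pi.copy()
                zs = zbar[:nw]
                pi_new[:nw] = zs / max(zs.sum(), 1e-300) * (1 - 2 * fixed_lapse)
                pi_new[nw:] = fixed_lapse
            else:  # none
                pi_new = np.r_[zbar[:nw] / max(zbar[:nw].sum(), 1e-300),
                               0.0, 0.0]
            if rule == "probabilistic":
                # one Newton-Raphson update per window's sensitivity vector,
                # with step-halving on the observed log-likelihood
                beta_new = beta.copy()
                for i in range(nw):
                    zi = z[:, i]
                    live = n_t > i
                    if not live.any() or zi[live].sum() < 1e-12:
                        continue
                    Xi = S[live, i:i + K]
                    h = expit(Xi @ beta[:, i])
                    r = y[live].astype(float)
                    g = Xi.T @ (zi[live] * (r - h))
                    wts = zi[live] * h * (1 - h)
                    Hm = (Xi * wts[:, None]).T @ Xi
                    Hm[np.diag_indices(K)] += 1e-10
                    try:
                        beta_new[:, i] = beta[:, i] + np.linalg.solve(Hm, g)
                    except np.linalg.LinAlgError:
                        continue
                H_new = _component_matrix(S, n_t, K, rule, beta_new)
                ll_new = _loglik(pi_new, H_new, y)
                scale = 1.0
                halvings = 0
                full_step = beta_new - beta
                while ll_new < ll and halvings < 10:
                    scale *= 0.5
                    beta_new = beta + scale * full_step
                    H_new = _component_matrix(S, n_t, K, rule, beta_new)
                    ll_new = _loglik(pi_new, H_new, y)
                    halvings += 1
                if ll_new < ll:
                    # revert beta; the pi update alone is a proper EM step
                    beta_new = beta
                    H_new = H
                    ll_new = _loglik(pi_new, H_new, y)
                beta, H = beta_new, H_new
            else:
                ll_new = _loglik(pi_new, H, y, w)
            if ll_new < ll - 1e-9:
                monotone = False
            pi = pi_new
            history.append(ll_new)
            if ll_new - ll < tol:
                ll = ll_new
                break
            ll = ll_new
        pruned = np.flatnonzero(pi[:nw] < 1e-8)
        start_logs.append({"start": s, "loglik": ll, "iters": len(history) - 1,
                           "monotone": monotone,
                           "pruned_components": pruned.tolist()})
        if best is None or ll > best["loglik"]:
            best = {"pi": pi, "beta": beta, "loglik": ll, "history": history,
                    "monotone": monotone}

    if lapse_mode == "free":
        n_free_pi = nw + 2 - 1
    elif lapse_mode == "fixed":
        n_free_pi = nw - 1
    else:
        n_free_pi = nw - 1
    n_params = n_free_pi + (K * nw if rule == "probabilistic" else 0)

    params = {"pi": best["pi"]}
    if best["beta"] is not None:
        params["beta"] = best["beta"]
    variant = f"snapshot.{rule}.K{K}.{lapse_mode}_lapse"
    return FittedModel(
        model_id="snapshot", variant=variant, params=params,
        loglik=best["loglik"], n_params=n_params,
        fit_meta={"rule": rule, "K": K, "lapse_mode": lapse_mode,
                  "n_starts": n_starts, "seed": seed, "tol": tol,
                  "monotone": best["monotone"], "starts": start_logs,
                  "loglik_history": best["history"],
                  "used_gains": gains is not None},
    )


def params_from_fit(fit: FittedModel) -> SnapshotParams:
    return SnapshotParams(
        pi=np.asarray(fit.params["pi"]),
        beta=None if "beta" not in fit.params else np.asarray(fit.params["beta"]),
        K=int(fit.fit_meta.get("K", 1)),
        rule=fit.fit_meta.get("rule", "deterministic"),
        lapse_mode=fit.fit_meta.get("lapse_mode", "free"),
    )
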