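"""Model-validation statistics for DSS choice data.

Psychophysical kernels, quantile psychometric curves, accuracy, boundary
(best-case) performance for the non-integration model families, and AIC
model comparison.  All statistics run through identical code paths for
observed and simulated choices, so data/model comparisons are
like-for-like by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import FittedModel, TrialTable
from .integration import fit_integration, params_from_fit, linear_predictor

__all__ = ["Kernel", "PsychometricCurve", "psychophysical_kernel",
           "psychometric_curve", "weighted_evidence", "accuracy",
           "boundary_performance", "compare_models"]


@dataclass
class Kernel:
    """Per-position logistic-regression weights (the psychophysical kernel)."""

    weights: np.ndarray
    se: np.ndarray
    bias: float
    bias_se: float
    fit: FittedModel


@dataclass
class PsychometricCurve:
    bin_centers: np.ndarray     # mean weighted evidence T per quantile bin
    proportion_right: np.ndarray
    counts: np.ndarray
    n_bins: int


def psychophysical_kernel(trials: TrialTable,
                          choices: np.ndarray | None = None,
                          prior_sd: float | None = 1.0) -> Kernel:
    """Logistic-regression weights of choice on per-position evidence.

    Plain (no session gain) logistic regression; standard errors come
    from the Laplace approximation at the mode.  Positions never observed
    in any trial get NaN weight/SE.
    """
    if choices is not None:
        trials = trials.with_choices(choices)
    fit = fit_integration(trials, use_session_gain=False, prior_sd=prior_sd)
    beta = np.asarray(fit.params["beta"], dtype=float)
    se = np.sqrt(np.diag(fit.posterior_cov))
    bias_se, beta_se = float(se[0]), se[1:]
    never = ~trials.mask.any(axis=0)
    beta[never] = np.nan
    beta_se = beta_se.copy()
    beta_se[never] = np.nan
    return Kernel(weights=beta, se=beta_se, bias=float(fit.params["beta0"]),
                  bias_se=bias_se, fit=fit)


def weighted_evidence(trials: TrialTable, reference_fit: FittedModel) -> np.ndarray:
    """Session-modulated weighted total evidence T_t = gamma_t sum_i beta_i S_ti."""
    params = params_from_fit(reference_fit)
    return linear_predictor(params, trials) - params.beta0


def psychometric_curve(trials: TrialTable, choices: np.ndarray | None,
                       reference_fit: FittedModel,
                       n_bins: int = 50) -> PsychometricCurve:
    """Proportion rightward per quantile bin of weighted evidence T_t.

    Bins are T-order-statistic quantiles (stable tie-break by trial
    order), so bin counts differ by at most one.
    """
    if choices is None:
        choices = trials.choice
    if n_bins > trials.n_trials:
        raise ValueError("more bins than trials")
    T = weighted_evidence(trials, reference_fit)
    order = np.argsort(T, kind="stable")
    bins = np.array_split(order, n_bins)
    centers = np.array([T[b].mean() for b in bins])
    prop = np.array([np.mean(choices[b]) for b in bins])
    counts = np.array([b.size for b in bins])
    return PsychometricCurve(bin_centers=centers, proportion_right=prop,
                             counts=counts, n_bins=n_bins)


def accuracy(choices: np.ndarray, category: np.ndarray) -> float:
    return float(np.mean(choices == category))


def boundary_performance(model_id: str, trials: TrialTable,
                         category: np.ndarray | None = None,
                         gains: np.ndarray | None = None,
                         theta_grid_size: int = 200) -> float:
    """Best achievable accuracy over all parameterizations of a model family.

    * ``snapshot``: deterministic, lapse-free, always attending the single
      sample position whose sign best predicts the category (zero-evidence
      samples count as coin flips).
    * ``extrema``: lapse-free, noise-free (sigma = 0) rule, threshold
      maximized over a grid of ``theta_grid_size`` points on [0, max|S|];
      trials where no sample reaches threshold score 0.5 (random default).
    """
    if category is None:
        category = trials.category
    if category is None:
        raise ValueError("boundary performance requires category labels")
    S = trials.scaled_evidence(gains)
    cat = np.asarray(category)
    if model_id == "snapshot":
        best = 0.0
        for i in range(trials.n_max):
            live = trials.mask[:, i]
            s = np.sign(S[:, i])
            score = np.where(s == 0, 0.5, (s > 0) == cat)
            score = np.where(live, score, 0.5)  # missing sample -> guess
            best = max(best, float(score.mean()))
        return best
    if model_id == "extrema":
        absS = np.where(trials.mask, np.abs(S), -np.inf)
        grid = np.linspace(0.0, absS.max(), theta_grid_size)
        best = 0.0
        for theta in grid:
            crossed = absS >= theta   # masked positions are -inf, never cross
            any_cross = crossed.any(axis=1)
            first = np.where(any_cross, crossed.argmax(axis=1), 0)
            s = np.sign(S[np.arange(trials.n_trials), first])
            score = np.where(
                any_cross, np.where(s == 0, 0.5, (s > 0) == cat), 0.5)
            best = max(best, float(score.mean()))
        return best
    raise ValueError(f"no boundary-performance rule for {model_id!r}")


def compare_models(fits: list[FittedModel]) -> pd.DataFrame:
    """AIC comparison table with deltas to the best and to integration."""
    rows = [{"model": f.model_id, "variant": f.variant,
             "n_params": f.n_params, "loglik": f.loglik, "aic": f.aic}
            for f in fits]
    df = pd.DataFrame(rows)
    df["delta_aic_best"] = df["aic"] - df["aic"].min()
    ref = df.loc[df["model"] == "integration", "aic"]
    df["delta_aic_vs_integration"] = (
        df["aic"] - ref.iloc[0] if len(ref) else np.nan)
    return df
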