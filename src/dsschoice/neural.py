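"""Poisson-GLM analysis of spike counts against sample evidence.

For each neuron, a Poisson GLM with log link regresses the trial spike
count (a 500 ms window after stimulus offset, upstream of this module)
on the per-sample evidence values:

    E[s_t] = exp(w0 + sum_i w_i S_ti).

The fitted weights define neuron-weighted early/late evidence (samples
1..3 vs 4..7 for seven-sample designs, first floor(n/2) in general) and
normalized counts s_t / exp(w0), which pool across neurons into a
*neural integration map* — the spike-count analogue of the behavioral
map, with straight isolines under additive evidence coding.

Three spike-count simulators generate counts under the competing
hypotheses: the GLM generative process (integration), activity driven by
the threshold-crossing sample of the behavioral extrema model, and
activity driven by a single attended sample with attention probabilities
proportional to the neuron's (non-negative, direction-signed) GLM
weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.ndimage import gaussian_filter

from .core_data import TrialTable
from .extrema import ExtremaParams, simulate_extrema_process

__all__ = ["NeuralFit", "fit_neuron_glm", "neuron_evidence_split",
           "normalized_counts", "neural_integration_map", "simulate_neuron"]


@dataclass
class NeuralFit:
    """Per-neuron Poisson-GLM weights and derived quantities."""

    w0: float
    w: np.ndarray
    se: np.ndarray              # Wald SEs, [w0, w...]
    preferred: int              # p(n) = sign of summed weights, in {-1, +1}
    degenerate: bool = False


def fit_neuron_glm(counts: np.ndarray, trials: TrialTable) -> NeuralFit:
    """Poisson regression of spike counts on per-sample evidence.

    The preferred direction is the sign of the summed sample weights
    (ties resolve to +1).  All-zero counts yield a degenerate flag.
    """
    counts = np.asarray(counts)
    if counts.shape != (trials.n_trials,):
        raise ValueError("counts must align with trials")
    if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.number):
        raise ValueError("counts must be non-negative")
    X = sm.add_constant(trials.evidence)
    if counts.max() == 0:
        return NeuralFit(w0=-np.inf, w=np.zeros(trials.n_max),
                         se=np.full(trials.n_max + 1, np.nan),
                         preferred=1, degenerate=True)
    res = sm.GLM(counts, X, family=sm.families.Poisson()).fit()
    w0, w = float(res.params[0]), np.asarray(res.params[1:])
    pref = 1 if w.sum() >= 0 else -1
    return NeuralFit(w0=w0, w=w, se=np.asarray(res.bse), preferred=pref)


def neuron_evidence_split(fit: NeuralFit,
                          trials: TrialTable) -> tuple[np.ndarray, np.ndarray]:
    """Neuron-weighted early/late evidence, E_t(n) and L_t(n).

    Uses the fitted weights only; the early window is samples 1..3 for
    seven-sample designs (floor(n/2) in general), matching the behavioral
    early/late split.
    """
    n_half = trials.n_samples // 2
    weighted = trials.evidence * fit.w[None, : trials.n_max]
    early = (np.arange(trials.n_max)[None, :] < n_half[:, None]) & trials.mask
    E = np.where(early, weighted, 0.0).sum(axis=1)
    L = np.where(trials.mask & ~early, weighted, 0.0).sum(axis=1)
    return E, L


def normalized_counts(fit: NeuralFit, counts: np.ndarray) -> np.ndarray:
    """Baseline-normalized counts s_t / exp(w0)."""
    return np.asarray(counts, dtype=float) / np.exp(fit.w0)


def neural_integration_map(fits: list[NeuralFit], counts_list: list[np.ndarray],
                           trials_list: list[TrialTable],
                           bin_width: float = 0.02, kernel_sd: float = 0.1,
                           ) -> dict:
    """Pooled smoothed normalized activity over (E, L) bins.

    Normalized counts and neuron-weighted evidence are merged across
    neurons, binned at ``bin_width`` and smoothed with a Gaussian kernel
    of SD ``kernel_sd`` (in evidence units); the map value is the
    smoothed average normalized count per bin.  Bins with no smoothed
    support are masked NaN.
    """
    if not fits:
        raise ValueError("need at least one fitted neuron")
    E_all, L_all, s_all = [], [], []
    for fit, counts, trials in zip(fits, counts_list, trials_list):
        if fit.degenerate:
            continue
        E, L = neuron_evidence_split(fit, trials)
        E_all.append(E)
        L_all.append(L)
        s_all.append(normalized_counts(fit, counts))
    E = np.concatenate(E_all)
    L = np.concatenate(L_all)
    s = np.concatenate(s_all)
    E_edges = np.arange(np.floor(E.min() / bin_width),
                        np.ceil(E.max() / bin_width) + 2) * bin_width
    L_edges = np.arange(np.floor(L.min() / bin_width),
                        np.ceil(L.max() / bin_width) + 2) * bin_width
    num, _, _ = np.histogram2d(L, E, bins=(L_edges, E_edges), weights=s)
    den, _, _ = np.histogram2d(L, E, bins=(L_edges, E_edges))
    sig = kernel_sd / bin_width
    num_s = gaussian_filter(num, sig)
    den_s = gaussian_filter(den, sig)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(den_s > 1e-10, num_s / den_s, np.nan)
    return {"E_edges": E_edges, "L_edges": L_edges, "map": m,
            "density": den, "bin_width": bin_width, "kernel_sd": kernel_sd}


def simulate_neuron(model_id: str, fit: NeuralFit, trials: TrialTable,
                    behavior_params: ExtremaParams | None = None,
                    seed: int = 0,
                    gains: np.ndarray | None = None) -> np.ndarray:
    """Simulate spike counts under one of the three coding hypotheses.

    * ``integration``: the Poisson-GLM generative process,
      rate = exp(w0 + sum_i w_i S_ti).
    * ``extrema``: the rate follows the sample that crosses the
      behavioral threshold (simulated with ``behavior_params``), scaled
      by half the summed weights and signed by the preferred direction;
      trials with no crossing fall back to the baseline rate exp(w0).
    * ``snapshot``: one attended sample per trial, drawn from a pmf
      proportional to the direction-signed GLM weights with negative
      entries ignored (renormalized); the rate follows that sample scaled
      by the summed weights.  If no weight is positive the pmf is uniform
      (flagged via a warning).
    """
    rng = np.random.default_rng(seed)
    S = trials.evidence
    n = trials.n_trials
    wsum = fit.w.sum()
    if model_id == "integration":
        rate = np.exp(fit.w0 + S @ fit.w[: trials.n_max])
        return rng.poisson(rate)
    if model_id == "extrema":
        if behavior_params is None:
            raise ValueError("extrema simulator needs behavioral parameters")
        _, crossing = simulate_extrema_process(behavior_params, trials,
                                               seed=seed + 1, gains=gains)
        drive = np.zeros(n)
        hit = crossing >= 0
        drive[hit] = fit.preferred * S[np.arange(n)[hit], crossing[hit]] \
            * wsum / 2.0
        rate = np.exp(fit.w0 + drive)
        return rng.poisson(rate)
    if model_id == "snapshot":
        w = fit.preferred * fit.w
        w = np.where(w > 0, w, 0.0)
        if w.sum() <= 0:
            import warnings
            warnings.warn("no positive attention weights; using uniform pmf")
            w = np.ones_like(w)
        pmf = w / w.sum()
        attended = rng.choice(trials.n_max, size=n, p=pmf)
        drive = fit.preferred * S[np.arange(n), attended] * wsum
        rate = np.exp(fit.w0 + drive)
        return rng.poisson(rate)
    raise ValueError(f"unknown model_id {model_id!r}")
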