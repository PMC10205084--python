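"""Integration maps: choice probability over early vs late evidence.

Each trial's weighted evidence is split into an early part E_t (first
floor(n_t/2) samples) and a late part L_t (the rest), using the weights
and session gains of a reference integration fit, so E_t + L_t equals the
total weighted evidence T_t exactly.  The *integration map* is the
kernel-smoothed proportion of rightward choices over the (E, L) plane.

If choices depend only on the sum E + L (temporal integration), map
isolines are straight diagonal lines; if single stimulus parts drive the
choice (snapshot-like strategies), isolines bend toward the axes.  Two
quantitative companions of the map:

* conditional psychometric fits — for each late-evidence bin, an MLE of
  p = pi_R + (1 - pi_L - pi_R) sigma(alpha E + beta); under integration
  the bias beta moves linearly with L and lapses stay null, under
  non-integration the lapses grow with |L|;
* Pearson correlation between data and model-simulation maps, with a
  trial-resampling bootstrap for comparing candidate models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from skimage import measure

from .core_data import FittedModel, TrialTable
from .integration import params_from_fit

__all__ = ["EvidenceSplit", "IntegrationMapGrid", "ConditionalFit",
           "split_evidence", "compute_map", "isolines",
           "isoline_straightness", "conditional_psychometrics",
           "map_pearson", "bootstrap_map_correlation"]

ISOLINE_LEVELS = (0.15, 0.3, 0.5, 0.7, 0.85)


@dataclass
class EvidenceSplit:
    E: np.ndarray
    L: np.ndarray
    source_fit: FittedModel | None = None

    @property
    def T(self) -> np.ndarray:
        return self.E + self.L

    def subset(self, idx) -> "EvidenceSplit":
        return EvidenceSplit(self.E[idx], self.L[idx], self.source_fit)


@dataclass
class IntegrationMapGrid:
    E_nodes: np.ndarray
    L_nodes: np.ndarray
    p: np.ndarray          # (nL, nE) smoothed P(rightward); NaN where masked
    density: np.ndarray    # (nL, nE) selected-trial count per node
    mask: np.ndarray       # True where density >= density_min
    spacing: float


@dataclass
class ConditionalFit:
    L_center: float
    alpha: float           # sensitivity to early evidence
    beta: float            # lateral bias
    pi_L: float
    pi_R: float
    n_trials: int
    converged: bool = True


def split_evidence(trials: TrialTable, fit: FittedModel) -> EvidenceSplit:
    """Early/late weighted evidence from an integration fit.

    Early = first floor(n_t/2) samples of each trial (3 of 7 for the
    monkey design), late = the remainder; the split is applied per trial
    for ragged data.  E + L equals the weighted total exactly.
    """
    params = params_from_fit(fit)
    beta = params.beta[: trials.n_max]
    g = np.ones(trials.n_trials) if params.gamma is None else \
        params.gamma[trials.session_index]
    weighted = trials.evidence * beta[None, :]
    n_half = trials.n_samples // 2
    early_mask = (np.arange(trials.n_max)[None, :] < n_half[:, None]) & trials.mask
    E = g * np.where(early_mask, weighted, 0.0).sum(axis=1)
    L = g * np.where(trials.mask & ~early_mask, weighted, 0.0).sum(axis=1)
    return EvidenceSplit(E=E, L=L, source_fit=fit)


def _grid_axis(x: np.ndarray, spacing: float) -> np.ndarray:
    lo, hi = np.quantile(x, [0.01, 0.99])  # central 98% of the data
    return np.arange(np.floor(lo / spacing), np.ceil(hi / spacing) + 1) * spacing


def compute_map(split: EvidenceSplit, choices: np.ndarray,
                grid_spacing: float = 0.1, selection_radius: float = 2.0,
                kernel_sd: float = 0.1, density_min: int = 10,
                E_nodes: np.ndarray | None = None,
                L_nodes: np.ndarray | None = None) -> IntegrationMapGrid:
    """Kernel-smoothed P(rightward) on a regular (E, L) grid.

    At each node, trials within ``selection_radius`` get Gaussian weights
    of SD ``kernel_sd`` in their (E, L) distance to the node; the node
    value is the weighted proportion of rightward choices.  Nodes with
    fewer than ``density_min`` *effectively weighted* trials — trials
    within min(selection_radius, 2.5 kernel_sd) — are masked (NaN).  (With
    the default radius of 2 and kernel SD of 0.1 the radius cut itself is
    inert: weights underflow far inside it; the density mask therefore
    counts the trials that actually support the estimate.)
    """
    choices = np.asarray(choices)
    if E_nodes is None:
        E_nodes = _grid_axis(split.E, grid_spacing)
    if L_nodes is None:
        L_nodes = _grid_axis(split.L, grid_spacing)
    nE, nL = E_nodes.size, L_nodes.size
    y = choices.astype(float)
    inv2s2 = 1.0 / (2.0 * kernel_sd ** 2)
    r2 = selection_radius ** 2

    # density: trials that meaningfully support each node's estimate
    from scipy.spatial import cKDTree
    tree = cKDTree(np.column_stack([split.E, split.L]))
    EE, LL = np.meshgrid(E_nodes, L_nodes)
    nodes = np.column_stack([EE.ravel(), LL.ravel()])
    density_radius = min(selection_radius, 2.5 * kernel_sd)
    density = tree.query_ball_point(
        nodes, r=density_radius, return_length=True).reshape(nL, nE)

    if np.exp(-r2 * inv2s2) < 1e-30:
        # the radius cut is numerically void (weights underflow long before
        # it); the Gaussian weight then factorizes over the two axes, and
        # the node sums become chunked matrix products
        num = np.zeros((nL, nE))
        den = np.zeros((nL, nE))
        for lo in range(0, split.E.size, 100_000):
            sl = slice(lo, lo + 100_000)
            WE = np.exp(-(split.E[sl, None] - E_nodes[None, :]) ** 2 * inv2s2)
            WL = np.exp(-(split.L[sl, None] - L_nodes[None, :]) ** 2 * inv2s2)
            num += WL.T @ (WE * y[sl, None])
            den += WL.T @ WE
        with np.errstate(invalid="ignore", divide="ignore"):
            p = num / den
    else:
        p = np.full((nL, nE), np.nan)
        dE2 = (split.E[:, None] - E_nodes[None, :]) ** 2
        for j, Lnode in enumerate(L_nodes):
            d2 = dE2 + ((split.L - Lnode) ** 2)[:, None]
            w = np.where(d2 < r2, np.exp(-d2 * inv2s2), 0.0)
            denom = w.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                p[j] = (w * y[:, None]).sum(axis=0) / denom
    mask = density >= density_min
    p[~mask] = np.nan
    if not mask.any():
        raise ValueError("no grid node meets the density threshold; "
                         "use a coarser grid or lower density_min")
    return IntegrationMapGrid(E_nodes=E_nodes, L_nodes=L_nodes, p=p,
                              density=density, mask=mask,
                              spacing=grid_spacing)


def isolines(grid: IntegrationMapGrid,
             levels=ISOLINE_LEVELS) -> dict[float, list[np.ndarray]]:
    """Contour polylines of the map in (E, L) coordinates per level."""
    out = {}
    for level in levels:
        segs = measure.find_contours(grid.p, level, mask=grid.mask)
        coords = []
        for seg in segs:
            L = np.interp(seg[:, 0], np.arange(grid.L_nodes.size), grid.L_nodes)
            E = np.interp(seg[:, 1], np.arange(grid.E_nodes.size), grid.E_nodes)
            coords.append(np.column_stack([E, L]))
        out[level] = coords
    return out


def isoline_straightness(grid: IntegrationMapGrid,
                         levels=ISOLINE_LEVELS) -> float:
    """Max perpendicular residual of isoline points from their LS line.

    Expressed in units of grid spacing; small values mean straight
    (integration-like) isolines.  Short segments (< 5 points) are skipped.
    """
    worst = 0.0
    for level, segs in isolines(grid, levels).items():
        for seg in segs:
            if seg.shape[0] < 5:
                continue
            c = seg - seg.mean(axis=0)
            # principal axis via SVD; residual = distance along minor axis
            _, _, vt = np.linalg.svd(c, full_matrices=False)
            resid = np.abs(c @ vt[1])
            worst = max(worst, float(resid.max()))
    return worst / grid.spacing


def _fit_conditional(E: np.ndarray, y: np.ndarray):
    """MLE of p = pi_R + (1 - pi_L - pi_R) sigma(alpha E + beta)."""
    def nll(x):
        a, b, pl, pr = x
        p = pr + (1.0 - pl - pr) * expit(a * E + b)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -np.sum(np.where(y == 1, np.log(p), np.log1p(-p)))

    best = None
    for a0 in (0.5, 2.0):
        res = minimize(nll, x0=np.array([a0, 0.0, 0.01, 0.01]),
                       method="L-BFGS-B",
                       bounds=[(-100, 100), (-100, 100), (0, 0.5), (0, 0.5)])
        if best is None or res.fun < best.fun:
            best = res
    return best


def conditional_psychometrics(split: EvidenceSplit, choices: np.ndarray,
                              bin_width: float = 0.5,
                              min_trials_per_bin: int = 100
                              ) -> list[ConditionalFit]:
    """Per-late-evidence-bin psychometric fits (bias + lapses + sensitivity).

    Late evidence is binned at ``bin_width``; bins holding fewer than
    ``min_trials_per_bin`` trials are dropped.
    """
    choices = np.asarray(choices)
    lo_edge = np.floor(split.L.min() / bin_width)
    hi_edge = max(np.ceil(split.L.max() / bin_width), lo_edge + 1)
    edges = np.arange(lo_edge, hi_edge + 1) * bin_width
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (split.L >= lo) & (split.L < hi)
        if sel.sum() < min_trials_per_bin:
            continue
        res = _fit_conditional(split.E[sel], choices[sel])
        a, b, pl, pr = res.x
        out.append(ConditionalFit(
            L_center=float((lo + hi) / 2), alpha=float(a), beta=float(b),
            pi_L=float(pl), pi_R=float(pr), n_trials=int(sel.sum()),
            converged=bool(res.success)))
    return out


def map_pearson(map_a: IntegrationMapGrid,
                map_b: IntegrationMapGrid) -> float:
    """Pearson correlation over jointly unmasked nodes of two maps."""
    if map_a.p.shape != map_b.p.shape:
        raise ValueError("maps must share the same grid")
    both = map_a.mask & map_b.mask
    if not both.any():
        raise ValueError("maps have disjoint unmasked support")
    a, b = map_a.p[both], map_b.p[both]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def bootstrap_map_correlation(split: EvidenceSplit,
                              choices_data: np.ndarray,
                              choices_model: np.ndarray,
                              n_boot: int = 100, seed: int = 0,
                              **map_kwargs) -> tuple[float, np.ndarray]:
    """Data-vs-model map correlation with a trial-resampling bootstrap.

    Both maps are computed on a shared grid from the same trials' (E, L)
    coordinates — the data map with observed choices, the model map with
    simulated ones.  Each bootstrap resamples trials with replacement and
    recomputes both maps.  Returns (point r, bootstrap r values); compare
    the bootstrap sets of two candidate models with an unpaired t-test.
    """
    g = map_kwargs.pop("grid_spacing", 0.1)
    E_nodes = _grid_axis(split.E, g)
    L_nodes = _grid_axis(split.L, g)

    def corr(idx):
        s = split.subset(idx)
        m_data = compute_map(s, np.asarray(choices_data)[idx],
                             grid_spacing=g, E_nodes=E_nodes,
                             L_nodes=L_nodes, **map_kwargs)
        m_model = compute_map(s, np.asarray(choices_model)[idx],
                              grid_spacing=g, E_nodes=E_nodes,
                              L_nodes=L_nodes, **map_kwargs)
        return map_pearson(m_data, m_model)

    n = split.E.size
    r0 = corr(np.arange(n))
    rng = np.random.default_rng(seed)
    boot = np.array([corr(rng.integers(0, n, size=n))
                     for _ in range(n_boot)])
    return r0, boot
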