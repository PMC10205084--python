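"""Synthetic discrete-sample-stimulus generators and model simulation.

Three stimulus designs are emulated so that every analysis in the package
can be exercised end-to-end without experimental data:

* **Monkey-style** motion pulses: seven samples per trial, each pulse
  strength drawn from a Gaussian (condition-specific mean and variance)
  rounded to the nearest integer; sessions in blocks with true
  multiplicative gains (log-uniform) for testing gain recovery.
* **Human-style** grating orientations: 5-10 samples per trial, grating
  angle alpha drawn around the category's reference angle alpha0 (45 or
  135 deg) from a von Mises distribution with concentration kappa, and
  evidence S = 2 kappa cos(2 (alpha - alpha0)); S is then the exact
  log-likelihood ratio between the two orientation categories and is
  bounded in [-2 kappa, 2 kappa].
* **Rat-style** amplitude-modulated sounds: 10 or 20 frames per trial,
  instantaneous evidence S drawn from a Beta distribution transformed to
  [-1, 1] (moment-matched to a condition grid of 7 means x 5 SDs); the
  left/right envelope amplitudes a_L = (1 + S) / 2, a_R = (1 - S) / 2 sum
  to 1 in every frame by construction.

:func:`simulate_choices` draws Bernoulli choices from any fitted or
explicitly parameterized model, so model-recovery and diagnostic suites
can run on fully-known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import FittedModel, TrialTable
from . import integration, snapshot, extrema

__all__ = [
    "MonkeyDesign", "HumanDesign", "RatDesign", "design_from_file",
    "gen_monkey_stimuli", "gen_human_stimuli", "gen_rat_stimuli",
    "rat_conditions", "rat_envelopes", "simulate_choices", "predict_prob",
]


# ---------------------------------------------------------------------------
# Designs
# ---------------------------------------------------------------------------

@dataclass
class MonkeyDesign:
    """Pulsed-motion design: integer pulse strengths from rounded Gaussians.

    ``conditions`` are (mean, variance) pairs of the generating Gaussian;
    each trial draws its condition uniformly.  The exact condition set of
    the original experiments is not published, so the default is a
    symmetric spread of means at a common variance — configurable, not
    canonical.
    """

    n_samples: int = 7
    conditions: list = field(default_factory=lambda: [
        (-1.5, 1.0), (-0.5, 1.0), (0.0, 1.0), (0.5, 1.0), (1.5, 1.0)])
    n_sessions: int = 1
    trials_per_session: int = 1000
    session_gain_range: tuple = (0.5, 2.0)

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if any(v < 0 for _, v in self.conditions):
            raise ValueError("pulse variances must be >= 0")


@dataclass
class HumanDesign:
    """Orientation-sequence design with variable sequence length."""

    seq_length_range: tuple = (5, 10)
    kappa: float = 0.3
    alpha0: tuple = (45.0, 135.0)   # degrees: clockwise / counterclockwise
    trials: int = 480

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("concentration kappa must be > 0")
        lo, hi = self.seq_length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid sequence-length range")


@dataclass
class RatDesign:
    """AM-sound design: framewise evidence from transformed Betas.

    The condition grid is 7 means x 5 SDs of the evidence distribution on
    [-1, 1].  ``f_am`` and ``phase`` describe the 20 Hz amplitude
    modulation and are metadata only (the analysis consumes evidence, not
    waveforms).  ``constrained=True`` emulates the early-session regime in
    which sample sequences were kept close to their nominal evidence
    (rejection sampling on the empirical mean).
    """

    n_samples: int = 10
    means: tuple = (-1.0, -0.5, -0.15, 0.0, 0.15, 0.5, 1.0)
    sds: tuple = (0.0, 0.11, 0.25, 0.57, 0.8)
    f_am: float = 20.0
    phase: float = 3 * np.pi / 2
    constrained: bool = False
    trials_per_condition: int = 100

    def __post_init__(self) -> None:
        if self.n_samples not in (10, 20):
            raise ValueError("rat stimuli use 10 or 20 samples")
        if any(abs(m) > 1 for m in self.means):
            raise ValueError("means must lie in [-1, 1]")


_DESIGNS = {"monkey": MonkeyDesign, "human": HumanDesign, "rat": RatDesign}


def design_from_file(path) -> MonkeyDesign | HumanDesign | RatDesign:
    """Load a stimulus design from a YAML or JSON config.

    The file must carry a ``species`` key (monkey | human | rat); the
    remaining keys mirror the design dataclass fields, e.g.::

        species: rat
        n_samples: 10
        trials_per_condition: 50
    """
    import json
    from pathlib import Path

    import yaml

    text = Path(path).read_text()
    cfg = json.loads(text) if str(path).endswith(".json") else \
        yaml.safe_load(text)
    species = cfg.pop("species", None)
    if species not in _DESIGNS:
        raise ValueError("design config needs species: monkey | human | rat")
    cls = _DESIGNS[species]
    for key in ("conditions", "means", "sds", "alpha0", "seq_length_range",
                "session_gain_range"):
        if key in cfg and isinstance(cfg[key], list):
            cfg[key] = [tuple(v) if isinstance(v, list) else v
                        for v in cfg[key]] if key == "conditions" else \
                tuple(cfg[key])
    return cls(**cfg)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def gen_monkey_stimuli(design: MonkeyDesign, seed: int = 0) -> TrialTable:
    """Integer pulse sequences; category = sign of the condition mean.

    For zero-mean conditions the rewarded category follows the empirical
    stimulus (sign of the summed pulses; random on an exact-zero sum).
    True session gains (log-uniform on ``session_gain_range``) are stored
    in ``meta['session_gains']`` for ground-truth checks.
    """
    rng = np.random.default_rng(seed)
    n_total = design.n_sessions * design.trials_per_session
    cond = rng.integers(0, len(design.conditions), size=n_total)
    mu = np.array([design.conditions[c][0] for c in cond])
    var = np.array([design.conditions[c][1] for c in cond])
    S = np.rint(rng.normal(mu[:, None], np.sqrt(var)[:, None],
                           size=(n_total, design.n_samples)))
    session = np.repeat(np.arange(design.n_sessions),
                        design.trials_per_session)
    category = np.where(mu > 0, 1, np.where(mu < 0, 0, -1))
    zero = category == -1
    if zero.any():
        tot = S[zero].sum(axis=1)
        emp = np.where(tot > 0, 1, np.where(tot < 0, 0, -1))
        ties = emp == -1
        emp[ties] = rng.integers(0, 2, size=ties.sum())
        category[zero] = emp
    lo, hi = design.session_gain_range
    gains = np.exp(rng.uniform(np.log(lo), np.log(hi),
                               size=design.n_sessions))
    choice = np.zeros(n_total, dtype=int)  # placeholder until simulated
    return TrialTable(evidence=S, choice=choice, session=session,
                      category=category,
                      meta={"design": "monkey", "session_gains": gains,
                            "condition": cond})


def gen_human_stimuli(design: HumanDesign, seed: int = 0) -> TrialTable:
    """Variable-length orientation sequences with von Mises sample angles.

    The doubled angle offset 2 (alpha - alpha0) is drawn from a von Mises
    with concentration kappa around the category's reference, which makes
    the printed evidence S = 2 kappa cos(2 (alpha - alpha0_cw)) the exact
    per-sample log-likelihood ratio for clockwise vs counterclockwise.
    Evidence is always signed relative to the clockwise reference (45
    deg), so category 1 (clockwise) yields positive-mean evidence.
    """
    rng = np.random.default_rng(seed)
    lo, hi = design.seq_length_range
    lengths = rng.integers(lo, hi + 1, size=design.trials)
    category = rng.integers(0, 2, size=design.trials)
    kappa = design.kappa
    evidence = []
    angles = []
    for t in range(design.trials):
        a0 = design.alpha0[0] if category[t] == 1 else design.alpha0[1]
        dbl = rng.vonmises(0.0, kappa, size=lengths[t])  # 2(alpha - alpha0)
        alpha = a0 + np.degrees(dbl) / 2.0
        # evidence relative to the clockwise reference
        s = 2.0 * kappa * np.cos(2.0 * np.radians(alpha - design.alpha0[0]))
        evidence.append(s)
        angles.append(alpha)
    table = TrialTable.from_ragged(
        evidence, np.zeros(design.trials, dtype=int),
        session=np.zeros(design.trials, dtype=int), category=category,
        meta={"design": "human", "kappa": kappa})
    table.meta["angles"] = angles
    return table


def _beta_moments(mean: float, sd: float) -> tuple[float, float]:
    """Shape (a, b) of Beta(a, b) such that X = 2B - 1 has given mean/SD."""
    mu = (1.0 + mean) / 2.0
    var = sd ** 2 / 4.0
    nu = mu * (1.0 - mu) / var - 1.0
    if nu <= 0:
        raise ValueError(
            f"condition (mean={mean}, sd={sd}) infeasible for support [-1, 1]")
    return mu * nu, (1.0 - mu) * nu


def rat_conditions(design: RatDesign) -> list[tuple[float, float]]:
    """Enumerate the full condition grid as (mean, SD) pairs."""
    return [(m, s) for m in design.means for s in design.sds]


def rat_envelopes(evidence: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Complementary AM envelopes a_L = (1+S)/2, a_R = (1-S)/2.

    Their sum is exactly 1 in every frame, which is the design's loudness-
    conservation constraint.
    """
    aL = (1.0 + evidence) / 2.0
    return aL, 1.0 - aL


def gen_rat_stimuli(design: RatDesign, seed: int = 0) -> TrialTable:
    """Framewise Beta-distributed evidence on the 7 x 5 condition grid.

    Conditions with |mean| = 1 sit on the support boundary, where the only
    distribution on [-1, 1] with that mean is the point mass; they are
    generated as such whatever their nominal SD label.  Any other
    user-supplied condition whose SD is infeasible for its mean raises a
    parameter error naming the condition.  Category = sign of the
    condition mean (empirical sign for mean-zero conditions).
    """
    rng = np.random.default_rng(seed)
    conds = rat_conditions(design)
    # validate feasibility up front (boundary means -> point mass)
    shapes = {}
    for (m, s) in conds:
        if s == 0.0 or abs(m) == 1.0:
            shapes[(m, s)] = None
        else:
            shapes[(m, s)] = _beta_moments(m, s)
    n = design.n_samples
    idx = rng.integers(0, len(conds),
                       size=design.trials_per_condition * len(conds))
    S = np.empty((idx.size, n))
    uniq_means = sorted(set(design.means))
    tol = 0.5 * min(np.diff(uniq_means)) if len(uniq_means) > 1 else 0.25
    for t, c in enumerate(idx):
        m, s = conds[c]
        if shapes[(m, s)] is None:
            S[t] = m
            continue
        a, b = shapes[(m, s)]
        for _ in range(1000):
            draw = 2.0 * rng.beta(a, b, size=n) - 1.0
            if not design.constrained or abs(draw.mean() - m) < tol:
                break
        S[t] = draw
    means = np.array([conds[c][0] for c in idx])
    category = np.where(means > 0, 1, np.where(means < 0, 0, -1))
    zero = category == -1
    if zero.any():
        tot = S[zero].sum(axis=1)
        emp = np.where(tot > 0, 1, np.where(tot < 0, 0, -1))
        ties = emp == -1
        emp[ties] = rng.integers(0, 2, size=ties.sum())
        category[zero] = emp
    return TrialTable(evidence=S, choice=np.zeros(idx.size, dtype=int),
                      session=np.zeros(idx.size, dtype=int),
                      category=category,
                      meta={"design": "rat", "condition": idx,
                            "conditions": conds, "f_am": design.f_am,
                            "phase": design.phase})


# ---------------------------------------------------------------------------
# Choice simulation
# ---------------------------------------------------------------------------

def predict_prob(model, trials: TrialTable,
                 gains: np.ndarray | None = None) -> np.ndarray:
    """Per-trial P(rightward) for a FittedModel or explicit parameter set."""
    if isinstance(model, FittedModel):
        if model.model_id == "integration":
            return integration.predict_integration(
                integration.params_from_fit(model), trials)
        if model.model_id == "snapshot":
            return snapshot.snapshot_choice_prob(
                snapshot.params_from_fit(model), trials, gains=gains)
        if model.model_id == "extrema":
            return extrema.extrema_choice_prob(
                extrema.params_from_fit(model), trials, gains=gains)
        raise ValueError(f"unknown model_id {model.model_id!r}")
    if isinstance(model, integration.IntegrationParams):
        return integration.predict_integration(model, trials)
    if isinstance(model, snapshot.SnapshotParams):
        return snapshot.snapshot_choice_prob(model, trials, gains=gains)
    if isinstance(model, extrema.ExtremaParams):
        return extrema.extrema_choice_prob(model, trials, gains=gains)
    raise TypeError(f"cannot predict from {type(model).__name__}")


def simulate_choices(model, trials: TrialTable, seed: int = 0,
                     gains: np.ndarray | None = None) -> np.ndarray:
    """Draw Bernoulli choices from the model's per-trial P(rightward)."""
    p = predict_prob(model, trials, gains=gains)
    rng = np.random.default_rng(seed)
    return (rng.random(trials.n_trials) < p).astype(int)
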