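"""Core data containers for discrete-sample-stimulus (DSS) choice experiments.

A DSS trial presents a sequence of brief stimulus samples, each carrying a
signed evidence value toward one of two categories; the subject reports a
binary choice at the end of the sequence.  :class:`TrialTable` is the
universal input to every model and analysis in this package;
:class:`FittedModel` is the universal fit result.

Choice coding convention (used consistently everywhere): ``choice == 1``
means rightward / category A, ``choice == 0`` means leftward / category B.
Positive sample evidence favors the rightward category.

Ragged trials (variable sample count) are stored as a padded evidence
matrix plus an explicit boolean validity mask; masked positions never
enter any likelihood or statistic.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TrialTable",
    "FittedModel",
    "SessionGains",
    "read_trials",
    "write_trials",
    "read_fit",
    "write_fit",
]


class ValidationError(ValueError):
    """Raised when an input table violates the data contract."""


@dataclass
class TrialTable:
    """Per-trial evidence samples, choices and session labels.

    Parameters
    ----------
    evidence:
        ``(n_trials, n_max)`` float array of signed sample evidence,
        padded with zeros at masked positions.
    choice:
        Binary vector; 1 = rightward/A, 0 = leftward/B.
    session:
        Integer session identifier per trial.
    mask:
        Boolean validity matrix, same shape as ``evidence``; ``True``
        marks a real sample.  Omitted -> all positions valid.
    category:
        Optional binary vector of the correct category (same coding as
        ``choice``).
    meta:
        Free-form metadata (e.g. generating session gains for synthetic
        data); never consulted by model code.
    """

    evidence: np.ndarray
    choice: np.ndarray
    session: np.ndarray | None = None
    mask: np.ndarray | None = None
    category: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.evidence = np.atleast_2d(np.asarray(self.evidence, dtype=float))
        self.choice = np.asarray(self.choice)
        n = self.evidence.shape[0]
        if self.session is None:
            self.session = np.zeros(n, dtype=int)
        self.session = np.asarray(self.session)
        if self.mask is None:
            self.mask = np.ones(self.evidence.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.category is not None:
            self.category = np.asarray(self.category)
        self._validate()

    def _validate(self) -> None:
        n, m = self.evidence.shape
        if self.choice.shape != (n,):
            raise ValidationError(
                f"choice has shape {self.choice.shape}, expected ({n},)")
        if self.mask.shape != (n, m):
            raise ValidationError("mask shape does not match evidence")
        if self.session.shape != (n,):
            raise ValidationError("session shape does not match trials")
        bad = ~np.isin(self.choice, (0, 1))
        if bad.any():
            raise ValidationError(
                f"choice values outside {{0,1}} at trials {np.flatnonzero(bad)[:5]}")
        if not np.isfinite(self.evidence[self.mask]).all():
            rows = np.flatnonzero(~np.isfinite(
                np.where(self.mask, self.evidence, 0.0)).all(axis=1))
            raise ValidationError(
                f"non-finite evidence at unmasked positions, trials {rows[:5]}")
        if (self.mask.sum(axis=1) < 1).any():
            raise ValidationError("every trial needs at least one sample")
        if self.category is not None:
            if self.category.shape != (n,):
                raise ValidationError("category shape does not match trials")
            if not np.isin(self.category, (0, 1)).all():
                raise ValidationError("category values outside {0,1}")
        # zero out padding so masked positions can never leak into sums
        self.evidence = np.where(self.mask, self.evidence, 0.0)

    # -- basic geometry -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.evidence.shape[0]

    @property
    def n_max(self) -> int:
        """Maximum sample count over trials (padded width)."""
        return self.evidence.shape[1]

    @property
    def n_samples(self) -> np.ndarray:
        """Per-trial number of valid samples n_t."""
        return self.mask.sum(axis=1)

    @property
    def is_ragged(self) -> bool:
        return bool((self.n_samples != self.n_max).any())

    # -- sessions -------------------------------------------------------
    @property
    def session_ids(self) -> np.ndarray:
        return np.unique(self.session)

    @property
    def n_sessions(self) -> int:
        return self.session_ids.size

    @property
    def session_index(self) -> np.ndarray:
        """Contiguous 0-based session index per trial."""
        return np.searchsorted(self.session_ids, self.session)

    # -- helpers --------------------------------------------------------
    def scaled_evidence(self, gains: np.ndarray | None) -> np.ndarray:
        """Session-gain-modulated evidence, gamma_t * S_ti (masked = 0)."""
        if gains is None:
            return self.evidence
        gains = np.asarray(gains, dtype=float)
        if gains.shape != (self.n_sessions,):
            raise ValueError(
                f"need one gain per session ({self.n_sessions}), got {gains.shape}")
        return self.evidence * gains[self.session_index][:, None]

    def total_evidence(self) -> np.ndarray:
        """Raw summed evidence per trial."""
        return self.evidence.sum(axis=1)

    def subset(self, idx) -> "TrialTable":
        idx = np.asarray(idx)
        return TrialTable(
            evidence=self.evidence[idx],
            choice=self.choice[idx],
            session=self.session[idx],
            mask=self.mask[idx],
            category=None if self.category is None else self.category[idx],
            meta=dict(self.meta),
        )

    def with_choices(self, choices: np.ndarray) -> "TrialTable":
        """Copy of the table with ``choice`` replaced (e.g. simulated)."""
        out = self.subset(np.arange(self.n_trials))
        out.choice = np.asarray(choices)
        out._validate()
        return out

    @classmethod
    def from_ragged(cls, evidence_lists, choice, session=None, category=None,
                    meta=None) -> "TrialTable":
        """Build a table from per-trial evidence sequences of varying length."""
        lengths = [len(e) for e in evidence_lists]
        n_max = max(lengths)
        ev = np.zeros((len(lengths), n_max))
        mask = np.zeros_like(ev, dtype=bool)
        for t, seq in enumerate(evidence_lists):
            ev[t, : lengths[t]] = seq
            mask[t, : lengths[t]] = True
        return cls(evidence=ev, choice=np.asarray(choice), session=session,
                   mask=mask, category=category, meta=meta or {})

    def __eq__(self, other) -> bool:
        if not isinstance(other, TrialTable):
            return NotImplemented
        same = (
            np.array_equal(self.evidence, other.evidence)
            and np.array_equal(self.choice, other.choice)
            and np.array_equal(self.session, other.session)
            and np.array_equal(self.mask, other.mask)
        )
        if not same:
            return False
        if (self.category is None) != (other.category is None):
            return False
        if self.category is not None and not np.array_equal(
                self.category, other.category):
            return False
        return True


@dataclass
class SessionGains:
    """Per-session multiplicative evidence gains gamma.

    The bilinear model p = sigma(beta0 + gamma_t * beta.S_t) is invariant
    to rescaling beta by c and gamma by 1/c; we remove the degeneracy by
    fixing mean(gamma) = 1 exactly.
    """

    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        if not np.isfinite(self.gamma).all():
            raise ValidationError("session gains must be finite")

    @property
    def normalized(self) -> bool:
        return bool(abs(self.gamma.mean() - 1.0) < 1e-9)

    def normalize(self) -> tuple["SessionGains", float]:
        """Return (normalized gains, scale) with mean(gamma) = 1 exactly."""
        scale = self.gamma.mean()
        return SessionGains(self.gamma / scale), scale


@dataclass
class FittedModel:
    """Result of fitting one choice model to a :class:`TrialTable`.

    ``aic = 2 * n_params - 2 * loglik`` always holds; ``loglik`` is the
    plain data log-likelihood at the optimum (prior terms excluded), so
    AIC comparisons across models are likelihood-based.
    """

    model_id: str                      # integration | snapshot | extrema
    variant: str
    params: dict                       # name -> scalar or array
    loglik: float
    n_params: int
    posterior_cov: np.ndarray | None = None
    cov_param_names: list | None = None
    fit_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.loglik is None or not np.isfinite(self.loglik):
            raise ValidationError("fit must carry a finite log-likelihood")
        self.params = {
            k: (np.asarray(v, dtype=float) if np.ndim(v) else float(v))
            for k, v in self.params.items()
        }
        if self.posterior_cov is not None:
            c = np.asarray(self.posterior_cov, dtype=float)
            if c.ndim != 2 or c.shape[0] != c.shape[1]:
                raise ValidationError("posterior_cov must be square")
            # store symmetrized; asymmetry beyond round-off is an error
            if not np.allclose(c, c.T, atol=1e-8 * (1 + np.abs(c).max())):
                raise ValidationError("posterior_cov must be symmetric")
            self.posterior_cov = (c + c.T) / 2.0

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    def __eq__(self, other) -> bool:
        if not isinstance(other, FittedModel):
            return NotImplemented
        if (self.model_id, self.variant, self.loglik, self.n_params) != (
                other.model_id, other.variant, other.loglik, other.n_params):
            return False
        if set(self.params) != set(other.params):
            return False
        for k in self.params:
            if not np.array_equal(np.asarray(self.params[k]),
                                  np.asarray(other.params[k])):
                return False
        if (self.posterior_cov is None) != (other.posterior_cov is None):
            return False
        if self.posterior_cov is not None and not np.array_equal(
                self.posterior_cov, other.posterior_cov):
            return False
        return True


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_CSV_FIXED = ("trial", "session", "choice", "category")


def read_trials(path, format: str | None = None) -> TrialTable:
    """Read a trial table from CSV (rectangular) or JSON (ragged allowed).

    CSV dialect: header ``trial,session,choice,category,S1..Sn`` (trial and
    category optional).  JSON: object with keys ``evidence`` (list of
    per-trial lists), ``choice``, optional ``session``, ``category``.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        df = pd.read_csv(path)
        scols = [c for c in df.columns if c.upper().startswith("S")
                 and c[1:].isdigit()]
        scols = sorted(scols, key=lambda c: int(c[1:]))
        if not scols:
            raise ValidationError(f"{path}: no evidence columns S1..Sn found")
        ev = df[scols].to_numpy(dtype=float)
        mask = ~df[scols].isna().to_numpy()
        bad = np.flatnonzero(~mask.any(axis=1))
        if bad.size:
            raise ValidationError(f"{path}: row {bad[0]} has no evidence samples")
        # ragged CSV rows: trailing NaN cells are treated as padding
        try:
            choice = df["choice"].to_numpy()
        except KeyError:
            raise ValidationError(f"{path}: missing 'choice' column") from None
        session = df["session"].to_numpy() if "session" in df else None
        category = (df["category"].to_numpy()
                    if "category" in df and df["category"].notna().all() else None)
        return TrialTable(evidence=np.where(mask, ev, 0.0), choice=choice,
                          session=session, mask=mask, category=category)
    if format == "json":
        with open(path) as fh:
            obj = json.load(fh)
        if "evidence" not in obj or "choice" not in obj:
            raise ValidationError(f"{path}: JSON needs 'evidence' and 'choice'")
        return TrialTable.from_ragged(
            obj["evidence"], obj["choice"],
            session=obj.get("session"), category=obj.get("category"))
    raise ValueError(f"unknown format {format!r}")


def write_trials(trials: TrialTable, path) -> None:
    """Write a trial table; CSV for rectangular data, JSON preserves raggedness."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        obj = {
            "evidence": [trials.evidence[t, trials.mask[t]].tolist()
                         for t in range(trials.n_trials)],
            "choice": trials.choice.tolist(),
            "session": trials.session.tolist(),
        }
        if trials.category is not None:
            obj["category"] = trials.category.tolist()
        path.write_text(json.dumps(obj))
        return
    cols = {"trial": np.arange(trials.n_trials),
            "session": trials.session, "choice": trials.choice}
    if trials.category is not None:
        cols["category"] = trials.category
    df = pd.DataFrame(cols)
    ev = np.where(trials.mask, trials.evidence, np.nan)
    for i in range(trials.n_max):
        df[f"S{i + 1}"] = ev[:, i]
    df.to_csv(path, index=False)


def write_fit(fit: FittedModel, path) -> None:
    """Serialize a fit to JSON with full float precision (lossless round-trip)."""
    def enc(v):
        if isinstance(v, np.ndarray):
            return {"__array__": v.tolist(), "shape": list(v.shape)}
        return v

    obj = {
        "model_id": fit.model_id,
        "variant": fit.variant,
        "params": {k: enc(v) for k, v in fit.params.items()},
        "loglik": fit.loglik,
        "n_params": fit.n_params,
        "aic": fit.aic,
        "posterior_cov": enc(fit.posterior_cov)
        if fit.posterior_cov is not None else None,
        "cov_param_names": fit.cov_param_names,
        "fit_meta": _jsonable(fit.fit_meta),
    }
    Path(path).write_text(json.dumps(obj))


def read_fit(path) -> FittedModel:
    with open(path) as fh:
        obj = json.load(fh)

    def dec(v):
        if isinstance(v, dict) and "__array__" in v:
            return np.asarray(v["__array__"], dtype=float).reshape(v["shape"])
        return v

    fit = FittedModel(
        model_id=obj["model_id"], variant=obj["variant"],
        params={k: dec(v) for k, v in obj["params"].items()},
        loglik=obj["loglik"], n_params=obj["n_params"],
        posterior_cov=dec(obj["posterior_cov"])
        if obj.get("posterior_cov") is not None else None,
        cov_param_names=obj.get("cov_param_names"),
        fit_meta=obj.get("fit_meta", {}),
    )
    return fit


def _jsonable(x):
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.bool_,)):
        return bool(x)
    return x
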