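"""The covariate-linked mixture model for competing events.

An individual first realises an event *type* from softmax (multinomial-logit)
mixture proportions pi(x), then an event *time* from that event's survival
family with covariate-linked parameters theta_j(x).  With right censoring the
likelihood contribution of individual i is

    pi_j(x_i) f_j(t_i; theta_j(x_i))            if event j observed at t_i
    sum_j pi_j(x_i) S_j(t_i; theta_j(x_i))      if censored at t_i

and the model log-likelihood is the sum of the log contributions.  The
censored term is accumulated in log space (log-sum-exp) so it stays finite at
large times; it equals the naive formula whenever the naive formula is
finite.

Identifiability: the softmax over k event types is over-parameterised by one
coefficient block, so the block of a designated *reference event* is pinned
at zero.  For k = 2 this is exactly the logistic parameterisation
logit(pi_nonref) = x' beta.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .distributions import SurvivalFamily, get_family

INTERCEPT = "intercept"

DEFAULT_EVENTS = ("recur", "death")
DEFAULT_CENSOR_LABEL = "cens"


class DataError(ValueError):
    """Dataset content violates the model's preconditions."""


# --------------------------------------------------------------------------
# dataset
# --------------------------------------------------------------------------

@dataclass
class CompetingRisksDataset:
    """Patient-level right-censored competing-risks data.

    ``time``: n non-negative event-or-censoring times.
    ``event``: n labels, each a declared event name or the censoring label.
    ``X``: n x p design frame including an ``intercept`` column of ones.
    ``latent``: optional frame of generator-internal columns (true event type
    and time before censoring); never used in estimation.
    """

    time: np.ndarray
    event: np.ndarray
    X: pd.DataFrame
    latent: pd.DataFrame | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=object)
        if not (len(self.time) == len(self.event) == len(self.X)):
            raise DataError("time, event and X must have equal length")
        # +inf is permitted: simulations from improper fitted distributions
        # (negative Gompertz shape) place mass at infinity
        if np.any(self.time < 0) or np.any(np.isnan(self.time)):
            raise DataError("times must be non-negative and not NaN")

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def column_names(self) -> list[str]:
        return list(self.X.columns)

    def validate_labels(self, spec: "ESPDSpec") -> None:
        allowed = set(spec.event_names) | {spec.censor_label}
        bad = [lab for lab in np.unique(self.event) if lab not in allowed]
        if bad:
            rows = np.flatnonzero(np.isin(self.event, bad))[:10]
            raise DataError(
                f"unknown event label(s) {bad} (e.g. rows {rows.tolist()}); "
                f"allowed: {sorted(allowed)}")

    def to_frame(self, include_latent: bool = False) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.time, "event": self.event})
        df = pd.concat([df, self.X.reset_index(drop=True)], axis=1)
        if include_latent and self.latent is not None:
            df = pd.concat([df, self.latent.reset_index(drop=True)], axis=1)
        return df

    def subset(self, idx) -> "CompetingRisksDataset":
        lat = self.latent.iloc[idx].reset_index(drop=True) if self.latent is not None else None
        return CompetingRisksDataset(
            self.time[idx], self.event[idx],
            self.X.iloc[idx].reset_index(drop=True), lat)


# --------------------------------------------------------------------------
# model specification and coefficient packing
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Block:
    """One coefficient block: kind is 'pi' or 'theta'."""
    kind: str
    event: str
    parameter: str | None
    covariates: tuple[str, ...]
    offset: int

    @property
    def size(self) -> int:
        return len(self.covariates)

    @property
    def slice(self) -> slice:
        return slice(self.offset, self.offset + self.size)

    @property
    def name(self) -> str:
        if self.kind == "pi":
            return f"pi.{self.event}"
        return f"theta.{self.event}.{self.parameter}"


@dataclass(frozen=True)
class ESPDSpec:
    """Declaration of the k competing events and their covariate links.

    ``families`` maps each event name to a registered family name or a
    :class:`SurvivalFamily`.  ``pi_covariates`` are the design columns
    entering the mixture proportions; ``theta_covariates`` maps
    event -> parameter -> columns (parameters left out get an intercept-only
    block, i.e. a single shared value — the usual "single shape across
    groups" layout).
    """

    event_names: tuple[str, ...] = DEFAULT_EVENTS
    families: dict = field(default_factory=lambda: {"recur": "weibull",
                                                    "death": "gompertz"})
    reference_event: str = "death"
    pi_covariates: tuple[str, ...] = (INTERCEPT,)
    theta_covariates: dict = field(default_factory=dict)
    censor_label: str = DEFAULT_CENSOR_LABEL

    def __post_init__(self):
        if len(self.event_names) < 2:
            raise ValueError("at least two competing events are required")
        if self.reference_event not in self.event_names:
            raise ValueError("reference_event must be one of event_names")
        if self.censor_label in self.event_names:
            raise ValueError("censor_label collides with an event name")
        for ev in self.event_names:
            if ev not in self.families:
                raise ValueError(f"no family declared for event '{ev}'")

    @property
    def k(self) -> int:
        return len(self.event_names)

    def family(self, event: str) -> SurvivalFamily:
        return get_family(self.families[event])

    def param_covariates(self, event: str, parameter: str) -> tuple[str, ...]:
        return tuple(self.theta_covariates.get(event, {}).get(parameter,
                                                              (INTERCEPT,)))

    def blocks(self) -> list[Block]:
        out, off = [], 0
        for ev in self.event_names:
            if ev == self.reference_event:
                continue
            b = Block("pi", ev, None, tuple(self.pi_covariates), off)
            out.append(b)
            off += b.size
        for ev in self.event_names:
            fam = self.family(ev)
            for par in fam.parameter_names:
                b = Block("theta", ev, par, self.param_covariates(ev, par), off)
                out.append(b)
                off += b.size
        return out

    @property
    def n_coefficients(self) -> int:
        return sum(b.size for b in self.blocks())

    def coefficient_names(self) -> list[str]:
        return [f"{b.name}.{c}" for b in self.blocks() for c in b.covariates]


@dataclass
class CoefficientVector:
    """Flat unconstrained coefficient vector plus its deterministic layout."""

    spec: ESPDSpec
    packed: np.ndarray

    def __post_init__(self):
        self.packed = np.atleast_1d(np.asarray(self.packed, dtype=float))
        if self.packed.shape != (self.spec.n_coefficients,):
            raise ValueError(
                f"packed length {self.packed.shape} does not match the "
                f"{self.spec.n_coefficients} coefficients implied by the spec")

    @classmethod
    def zeros(cls, spec: ESPDSpec) -> "CoefficientVector":
        return cls(spec, np.zeros(spec.n_coefficients))

    @classmethod
    def from_dict(cls, spec: ESPDSpec, values: dict) -> "CoefficientVector":
        """Build from {block name: array}, e.g. {"pi.recur": [-0.4, 0.4, 0.8]}."""
        packed = np.zeros(spec.n_coefficients)
        blocks = {b.name: b for b in spec.blocks()}
        for name, vals in values.items():
            if name not in blocks:
                raise KeyError(f"unknown coefficient block '{name}'; "
                               f"have {sorted(blocks)}")
            b = blocks[name]
            vals = np.atleast_1d(np.asarray(vals, dtype=float))
            if vals.shape != (b.size,):
                raise ValueError(f"block '{name}' expects {b.size} values "
                                 f"({b.covariates}), got {vals.shape}")
            packed[b.slice] = vals
        return cls(spec, packed)

    def unpack(self) -> dict:
        return {b.name: self.packed[b.slice].copy() for b in self.spec.blocks()}

    def block(self, name: str) -> np.ndarray:
        for b in self.spec.blocks():
            if b.name == name:
                return self.packed[b.slice]
        raise KeyError(name)

    def as_series(self) -> pd.Series:
        return pd.Series(self.packed, index=self.spec.coefficient_names())


# --------------------------------------------------------------------------
# likelihood workspace: pre-extracted design matrices for fast evaluation
# --------------------------------------------------------------------------

def _design(X: pd.DataFrame, cols: tuple[str, ...]) -> np.ndarray:
    missing = [c for c in cols if c not in X.columns]
    if missing:
        raise DataError(f"design matrix is missing column(s) {missing}; "
                        f"available: {list(X.columns)}")
    return np.ascontiguousarray(X[list(cols)].to_numpy(dtype=float))


class LikelihoodWorkspace:
    """Caches everything per-dataset so repeated coefficient evaluations
    (optimiser/sampler inner loops) cost only small matrix products."""

    def __init__(self, data: CompetingRisksDataset, spec: ESPDSpec):
        data.validate_labels(spec)
        self.spec = spec
        self.t = data.time
        self.n = data.n
        self.blocks = spec.blocks()
        self.pi_blocks = [b for b in self.blocks if b.kind == "pi"]
        self.theta_blocks = {(b.event, b.parameter): b
                             for b in self.blocks if b.kind == "theta"}
        self.X_pi = _design(data.X, tuple(spec.pi_covariates))
        self.X_theta = {key: _design(data.X, b.covariates)
                        for key, b in self.theta_blocks.items()}
        self.event_rows = {ev: np.flatnonzero(data.event == ev)
                           for ev in spec.event_names}
        self.cens_rows = np.flatnonzero(data.event == spec.censor_label)
        self.n_events = {ev: len(r) for ev, r in self.event_rows.items()}

    # -- pieces ------------------------------------------------------------
    def log_pi(self, packed: np.ndarray) -> np.ndarray:
        """n x k matrix of log mixture proportions (reference pinned at 0)."""
        scores = np.zeros((self.n, self.spec.k))
        for j, ev in enumerate(self.spec.event_names):
            if ev == self.spec.reference_event:
                continue
            b = next(pb for pb in self.pi_blocks if pb.event == ev)
            scores[:, j] = self.X_pi @ packed[b.slice]
        return scores - logsumexp(scores, axis=1, keepdims=True)

    def natural_params(self, packed: np.ndarray, event: str,
                       rows: np.ndarray | slice = slice(None)) -> list[np.ndarray]:
        fam = self.spec.family(event)
        out = []
        for par, link in zip(fam.parameter_names, fam.links):
            b = self.theta_blocks[(event, par)]
            eta = self.X_theta[(event, par)][rows] @ packed[b.slice]
            out.append(link.to_natural(eta))
        return out

    def loglik(self, packed: np.ndarray) -> float:
        """Total log-likelihood; -inf (never NaN) on numerical failure."""
        with np.errstate(all="ignore"):
            lp = self.log_pi(packed)
            total = 0.0
            for j, ev in enumerate(self.spec.event_names):
                rows = self.event_rows[ev]
                if len(rows):
                    params = self.natural_params(packed, ev, rows)
                    total += float(np.sum(lp[rows, j])
                                   + np.sum(self.spec.family(ev).logpdf(
                                       self.t[rows], *params)))
            if len(self.cens_rows):
                terms = np.empty((len(self.cens_rows), self.spec.k))
                for j, ev in enumerate(self.spec.event_names):
                    params = self.natural_params(packed, ev, self.cens_rows)
                    terms[:, j] = (lp[self.cens_rows, j]
                                   + self.spec.family(ev).logsf(
                                       self.t[self.cens_rows], *params))
                total += float(np.sum(logsumexp(terms, axis=1)))
        if not np.isfinite(total):
            return -np.inf
        return total


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------

def mixture_probs(spec: ESPDSpec, coefs: CoefficientVector,
                  X: pd.DataFrame) -> np.ndarray:
    """n x k matrix of event-type probabilities pi(x) (rows sum to 1)."""
    scores = np.zeros((len(X), spec.k))
    for j, ev in enumerate(spec.event_names):
        if ev == spec.reference_event:
            continue
        b = next(bl for bl in spec.blocks()
                 if bl.kind == "pi" and bl.event == ev)
        scores[:, j] = _design(X, b.covariates) @ coefs.packed[b.slice]
    return np.exp(scores - logsumexp(scores, axis=1, keepdims=True))


def loglik(data: CompetingRisksDataset, spec: ESPDSpec,
           coefs: CoefficientVector | np.ndarray) -> float:
    """Censoring-aware joint log-likelihood of the mixture model."""
    packed = coefs.packed if isinstance(coefs, CoefficientVector) else np.asarray(coefs, float)
    return LikelihoodWorkspace(data, spec).loglik(packed)


def conditional_event_probs(spec: ESPDSpec, coefs: CoefficientVector,
                            x_i: pd.DataFrame | pd.Series | dict,
                            t_i: float) -> np.ndarray:
    """P(latent event = j | still event-free at t_i, covariates x_i).

    Computed as pi_j S_j(t_i) / sum_l pi_l S_l(t_i); at t_i = 0 this is the
    unconditional mixture probability vector.
    """
    if t_i < 0:
        raise ValueError("t_i must be non-negative")
    if isinstance(x_i, dict):
        x_i = pd.DataFrame([x_i])
    elif isinstance(x_i, pd.Series):
        x_i = x_i.to_frame().T
    log_terms = np.empty(spec.k)
    lp = np.log(mixture_probs(spec, coefs, x_i)[0])
    for j, ev in enumerate(spec.event_names):
        fam = spec.family(ev)
        params = []
        for par, link in zip(fam.parameter_names, fam.links):
            b = next(bl for bl in spec.blocks()
                     if bl.kind == "theta" and bl.event == ev
                     and bl.parameter == par)
            params.append(link.to_natural(
                float(_design(x_i, b.covariates)[0] @ coefs.packed[b.slice])))
        log_terms[j] = lp[j] + float(fam.logsf(t_i, *params))
    if np.all(log_terms < np.log(np.finfo(float).tiny)):
        raise FloatingPointError(
            "all mixture survival terms underflow to zero at "
            f"t={t_i}; consider rescaling time to smaller units")
    return np.exp(log_terms - logsumexp(log_terms))
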