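"""Two-step generative process and the reference study population.

Event generation follows the "event type first, event time second" recipe:
for each individual the event type is drawn from the covariate-linked softmax
mixture proportions, then the event time from that event's survival family
with covariate-linked parameters.

The reference population emulated throughout the package is an oncology-like
cohort with two competing events, disease recurrence and death before
recurrence:

* disease stage IA / IB / II with equal probability, entered as two dummy
  columns against reference IA;
* age ~ Normal(60, 5) years, used centred at the population mean of 60;
* logit pi(recur)      = -0.4 + 0.4 stageIB + 0.8 stageII
* recurrence           ~ Weibull(shape = exp(0.7),
                                 scale = exp(2 - 0.2 stageIB - 0.6 stageII))
* death pre-recurrence ~ Gompertz(shape = 0.1,
                                  rate  = exp(-3.5 + 0.1 age_centred))

Censoring is an independent exponential process: a censoring time is drawn
per individual and the row is censored whenever it precedes the event time.
The exponential rate is calibrated per sample by bisection (censoring times
are a monotone function of the rate for a fixed set of uniform draws) until
the realised censored proportion is as close to the target as the sample
allows.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import (INTERCEPT, CompetingRisksDataset, CoefficientVector,
                    ESPDSpec)
from . import model as _model

STAGE_LEVELS = ("IA", "IB", "II")


def _as_rng(rng: int | np.random.Generator) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


def study_spec() -> ESPDSpec:
    """Model declaration for the reference stage/age population."""
    return ESPDSpec(
        event_names=("recur", "death"),
        families={"recur": "weibull", "death": "gompertz"},
        reference_event="death",
        pi_covariates=(INTERCEPT, "stageIB", "stageII"),
        theta_covariates={
            "recur": {"scale": (INTERCEPT, "stageIB", "stageII")},
            "death": {"rate": (INTERCEPT, "age_c")},
        })


def true_coefficients(spec: ESPDSpec | None = None) -> CoefficientVector:
    """The generating coefficient values on the unconstrained scale."""
    spec = spec or study_spec()
    return CoefficientVector.from_dict(spec, {
        "pi.recur": [-0.4, 0.4, 0.8],
        "theta.recur.shape": [0.7],
        "theta.recur.scale": [2.0, -0.2, -0.6],
        "theta.death.shape": [0.1],
        "theta.death.rate": [-3.5, 0.1],
    })


@dataclass(frozen=True)
class TruePopulationParams:
    """Generating model for the reference population (overridable)."""

    spec: ESPDSpec = field(default_factory=study_spec)
    coefs: CoefficientVector | None = None
    age_mean: float = 60.0
    age_sd: float = 5.0

    def coefficients(self) -> CoefficientVector:
        return self.coefs if self.coefs is not None else true_coefficients(self.spec)

    def with_coefficients(self, values: dict) -> "TruePopulationParams":
        merged = self.coefficients().unpack()
        merged.update(values)
        return replace(self, coefs=CoefficientVector.from_dict(self.spec, merged))

    def to_dict(self) -> dict:
        return {"events": list(self.spec.event_names),
                "families": {e: self.spec.family(e).name
                             for e in self.spec.event_names},
                "coefficients": {k: v.tolist()
                                 for k, v in self.coefficients().unpack().items()},
                "age_mean": self.age_mean, "age_sd": self.age_sd}


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the simulation-study grid."""

    p_censored: float = 0.0
    n_sample: int = 500
    n_run: int = 500
    n_sim: int = 200_000
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.p_censored < 1.0):
            raise ValueError("p_censored must be in [0, 1)")
        if min(self.n_sample, self.n_run, self.n_sim) < 1:
            raise ValueError("all counts must be positive")


def draw_covariates(n: int, rng: int | np.random.Generator,
                    age_mean: float = 60.0, age_sd: float = 5.0) -> pd.DataFrame:
    """Stage (uniform over IA/IB/II, dummy-coded) and centred age."""
    rng = _as_rng(rng)
    stage = rng.integers(0, 3, size=n)
    age = rng.normal(age_mean, age_sd, size=n)
    return pd.DataFrame({
        INTERCEPT: np.ones(n),
        "stageIB": (stage == 1).astype(float),
        "stageII": (stage == 2).astype(float),
        "age_c": age - age_mean,
        "stage": pd.Categorical.from_codes(stage, categories=list(STAGE_LEVELS)),
        "age": age,
    })


def simulate_espd(params: TruePopulationParams | tuple, X: pd.DataFrame,
                  rng: int | np.random.Generator,
                  allow_improper: bool = False) -> CompetingRisksDataset:
    """Two-step simulation given covariates: type from pi(x), then time.

    ``params`` is a :class:`TruePopulationParams` or a ``(spec, coefs)``
    pair, so the same machinery simulates from fitted estimates.  The output
    carries no censored rows.
    """
    if isinstance(params, TruePopulationParams):
        spec, coefs = params.spec, params.coefficients()
    else:
        spec, coefs = params
    rng = _as_rng(rng)
    n = len(X)
    pi = _model.mixture_probs(spec, coefs, X)
    # vectorised categorical draw
    u = rng.random(n)
    event_idx = (u[:, None] >= np.cumsum(pi, axis=1)).sum(axis=1)
    event_idx = np.minimum(event_idx, spec.k - 1)

    times = np.empty(n)
    labels = np.empty(n, dtype=object)
    ws_cols = X
    u_time = rng.random(n)
    for j, ev in enumerate(spec.event_names):
        rows = np.flatnonzero(event_idx == j)
        labels[rows] = ev
        if len(rows) == 0:
            continue
        fam = spec.family(ev)
        nat = []
        for par, link in zip(fam.parameter_names, fam.links):
            b = next(bl for bl in spec.blocks()
                     if bl.kind == "theta" and bl.event == ev
                     and bl.parameter == par)
            eta = ws_cols.iloc[rows][list(b.covariates)].to_numpy(float) \
                @ coefs.packed[b.slice]
            nat.append(link.to_natural(eta))
        if not allow_improper and not fam.is_proper(*nat):
            raise ValueError(
                f"fitted/true parameters for event '{ev}' give an improper "
                "distribution; pass allow_improper=True to sample (infinite "
                "times are returned as inf)")
        times[rows] = fam.ppf(u_time[rows], *nat)
    return CompetingRisksDataset(times, labels, X.reset_index(drop=True))


def generate_population(params: TruePopulationParams | None = None,
                        n_sim: int = 200_000,
                        rng: int | np.random.Generator = 0) -> CompetingRisksDataset:
    """Reference population: draw covariates, then the two-step simulator."""
    params = params or TruePopulationParams()
    rng = _as_rng(rng)
    X = draw_covariates(n_sim, rng, params.age_mean, params.age_sd)
    return simulate_espd(params, X, rng)


# --------------------------------------------------------------------------
# censoring
# --------------------------------------------------------------------------

def _censored_fraction(neg_log_u: np.ndarray, t: np.ndarray,
                       rate: float) -> float:
    return float(np.mean(neg_log_u / rate < t))


def calibrate_censoring_rate(t: np.ndarray, neg_log_u: np.ndarray,
                             p_censored: float, tol: float = 0.005,
                             rel_width: float = 1e-10) -> float:
    """Bisection on the exponential censoring rate.

    For a fixed set of uniform draws the censoring times -log(u)/rate shrink
    as the rate grows, so the realised censored proportion is non-decreasing
    in the rate; bisection converges to the rate whose realised proportion is
    the nearest achievable to the target (exactly, up to the 1/n label
    granularity of the sample).
    """
    lo, hi = 1e-8, 1.0
    for _ in range(4000):
        if _censored_fraction(neg_log_u, t, hi) >= p_censored:
            break
        hi *= 2.0
    for _ in range(4000):
        if _censored_fraction(neg_log_u, t, lo) <= p_censored:
            break
        lo /= 2.0
    best_rate, best_gap = hi, abs(_censored_fraction(neg_log_u, t, hi) - p_censored)
    for _ in range(10_000):
        mid = 0.5 * (lo + hi)
        frac = _censored_fraction(neg_log_u, t, mid)
        gap = abs(frac - p_censored)
        if gap < best_gap:
            best_rate, best_gap = mid, gap
        if gap <= tol or (hi - lo) < rel_width * max(hi, 1e-300):
            break
        if frac < p_censored:
            lo = mid
        else:
            hi = mid
    return best_rate


def apply_censoring(data: CompetingRisksDataset, p_censored: float,
                    rng: int | np.random.Generator,
                    censor_label: str = _model.DEFAULT_CENSOR_LABEL
                    ) -> CompetingRisksDataset:
    """Independent exponential censoring calibrated to a target proportion.

    The latent (pre-censoring) event type and time are kept in the returned
    dataset's ``latent`` frame so evaluation code can compare against truth;
    they are not part of the fit-facing columns.
    """
    if not (0.0 <= p_censored < 1.0):
        raise ValueError("p_censored must be in [0, 1)")
    if p_censored == 0.0:
        return CompetingRisksDataset(
            data.time.copy(), data.event.copy(), data.X.copy(),
            pd.DataFrame({"latent_event": data.event.copy(),
                          "latent_time": data.time.copy()}))
    rng = _as_rng(rng)
    neg_log_u = -np.log1p(-rng.random(data.n))
    rate = calibrate_censoring_rate(data.time, neg_log_u, p_censored)
    c_times = neg_log_u / rate
    censored = c_times < data.time
    time = np.where(censored, c_times, data.time)
    event = np.where(censored, censor_label, data.event).astype(object)
    latent = pd.DataFrame({"latent_event": data.event.copy(),
                           "latent_time": data.time.copy()})
    return CompetingRisksDataset(time, event, data.X.copy(), latent)
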