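"""Parametric survival families used as event-time distributions.

Each family exposes the density f(t), cumulative distribution F(t), survival
S(t) = 1 - F(t), their logarithms, the quantile function (inverse CDF) and
inverse-CDF random sampling, all vectorised over both the time argument and
the parameter values (per-individual parameters arise when distribution
parameters are linked to covariates).

Parameterisations
-----------------
weibull      (shape k, scale b):  S(t) = exp(-(t/b)^k)          -- AFT form
gompertz     (shape b, rate a):   h(t) = a * exp(b t), so
                                  S(t) = exp(-(a/b)(exp(b t) - 1))
exponential  (rate r):            S(t) = exp(-r t)

All strictly positive parameters use a log link from the unconstrained
coefficient scale; the Gompertz shape uses the identity link (it may be
negative, in which case the distribution is improper: a fraction
exp(rate/shape) of the mass sits at +infinity and sampling requires an
explicit opt-in).

The registry is open: ``register_family`` accepts any object implementing the
``SurvivalFamily`` contract, so further families (log-normal, log-logistic,
gamma, ...) can be added without touching the rest of the package.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np


class ParameterError(ValueError):
    """A distribution parameter violates its family's constraints."""


# --------------------------------------------------------------------------
# links between the unconstrained coefficient scale and the natural scale
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Link:
    name: str
    to_natural: Callable[[np.ndarray], np.ndarray]
    to_unconstrained: Callable[[np.ndarray], np.ndarray]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Link({self.name})"


LOG = Link("log", np.exp, np.log)
IDENTITY = Link("identity", lambda x: x, lambda x: x)


# --------------------------------------------------------------------------
# family definition
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalFamily:
    """A parametric time-to-event family.

    The log-density/log-survival callables take ``(t, *params)`` where every
    argument may be a scalar or an array; broadcasting rules apply.  ``ppf``
    maps a uniform variate u in [0, 1) to a time.  ``validate`` raises
    :class:`ParameterError` naming the offending parameter.  ``is_proper``
    returns False when the parameter set places mass at +infinity.
    """

    name: str
    parameter_names: tuple[str, ...]
    links: tuple[Link, ...]
    _logpdf: Callable[..., np.ndarray]
    _logsf: Callable[..., np.ndarray]
    _ppf: Callable[..., np.ndarray]
    _validate: Callable[..., None]
    _is_proper: Callable[..., bool] = lambda *p: True

    # -- natural-scale evaluations ----------------------------------------
    def validate(self, *params) -> None:
        self._validate(*params)

    def is_proper(self, *params) -> bool:
        return bool(self._is_proper(*params))

    def logpdf(self, t, *params):
        return self._logpdf(np.asarray(t, dtype=float), *params)

    def logsf(self, t, *params):
        return self._logsf(np.asarray(t, dtype=float), *params)

    def pdf(self, t, *params):
        return np.exp(self.logpdf(t, *params))

    def sf(self, t, *params):
        return np.exp(self.logsf(t, *params))

    def cdf(self, t, *params):
        return -np.expm1(self.logsf(t, *params))

    def ppf(self, u, *params):
        return self._ppf(np.asarray(u, dtype=float), *params)

    def rvs(self, *params, size: int, rng: np.random.Generator,
            allow_improper: bool = False) -> np.ndarray:
        if not allow_improper and not self.is_proper(*params):
            raise ParameterError(
                f"{self.name}: parameters give an improper distribution "
                "(positive mass at +infinity); pass allow_improper=True to "
                "sample anyway (infinite draws are returned as inf)")
        u = rng.random(size)
        return self.ppf(u, *params)


def _check_positive(name: str, family: str, value) -> None:
    v = np.asarray(value, dtype=float)
    if not np.all(v > 0):
        raise ParameterError(f"{family}: parameter '{name}' must be > 0")


# -- Weibull (shape, scale), S(t) = exp(-(t/scale)^shape) -------------------

def _weib_logsf(t, shape, scale):
    return -np.power(t / scale, shape)


def _weib_logpdf(t, shape, scale):
    shape = np.asarray(shape, dtype=float)
    scale = np.asarray(scale, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = t / scale
        out = (np.log(shape / scale) + (shape - 1.0) * np.log(z)
               - np.power(z, shape))
    # t == 0: density is rate-like for shape==1, 0 for shape>1, +inf for <1
    if np.any(t == 0):
        at0 = np.where(shape == 1.0, -np.log(scale),
                       np.where(shape > 1.0, -np.inf, np.inf))
        out = np.where(t == 0, at0, out)
    return out


def _weib_ppf(u, shape, scale):
    return scale * np.power(-np.log1p(-u), 1.0 / np.asarray(shape, float))


def _weib_validate(shape, scale):
    _check_positive("shape", "weibull", shape)
    _check_positive("scale", "weibull", scale)


# -- Gompertz (shape, rate), h(t) = rate * exp(shape t) ---------------------
# shape == 0 is the exponential limit; handled analytically via expm1 and a
# series-safe branch so the shape -> 0 limit is continuous to ~1e-16.

def _gomp_cumhaz(t, shape, rate):
    shape = np.asarray(shape, dtype=float)
    rate = np.asarray(rate, dtype=float)
    small = np.abs(shape) < 1e-12
    safe = np.where(small, 1.0, shape)
    with np.errstate(over="ignore"):
        h = rate * np.expm1(safe * t) / safe
    return np.where(small, rate * t, h)


def _gomp_logsf(t, shape, rate):
    return -_gomp_cumhaz(t, shape, rate)


def _gomp_logpdf(t, shape, rate):
    return np.log(rate) + np.asarray(shape, float) * t + _gomp_logsf(t, shape, rate)


def _gomp_ppf(u, shape, rate):
    shape = np.asarray(shape, dtype=float)
    rate = np.asarray(rate, dtype=float)
    small = np.abs(shape) < 1e-12
    safe = np.where(small, 1.0, shape)
    arg = 1.0 - safe * np.log1p(-u) / rate
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(arg > 0, np.log(np.where(arg > 0, arg, 1.0)) / safe, np.inf)
    return np.where(small, -np.log1p(-u) / rate, t)


def _gomp_validate(shape, rate):
    _check_positive("rate", "gompertz", rate)
    if not np.all(np.isfinite(np.asarray(shape, dtype=float))):
        raise ParameterError("gompertz: parameter 'shape' must be finite")


def _gomp_proper(shape, rate):
    return np.all(np.asarray(shape, dtype=float) >= 0)


# -- Exponential (rate) -----------------------------------------------------

def _exp_logsf(t, rate):
    return -np.asarray(rate, float) * t


def _exp_logpdf(t, rate):
    return np.log(rate) - np.asarray(rate, float) * t


def _exp_ppf(u, rate):
    return -np.log1p(-u) / np.asarray(rate, float)


def _exp_validate(rate):
    _check_positive("rate", "exponential", rate)


WEIBULL = SurvivalFamily(
    name="weibull", parameter_names=("shape", "scale"), links=(LOG, LOG),
    _logpdf=_weib_logpdf, _logsf=_weib_logsf, _ppf=_weib_ppf,
    _validate=_weib_validate)

GOMPERTZ = SurvivalFamily(
    name="gompertz", parameter_names=("shape", "rate"), links=(IDENTITY, LOG),
    _logpdf=_gomp_logpdf, _logsf=_gomp_logsf, _ppf=_gomp_ppf,
    _validate=_gomp_validate, _is_proper=_gomp_proper)

EXPONENTIAL = SurvivalFamily(
    name="exponential", parameter_names=("rate",), links=(LOG,),
    _logpdf=_exp_logpdf, _logsf=_exp_logsf, _ppf=_exp_ppf,
    _validate=_exp_validate)


_REGISTRY: dict[str, SurvivalFamily] = {}


def register_family(family: SurvivalFamily, overwrite: bool = False) -> None:
    """Add a family to the registry (user-supplied families welcome)."""
    if family.name in _REGISTRY and not overwrite:
        raise ValueError(f"family '{family.name}' already registered")
    _REGISTRY[family.name] = family


def get_family(family: str | SurvivalFamily) -> SurvivalFamily:
    if isinstance(family, SurvivalFamily):
        return family
    try:
        return _REGISTRY[family]
    except KeyError:
        raise KeyError(
            f"unknown survival family '{family}'; registered: "
            f"{sorted(_REGISTRY)}") from None


for _fam in (WEIBULL, GOMPERTZ, EXPONENTIAL):
    register_family(_fam)


# --------------------------------------------------------------------------
# functional front-end (validating, array-returning)
# --------------------------------------------------------------------------

def _prep(family, t, params):
    fam = get_family(family)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    params = [np.asarray(p, dtype=float) for p in params]
    if len(params) != len(fam.parameter_names):
        raise ParameterError(
            f"{fam.name}: expected parameters {fam.parameter_names}, "
            f"got {len(params)} values")
    fam.validate(*params)
    return fam, t, params


def density(family: str | SurvivalFamily, t, params: Sequence) -> np.ndarray:
    """f(t) on the natural parameter scale; vectorises over t and params."""
    fam, t, params = _prep(family, t, params)
    return fam.pdf(t, *params)


def survival(family: str | SurvivalFamily, t, params: Sequence) -> np.ndarray:
    """S(t) = 1 - F(t); S(0) = 1."""
    fam, t, params = _prep(family, t, params)
    return fam.sf(t, *params)


def cumulative(family: str | SurvivalFamily, t, params: Sequence) -> np.ndarray:
    """F(t) = P(T <= t)."""
    fam, t, params = _prep(family, t, params)
    return fam.cdf(t, *params)


def quantile(family: str | SurvivalFamily, u, params: Sequence) -> np.ndarray:
    """Inverse CDF: the time t with F(t) = u."""
    fam = get_family(family)
    params = [np.asarray(p, dtype=float) for p in params]
    fam.validate(*params)
    return fam.ppf(u, *params)


def sample_times(family: str | SurvivalFamily, params: Sequence, n: int,
                 rng: int | np.random.Generator,
                 allow_improper: bool = False) -> np.ndarray:
    """Draw n i.i.d. event times by inverse-CDF sampling.

    ``rng`` is a seed or a numpy Generator.  Improper parameter sets (Gompertz
    with negative shape) are rejected unless ``allow_improper=True``, in which
    case draws beyond the finite mass come back as ``inf``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    fam = get_family(family)
    params = [np.asarray(p, dtype=float) for p in params]
    fam.validate(*params)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return fam.rvs(*params, size=n, rng=rng, allow_improper=allow_improper)
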