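"""Exponential dose-response model family and closed-form benchmark doses.

The family is the nested set of continuous dose-response models recommended
by EFSA for continuous toxicity endpoints, restricted to increasing
responses (revertant counts rise with dose):

======  ==========================================  ==================
model   mean response at dose ``x``                 free parameters
======  ==========================================  ==================
m1      ``a``                                       a
m2      ``a * exp(b*x)``                            a, b
m3      ``a * exp(b*x**d)``                         a, b, d
m4      ``a * (c - (c-1)*exp(-b*x))``               a, b, c
m5      ``a * (c - (c-1)*exp(-b*x**d))``            a, b, c, d
======  ==========================================  ==================

``a`` is the background response (revertants/plate at dose zero), ``b`` the
potency parameter, ``c`` the plateau expressed as a fold of background
(``c > 1``), and ``d`` a dimensionless log-steepness restricted to
``[1, 4]`` so the dose-response has finite slope at dose zero.

The benchmark dose (critical effect dose, CED) is the dose at which the
mean response reaches ``a * (1 + ces)`` for a critical effect size ``ces``
(default 1.0, i.e. a doubling over background).  For m4/m5 the plateau
``a*c`` may lie below the benchmark response, in which case the CED does
not exist (``status == "not_reached"``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MODEL_IDS",
    "N_PARAMS",
    "D_RANGE",
    "ExponentialParams",
    "BenchmarkSpec",
    "CedResult",
    "mean_response",
    "ced",
    "nesting",
]

MODEL_IDS = ("m1", "m2", "m3", "m4", "m5")

#: number of free mean-function parameters per model
N_PARAMS = {"m1": 1, "m2": 2, "m3": 3, "m4": 3, "m5": 4}

#: which parameters each model uses
_USES = {"m1": "a", "m2": "ab", "m3": "abd", "m4": "abc", "m5": "abcd"}

#: allowed range for the log-steepness parameter d
D_RANGE = (1.0, 4.0)


@dataclass(frozen=True)
class ExponentialParams:
    """Parameters of one member of the exponential model family.

    Unused parameters for a given ``model_id`` must be ``None``.
    """

    model_id: str
    a: float
    b: float | None = None
    c: float | None = None
    d: float | None = None

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        uses = _USES[self.model_id]
        for name in "abcd":
            val = getattr(self, name)
            if name in uses:
                if val is None:
                    raise ValueError(
                        f"{self.model_id} requires parameter {name!r}"
                    )
            elif val is not None:
                raise ValueError(
                    f"{self.model_id} does not use parameter {name!r}"
                )
        if self.a <= 0:
            raise ValueError("background a must be > 0")
        if self.b is not None and self.b <= 0:
            raise ValueError("potency b must be > 0")
        if self.c is not None and self.c <= 1:
            raise ValueError("plateau fold c must be > 1")
        if self.d is not None and not (D_RANGE[0] <= self.d <= D_RANGE[1]):
            raise ValueError(f"log-steepness d must lie in {D_RANGE}")

    @property
    def n_params(self) -> int:
        return N_PARAMS[self.model_id]

    def to_dict(self) -> dict:
        out = {"model_id": self.model_id, "a": self.a}
        for name in "bcd":
            if name in _USES[self.model_id]:
                out[name] = getattr(self, name)
        return out


@dataclass(frozen=True)
class BenchmarkSpec:
    """Benchmark response definition.

    ``ces`` is the critical effect size as a fractional increase over
    background: 1.0 means the benchmark response is a doubling of the
    vehicle-control response.
    """

    ces: float = 1.0

    def __post_init__(self) -> None:
        if self.ces <= 0:
            raise ValueError("ces must be > 0")


@dataclass(frozen=True)
class CedResult:
    """Critical effect dose, or the finding that the plateau never reaches it."""

    status: str  # "reached" | "not_reached"
    ced: float | None = None

    def __post_init__(self) -> None:
        if self.status not in ("reached", "not_reached"):
            raise ValueError(f"invalid status {self.status!r}")
        if self.status == "reached" and (self.ced is None or self.ced <= 0):
            raise ValueError("reached requires ced > 0")

    @property
    def reached(self) -> bool:
        return self.status == "reached"


def log_shape(model_id: str, x, b=None, c=None, d=None):
    """Log of the mean response with background a = 1.

    Works on scaled or natural doses; vectorized over ``x``.  Computing in
    log space keeps the likelihood finite even for extreme potency values.
    """
    x = np.asarray(x, dtype=float)
    if model_id == "m1":
        return np.zeros_like(x)
    if model_id == "m2":
        return b * x
    if model_id == "m3":
        return b * np.power(x, d)
    if model_id == "m4":
        return np.log(c - (c - 1.0) * np.exp(-b * x))
    if model_id == "m5":
        return np.log(c - (c - 1.0) * np.exp(-b * np.power(x, d)))
    raise ValueError(f"unknown model_id {model_id!r}")


def mean_response(params: ExponentialParams, dose):
    """Mean response at ``dose`` (same dose units as ``b`` was fitted in).

    Vectorized; returns a scalar for scalar input.
    """
    dose_arr = np.asarray(dose, dtype=float)
    if np.any(dose_arr < 0):
        raise ValueError("dose must be >= 0")
    out = params.a * np.exp(
        log_shape(params.model_id, dose_arr, params.b, params.c, params.d)
    )
    if np.isscalar(dose) or np.ndim(dose) == 0:
        return float(out)
    return out


def ced_from_shape(model_id: str, ces: float, b=None, c=None, d=None):
    """Closed-form CED for given shape parameters, or None if not reached.

    The plateau models only reach the benchmark response when
    ``c > 1 + ces``.
    """
    target = math.log1p(ces)
    if model_id == "m2":
        return target / b
    if model_id == "m3":
        return (target / b) ** (1.0 / d)
    if model_id in ("m4", "m5"):
        if c <= 1.0 + ces:
            return None
        x = -math.log((c - 1.0 - ces) / (c - 1.0)) / b
        if model_id == "m5":
            x = x ** (1.0 / d)
        return x
    raise ValueError(f"model {model_id!r} has no dose dependence")


def b_from_ced(model_id: str, ced_value: float, ces: float, c=None, d=None) -> float:
    """Potency parameter implied by a given CED (the inverse of the closed form).

    Used to re-parameterize the likelihood so the CED is an explicit
    parameter during profile-likelihood interval construction; requires
    ``c > 1 + ces`` for the plateau models.
    """
    target = math.log1p(ces)
    if ced_value <= 0:
        raise ValueError("ced must be > 0")
    if model_id == "m2":
        return target / ced_value
    if model_id == "m3":
        return target / ced_value**d
    if model_id in ("m4", "m5"):
        if c <= 1.0 + ces:
            raise ValueError("plateau below benchmark response: CED undefined")
        num = -math.log((c - 1.0 - ces) / (c - 1.0))
        if model_id == "m5":
            return num / ced_value**d
        return num / ced_value
    raise ValueError(f"model {model_id!r} has no dose dependence")


def ced(params: ExponentialParams, spec: BenchmarkSpec = BenchmarkSpec()) -> CedResult:
    """Critical effect dose for the given parameters and benchmark spec."""
    if params.model_id == "m1":
        raise ValueError("m1 has no dose dependence; CED undefined")
    value = ced_from_shape(
        params.model_id, spec.ces, b=params.b, c=params.c, d=params.d
    )
    if value is None:
        return CedResult("not_reached")
    return CedResult("reached", float(value))


def nesting(model_id: str) -> frozenset:
    """Simpler models preceding ``model_id`` on the selection ladder.

    The ladder order is m1 -> m2 -> {m3, m4} -> m5.
    """
    ladder = {
        "m1": frozenset(),
        "m2": frozenset({"m1"}),
        "m3": frozenset({"m1", "m2"}),
        "m4": frozenset({"m1", "m2"}),
        "m5": frozenset({"m1", "m2", "m3", "m4"}),
    }
    try:
        return ladder[model_id]
    except KeyError:
        raise ValueError(f"unknown model_id {model_id!r}") from None
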