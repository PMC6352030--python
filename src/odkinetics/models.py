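"""Kinetic model families for osmotic-dehydration mass transfer.

Three empirical families describe how a response ``Y`` (water content,
water loss, solid gain, true water loss, or the true-to-nominal water
loss ratio) evolves with immersion time ``tau`` (minutes):

Peleg
    ``Y(tau) = Y0 +/- tau / (k1 + k2*tau)`` — a two-parameter hyperbola.
    ``1/k1`` is the initial rate of change and ``Y0 +/- 1/k2`` the
    equilibrium (asymptotic) value.  The sign is carried explicitly as a
    ``direction`` (+1 for responses rising from Y0, -1 for falling).

Kelvin-Voigt
    ``Y(tau) = A * (1 - exp(-tau/B))`` — single-exponential saturation
    towards the equilibrium value ``A`` with time constant ``B`` (min).
    At ``tau = B`` the response has covered 63.2% of the way to ``A``
    (36.8% remains).  The rate form ``A * (1 - exp(-K*tau))`` with
    ``K = 1/B`` is the same curve.

Burgers
    ``Y(tau) = A * (1 - exp(-tau/B)) + C*tau`` — Kelvin-Voigt plus a
    constant-rate term; ``C`` (response units per minute) captures a
    sustained uptake/loss phase after the exponential transient.  With
    ``C = 0`` it reduces exactly to Kelvin-Voigt.

Time is in minutes throughout.  Some published tables label the Peleg
constants with hour-based units; those labels are display metadata and
the numerical values here are consistent with minutes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "PelegParams",
    "KelvinVoigtParams",
    "BurgersParams",
    "ModelParams",
    "FAMILIES",
    "eval_peleg",
    "eval_kelvin_voigt",
    "eval_burgers",
    "evaluate",
    "peleg_initial_rate",
    "peleg_equilibrium",
    "params_from_dict",
    "params_to_dict",
]

#: Recognised model family keys, as used in configuration and reports.
FAMILIES = ("peleg", "kelvin_voigt", "burgers")


@dataclass(frozen=True)
class PelegParams:
    """Peleg model parameters.

    k1 : initial-rate constant (min per response unit); must be > 0.
    k2 : capacity constant (per response unit); must be > 0.
    y0 : response value at tau = 0.
    direction : +1 if the response increases from y0, -1 if it decreases.
    """

    k1: float
    k2: float
    y0: float = 0.0
    direction: int = 1

    def __post_init__(self) -> None:
        if not self.k1 > 0:
            raise ValueError(f"Peleg k1 must be > 0, got {self.k1}")
        if not self.k2 > 0:
            raise ValueError(f"Peleg k2 must be > 0, got {self.k2}")
        if self.direction not in (1, -1):
            raise ValueError(f"direction must be +1 or -1, got {self.direction}")


@dataclass(frozen=True)
class KelvinVoigtParams:
    """Kelvin-Voigt parameters: equilibrium value ``a`` and time constant ``b`` (min)."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise ValueError(f"Kelvin-Voigt time constant b must be > 0, got {self.b}")

    @property
    def k(self) -> float:
        """Rate constant of the equivalent rate form, K = 1/B (min^-1)."""
        return 1.0 / self.b


@dataclass(frozen=True)
class BurgersParams:
    """Burgers parameters: retardation value ``a``, time constant ``b`` (min),
    constant-rate velocity ``c`` (response units/min)."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise ValueError(f"Burgers time constant b must be > 0, got {self.b}")


ModelParams = Union[PelegParams, KelvinVoigtParams, BurgersParams]


def _check_tau(tau):
    t = np.asarray(tau, dtype=float)
    if np.any(t < 0):
        raise ValueError("immersion time tau must be >= 0")
    return t


def _scalar_like(template, value):
    return float(value) if np.ndim(template) == 0 else value


def eval_peleg(tau, p: PelegParams):
    """Evaluate the Peleg model, Y = Y0 + direction * tau / (k1 + k2*tau)."""
    t = _check_tau(tau)
    y = p.y0 + p.direction * t / (p.k1 + p.k2 * t)
    return _scalar_like(tau, y)


def eval_kelvin_voigt(tau, p: KelvinVoigtParams):
    """Evaluate the Kelvin-Voigt model, Y = A * (1 - exp(-tau/B))."""
    t = _check_tau(tau)
    y = p.a * (1.0 - np.exp(-t / p.b))
    return _scalar_like(tau, y)


def eval_burgers(tau, p: BurgersParams):
    """Evaluate the Burgers model, Y = A * (1 - exp(-tau/B)) + C*tau."""
    t = _check_tau(tau)
    y = p.a * (1.0 - np.exp(-t / p.b)) + p.c * t
    return _scalar_like(tau, y)


def evaluate(family: str, tau, params: ModelParams):
    """Evaluate a model family by key ("peleg", "kelvin_voigt", "burgers")."""
    if family == "peleg":
        return eval_peleg(tau, params)
    if family == "kelvin_voigt":
        return eval_kelvin_voigt(tau, params)
    if family == "burgers":
        return eval_burgers(tau, params)
    raise ValueError(f"unknown model family {family!r}; valid keys: {FAMILIES}")


def peleg_initial_rate(p: PelegParams) -> float:
    """Initial rate of change dY/dtau at tau = 0, equal to direction/k1."""
    return p.direction / p.k1


def peleg_equilibrium(p: PelegParams) -> float:
    """Asymptotic response value, Y0 + direction/k2 (the tau -> inf limit)."""
    return p.y0 + p.direction / p.k2


def params_from_dict(family: str, d: dict) -> ModelParams:
    """Build a parameter object from a plain mapping (config/JSON friendly).

    Keys: Peleg ``k1, k2[, y0, direction]``; Kelvin-Voigt ``a, b``;
    Burgers ``a, b, c``.  Unknown keys raise.
    """
    d = {k.lower(): v for k, v in d.items() if k.lower() != "family"}
    try:
        if family == "peleg":
            return PelegParams(**d)
        if family == "kelvin_voigt":
            return KelvinVoigtParams(**d)
        if family == "burgers":
            return BurgersParams(**d)
    except TypeError as exc:
        raise ValueError(f"bad parameter keys for family {family!r}: {sorted(d)}") from exc
    raise ValueError(f"unknown model family {family!r}; valid keys: {FAMILIES}")


def params_to_dict(params: ModelParams) -> dict:
    """Plain-dict view of a parameter object, with its family key included."""
    if isinstance(params, PelegParams):
        return {"family": "peleg", "k1": params.k1, "k2": params.k2,
                "y0": params.y0, "direction": params.direction}
    if isinstance(params, KelvinVoigtParams):
        return {"family": "kelvin_voigt", "a": params.a, "b": params.b}
    if isinstance(params, BurgersParams):
        return {"family": "burgers", "a": params.a, "b": params.b, "c": params.c}
    raise TypeError(f"not a model parameter object: {params!r}")
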