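"""Synthetic osmotic-dehydration studies with known ground truth.

The generator emulates a factorial immersion study: apple-like samples
(~20 g, initial water content 5.69 g H2O per g dry matter) dipped in
five osmotic solutions — the polyols erythritol, xylitol and maltitol
and dihydroxyacetone (DHA) at 30% concentration, with 50% sucrose as
the reference — sampled at 30-min steps from 0 to 180 min, with two
technological replicates.

True water-loss and solid-gain trajectories come from the kinetic model
families (Peleg / Kelvin-Voigt / Burgers) with per-solute parameters;
the mass-balance relations are then inverted to obtain the sample mass
and dry-matter fraction a balance and drying oven would record, and
independent additive Gaussian noise is applied to both.  Because every
downstream quantity is derived from these two raw observables, the
noise propagates to WC/SG/WL/WL_T/CR exactly as measurement error
would.

The default per-solute true parameters qualitatively mirror the
reference behaviour of such studies: sucrose shows the highest water
loss and solid gain (with a pronounced constant-rate phase), maltitol
the lowest water loss.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import models
from .models import params_from_dict

__all__ = [
    "SimConfig",
    "DEFAULT_TRUE_MODELS",
    "DEFAULT_TIME_GRID",
    "InfeasibleKineticsError",
    "simulate_true_kinetics",
    "invert_to_raw",
    "generate_study",
]

log = logging.getLogger(__name__)

#: Immersion-time grid in minutes: 30-min steps up to 180, plus the tau=0 state.
DEFAULT_TIME_GRID = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0)

#: True WL/SG generating models per solute (best-describing family and its
#: fitted parameters for each response in the emulated study).
DEFAULT_TRUE_MODELS: dict = {
    "erythritol": {
        "wl": {"family": "kelvin_voigt", "a": 1.557, "b": 37.648},
        "sg": {"family": "kelvin_voigt", "a": 0.871, "b": 115.812},
    },
    "xylitol": {
        "wl": {"family": "burgers", "a": 0.957, "b": 19.818, "c": 3.304e-3},
        "sg": {"family": "kelvin_voigt", "a": 0.634, "b": 77.564},
    },
    "maltitol": {
        "wl": {"family": "burgers", "a": 0.574, "b": 26.915, "c": 2.038e-3},
        "sg": {"family": "kelvin_voigt", "a": 0.456, "b": 96.233},
    },
    "DHA": {
        "wl": {"family": "kelvin_voigt", "a": 1.340, "b": 28.683},
        "sg": {"family": "kelvin_voigt", "a": 0.418, "b": 45.490},
    },
    "sucrose": {
        "wl": {"family": "burgers", "a": 0.941, "b": 19.074, "c": 6.332e-3},
        "sg": {"family": "burgers", "a": 0.599, "b": 19.488, "c": 0.704e-3},
    },
}


class InfeasibleKineticsError(ValueError):
    """True kinetics imply a physically impossible sample state."""


@dataclass
class SimConfig:
    """Configuration of a synthetic study.

    solutes : mapping solute -> {"wl": model spec, "sg": model spec}
        where a model spec is {"family": key, <parameters>}.
    time_grid : immersion times in minutes, strictly increasing from 0.
    replicates : technological replicates per treatment (default 2).
    m0_mean, m0_sd : initial sample mass, g (nominal 20 g; the per-
        replicate draw has sd 0.7 g, keeping essentially all samples
        within the nominal +/- 2 g).
    s0 : initial dry-matter fraction (0.1495, i.e. WC0 = 5.69 g/g d.m.).
    noise_sd_mass, noise_sd_s : additive Gaussian measurement noise on
        mass (g) and dry fraction — typical balance / oven precision.
    aw_proxy : optional (intercept, slope, noise_sd) of a linear-in-WC
        water-activity proxy; None disables the a_w column.
    seed : RNG seed; a fixed seed reproduces the study byte-for-byte.
    """

    solutes: Mapping[str, Mapping] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_TRUE_MODELS))
    time_grid: tuple = DEFAULT_TIME_GRID
    replicates: int = 2
    m0_mean: float = 20.0
    m0_sd: float = 0.7
    s0: float = 0.1495
    noise_sd_mass: float = 0.05
    noise_sd_s: float = 0.002
    aw_proxy: Optional[tuple] = None
    seed: int = 0

    def __post_init__(self) -> None:
        grid = tuple(float(t) for t in self.time_grid)
        if grid[0] != 0 or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("time grid must be strictly increasing from 0")
        object.__setattr__(self, "time_grid", grid)
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if not 0 < self.s0 <= 1:
            raise ValueError("s0 must be in (0, 1]")
        for sd in (self.m0_sd, self.noise_sd_mass, self.noise_sd_s):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "time_grid" in raw:
            raw["time_grid"] = tuple(raw["time_grid"])
        if raw.get("aw_proxy") is not None:
            raw["aw_proxy"] = tuple(raw["aw_proxy"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ValueError(f"unknown configuration key(s) in {path}: {exc}") from exc

    def to_yaml(self, path) -> None:
        raw = {
            "solutes": {k: {r: dict(v) for r, v in spec.items()}
                        for k, spec in self.solutes.items()},
            "time_grid": list(self.time_grid),
            "replicates": self.replicates,
            "m0_mean": self.m0_mean,
            "m0_sd": self.m0_sd,
            "s0": self.s0,
            "noise_sd_mass": self.noise_sd_mass,
            "noise_sd_s": self.noise_sd_s,
            "aw_proxy": list(self.aw_proxy) if self.aw_proxy else None,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _true_params(spec: Mapping):
    spec = dict(spec)
    family = spec.pop("family")
    if family == "peleg":
        spec.setdefault("y0", 0.0)
        spec.setdefault("direction", 1)
        if spec["y0"] != 0.0 or spec["direction"] != 1:
            raise ValueError("true WL/SG kinetics must start at 0 and increase")
    return family, params_from_dict(family, {"family": family, **spec})


def simulate_true_kinetics(config: SimConfig, solute: str):
    """Noise-free (tau, WL, SG) trajectories of one solute on the grid."""
    if solute not in config.solutes:
        raise KeyError(f"no true model configured for solute {solute!r}")
    tau = np.asarray(config.time_grid, dtype=float)
    spec = config.solutes[solute]
    out = {}
    for response in ("wl", "sg"):
        family, params = _true_params(spec[response])
        out[response] = np.asarray(models.evaluate(family, tau, params), dtype=float)
    return tau, out["wl"], out["sg"]


def invert_to_raw(wl, sg, m_o: float, s_o: float):
    """Invert the mass-balance relations: (WL, SG) -> (m_tau, s_tau).

    m_tau = s_o*m_o*(1+SG) + (1-s_o)*m_o - WL*s_o*m_o and
    s_tau = s_o*m_o*(1+SG) / m_tau, the exact algebraic inverse of the
    solid-gain and water-loss definitions, so a round trip reproduces
    (SG, WL) to machine precision.

    Raises :class:`InfeasibleKineticsError` if the implied state is
    unphysical (mass <= 0 or dry fraction outside (0, 1]).
    """
    wl = np.asarray(wl, dtype=float)
    sg = np.asarray(sg, dtype=float)
    if np.any(sg <= -1):
        raise InfeasibleKineticsError("solid gain must be > -1")
    dm = s_o * m_o * (1.0 + sg)          # dry matter now present
    m_tau = dm + (1.0 - s_o) * m_o - wl * s_o * m_o
    if np.any(m_tau <= 0):
        raise InfeasibleKineticsError("implied sample mass <= 0")
    s_tau = dm / m_tau
    if np.any((s_tau <= 0) | (s_tau > 1)):
        raise InfeasibleKineticsError("implied dry fraction outside (0, 1]")
    if np.ndim(wl) == 0 and np.ndim(sg) == 0:
        return float(m_tau), float(s_tau)
    return m_tau, s_tau


def _noisy_state(rng, m_true, s_true, sd_m, sd_s, max_tries: int = 100):
    """Add measurement noise, resampling (then clipping) into validity."""
    for _ in range(max_tries):
        m = m_true + rng.normal(0.0, sd_m)
        s = s_true + rng.normal(0.0, sd_s)
        if m > 0 and 0 < s <= 1:
            return m, s
    log.warning("noise resampling exhausted; clipping to validity bounds")
    return max(m_true, 1e-6), float(np.clip(s_true, 1e-6, 1.0))


def generate_study(config: SimConfig):
    """Generate one full synthetic study.

    Returns ``(measurements, initial, truth)``: the raw measurement
    table (``solute, replicate, tau_min, mass_g, dry_fraction[, a_w]``),
    the per-replicate initial states (``solute, replicate, m0_g, s0``),
    and a ground-truth record (the generating models and design
    constants) for parameter-recovery checks.

    tau = 0 rows restate the initial state exactly (the initial weighing
    *is* the tau = 0 measurement); noise enters from the first immersion
    time onward.  Fixed seed => identical output.
    """
    rng = np.random.default_rng(config.seed)
    meas_rows = []
    init_rows = []
    for solute in config.solutes:
        tau, wl, sg = simulate_true_kinetics(config, solute)
        for rep in range(1, config.replicates + 1):
            m0 = -1.0
            for _ in range(100):
                m0 = rng.normal(config.m0_mean, config.m0_sd)
                if m0 > 0:
                    break
            init_rows.append({"solute": solute, "replicate": rep,
                              "m0_g": m0, "s0": config.s0})
            m_true, s_true = invert_to_raw(wl, sg, m0, config.s0)
            for j, t in enumerate(tau):
                if t == 0:
                    m_obs, s_obs = m0, config.s0
                else:
                    m_obs, s_obs = _noisy_state(
                        rng, m_true[j], s_true[j],
                        config.noise_sd_mass, config.noise_sd_s)
                row = {"solute": solute, "replicate": rep, "tau_min": t,
                       "mass_g": m_obs, "dry_fraction": s_obs}
                if config.aw_proxy is not None:
                    b0, b1, sd_aw = config.aw_proxy
                    wc_true = (1.0 - s_true[j]) / s_true[j]
                    aw = b0 + b1 * wc_true + rng.normal(0.0, sd_aw)
                    row["a_w"] = float(np.clip(aw, 1e-6, 1 - 1e-6))
                meas_rows.append(row)
    measurements = pd.DataFrame(meas_rows)
    initial = pd.DataFrame(init_rows)
    truth = {
        "solutes": {k: {r: dict(v) for r, v in spec.items()}
                    for k, spec in config.solutes.items()},
        "time_grid": list(config.time_grid),
        "replicates": config.replicates,
        "m0_mean": config.m0_mean,
        "s0": config.s0,
        "noise_sd_mass": config.noise_sd_mass,
        "noise_sd_s": config.noise_sd_s,
        "seed": config.seed,
    }
    return measurements, initial, truth
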