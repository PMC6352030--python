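"""Mass-transfer kinetic parameters from raw gravimetric measurements.

An osmotic-dehydration run is followed by weighing samples and measuring
their dry-matter mass fraction ``s`` at each immersion time ``tau``.
From the initial state ``(m0, s0)`` and the state ``(m_tau, s_tau)`` at
time ``tau`` five descriptors are computed, all on a dry-matter basis:

WC   water content, g water per g dry matter: (1 - s_tau) / s_tau
SG   solid gain, g solids taken up per g initial dry matter
WL   water loss, g water removed per g initial dry matter
WL_T true water loss, WL corrected for concurrent solid uptake: WL/(1+SG)
CR   ratio WL_T / WL, algebraically 1/(1+SG); close to 1 means
     dehydration with little solute impregnation

WL and SG may legitimately be negative (a sample that swelled or leached
solids); such values are kept and flagged in the log, never clipped.
CR is undefined (0/0) at WL = 0, i.e. at tau = 0; tables report it as
missing there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "RawMeasurement",
    "InitialState",
    "water_content",
    "water_content_per_initial_dm",
    "solid_gain",
    "water_loss",
    "true_water_loss",
    "cr_ratio",
    "kinetics_table",
    "KINETIC_COLUMNS",
]

log = logging.getLogger(__name__)

#: Kinetic descriptor columns, in table order.
KINETIC_COLUMNS = ("WC", "SG", "WL", "WLT", "CR")


@dataclass(frozen=True)
class RawMeasurement:
    """One (solute, replicate, time) observation of mass and dry matter."""

    solute: str
    replicate: str
    tau: float            # immersion time, min
    m_tau: float          # sample mass, g
    s_tau: float          # dry-matter mass fraction
    a_w: Optional[float] = None  # water activity, if measured

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")
        if not self.m_tau > 0:
            raise ValueError(f"mass must be > 0, got {self.m_tau}")
        if not 0 < self.s_tau <= 1:
            raise ValueError(f"dry fraction must be in (0, 1], got {self.s_tau}")
        if self.a_w is not None and not 0 < self.a_w < 1:
            raise ValueError(f"water activity must be in (0, 1), got {self.a_w}")


@dataclass(frozen=True)
class InitialState:
    """Initial mass and dry-matter fraction of a replicate's samples."""

    m_o: float
    s_o: float

    def __post_init__(self) -> None:
        if not self.m_o > 0:
            raise ValueError(f"initial mass must be > 0, got {self.m_o}")
        if not 0 < self.s_o <= 1:
            raise ValueError(f"initial dry fraction must be in (0, 1], got {self.s_o}")


def _as_float(x):
    return np.asarray(x, dtype=float)


def _ret(template, value):
    return float(value) if np.ndim(template) == 0 else value


def water_content(s_tau):
    """Water content on a dry basis, WC = (1 - s)/s, in g H2O per g d.m.

    Accepts a scalar or array dry-matter fraction in (0, 1].
    """
    s = _as_float(s_tau)
    if np.any(s <= 0) or np.any(s > 1):
        raise ValueError("dry-matter fraction must be in (0, 1]")
    return _ret(s_tau, (1.0 - s) / s)


def water_content_per_initial_dm(s_tau, m_tau, m_o, s_o):
    """Alternative water-content convention: water mass per g *initial* dry
    matter, (1 - s_tau) * m_tau / (s_o * m_o).

    The dry-basis form :func:`water_content` is the default throughout;
    this variant is kept for comparison with per-initial-dry-matter
    bookkeeping.
    """
    s, m = _as_float(s_tau), _as_float(m_tau)
    if np.any(s <= 0) or np.any(s > 1):
        raise ValueError("dry-matter fraction must be in (0, 1]")
    denom = s_o * m_o
    if not denom > 0:
        raise ValueError("initial dry matter s_o * m_o must be > 0")
    return _ret(s_tau, (1.0 - s) * m / denom)


def solid_gain(s_tau, m_tau, m_o, s_o):
    """Solid gain, SG = (s_tau*m_tau - s_o*m_o) / (s_o*m_o)."""
    s, m = _as_float(s_tau), _as_float(m_tau)
    denom = _as_float(s_o) * _as_float(m_o)
    if np.any(denom <= 0):
        raise ValueError("initial dry matter s_o * m_o must be > 0")
    return _ret(s_tau, (s * m - denom) / denom)


def water_loss(s_tau, m_tau, m_o, s_o):
    """Water loss, WL = [(1-s_o)*m_o - (1-s_tau)*m_tau] / (s_o*m_o).

    Negative when the sample gained water; such values are retained.
    """
    s, m = _as_float(s_tau), _as_float(m_tau)
    s_o, m_o = _as_float(s_o), _as_float(m_o)
    denom = s_o * m_o
    if np.any(denom <= 0):
        raise ValueError("initial dry matter s_o * m_o must be > 0")
    return _ret(s_tau, ((1.0 - s_o) * m_o - (1.0 - s) * m) / denom)


def true_water_loss(wl, sg):
    """True water loss, WL_T = WL / (1 + SG).

    Expresses the water removed per gram of the dry matter actually
    present, so concurrent solute uptake no longer inflates the figure.
    """
    wl_, sg_ = _as_float(wl), _as_float(sg)
    if np.any(sg_ <= -1):
        raise ValueError("solid gain must be > -1")
    return _ret(wl, wl_ / (1.0 + sg_))


def cr_ratio(wl_t, wl):
    """Ratio of true to nominal water loss, CR = WL_T / WL = 1/(1+SG).

    Scalar inputs with WL = 0 raise (the ratio is 0/0 there); array
    inputs return NaN at those positions so tables can report a missing
    value rather than a fabricated 0.
    """
    wlt_, wl_ = _as_float(wl_t), _as_float(wl)
    if np.ndim(wl) == 0:
        if wl_ == 0:
            raise ValueError("CR is undefined at WL = 0 (report as missing)")
        return float(wlt_ / wl_)
    out = np.full(np.broadcast(wlt_, wl_).shape, np.nan)
    nz = wl_ != 0
    np.divide(wlt_, wl_, out=out, where=nz)
    return out


def _require_columns(df: pd.DataFrame, cols, name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise KeyError(f"{name} is missing required column(s): {missing}")


def kinetics_table(
    measurements: pd.DataFrame,
    initial: pd.DataFrame,
    *,
    wc_per_initial_dm: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Derive the kinetic descriptors from raw measurement tables.

    Parameters
    ----------
    measurements
        Columns ``solute, replicate, tau_min, mass_g, dry_fraction``
        (optionally ``a_w``); one row per (solute, replicate, time).
    initial
        Columns ``solute, replicate, m0_g, s0``; one row per replicate.
    wc_per_initial_dm
        If True, report WC per gram of initial dry matter instead of the
        default dry-basis (1-s)/s convention.

    Returns
    -------
    (by_rep, averaged)
        ``by_rep`` has one row per measurement with WC, SG, WL, WLT, CR;
        ``averaged`` is the replicate mean per (solute, tau_min) —
        the series the model fits consume by default.

    Raises
    ------
    KeyError if a measurement has no matching initial state, or a
    required column is absent.  ValueError on duplicated
    (solute, replicate, tau) keys or out-of-range values.
    """
    _require_columns(measurements, ["solute", "replicate", "tau_min", "mass_g", "dry_fraction"],
                     "measurements")
    _require_columns(initial, ["solute", "replicate", "m0_g", "s0"], "initial")

    keys = ["solute", "replicate", "tau_min"]
    if measurements.duplicated(keys).any():
        dup = measurements[measurements.duplicated(keys, keep=False)][keys]
        raise ValueError(f"duplicate (solute, replicate, tau) rows:\n{dup}")
    if initial.duplicated(["solute", "replicate"]).any():
        raise ValueError("duplicate (solute, replicate) rows in initial table")

    df = measurements.merge(initial, on=["solute", "replicate"], how="left",
                            validate="many_to_one")
    if df["m0_g"].isna().any():
        orphans = df.loc[df["m0_g"].isna(), ["solute", "replicate"]].drop_duplicates()
        raise KeyError(f"no initial state for replicate(s):\n{orphans}")

    s, m = df["dry_fraction"].to_numpy(float), df["mass_g"].to_numpy(float)
    s0, m0 = df["s0"].to_numpy(float), df["m0_g"].to_numpy(float)
    tau = df["tau_min"].to_numpy(float)
    if np.any(tau < 0):
        raise ValueError("tau_min must be >= 0")
    if np.any((s <= 0) | (s > 1)) or np.any(m <= 0):
        raise ValueError("dry_fraction must be in (0, 1] and mass_g > 0")
    # a tau=0 record must restate the initial state it came from
    at0 = tau == 0
    if np.any(at0) and not (np.allclose(m[at0], m0[at0], rtol=1e-9)
                            and np.allclose(s[at0], s0[at0], rtol=1e-9)):
        raise ValueError("tau=0 measurements disagree with the initial table")

    denom = s0 * m0
    wc = (1.0 - s) * m / denom if wc_per_initial_dm else (1.0 - s) / s
    sg = (s * m - denom) / denom
    wl = ((1.0 - s0) * m0 - (1.0 - s) * m) / denom
    wlt = wl / (1.0 + sg)
    cr = cr_ratio(wlt, wl)

    n_neg = int(np.sum((wl < 0) | (sg < 0)))
    if n_neg:
        log.warning("%d record(s) with negative WL or SG retained (not clipped)", n_neg)

    by_rep = pd.DataFrame({
        "solute": df["solute"], "replicate": df["replicate"], "tau_min": tau,
        "WC": wc, "SG": sg, "WL": wl, "WLT": wlt, "CR": cr,
    }).sort_values(["solute", "replicate", "tau_min"], kind="stable").reset_index(drop=True)

    averaged = (
        by_rep.groupby(["solute", "tau_min"], sort=True)[list(KINETIC_COLUMNS)]
        .mean()  # CR averages over replicates where defined; all-NaN (tau=0) stays NaN
        .reset_index()
    )
    return by_rep, averaged
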