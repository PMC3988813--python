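"""Totally confined diffusivity from supercooled-water thermodynamics.

Nanoconfined water behaves like supercooled bulk water: the enthalpy
change of moving a molecule from bulk into the adsorbed layer,
Delta h ~ -epsilon (the wall-potential well depth), maps onto an
effective supercooled temperature through

    f(T) = integral_{T0}^{T} c_p dT,        T = f^{-1}(Delta h),

and the measured diffusivity ratio of strongly confined water,
D(T)/D_B = g(T), evaluated at that temperature gives

    D_C / D_B = g( f^{-1}(-epsilon) ).

c_p(T) and g(T) are experimental property tables of (confined) water
supplied by the user; synthetic tables are used in tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq

from .constants import kj_per_mol_to_j_per_kg

logger = logging.getLogger(__name__)

__all__ = [
    "ThermoTables",
    "enthalpy_function",
    "invert_enthalpy",
    "dc_ratio",
    "load_two_column",
]


@dataclass
class ThermoTables:
    """Experimental curves for the supercooled-water route.

    cp_samples : (T [K], c_p [J kg^-1 K^-1]) pairs, strictly increasing T.
    g_samples  : (T [K], D(T)/D_B) pairs, ratios in [0, 1].
    T0         : anchor temperature where f(T0) = 0 (bulk water), K.
    """

    cp_samples: Sequence[tuple[float, float]]
    g_samples: Sequence[tuple[float, float]]
    T0: float = 300.0

    def __post_init__(self) -> None:
        cp = np.asarray(self.cp_samples, dtype=float)
        g = np.asarray(self.g_samples, dtype=float)
        for name, arr in (("cp_samples", cp), ("g_samples", g)):
            if arr.ndim != 2 or arr.shape[0] < 2:
                raise ValueError(f"{name}: need >= 2 (T, value) rows")
            if np.any(np.diff(arr[:, 0]) <= 0):
                raise ValueError(f"{name}: T grid must be strictly increasing")
        if np.any(cp[:, 1] <= 0):
            raise ValueError("c_p must be positive")
        if np.any((g[:, 1] < 0) | (g[:, 1] > 1)):
            raise ValueError("diffusivity ratios must lie in [0, 1]")
        if not (cp[0, 0] <= self.T0 <= cp[-1, 0]):
            raise ValueError("T0 must lie within the c_p table range")
        self._cp = cp
        self._g = g


def enthalpy_function(tables: ThermoTables) -> Callable[[float], float]:
    """f(T) = integral_{T0}^{T} c_p dT on the (linearly interpolated) table.

    The integral of the piecewise-linear c_p is evaluated exactly
    (trapezoid per segment), anchored so f(T0) = 0.  Evaluation outside
    the table range raises (no extrapolation).
    """
    T_grid = tables._cp[:, 0]
    cp_grid = tables._cp[:, 1]
    cum = np.concatenate(
        [[0.0], cumulative_trapezoid(cp_grid, T_grid)]
    )  # integral from T_grid[0]

    def _raw(T: float) -> float:
        if not (T_grid[0] - 1e-12 <= T <= T_grid[-1] + 1e-12):
            raise ValueError(
                f"T={T} K outside c_p table range "
                f"[{T_grid[0]}, {T_grid[-1]}]"
            )
        T = float(np.clip(T, T_grid[0], T_grid[-1]))
        j = int(np.searchsorted(T_grid, T, side="right") - 1)
        j = min(j, len(T_grid) - 2)
        cp_T = np.interp(T, T_grid, cp_grid)
        return float(cum[j] + 0.5 * (cp_grid[j] + cp_T) * (T - T_grid[j]))

    offset = _raw(tables.T0)

    def f(T: float) -> float:
        return _raw(T) - offset

    f.domain = (float(T_grid[0]), float(T_grid[-1]))  # type: ignore[attr-defined]
    return f


def invert_enthalpy(
    f: Callable[[float], float], tables: ThermoTables
) -> Callable[[float], float]:
    """Inverse of the strictly increasing f: Delta h [J/kg] -> T [K]."""
    t_lo, t_hi = f.domain  # type: ignore[attr-defined]
    h_lo, h_hi = f(t_lo), f(t_hi)

    def finv(dh: float) -> float:
        if not (h_lo - 1e-9 <= dh <= h_hi + 1e-9):
            raise ValueError(
                f"Delta h={dh} J/kg outside range [{h_lo:.6g}, {h_hi:.6g}]"
            )
        dh = float(np.clip(dh, h_lo, h_hi))
        return float(brentq(lambda T: f(T) - dh, t_lo, t_hi, xtol=1e-9))

    finv.range = (h_lo, h_hi)  # type: ignore[attr-defined]
    return finv


def dc_ratio(epsilon: float, tables: ThermoTables) -> float:
    """D_C/D_B for a wall-potential well depth *epsilon* (kJ/mol > 0).

    epsilon is converted to a specific energy (J/kg, per water mass) and
    entered as Delta h = -epsilon.  Wells deeper than the table range
    return 0 (totally arrested adsorbed layer).  The result is clamped
    to [0, 1].
    """
    if epsilon < 0:
        raise ValueError("epsilon (well depth) must be >= 0")
    f = enthalpy_function(tables)
    finv = invert_enthalpy(f, tables)
    dh = -kj_per_mol_to_j_per_kg(epsilon)
    h_lo, _ = finv.range  # type: ignore[attr-defined]
    if dh < h_lo:
        logger.warning(
            "well depth %.3g kJ/mol beyond the c_p table range; D_C ~ 0",
            epsilon,
        )
        return 0.0
    T = finv(dh)
    g = tables._g
    if T < g[0, 0]:
        logger.warning("T=%.1f K below the g table range; D_C ~ 0", T)
        return 0.0
    ratio = float(np.interp(T, g[:, 0], g[:, 1]))
    return float(np.clip(ratio, 0.0, 1.0))


def load_two_column(path: str | Path) -> list[tuple[float, float]]:
    """Read a two-column text table (comments with '#')."""
    arr = np.loadtxt(path, comments="#", ndmin=2)
    if arr.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns")
    return [(float(a), float(b)) for a, b in arr[:, :2]]
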