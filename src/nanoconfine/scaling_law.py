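"""The D(theta) scaling law and its least-squares calibration.

    D(theta) = D_B [1 + (D_C/D_B - 1) theta]

interpolates linearly between the bulk self-diffusion coefficient D_B
(theta = 0) and the totally confined one D_C (theta = 1).  A
density-weighted variant replaces theta by the confined-molecule number
fraction when the adsorbed-layer density differs from bulk.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ScalingLaw",
    "DEFAULT_D_BULK",
    "predict_D",
    "predict_D_density",
    "invert_theta",
    "fit_law",
    "percent_change",
]

#: bulk water self-diffusion coefficient at 300 K, m^2/s
DEFAULT_D_BULK = 2.60e-9


@dataclass(frozen=True)
class ScalingLaw:
    """Parameters of the linear D(theta) map (m^2/s; densities kg/m^3)."""

    D_B: float = DEFAULT_D_BULK
    D_C: float = 0.0
    rho_B: float | None = None
    rho_C: float | None = None

    def __post_init__(self) -> None:
        if self.D_B <= 0:
            raise ValueError("D_B must be positive")
        if not (0.0 <= self.D_C <= self.D_B):
            raise ValueError("require 0 <= D_C <= D_B")


def _check_theta(theta) -> np.ndarray:
    t = np.asarray(theta, dtype=float)
    if np.any((t < 0) | (t > 1)):
        raise ValueError("theta must lie in [0, 1]")
    return t


def predict_D(theta, law: ScalingLaw = ScalingLaw()):
    """Self-diffusion coefficient at confinement fraction theta.

    With D_C = 0 this is the one-parameter law D = D_B (1 - theta).
    """
    t = _check_theta(theta)
    out = law.D_B * (1.0 + (law.D_C / law.D_B - 1.0) * t)
    return out if out.ndim else float(out)


def predict_D_density(theta, law: ScalingLaw):
    """Density-weighted mixing rule: theta is replaced by the confined
    number fraction w = rho_C theta / (rho_C theta + rho_B (1-theta))."""
    if law.rho_B is None or law.rho_C is None:
        raise ValueError("density-weighted law requires rho_B and rho_C")
    if law.rho_B <= 0 or law.rho_C <= 0:
        raise ValueError("densities must be positive")
    t = _check_theta(theta)
    w = law.rho_C * t / (law.rho_C * t + law.rho_B * (1.0 - t))
    out = law.D_B * (1.0 + (law.D_C / law.D_B - 1.0) * w)
    return out if out.ndim else float(out)


def invert_theta(D: float, law: ScalingLaw) -> float:
    """Algebraic inverse of predict_D: theta = (D_B - D)/(D_B - D_C)."""
    lo, hi = min(law.D_C, law.D_B), law.D_B
    if not (lo - 1e-15 <= D <= hi + 1e-15):
        raise ValueError(f"D={D} outside [D_C, D_B]=[{lo}, {hi}]")
    if law.D_B == law.D_C:
        return 0.0
    return float(np.clip((law.D_B - D) / (law.D_B - law.D_C), 0.0, 1.0))


def fit_law(
    points: Sequence[tuple[float, float, float]] | np.ndarray,
    fix_dc_zero: bool = False,
    weighted: bool = True,
) -> tuple[ScalingLaw, float]:
    """Least-squares fit of (theta, D[, sigma_D]) points to the linear law.

    Returns the fitted law and the coefficient of determination
    R^2 = 1 - SS_res/SS_tot.  With *weighted*, inverse-variance weights
    from the sigma_D column are used when available.  A fitted D_C below
    zero is clamped to 0 (the law's physical domain).

    With *fix_dc_zero*, only D_B is fitted in D = D_B (1 - theta).
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (theta, D) points")
    theta, D = arr[:, 0], arr[:, 1]
    if np.ptp(theta) == 0:
        raise ValueError("degenerate fit: all theta values identical")
    if weighted and arr.shape[1] >= 3 and np.all(arr[:, 2] > 0):
        w = 1.0 / arr[:, 2] ** 2
    else:
        w = np.ones_like(theta)

    if fix_dc_zero:
        x = 1.0 - theta
        d_b = float(np.sum(w * x * D) / np.sum(w * x * x))
        d_c = 0.0
    else:
        # D = a + b*theta, D_B = a, D_C = a + b
        A = np.column_stack([np.ones_like(theta), theta])
        Aw = A * np.sqrt(w)[:, None]
        coef, *_ = np.linalg.lstsq(Aw, D * np.sqrt(w), rcond=None)
        d_b = float(coef[0])
        d_c = float(coef[0] + coef[1])
        if d_c < 0.0:
            d_c = 0.0
            x = 1.0 - theta
            d_b = float(np.sum(w * x * D) / np.sum(w * x * x))
    d_c = min(d_c, d_b)
    law = ScalingLaw(D_B=d_b, D_C=d_c)
    pred = predict_D(np.clip(theta, 0.0, 1.0), law)
    ss_res = float(np.sum(w * (D - pred) ** 2))
    ss_tot = float(np.sum(w * (D - np.average(D, weights=w)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return law, r2


def percent_change(old: float, new: float) -> float:
    """Signed percentage change from *old* to *new* (positive = increase)."""
    if old == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (new - old) / old
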