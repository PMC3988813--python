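"""From the confinement length delta to the scaling parameter theta.

theta = V_in / V_w : the fraction of the water volume lying within the
wall-influence layer of thickness delta.  V_in is computed per surface
with an exact shell formula where curvature matters (sphere, cylinder),
and the apparent fraction is corrected for overlapping influence volumes
with the continuum-percolation factor 1 - exp(-theta).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

__all__ = [
    "SurfaceSpec",
    "ThetaResult",
    "volume_of_influence",
    "water_volume",
    "particle_volume",
    "theta_apparent",
    "cpt_correct",
    "compute_theta",
]

Shape = Literal["plane", "sphere", "cylinder_inner", "cylinder_outer"]


@dataclass
class SurfaceSpec:
    """One confining surface: its SAS area, delta and curvature class.

    radius and length (nm) are required for the curved shapes; *count*
    replicates identical surfaces (e.g. N nanoparticles in a pore).
    """

    S_tot: float
    delta: float
    shape: Shape = "plane"
    radius: float | None = None
    length: float | None = None
    count: int = 1

    def __post_init__(self) -> None:
        if self.S_tot <= 0:
            raise ValueError("S_tot must be positive")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.shape != "plane":
            if self.radius is None or self.radius <= 0:
                raise ValueError(f"shape {self.shape!r} requires radius > 0")
        if self.shape.startswith("cylinder"):
            if self.length is None or self.length <= 0:
                raise ValueError("cylinder shapes require length > 0")


@dataclass
class ThetaResult:
    V_in: float
    V_w: float
    theta_apparent: float
    theta: float


def _single_volume(spec: SurfaceSpec) -> float:
    d = spec.delta
    if spec.shape == "plane":
        return spec.S_tot * d
    R = spec.radius
    if spec.shape == "sphere":
        return 4.0 * math.pi / 3.0 * ((R + d) ** 3 - R**3)
    L = spec.length
    if spec.shape == "cylinder_inner":
        d = min(d, R)  # layer cannot exceed the pore radius
        return math.pi * L * (R**2 - (R - d) ** 2)
    if spec.shape == "cylinder_outer":
        return math.pi * L * ((R + d) ** 2 - R**2)
    raise ValueError(f"unknown shape {spec.shape!r}")


def volume_of_influence(specs: Sequence[SurfaceSpec]) -> float:
    """Total influence volume, nm^3, summed over surfaces x count.

    Planes use the first-order S.delta product; curved surfaces use the
    exact shell volumes, which exceed S.delta for convex walls and
    saturate at the full pore volume for narrow cylindrical pores.
    """
    if not specs:
        raise ValueError("at least one surface spec required")
    return float(sum(_single_volume(sp) * sp.count for sp in specs))


def water_volume(n_sol: int, rho_n: float) -> float:
    """Water volume V_w = N_sol / rho_n (nm^3) from the molecule count
    and number density (nm^-3)."""
    if rho_n <= 0:
        raise ValueError("rho_n must be positive")
    if n_sol < 0:
        raise ValueError("n_sol must be >= 0")
    return n_sol / rho_n


def particle_volume(v_box: float, v_w: float) -> float:
    """Volume occupied by the solvated solid: V_p = V_box - V_w."""
    if v_box < v_w:
        raise ValueError("V_box must be >= V_w")
    return v_box - v_w


def theta_apparent(V_in: float, V_w: float) -> float:
    """Raw ratio V_in / V_w, not clamped (diagnostic value)."""
    if V_w <= 0:
        raise ValueError("V_w must be positive")
    if V_in < 0:
        raise ValueError("V_in must be >= 0")
    return V_in / V_w


def cpt_correct(theta_app: float, overlap: bool = True) -> float:
    """Continuum-percolation overlap correction.

    Randomly placed overlapping influence volumes cover an effective
    fraction 1 - exp(-theta); without overlap the apparent fraction is
    kept, clamped to 1.
    """
    if theta_app < 0:
        raise ValueError("theta_app must be >= 0")
    if overlap:
        return -math.expm1(-theta_app)
    return min(theta_app, 1.0)


def compute_theta(
    specs: Sequence[SurfaceSpec],
    V_w: float,
    overlap: bool | None = None,
    rho_n_rel_std: float = 0.0,
) -> ThetaResult:
    """Full pipeline: V_in, apparent theta, overlap-corrected theta.

    *overlap* defaults to automatic: enabled when more than one influence
    volume is present.  ``rho_n_rel_std`` (relative s.d. of the water
    number density) is available to callers for error propagation on
    theta; it does not change the central value.
    """
    V_in = volume_of_influence(specs)
    t_app = theta_apparent(V_in, V_w)
    if overlap is None:
        overlap = sum(sp.count for sp in specs) > 1
    theta = cpt_correct(t_app, overlap)
    theta = min(max(theta, 0.0), 1.0)
    return ThetaResult(V_in=V_in, V_w=V_w, theta_apparent=t_app, theta=theta)
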