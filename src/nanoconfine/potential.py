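"""Effective wall potential and the characteristic confinement length delta.

For a surface atom i, the potential felt by a water molecule at distance
n along the outward SAS normal is

    U_eff(n) = U_vdw(n) + U_c(n)

with a 12-6 Lennard-Jones sum over the atom's neighbourhood and a
thermally averaged dipole-field Coulomb term

    U_c = -E mu_w Gamma(mu_w E / kB T),    Gamma(x) = coth(x) - 1/x.

The local confinement length delta_i is the distance between the two
zeros of U_eff(n) + alpha kB T (alpha ~ 1/4): inside that interval a
water molecule with thermal kinetic energy cannot escape the well.
Surface (SAS-weighted) averaging of delta_i gives the structure-level
delta that feeds the scaling parameter theta.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from .constants import (
    BOLTZMANN_J,
    ELEMENTARY_CHARGE,
    KB_KJMOL,
    NM,
    VACUUM_PERMITTIVITY,
    joule_to_kj_per_mol,
)
from .sas import SASResult, compute_sas, surface_atoms
from .structures import ParamStructure, WaterModel, SPCE

logger = logging.getLogger(__name__)

__all__ = [
    "PotentialConfig",
    "PotentialProfile",
    "ConfinementResult",
    "langevin",
    "dipole_energy",
    "coulomb_field",
    "lj_profile",
    "effective_profile",
    "local_delta",
    "mean_delta",
    "sigmoidal_permittivity",
    "constant_permittivity",
]

_R_FLOOR = 1e-4  # nm, guards grid points coincident with an atom centre


def constant_permittivity(value: float = 1.0):
    """Relative-permittivity model: constant (oracle/testing mode)."""
    if value < 1.0:
        raise ValueError("relative permittivity must be >= 1")

    def eps_r(r: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(r, dtype=float), value)

    return eps_r


def sigmoidal_permittivity(
    eps_bulk: float = 78.0, midpoint: float = 0.4, width: float = 0.1
):
    """Distance-dependent permittivity rising from ~1 at contact to bulk.

    A sigmoidal switch is the standard implicit-screening choice for
    interfacial water; *midpoint* and *width* are in nm.
    """

    def eps_r(r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        return 1.0 + (eps_bulk - 1.0) / (1.0 + np.exp(-(r - midpoint) / width))

    return eps_r


@dataclass
class PotentialConfig:
    """Numerical and physical knobs of the delta computation.

    cutoff : nm, neighbour search radius (atom i included).
    grid_start, grid_points : the n-grid spans [grid_start, cutoff].
    alpha : thermal-level factor; 1/4 is exact for planar walls.
    temperature : K.
    combine_lj : apply Lorentz-Berthelot against the water oxygen; set
        False when the table already stores water-combined parameters.
    surface_area_threshold : nm^2, minimum S_loc for an atom to count as
        a surface atom in the average.
    """

    cutoff: float = 1.0
    grid_start: float = 0.05
    grid_points: int = 2000
    alpha: float = 0.25
    temperature: float = 300.0
    combine_lj: bool = True
    eps_r_model: object = field(default_factory=sigmoidal_permittivity)
    probe_radius: float = 0.14
    sas_points: int = 960
    surface_area_threshold: float = 1e-3

    def grid(self) -> np.ndarray:
        return np.linspace(self.grid_start, self.cutoff, self.grid_points)


@dataclass
class PotentialProfile:
    """Tabulated U_eff along an atom's outward normal."""

    n_grid: np.ndarray
    U_vdw: np.ndarray
    U_c: np.ndarray

    @property
    def U_eff(self) -> np.ndarray:
        return self.U_vdw + self.U_c

    @property
    def well_depth(self) -> float:
        m = float(self.U_eff.min())
        return -m if m < 0 else 0.0

    @property
    def well_position(self) -> float:
        return float(self.n_grid[int(np.argmin(self.U_eff))])


@dataclass
class ConfinementResult:
    """Per-atom and surface-averaged confinement lengths."""

    delta_i: dict[int, float]
    delta_mean: float
    epsilon_mean: float
    epsilon_max: float
    alpha: float


def langevin(x):
    """Langevin function coth(x) - 1/x, series-stabilized near 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("langevin argument must be >= 0")
    out = np.empty_like(x)
    small = x < 1e-3
    xs = x[small]
    out[small] = xs / 3.0 - xs**3 / 45.0
    xl = x[~small]
    out[~small] = 1.0 / np.tanh(xl) - 1.0 / xl
    return out if out.ndim else float(out)


def dipole_energy(E, water: WaterModel = SPCE, T: float = 300.0):
    """Thermally averaged dipole energy -E mu Gamma(mu E / kB T), kJ/mol.

    E is the field strength in V/m; the Boltzmann average over dipole
    orientations yields the Langevin factor.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    E = np.asarray(E, dtype=float)
    x = water.dipole_moment * E / (BOLTZMANN_J * T)
    u_joule = -water.dipole_moment * E * langevin(x)
    out = joule_to_kj_per_mol(u_joule)
    return out if out.ndim else float(out)


def _minimum_image(d: np.ndarray, box) -> np.ndarray:
    if box is None:
        return d
    box = np.asarray(box, dtype=float)
    return d - box * np.round(d / box)


def _neighbours(i: int, s: ParamStructure, cutoff: float) -> np.ndarray:
    pos = s.positions()
    d = _minimum_image(pos - pos[i], s.box)
    dist = np.linalg.norm(d, axis=1)
    return np.flatnonzero(dist <= cutoff)


def coulomb_field(
    point: np.ndarray,
    neighbour_positions: np.ndarray,
    charges: np.ndarray,
    eps_r_model=None,
    box=None,
) -> float:
    """Electric field strength (V/m) at *point* from partial charges.

    Vector Coulomb sum q_k / (4 pi eps0 eps_r(r_k) r_k^2); the magnitude
    of the resultant is returned.  Distances in nm, charges in e.
    """
    if eps_r_model is None:
        eps_r_model = constant_permittivity(1.0)
    d = _minimum_image(
        np.atleast_2d(neighbour_positions) - np.asarray(point, float), box
    )
    r = np.linalg.norm(d, axis=1)
    r = np.maximum(r, _R_FLOOR)
    eps_r = np.asarray(eps_r_model(r), dtype=float)
    q = np.asarray(charges, dtype=float) * ELEMENTARY_CHARGE
    # field from k points away from a positive charge, i.e. along -d
    mag = q / (4.0 * np.pi * VACUUM_PERMITTIVITY * eps_r * (r * NM) ** 2)
    vec = -(d / r[:, None]) * mag[:, None]
    return float(np.linalg.norm(vec.sum(axis=0)))


def lj_profile(
    i: int,
    s: ParamStructure,
    water: WaterModel = SPCE,
    normal: np.ndarray | None = None,
    grid: np.ndarray | None = None,
    cutoff: float = 1.0,
    combine_lj: bool = True,
) -> np.ndarray:
    """12-6 Lennard-Jones energy (kJ/mol) along atom i's outward normal.

    Parameters are Lorentz-Berthelot combined with the water oxygen when
    *combine_lj*; otherwise the stored values are taken as already
    water-combined.
    """
    if normal is None:
        raise ValueError("an outward normal is required")
    if grid is None:
        grid = np.linspace(0.05, cutoff, 2000)
    idx = _neighbours(i, s, cutoff)
    pos = s.positions()[idx]
    eps_k = s.lj_epsilons()[idx]
    sig_k = s.lj_sigmas()[idx]
    if combine_lj:
        sig_k = 0.5 * (sig_k + water.lj_sigma_O)
        eps_k = np.sqrt(eps_k * water.lj_epsilon_O)
    pts = s.positions()[i] + np.outer(grid, normal)  # (G, 3)
    d = pts[:, None, :] - pos[None, :, :]  # (G, K, 3)
    if s.box is not None:
        box = np.asarray(s.box, dtype=float)
        d -= box * np.round(d / box)
    r = np.sqrt(np.einsum("gkd,gkd->gk", d, d))
    n_floored = int((r < _R_FLOOR).sum())
    if n_floored:
        logger.debug("floored %d grid-point distances", n_floored)
    r = np.maximum(r, _R_FLOOR)
    sr6 = (sig_k[None, :] / r) ** 6
    return np.einsum("gk,k->g", sr6 * sr6 - sr6, 4.0 * eps_k)


def effective_profile(
    i: int,
    s: ParamStructure,
    sas: SASResult,
    water: WaterModel = SPCE,
    config: PotentialConfig | None = None,
) -> PotentialProfile:
    """U_eff = U_vdw + U_c along the SAS normal of surface atom i."""
    config = config or PotentialConfig()
    atom_id = s.atoms[i].id
    if sas.S_loc.get(atom_id, 0.0) <= 0 or atom_id not in sas.normal:
        raise ValueError(
            f"atom {atom_id} has no accessible surface / normal; "
            "select atoms via surface_atoms() first"
        )
    normal = sas.normal[atom_id]
    grid = config.grid()
    u_vdw = lj_profile(
        i, s, water, normal=normal, grid=grid, cutoff=config.cutoff,
        combine_lj=config.combine_lj,
    )
    idx = _neighbours(i, s, config.cutoff)
    charges = s.charges()[idx]
    if np.any(charges != 0.0):
        pos_k = s.positions()[idx]
        base = s.positions()[i]
        pts = base + np.outer(grid, normal)  # (G, 3)
        d = pos_k[None, :, :] - pts[:, None, :]  # (G, K, 3)
        d = _minimum_image(d, s.box)
        r = np.sqrt(np.einsum("gkd,gkd->gk", d, d))
        r = np.maximum(r, _R_FLOOR)
        eps_r = np.asarray(config.eps_r_model(r), dtype=float)
        mag = (charges[None, :] * ELEMENTARY_CHARGE) / (
            4.0 * np.pi * VACUUM_PERMITTIVITY * eps_r * (r * NM) ** 2
        )
        vec = -(d / r[..., None]) * mag[..., None]
        E = np.linalg.norm(vec.sum(axis=1), axis=1)
        u_c = dipole_energy(E, water, config.temperature)
    else:
        u_c = np.zeros_like(grid)
    return PotentialProfile(n_grid=grid, U_vdw=u_vdw, U_c=np.asarray(u_c))


def local_delta(
    p: PotentialProfile,
    T: float = 300.0,
    alpha: float = 0.25,
    refine_tol: float = 1e-9,
) -> float:
    """Width of the trapped region: distance between the zeros of
    U_eff(n) + alpha kB T.

    Returns 0 when the well is shallower than alpha kB T.  With several
    sign changes, the innermost and outermost crossings bracketing the
    global minimum are used (largest trapped region).  Roots are refined
    on a cubic-spline interpolant to *refine_tol* nm.
    """
    if T <= 0 or alpha <= 0:
        raise ValueError("T and alpha must be positive")
    u = np.asarray(p.U_eff, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite values in potential profile")
    level = alpha * KB_KJMOL * T
    if p.well_depth <= level:
        return 0.0
    g = u + level  # roots of g = 0
    n = p.n_grid
    imin = int(np.argmin(u))
    spline = CubicSpline(n, g)

    sign = np.sign(g)
    crossings = np.flatnonzero(sign[:-1] * sign[1:] < 0)

    def _refine(k: int) -> float:
        return float(brentq(spline, n[k], n[k + 1], xtol=refine_tol))

    left = [k for k in crossings if k < imin]
    right = [k for k in crossings if k >= imin]
    if left:
        n1 = _refine(left[0])  # innermost crossing before the minimum
    elif g[0] < 0:
        n1 = float(n[0])  # well extends to the wall side of the grid
    else:
        return 0.0
    if right:
        n2 = _refine(right[-1])  # outermost crossing after the minimum
    else:
        return 0.0
    return max(0.0, n2 - n1)


def mean_delta(
    s: ParamStructure,
    sas: SASResult | None = None,
    water: WaterModel = SPCE,
    config: PotentialConfig | None = None,
) -> ConfinementResult:
    """SAS-weighted mean confinement length over the structure's surface.

        delta = sum_i delta_i S_loc,i / S_tot

    Bulk atoms carry zero SAS weight, so only genuine surface atoms
    contribute.  ``epsilon_mean`` is the equally SAS-weighted well depth
    (the energy entering the supercooled-water route), ``epsilon_max``
    the deepest well encountered.
    """
    config = config or PotentialConfig()
    if sas is None:
        sas = compute_sas(s, probe_radius=config.probe_radius,
                          n_points=config.sas_points)
    if sas.S_tot <= 0:
        raise ValueError("structure has zero accessible surface")
    id_to_index = {a.id: k for k, a in enumerate(s.atoms)}
    delta_i: dict[int, float] = {}
    eps_weighted = 0.0
    delta_weighted = 0.0
    eps_max = 0.0
    for atom_id in surface_atoms(sas, config.surface_area_threshold):
        if atom_id not in sas.normal:
            continue
        prof = effective_profile(id_to_index[atom_id], s, sas, water, config)
        d = local_delta(prof, T=config.temperature, alpha=config.alpha)
        delta_i[atom_id] = d
        w = sas.S_loc[atom_id]
        delta_weighted += d * w
        eps_weighted += prof.well_depth * w
        eps_max = max(eps_max, prof.well_depth)
    return ConfinementResult(
        delta_i=delta_i,
        delta_mean=delta_weighted / sas.S_tot,
        epsilon_mean=eps_weighted / sas.S_tot,
        epsilon_max=eps_max,
        alpha=config.alpha,
    )
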