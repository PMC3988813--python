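"""Solvent-accessible surface areas and outward patch normals.

Shrake-Rupley point sampling: each atom carries an expanded sphere of
radius sigma/2 + probe; the accessible fraction of a deterministic
quasi-uniform point set gives the per-atom area ``S_loc``, and the
centroid of the accessible points defines an outward normal.  The normal
is what the wall-potential module integrates along, so it is computed
here rather than by an external SASA library.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structures import ParamStructure

__all__ = ["SASResult", "compute_sas", "surface_atoms", "DEFAULT_PROBE",
           "DEFAULT_N_POINTS"]

DEFAULT_PROBE = 0.14  # nm, water probe radius
DEFAULT_N_POINTS = 960


@dataclass
class SASResult:
    """Total and per-atom solvent-accessible areas with patch geometry."""

    S_tot: float
    S_loc: dict[int, float]
    normal: dict[int, np.ndarray] = field(default_factory=dict)
    patch_centroid: dict[int, np.ndarray] = field(default_factory=dict)


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def compute_sas(
    s: ParamStructure,
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    radii: np.ndarray | None = None,
) -> SASResult:
    """Shrake-Rupley solvent-accessible surface of a structure.

    Parameters
    ----------
    s
        Structure whose atoms carry LJ sigmas; the SAS atomic radius of
        atom k is ``sigma_k / 2`` unless *radii* overrides it.
    probe_radius
        Probe (water) radius in nm.
    n_points
        Test points per atom; the sphere-closure error scales roughly as
        ``2 / sqrt(n_points)``.

    Notes
    -----
    With a periodic box present, neighbour occlusion uses the minimum
    image convention.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    if n_points < 32:
        raise ValueError("n_points must be >= 32")
    pos = s.positions()
    n_atoms = len(pos)
    if radii is None:
        radii = s.lj_sigmas() / 2.0
    radii = np.asarray(radii, dtype=float)
    expanded = radii + probe_radius
    unit = fibonacci_sphere(n_points)

    box = np.asarray(s.box, dtype=float) if s.box is not None else None
    max_r = expanded.max()
    cutoff = 2.0 * max_r
    if box is not None and cutoff > box.min() / 2.0:
        # minimum image only valid below half the box; fall back to direct
        box_tree = None
    else:
        box_tree = box
    if box_tree is not None:
        tree = cKDTree(np.mod(pos, box_tree), boxsize=box_tree)
    else:
        tree = cKDTree(pos)
    pairs = tree.query_ball_point(
        np.mod(pos, box_tree) if box_tree is not None else pos, cutoff
    )

    S_loc: dict[int, float] = {}
    normal: dict[int, np.ndarray] = {}
    centroid: dict[int, np.ndarray] = {}
    for i in range(n_atoms):
        pts = pos[i] + expanded[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in pairs[i]:
            if j == i:
                continue
            d = pts - pos[j]
            if box is not None:
                d -= box * np.round(d / box)
            accessible &= np.einsum("ij,ij->i", d, d) > expanded[j] ** 2
        frac = accessible.mean()
        area = frac * 4.0 * np.pi * expanded[i] ** 2
        S_loc[s.atoms[i].id] = float(area)
        if accessible.any() and area > 0:
            c = pts[accessible].mean(axis=0)
            centroid[s.atoms[i].id] = c
            v = c - pos[i]
            nv = np.linalg.norm(v)
            if nv > 1e-12:
                normal[s.atoms[i].id] = v / nv
    S_tot = float(sum(S_loc.values()))
    return SASResult(S_tot=S_tot, S_loc=S_loc, normal=normal,
                     patch_centroid=centroid)


def surface_atoms(res: SASResult, threshold: float = 0.0) -> list[int]:
    """Atom ids with accessible area strictly above *threshold*, sorted."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return sorted(i for i, a in res.S_loc.items() if a > threshold)


def write_sas_table(res: SASResult, path) -> None:
    """Export per-atom areas and normals as a text table."""
    lines = ["# atom_id S_loc nx ny nz"]
    for i in sorted(res.S_loc):
        n = res.normal.get(i)
        if n is None:
            lines.append(f"{i} {res.S_loc[i]:.9f} nan nan nan")
        else:
            lines.append(
                f"{i} {res.S_loc[i]:.9f} {n[0]:.6f} {n[1]:.6f} {n[2]:.6f}"
            )
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
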