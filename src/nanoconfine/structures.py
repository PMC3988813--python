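"""Atomistic solid structures: PDB ingestion, synthetic builders, water models.

Structures are plain collections of atoms carrying positions (nm),
Lennard-Jones parameters (kJ/mol, nm) and partial charges (e).  Builders
produce the idealized solids used throughout: spherical nanoparticles,
cylindrical pores, armchair carbon nanotubes and planar slabs, all on
deterministic lattices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .constants import ANGSTROM_TO_NM

__all__ = [
    "Atom",
    "ParamStructure",
    "WaterModel",
    "SPCE",
    "ParameterTable",
    "read_structure",
    "read_table",
    "write_table",
    "build_sphere",
    "build_cylindrical_pore",
    "build_cnt",
    "build_planar_slab",
]


@dataclass(frozen=True)
class Atom:
    """A single solid atom with force-field parameters.

    Positions are in nm, ``lj_epsilon`` in kJ/mol, ``lj_sigma`` in nm and
    ``charge`` in elementary charges.
    """

    id: int
    element: str
    position: tuple[float, float, float]
    lj_epsilon: float
    lj_sigma: float
    charge: float = 0.0
    is_surface: bool = False

    def __post_init__(self) -> None:
        if self.lj_epsilon < 0:
            raise ValueError(f"atom {self.id}: lj_epsilon must be >= 0")
        if self.lj_sigma <= 0:
            raise ValueError(f"atom {self.id}: lj_sigma must be > 0")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.id}: non-finite position")


@dataclass
class ParamStructure:
    """A parameterized solid structure: atoms plus an optional periodic box."""

    atoms: list[Atom]
    box: tuple[float, float, float] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("structure must contain at least one atom")
        ids = [a.id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise ValueError("atom ids must be unique")
        if self.box is not None:
            box = np.asarray(self.box, dtype=float)
            if np.any(box <= 0):
                raise ValueError("box lengths must be positive")
            pos = self.positions()
            if np.any(pos < -1e-9) or np.any(pos > box + 1e-9):
                raise ValueError("all positions must lie inside the box")

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def lj_epsilons(self) -> np.ndarray:
        return np.array([a.lj_epsilon for a in self.atoms], dtype=float)

    def lj_sigmas(self) -> np.ndarray:
        return np.array([a.lj_sigma for a in self.atoms], dtype=float)

    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    def with_charges_zeroed(self) -> "ParamStructure":
        atoms = [replace(a, charge=0.0) for a in self.atoms]
        return ParamStructure(atoms=atoms, box=self.box, label=self.label)

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass(frozen=True)
class WaterModel:
    """Water parameters entering the wall potential and the scaling law.

    Defaults correspond to the rigid three-site SPC/E model at 300 K.
    """

    dipole_moment: float = 7.50e-30  # C m
    lj_sigma_O: float = 0.3166  # nm
    lj_epsilon_O: float = 0.6502  # kJ/mol
    bulk_density: float = 997.0  # kg/m^3
    bulk_diffusivity: float = 2.60e-9  # m^2/s at 300 K
    molecule_mass: float = 2.9915e-26  # kg

    def __post_init__(self) -> None:
        for name in (
            "dipole_moment",
            "lj_sigma_O",
            "lj_epsilon_O",
            "bulk_density",
            "bulk_diffusivity",
            "molecule_mass",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


#: default water model (SPC/E)
SPCE = WaterModel()


@dataclass
class ParameterTable:
    """Map atom type -> (lj_epsilon kJ/mol, lj_sigma nm, charge e)."""

    entries: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def lookup(self, atom_type: str) -> tuple[float, float, float]:
        key = atom_type.strip()
        if key in self.entries:
            return self.entries[key]
        # element-symbol fallback (case-insensitive)
        for cand in (key.upper(), key.capitalize()):
            if cand in self.entries:
                return self.entries[cand]
        raise KeyError(
            f"atom type {atom_type!r} has no entry in the parameter table"
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ParameterTable":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        entries = {}
        for key, val in raw.items():
            entries[str(key)] = (
                float(val["epsilon"]),
                float(val["sigma"]),
                float(val.get("charge", 0.0)),
            )
        return cls(entries)


def read_structure(path: str | Path, table: ParameterTable) -> ParamStructure:
    """Read a PDB file into a :class:`ParamStructure`.

    Coordinates are converted from A to nm.  Atom types are resolved
    against *table* by atom name first, then element symbol.  Only the
    first altloc of each atom is kept.
    """
    from Bio.PDB import PDBParser
    import warnings

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prevalidate_pdb(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = parser.get_structure(path.stem, str(path))[0]

    atoms: list[Atom] = []
    unresolved: set[str] = set()
    idx = 0
    for atom in model.get_atoms():
        if atom.get_altloc() not in (" ", "", "A"):
            continue
        name = atom.get_name()
        element = (atom.element or name[:1]).strip() or name[:1]
        try:
            eps, sig, q = table.lookup(name)
        except KeyError:
            # "X" is Biopython's unknown-element placeholder, not a type
            if element == "X" and name.upper() != "X":
                unresolved.add(name)
                continue
            try:
                eps, sig, q = table.lookup(element)
            except KeyError:
                unresolved.add(name)
                continue
        pos = tuple(float(c) * ANGSTROM_TO_NM for c in atom.coord)
        atoms.append(
            Atom(id=idx, element=element, position=pos, lj_epsilon=eps,
                 lj_sigma=sig, charge=q)
        )
        idx += 1
    if unresolved:
        raise KeyError(
            "unresolvable atom type(s): " + ", ".join(sorted(unresolved))
        )
    return ParamStructure(atoms=atoms, label=path.stem)


def _prevalidate_pdb(path: Path) -> None:
    """Light column check on ATOM/HETATM records; errors carry line numbers."""
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            if len(line) < 54:
                raise ValueError(f"{path}:{lineno}: truncated coordinate record")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: malformed coordinates in record"
                ) from exc


_TABLE_HEADER = "# id type x y z epsilon sigma charge surface"


def write_table(s: ParamStructure, path: str | Path) -> None:
    """Serialize a structure as a whitespace-delimited text table."""
    lines = [_TABLE_HEADER]
    if s.box is not None:
        lines.append("# box %.9f %.9f %.9f" % tuple(s.box))
    for a in s.atoms:
        lines.append(
            "%d %s %.9f %.9f %.9f %.9f %.9f %.9f %d"
            % (a.id, a.element, *a.position, a.lj_epsilon, a.lj_sigma,
               a.charge, int(a.is_surface))
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_table(path: str | Path) -> ParamStructure:
    """Read a structure from the text-table format of :func:`write_table`."""
    atoms: list[Atom] = []
    box = None
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if parts and parts[0] == "box":
                box = tuple(float(x) for x in parts[1:4])
            continue
        parts = line.split()
        if len(parts) != 9:
            raise ValueError(f"{path}:{lineno}: expected 9 columns")
        atoms.append(
            Atom(
                id=int(parts[0]),
                element=parts[1],
                position=(float(parts[2]), float(parts[3]), float(parts[4])),
                lj_epsilon=float(parts[5]),
                lj_sigma=float(parts[6]),
                charge=float(parts[7]),
                is_surface=bool(int(parts[8])),
            )
        )
    return ParamStructure(atoms=atoms, box=box, label=Path(path).stem)


def _atoms_from_lattice(
    points: Iterable[tuple[float, float, float]],
    atom_type: str,
    table: ParameterTable,
    surface_flags: Iterable[bool] | None = None,
) -> list[Atom]:
    eps, sig, q = table.lookup(atom_type)
    flags = list(surface_flags) if surface_flags is not None else None
    atoms = []
    for i, p in enumerate(points):
        surf = flags[i] if flags is not None else False
        atoms.append(
            Atom(id=i, element=atom_type, position=tuple(p), lj_epsilon=eps,
                 lj_sigma=sig, charge=q, is_surface=surf)
        )
    return atoms


def build_sphere(
    radius: float, spacing: float, atom_type: str, table: ParameterTable
) -> ParamStructure:
    """Simple-cubic lattice clipped to a sphere centred at the origin."""
    if not (radius > spacing > 0):
        raise ValueError("require radius > spacing > 0")
    n = int(math.floor(radius / spacing))
    grid = np.arange(-n, n + 1) * spacing
    xx, yy, zz = np.meshgrid(grid, grid, grid, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    keep = np.linalg.norm(pts, axis=1) <= radius + 1e-12
    pts = pts[keep]
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))
    pts = pts[order]
    atoms = _atoms_from_lattice(pts, atom_type, table)
    return ParamStructure(atoms=atoms, label=f"sphere_r{radius:g}")


def build_cylindrical_pore(
    pore_radius: float,
    wall_thickness: float,
    length: float,
    spacing: float,
    atom_type: str,
    table: ParameterTable,
) -> ParamStructure:
    """Annular lattice shell around an axial (z) pore.

    Atoms occupy radial distances in [pore_radius, pore_radius + wall
    thickness]; the axial direction is periodic with period *length*.
    """
    if min(pore_radius, wall_thickness, length, spacing) <= 0:
        raise ValueError("all dimensions must be positive")
    if wall_thickness < spacing:
        raise ValueError("wall_thickness must be >= spacing")
    r_out = pore_radius + wall_thickness
    n = int(math.floor(r_out / spacing))
    grid = np.arange(-n, n + 1) * spacing
    xx, yy = np.meshgrid(grid, grid, indexing="ij")
    xy = np.column_stack([xx.ravel(), yy.ravel()])
    rad = np.linalg.norm(xy, axis=1)
    keep = (rad >= pore_radius - 1e-12) & (rad <= r_out + 1e-12)
    xy = xy[keep]
    nz = max(1, int(round(length / spacing)))
    zs = np.arange(nz) * spacing
    pts = np.concatenate(
        [np.column_stack([xy, np.full(len(xy), z)]) for z in zs]
    )
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))
    pts = pts[order]
    # shift into a positive box for the periodic axial direction
    half = r_out + spacing
    pts[:, 0] += half
    pts[:, 1] += half
    box = (2 * half, 2 * half, nz * spacing)
    atoms = _atoms_from_lattice(pts, atom_type, table)
    return ParamStructure(atoms=atoms, box=box,
                          label=f"pore_r{pore_radius:g}")


#: C-C bond length in graphene, nm
CC_BOND = 0.142

#: default carbon LJ parameters for nanotube walls (already water-combined)
CNT_SIGMA = 0.36
CNT_EPSILON = 0.29


def cnt_diameter(n: int, m: int, a_cc: float = CC_BOND) -> float:
    """Diameter of an (n, m) nanotube from the rolled-graphene formula."""
    a = math.sqrt(3.0) * a_cc
    return a * math.sqrt(n * n + n * m + m * m) / math.pi


def build_cnt(
    n: int, m: int, length: float, table: ParameterTable | None = None
) -> ParamStructure:
    """Armchair (n, n) single-wall carbon nanotube along z.

    Carbon atoms are neutral; LJ parameters default to pre-combined
    carbon-water values (sigma 0.36 nm, epsilon 0.29 kJ/mol) unless a
    table supplies a "C" entry.
    """
    if n != m:
        raise ValueError(
            f"chirality ({n},{m}) unsupported: only armchair (n=m) tubes"
        )
    if length <= 0:
        raise ValueError("length must be positive")
    if table is not None and "C" in table.entries:
        eps, sig, q = table.lookup("C")
    else:
        eps, sig, q = CNT_EPSILON, CNT_SIGMA, 0.0

    a_cc = CC_BOND
    a = math.sqrt(3.0) * a_cc
    diameter = cnt_diameter(n, m, a_cc)
    radius = diameter / 2.0
    circumference = math.pi * diameter
    period = a  # armchair translational period along the axis

    # unrolled armchair unit cell: 4n atoms in (u, v) in [0, C) x [0, T)
    cell_uv = []
    for j in range(n):
        u0 = j * 3.0 * a_cc
        cell_uv.extend(
            [
                (u0 + 0.0, 0.0),
                (u0 + a_cc, 0.0),
                (u0 + 1.5 * a_cc, period / 2.0),
                (u0 + 2.5 * a_cc, period / 2.0),
            ]
        )
    n_cells = max(1, int(round(length / period)))
    pts = []
    for c in range(n_cells):
        z0 = c * period
        for u, v in cell_uv:
            phi = 2.0 * math.pi * u / circumference
            pts.append(
                (radius * math.cos(phi), radius * math.sin(phi), z0 + v)
            )
    pts = np.asarray(pts)
    shift = radius + 0.5
    pts[:, 0] += shift
    pts[:, 1] += shift
    box = (2 * shift, 2 * shift, n_cells * period)
    atoms = [
        Atom(id=i, element="C", position=tuple(p), lj_epsilon=eps,
             lj_sigma=sig, charge=q)
        for i, p in enumerate(pts)
    ]
    return ParamStructure(atoms=atoms, box=box, label=f"cnt_{n}_{m}")


def build_planar_slab(
    area: float,
    layers: int,
    spacing: float,
    atom_type: str,
    table: ParameterTable,
) -> ParamStructure:
    """Rectangular simple-cubic slab; outward normal +z for the top layer.

    *area* is the in-plane (x, y) area in nm^2; the slab is laterally
    periodic.  Atoms of the top layer are flagged ``is_surface``.
    """
    if layers < 1:
        raise ValueError("layers must be >= 1")
    if area <= 0 or spacing <= 0:
        raise ValueError("area and spacing must be positive")
    side = math.sqrt(area)
    nxy = max(1, int(round(side / spacing)))
    xs = np.arange(nxy) * spacing
    pts = []
    flags = []
    for k in range(layers):
        z = k * spacing
        top = k == layers - 1
        for x in xs:
            for y in xs:
                pts.append((x, y, z))
                flags.append(top)
    box = (nxy * spacing, nxy * spacing, layers * spacing + 10.0)
    atoms = _atoms_from_lattice(pts, atom_type, table, surface_flags=flags)
    return ParamStructure(atoms=atoms, box=box, label="slab")
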