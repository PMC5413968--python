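"""Density grids, atomic models and their file formats.

The whole analysis operates on dense scalar fields sampled on an isotropic
Cartesian grid (``DensityMap``) and on flat lists of atoms (``StructureModel``).
Maps are exchanged as CCP4/MRC volumes (mode 2, 32-bit float) and models as
PDB coordinate files, both through :mod:`gemmi`.

Grid convention: the center of voxel ``(0, 0, 0)`` sits at ``origin`` and the
Cartesian position of voxel ``(i, j, k)`` is ``origin + index * spacing``.
Voxels excluded from analysis (e.g. outside a warped map's support) are
marked with NaN and propagate as "missing" through all statistics.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "DensityMap",
    "Atom",
    "StructureModel",
    "Dataset",
    "MapFormatError",
    "ModelFormatError",
    "read_map",
    "write_map",
    "read_model",
    "write_model",
]


class MapFormatError(ValueError):
    """Raised for unreadable or unsupported volume files."""


class ModelFormatError(ValueError):
    """Raised for unreadable coordinate files."""


@dataclass
class DensityMap:
    """A scalar field on an isotropic, axis-aligned Cartesian grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Density samples; NaN marks missing voxels.
    spacing : float
        Voxel edge length in Angstrom (isotropic).
    origin : ndarray, shape (3,)
        Cartesian position (Angstrom) of the center of voxel (0, 0, 0).
    label : str
        Free-text provenance.
    """

    values: np.ndarray
    spacing: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if min(self.values.shape) < 2:
            raise ValueError("grid needs at least 2 voxels per axis")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in cubic Angstrom."""
        return float(self.spacing) ** 3

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of missing (NaN) voxels."""
        return np.isnan(self.values)

    def index_to_position(self, indices: np.ndarray) -> np.ndarray:
        """Cartesian positions (Å) of voxel indices (…, 3)."""
        return np.asarray(indices, dtype=float) * self.spacing + self.origin

    def position_to_index(self, positions: np.ndarray) -> np.ndarray:
        """Fractional voxel indices (…, 3) of Cartesian positions (Å)."""
        return (np.asarray(positions, dtype=float) - self.origin) / self.spacing

    def grid_positions(self) -> np.ndarray:
        """All voxel-center positions as an (nx, ny, nz, 3) array."""
        idx = np.stack(
            np.meshgrid(*(np.arange(n) for n in self.shape), indexing="ij"), axis=-1
        )
        return self.index_to_position(idx)

    def like(self, values: np.ndarray, label: str | None = None) -> "DensityMap":
        """A new map on this grid with different values."""
        return DensityMap(
            values=np.asarray(values, dtype=np.float64),
            spacing=self.spacing,
            origin=self.origin.copy(),
            label=self.label if label is None else label,
        )

    def copy(self) -> "DensityMap":
        return replace(self, values=self.values.copy(), origin=self.origin.copy())


@dataclass(frozen=True)
class Atom:
    chain: str
    resnum: int
    resname: str
    name: str
    element: str
    altloc: str  # "" for the shared/blank conformer
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    b_factor: float = 20.0

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chain, self.resnum, self.name, self.altloc)

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    def moved(self, position: Sequence[float], **kw) -> "Atom":
        x, y, z = position
        return replace(self, x=float(x), y=float(y), z=float(z), **kw)


@dataclass
class StructureModel:
    """A flat atom list with conformer (altloc) labels."""

    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [a.key for a in self.atoms]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (chain, resnum, atom, altloc) keys")
        for a in self.atoms:
            if not 0.0 <= a.occupancy <= 1.0:
                raise ValueError(f"occupancy out of [0,1] for {a.key}")
            if a.b_factor < 0:
                raise ValueError(f"negative B-factor for {a.key}")

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def coordinates(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms]).reshape(-1, 3)

    def select(self, predicate) -> "StructureModel":
        return StructureModel([a for a in self.atoms if predicate(a)])

    def ca_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.name == "CA"]

    def by_key(self) -> dict[tuple, Atom]:
        return {a.key: a for a in self.atoms}


@dataclass
class Dataset:
    """One crystal: an aligned map, its refined model and nominal resolution."""

    id: str
    map: DensityMap
    model: StructureModel
    resolution: float
    role: str = "ground-state-candidate"  # or "putative-changed"

    def __post_init__(self) -> None:
        if not self.resolution > 0:
            raise ValueError("resolution must be positive")


# ---------------------------------------------------------------------------
# CCP4/MRC volumes

_ANISOTROPY_TOL = 1e-3


def read_map(path: str | os.PathLike) -> DensityMap:
    """Read a CCP4/MRC volume into a :class:`DensityMap`.

    The voxel size must be isotropic within 1e-3 Å; anisotropic grids are
    rejected because the statistical model compares voxels across datasets
    on one common cubic lattice.
    """
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise MapFormatError(f"cannot read map {path!r}: {exc}") from exc
    grid = ccp4.grid
    shape = (grid.nu, grid.nv, grid.nw)
    cell = grid.unit_cell
    steps = np.array([cell.a / shape[0], cell.b / shape[1], cell.c / shape[2]])
    if steps.max() - steps.min() > _ANISOTROPY_TOL:
        raise MapFormatError(
            f"anisotropic voxels {steps} exceed {_ANISOTROPY_TOL} Å tolerance"
        )
    values = np.array(grid, copy=True, dtype=np.float64)
    origin = np.array([ccp4.header_float(w) for w in (50, 51, 52)], dtype=float)
    if not np.all(np.isfinite(values)):
        # MRC uses huge sentinels for masked voxels in some producers; map to NaN
        values[~np.isfinite(values)] = np.nan
    return DensityMap(values=values, spacing=float(steps.mean()), origin=origin,
                      label=str(path))


def write_map(density: DensityMap, path: str | os.PathLike) -> None:
    """Write a :class:`DensityMap` as a CCP4/MRC mode-2 volume (P1 cell)."""
    arr = np.asarray(density.values, dtype=np.float32)
    grid = gemmi.FloatGrid(arr)
    nx, ny, nz = density.shape
    grid.unit_cell = gemmi.UnitCell(
        nx * density.spacing, ny * density.spacing, nz * density.spacing, 90, 90, 90
    )
    grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for word, val in zip((50, 51, 52), density.origin):
        ccp4.set_header_float(word, float(val))
    try:
        ccp4.write_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot write map {path!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# PDB models

def read_model(path: str | os.PathLike) -> StructureModel:
    """Read ATOM/HETATM records (first model), altloc column respected."""
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError, OSError) as exc:
        raise ModelFormatError(f"cannot read model {path!r}: {exc}") from exc
    atoms: list[Atom] = []
    if len(st) == 0:
        return StructureModel([])
    for chain in st[0]:
        for res in chain:
            for a in res:
                alt = a.altloc if a.altloc not in ("\0", " ") else ""
                atoms.append(
                    Atom(
                        chain=chain.name,
                        resnum=res.seqid.num,
                        resname=res.name,
                        name=a.name,
                        element=a.element.name,
                        altloc=alt,
                        x=a.pos.x,
                        y=a.pos.y,
                        z=a.pos.z,
                        # PDB stores occ/B with 2 decimals; snap to format precision
                        occupancy=round(a.occ, 2),
                        b_factor=round(a.b_iso, 2),
                    )
                )
    return StructureModel(atoms)


def write_model(model: StructureModel, path: str | os.PathLike) -> None:
    """Write a model as PDB; conformer labels go to the altloc column."""
    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(1, 1, 1, 90, 90, 90)
    st.spacegroup_hm = "P 1"
    gm = gemmi.Model("1")
    # gemmi containers copy on add, so residues/chains must be complete
    # before insertion
    residues: dict[tuple[str, int], gemmi.Residue] = {}
    chain_order: list[str] = []
    for atom in model.atoms:
        rkey = (atom.chain, atom.resnum)
        if rkey not in residues:
            res = gemmi.Residue()
            res.name = atom.resname
            res.seqid = gemmi.SeqId(atom.resnum, " ")
            residues[rkey] = res
        if atom.chain not in chain_order:
            chain_order.append(atom.chain)
        ga = gemmi.Atom()
        ga.name = atom.name
        ga.altloc = atom.altloc if atom.altloc else "\0"
        ga.pos = gemmi.Position(atom.x, atom.y, atom.z)
        ga.occ = atom.occupancy
        ga.b_iso = atom.b_factor
        ga.element = gemmi.Element(atom.element)
        residues[rkey].add_atom(ga)
    for chain_name in chain_order:
        chain = gemmi.Chain(chain_name)
        for (cname, _), res in residues.items():
            if cname == chain_name:
                chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    try:
        st.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot write model {path!r}: {exc}") from exc
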