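"""Synthetic multi-crystal fragment screens with known ground truth.

Generates ensembles of density maps that follow, by construction, the
statistical structure the analysis assumes: each dataset's map is the
low-passed density of a pseudo-protein, plus per-voxel natural variation
(standard deviation ``s_m``, nonzero inside designated "variable regions"),
plus per-dataset noise of standard deviation ``sigma_i``.  Event datasets
superpose a changed-state density (shifted side chain plus a small ligand)
at partial occupancy before the noise is added.  The hidden parameters —
true mean map, s-field, per-dataset sigma, per-event occupancy and
changed-state density — are returned as a :class:`SyntheticTruth` so every
downstream estimator can be tested for recovery.

The per-dataset resolution low-pass applies to the *structural* density
only; variation and noise are injected per voxel afterwards, so that the
recorded ``sigma_i`` and ``s`` are exactly the standard deviations present
in the final map (the quantities the estimators target).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import affine_transform

from .grid_io import Atom, Dataset, DensityMap, StructureModel
from .resolution import lowpass_truncate

__all__ = [
    "ELECTRON_COUNTS",
    "SyntheticConfig",
    "SyntheticTruth",
    "density_from_atoms",
    "resolution_blur",
    "random_protein",
    "simulate_screen",
    "degrade_reference",
]

ELECTRON_COUNTS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "P": 15, "S": 16, "CL": 17,
    "Cl": 17, "BR": 35, "Br": 35,
}

EIGHT_PI_SQ = 8.0 * np.pi**2

_WATER_BASE = 500  # pocket waters: chain W, resnum 500 + 10*pocket + j


def resolution_blur(d: float) -> float:
    """Gaussian blur width (Å) emulating a resolution-d map's smoothing."""
    return 0.225 * d


@dataclass
class EventSpec:
    """An injected changed state: a small ligand near a designated side
    chain, which is itself displaced."""

    occupancy: float
    residue_index: int = 0  # which designated side chain hosts the event
    n_ligand_atoms: int = 8
    shift: float = 1.5  # side-chain displacement, Å

    def __post_init__(self) -> None:
        if not 0.0 < self.occupancy <= 1.0:
            raise ValueError("occupancy must be in (0, 1]")


@dataclass
class SyntheticConfig:
    """Study conditions for a simulated screen.

    Defaults emulate a modest fragment-screening campaign: 40 hit-free
    crystals on a 48^3 grid at 0.5 Å spacing, map noise 5–15% of a
    well-ordered carbon peak, resolutions spread over 1.8–2.2 Å to exercise
    binning, a 60-residue pseudo-protein and one naturally variable region.
    """

    n_ground: int = 40
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: float = 0.5
    protein: StructureModel | None = None
    n_residues: int = 60
    n_side_chains: int = 3
    sigma_range: tuple[float, float] = (0.05, 0.15)
    variable_regions: list[tuple[np.ndarray, float, float]] | None = None
    n_variable_regions: int = 1
    variable_region_radius: float = 3.0
    variable_region_s: float = 0.1
    events: list[EventSpec] = field(default_factory=list)
    non_isomorphism: tuple[float, float] = (0.0, 0.0)  # (Å shift, ° rotation)
    resolution_range: tuple[float, float] = (1.8, 2.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ground < 2:
            raise ValueError("need at least 2 ground datasets")
        if not (self.sigma_range[0] > 0 and self.sigma_range[1] >= self.sigma_range[0]):
            raise ValueError("sigma_range must be positive and ordered")
        if self.resolution_range[0] < 2 * self.spacing:
            raise ValueError("finest resolution below the grid Nyquist limit")


@dataclass
class SyntheticTruth:
    mu: DensityMap
    s: DensityMap
    sigma: dict[str, float]
    events: list[dict] = field(default_factory=list)  # mask, occupancy, nu, id
    protein: StructureModel | None = None


def density_from_atoms(
    atoms: StructureModel | list[Atom],
    grid: DensityMap,
    blur: float = 0.0,
    cutoff_sigmas: float = 5.0,
    margin: float = 5.0,
) -> DensityMap:
    """Sum of isotropic atom-centered Gaussians on the given grid.

    Each atom contributes a normalized Gaussian of variance
    ``B/(8 pi^2) + blur^2`` scaled by ``occupancy * electron count``, so the
    grid integral of one atom approximates its electron count.  Linear in
    the atom list.
    """
    atom_list = list(atoms)
    out = np.zeros(grid.shape)
    lo = grid.origin - margin
    hi = grid.index_to_position(np.array(grid.shape) - 1) + margin
    axes = [np.arange(n) * grid.spacing + grid.origin[d]
            for d, n in enumerate(grid.shape)]
    for atom in atom_list:
        pos = atom.position
        if np.any(pos < lo) or np.any(pos > hi):
            raise ValueError(
                f"atom {atom.key} at {pos} lies outside the grid + {margin} Å margin"
            )
        var = atom.b_factor / EIGHT_PI_SQ + blur**2
        if var <= 0:
            raise ValueError("zero-width atom (B = 0 and no blur)")
        amp = atom.occupancy * ELECTRON_COUNTS.get(atom.element.upper(), 6)
        amp /= (2 * np.pi * var) ** 1.5
        half = cutoff_sigmas * np.sqrt(var)
        sl, gs = [], []
        for d in range(3):
            i0 = max(0, int(np.floor((pos[d] - half - grid.origin[d]) / grid.spacing)))
            i1 = min(grid.shape[d], int(np.ceil((pos[d] + half - grid.origin[d]) / grid.spacing)) + 1)
            if i1 <= i0:
                break
            sl.append(slice(i0, i1))
            gs.append(np.exp(-((axes[d][i0:i1] - pos[d]) ** 2) / (2 * var)))
        else:
            out[tuple(sl)] += amp * (
                gs[0][:, None, None] * gs[1][None, :, None] * gs[2][None, None, :]
            )
    return grid.like(out, label="model-density")


def random_protein(
    grid: DensityMap,
    n_residues: int = 60,
    n_side_chains: int = 3,
    rng: np.random.Generator | None = None,
    step: float = 3.8,
    min_separation: float = 3.0,
    margin: float = 5.0,
) -> StructureModel:
    """A pseudo-protein: Cα trace on a self-avoiding random walk inside the
    grid, with a few designated side-chain (CB) atoms for event injection.
    The walk backtracks out of dead ends, so dense folds in small boxes
    still terminate."""
    rng = np.random.default_rng() if rng is None else rng
    lo = grid.origin + margin
    hi = grid.index_to_position(np.array(grid.shape) - 1) - margin
    center = (lo + hi) / 2
    coords = [center.copy()]
    attempts = 0
    rejections = 0
    while len(coords) < n_residues:
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        cand = coords[-1] + step * direction
        attempts += 1
        if attempts > 200000:
            raise RuntimeError("self-avoiding walk failed; enlarge the grid")
        ok = not (np.any(cand < lo) or np.any(cand > hi))
        if ok and len(coords) > 1:
            d = np.linalg.norm(np.array(coords[:-1]) - cand, axis=1)
            ok = d.min() >= min_separation
        if not ok:
            rejections += 1
            if rejections > 200 and len(coords) > 1:  # dead end: back up
                coords.pop()
                rejections = 0
            continue
        rejections = 0
        coords.append(cand)
    atoms = []
    sc_residues = set(np.linspace(5, n_residues - 5, n_side_chains).astype(int))
    all_ca = np.array(coords)
    pocket = 0
    for i, pos in enumerate(coords):
        resnum = i + 1
        atoms.append(Atom("A", resnum, "ALA", "CA", "C", "",
                          *pos, occupancy=1.0, b_factor=20.0))
        if i in sc_residues:
            # point the side chain and its solvent pocket into clear
            # solvent: among candidate directions, take the site farthest
            # from the rest of the chain (a surface pocket, not a clash)
            best_dir, best_score = None, -np.inf
            others = np.delete(all_ca, i, axis=0)
            for _ in range(200):
                u = rng.standard_normal(3)
                u /= np.linalg.norm(u)
                site_c = pos + 6.0 * u
                if np.any(site_c < lo + 1.0) or np.any(site_c > hi - 1.0):
                    continue
                score = np.linalg.norm(others - site_c, axis=1).min()
                if score > best_score:
                    best_dir, best_score = u, score
            if best_dir is None:
                best_dir = np.array([1.0, 0.0, 0.0])
            cb = pos + 1.5 * best_dir
            atoms.append(Atom("A", resnum, "ALA", "CB", "C", "",
                              *cb, occupancy=1.0, b_factor=22.0))
            # ordered solvent ringing the pocket; a bound ligand displaces
            # these waters, so the site carries ground-state density that is
            # dissimilar to the ligand, while the ligand's own positive
            # difference density stays in one piece at the pocket center
            site = pos + 6.0 * best_dir
            for j in range(4):
                u = rng.standard_normal(3)
                u /= np.linalg.norm(u)
                wpos = site + 2.8 * u
                atoms.append(Atom("W", _WATER_BASE + 10 * pocket + j, "HOH",
                                  "O", "O", "", *wpos,
                                  occupancy=1.0, b_factor=30.0))
            pocket += 1
    return StructureModel(atoms)


def _make_ligand(site: np.ndarray, n_atoms: int, rng: np.random.Generator,
                 avoid: np.ndarray | None = None) -> list[Atom]:
    """A compact bonded cluster of carbons at a site: atoms grow off
    existing ones at bond length, stay within 2.2 Å of the center and clear
    of ``avoid`` positions (the displaced waters), so the bound-state
    density is contiguous yet dissimilar from the solvent it replaces."""
    coords: list[np.ndarray] = [site.copy()]
    attempts = 0
    while len(coords) < n_atoms:
        attempts += 1
        if attempts > 50000:
            raise RuntimeError("ligand placement failed")
        base = coords[rng.integers(len(coords))]
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        cand = base + 1.5 * direction
        if np.linalg.norm(cand - site) > 2.2:
            continue
        if avoid is not None and len(avoid):
            if np.linalg.norm(avoid - cand, axis=1).min() < 1.5:
                continue
        if np.linalg.norm(np.array(coords) - cand, axis=1).min() < 1.2:
            continue
        coords.append(cand)
    return [
        Atom("L", 900 + k, "LIG", f"C{k + 1}", "C", "",
             *pos, occupancy=1.0, b_factor=25.0)
        for k, pos in enumerate(coords)
    ]


def _changed_model(protein: StructureModel, spec: EventSpec,
                   rng: np.random.Generator,
                   grid: DensityMap) -> tuple[StructureModel, np.ndarray]:
    """The bound state: ligand replacing the pocket waters, side chain shifted.

    The ligand cluster is centered on the pocket's ordered waters (which it
    displaces), so the event site overlaps genuine ground-state density —
    the situation the background-correction contrast scan relies on.
    """
    side_chains = [a for a in protein if a.name == "CB"]
    if not side_chains:
        raise ValueError("protein has no designated side chains")
    k = spec.residue_index % len(side_chains)
    sc = side_chains[k]
    ca = next(a for a in protein
              if a.chain == sc.chain and a.resnum == sc.resnum and a.name == "CA")
    waters = [a for a in protein
              if a.chain == "W" and _WATER_BASE + 10 * k <= a.resnum < _WATER_BASE + 10 * (k + 1)]
    if waters:
        site = np.mean([w.position for w in waters], axis=0)
    else:
        site = sc.position + 2.5 * (sc.position - ca.position) / np.linalg.norm(
            sc.position - ca.position)
    lo = grid.origin + 4.0
    hi = grid.index_to_position(np.array(grid.shape) - 1) - 4.0
    site = np.clip(site, lo, hi)
    water_coords = np.array([w.position for w in waters]).reshape(-1, 3)
    ligand = _make_ligand(site, spec.n_ligand_atoms, rng, avoid=water_coords)
    away = sc.position - ca.position
    away /= np.linalg.norm(away)
    perp = np.cross(away, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(away, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    water_set = set(id(w) for w in waters)
    atoms = []
    for a in protein:
        if a is sc:
            atoms.append(a.moved(sc.position + spec.shift * perp))
        elif id(a) in water_set:
            continue  # pocket solvent displaced by the ligand
        else:
            atoms.append(a)
    atoms.extend(ligand)
    return StructureModel(atoms), site


def _rigid_jitter_map(values: np.ndarray, R: np.ndarray, shift_vox: np.ndarray,
                      center_vox: np.ndarray) -> np.ndarray:
    """Resample a map under the rigid motion x -> R (x - c) + c + shift."""
    # affine_transform maps output index o to input index M @ o + offset
    M = R.T
    offset = center_vox - M @ (center_vox + shift_vox)
    return affine_transform(values, M, offset=offset, order=1, mode="nearest")


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * K @ K


def simulate_screen(config: SyntheticConfig) -> tuple[list[Dataset], SyntheticTruth]:
    """Generate a full synthetic screen; reproducible from ``config.seed``.

    Ground datasets: ``lowpass(mu) + s_field * xi + sigma_i * eps`` with
    xi, eps per-voxel standard normal.  Event datasets mix
    ``(1 - o) * ground + o * changed`` in the structural part before noise.
    """
    rng = np.random.default_rng(config.seed)
    grid = DensityMap(np.zeros(config.grid_shape), config.spacing)
    protein = config.protein or random_protein(
        grid, config.n_residues, config.n_side_chains, rng
    )
    base_blur = resolution_blur(config.resolution_range[0])
    mu = density_from_atoms(protein, grid, blur=base_blur)

    s_field = np.zeros(config.grid_shape)
    regions = config.variable_regions
    if regions is None:
        regions = []
        ca = protein.ca_atoms()
        for k in range(config.n_variable_regions):
            anchor = ca[(len(ca) // (config.n_variable_regions + 1)) * (k + 1)]
            regions.append((anchor.position, config.variable_region_radius,
                            config.variable_region_s))
    pos_grid = grid.grid_positions()
    for center, radius, s_val in regions:
        dist = np.linalg.norm(pos_grid - np.asarray(center), axis=-1)
        s_field[dist <= radius] = s_val
    truth = SyntheticTruth(
        mu=grid.like(mu.values.copy(), label="true-mu"),
        s=grid.like(s_field.copy(), label="true-s"),
        sigma={},
        protein=protein,
    )

    datasets: list[Dataset] = []
    n_total = config.n_ground + len(config.events)
    resolutions = rng.uniform(*config.resolution_range, size=n_total)
    sigmas = rng.uniform(*config.sigma_range, size=n_total)

    def finish(idx: int, structural: DensityMap, model: StructureModel,
               role: str, ds_id: str) -> Dataset:
        d_i, sigma_i = float(resolutions[idx]), float(sigmas[idx])
        base = lowpass_truncate(structural, d_i)
        values = base.values + s_field * rng.standard_normal(config.grid_shape)
        values = values + sigma_i * rng.standard_normal(config.grid_shape)
        out_model = model
        shift_mag, rot_mag = config.non_isomorphism
        if shift_mag > 0 or rot_mag > 0:
            shift = shift_mag * rng.standard_normal(3)
            R = _rotation_matrix(rng.standard_normal(3),
                                 np.deg2rad(rot_mag) * rng.standard_normal())
            center = grid.index_to_position((np.array(grid.shape) - 1) / 2)
            values = _rigid_jitter_map(
                values, R, shift / grid.spacing,
                (np.array(grid.shape) - 1) / 2,
            )
            out_model = StructureModel([
                a.moved(R @ (a.position - center) + center + shift)
                for a in model
            ])
        truth.sigma[ds_id] = sigma_i
        return Dataset(
            id=ds_id,
            map=grid.like(values, label=ds_id),
            model=out_model,
            resolution=d_i,
            role=role,
        )

    for i in range(config.n_ground):
        ds_id = f"ground_{i:03d}"
        datasets.append(finish(i, mu, protein, "ground-state-candidate", ds_id))

    for j, spec in enumerate(config.events):
        ds_id = f"event_{j:03d}"
        changed, site = _changed_model(protein, spec, rng, grid)
        nu = density_from_atoms(changed, grid, blur=base_blur)
        mixed = grid.like((1 - spec.occupancy) * mu.values
                          + spec.occupancy * nu.values)
        ds = finish(config.n_ground + j, mixed, protein, "putative-changed", ds_id)
        datasets.append(ds)
        sigma_mid = float(np.mean(config.sigma_range))
        signal = spec.occupancy * np.abs(nu.values - mu.values)
        # approximate detectable region: where the injected signal clears the
        # typical noise, guaranteed non-empty for weak events
        thresh = min(2.5 * sigma_mid, 0.5 * float(signal.max()))
        truth.events.append({
            "dataset_id": ds_id,
            "occupancy": spec.occupancy,
            "site": site,
            "nu": nu,
            "mask": signal > thresh,
        })
    return datasets, truth


def degrade_reference(
    datasets: list[Dataset],
    truth: SyntheticTruth,
    jitter: float,
    weight: float = 0.3,
    seed: int = 0,
) -> list[Dataset]:
    """Emulate phase error from a corrupted reference model.

    Each map is blended toward the density of a coordinate-jittered copy of
    the true protein: ``map' = (1 - w) * map + w * rho(jittered model)``.
    ``jitter = 0`` (or ``weight = 0``) is the identity.  The recorded truth
    is untouched — the point is to test robustness against it.
    """
    if jitter < 0:
        raise ValueError("jitter must be non-negative")
    if jitter == 0 or weight == 0:
        return datasets
    rng = np.random.default_rng(seed)
    if truth.protein is None:
        raise ValueError("truth carries no protein model")
    out = []
    for ds in datasets:
        wrong = StructureModel([
            a.moved(a.position + jitter * rng.standard_normal(3))
            for a in truth.protein
        ])
        wrong_density = density_from_atoms(
            wrong, ds.map, blur=resolution_blur(ds.resolution)
        )
        blended = (1 - weight) * ds.map.values + weight * wrong_density.values
        out.append(Dataset(ds.id, ds.map.like(blended, label=f"degraded:{ds.id}"),
                           ds.model, ds.resolution, ds.role))
    return out
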