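"""Ensemble model construction and real-space validation metrics.

Ligands found by event maps bind at partial occupancy, so the deposited
model must carry *both* states: the changed state (ligand plus induced
protein shifts) and the ground state it displaces.  ``merge_ensemble``
builds that two-state model: atoms identical in both states stay once with
a blank altloc; ground-only or moved atoms get one fresh conformer label,
changed-only or moved atoms another, and paired conformer occupancies are
constrained to sum to one.  The changed-state occupancy is initialized to
``2 * (1 - BDC)``, clamped away from degenerate values.

Validation follows four real-space metrics: RSCC (model-to-density fit,
pass above 0.7), RSZD (residual difference density near the model, pass
below 3), the B-factor ratio of changed atoms to surrounding side chains
(warn above 1.5, fail above 3) and the coordinate RMSD between the built
and refined positions (pass below 1 Å).  The RSZD here is a documented
surrogate for the EDSTATS score — the per-atom aggregate
``|mean Z| * sqrt(N)`` over a small mask, maximized over atoms — calibrated
so a correct model under known noise scores below 3 in at least 95% of
trials; it is not bit-compatible with EDSTATS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .grid_io import Atom, DensityMap, StructureModel

__all__ = [
    "EnsembleModel",
    "ValidationReport",
    "merge_ensemble",
    "extract_changed_state",
    "rscc",
    "rszd",
    "bfactor_ratio",
    "coord_rmsd",
    "validate",
    "restraint_table",
]

GROUND_CONFORMER = "C"
CHANGED_CONFORMER = "D"
BACKBONE_NAMES = {"N", "CA", "C", "O"}

RSCC_PASS = 0.7
RSZD_PASS = 3.0
B_RATIO_WARN = 1.5
B_RATIO_FAIL = 3.0
RMSD_PASS = 1.0


class NoEnvironmentError(ValueError):
    pass


@dataclass
class EnsembleModel:
    model: StructureModel
    ground_conformer: str = GROUND_CONFORMER
    changed_conformer: str = CHANGED_CONFORMER
    occupancy_changed: float = 0.5  # q
    bdc: float | None = None

    def shared(self) -> StructureModel:
        return self.model.select(lambda a: a.altloc == "")

    def ground_only(self) -> StructureModel:
        return self.model.select(lambda a: a.altloc == self.ground_conformer)

    def changed_only(self) -> StructureModel:
        return self.model.select(lambda a: a.altloc == self.changed_conformer)


@dataclass
class ValidationReport:
    rscc: float | None = None
    rszd: float | None = None
    b_ratio: float | None = None
    rmsd: float | None = None
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def rscc_pass(self) -> bool | None:
        return None if self.rscc is None else self.rscc > RSCC_PASS

    @property
    def rszd_pass(self) -> bool | None:
        return None if self.rszd is None else self.rszd < RSZD_PASS

    @property
    def b_ratio_flag(self) -> str | None:
        if self.b_ratio is None:
            return None
        if self.b_ratio > B_RATIO_FAIL:
            return "fail"
        if self.b_ratio > B_RATIO_WARN:
            return "warn"
        return "pass"

    @property
    def rmsd_pass(self) -> bool | None:
        return None if self.rmsd is None else self.rmsd < RMSD_PASS

    @property
    def all_pass(self) -> bool:
        return (bool(self.rscc_pass) and bool(self.rszd_pass)
                and self.b_ratio_flag == "pass" and bool(self.rmsd_pass))


def merge_ensemble(
    ground: StructureModel,
    changed: StructureModel,
    bdc: float,
    move_tolerance: float = 0.1,
    q_clamp: tuple[float, float] = (0.05, 1.0),
) -> EnsembleModel:
    """Merge ground- and changed-state models into a two-conformer ensemble.

    Atoms present in both states within ``move_tolerance`` Å are shared
    (blank altloc, the changed-state coordinates are kept so the changed
    model is exactly recoverable).  Ground-only or moved atoms become
    conformer C at occupancy ``1 - q``; changed-only or moved atoms become
    conformer D at occupancy ``q`` with ``q = clamp(2 * (1 - bdc))``.
    """
    if not 0.0 <= bdc < 1.0:
        raise ValueError("bdc must be in [0, 1)")
    used = {a.altloc for a in ground} | {a.altloc for a in changed}
    if GROUND_CONFORMER in used or CHANGED_CONFORMER in used:
        raise ValueError(
            f"conformer labels {GROUND_CONFORMER}/{CHANGED_CONFORMER} "
            "already in use; relabel inputs first"
        )
    if len(ground) and len(changed):
        gap = np.linalg.norm(
            ground.coordinates().mean(axis=0) - changed.coordinates().mean(axis=0)
        )
        if gap > 20.0:
            raise ValueError(
                f"models appear to be in different frames (centroids {gap:.1f} Å apart)"
            )
    q = float(np.clip(2.0 * (1.0 - bdc), *q_clamp))
    g_by_key = {(a.chain, a.resnum, a.name): a for a in ground}
    c_by_key = {(a.chain, a.resnum, a.name): a for a in changed}
    atoms: list[Atom] = []
    for key, ga in g_by_key.items():
        ca = c_by_key.get(key)
        if ca is not None and np.linalg.norm(ga.position - ca.position) <= move_tolerance:
            atoms.append(replace(ca, altloc="", occupancy=1.0))
        else:
            atoms.append(replace(ga, altloc=GROUND_CONFORMER, occupancy=1.0 - q))
    for key, ca in c_by_key.items():
        ga = g_by_key.get(key)
        if ga is not None and np.linalg.norm(ga.position - ca.position) <= move_tolerance:
            continue  # already emitted as shared
        atoms.append(replace(ca, altloc=CHANGED_CONFORMER, occupancy=q))
    return EnsembleModel(
        model=StructureModel(atoms),
        occupancy_changed=q,
        bdc=bdc,
    )


def extract_changed_state(ensemble: EnsembleModel) -> StructureModel:
    """Drop the ground-only conformer; shared + changed atoms remain, with
    occupancies restored to 1 (the extracted model is a full single state)."""
    atoms = [
        replace(a, altloc="", occupancy=1.0)
        for a in ensemble.model
        if a.altloc in ("", ensemble.changed_conformer)
    ]
    return StructureModel(atoms)


# ---------------------------------------------------------------------------
# real-space metrics

def _atom_mask(positions: np.ndarray, grid: DensityMap, radius: float) -> np.ndarray:
    """Boolean voxel mask within `radius` Å of any of the given positions."""
    pts = grid.grid_positions().reshape(-1, 3)
    tree = cKDTree(positions)
    d, _ = tree.query(pts, k=1, distance_upper_bound=radius + 1e-9)
    return (d <= radius).reshape(grid.shape)


def rscc(
    atoms: StructureModel,
    observed: DensityMap,
    radius: float = 1.5,
    blur: float = 0.0,
) -> float:
    """Real-space correlation between observed density and the model density
    (atom-centered Gaussians) over voxels within `radius` of the atoms."""
    from .synthetic import density_from_atoms

    if len(atoms) == 0:
        raise ValueError("no atoms selected")
    model_density = density_from_atoms(atoms, observed, blur=blur)
    mask = _atom_mask(atoms.coordinates(), observed, radius)
    mask &= ~np.isnan(observed.values)
    if mask.sum() < 10:
        raise ValueError(f"only {int(mask.sum())} voxels in mask; need >= 10")
    x = observed.values[mask]
    y = model_density.values[mask]
    xm, ym = x - x.mean(), y - y.mean()
    denom = np.sqrt((xm**2).sum() * (ym**2).sum())
    if denom == 0:
        return 0.0
    return float((xm * ym).sum() / denom)


def rszd(
    atoms: StructureModel,
    observed: DensityMap,
    model_density: DensityMap,
    sigma_map: DensityMap | float,
    radius: float = 1.5,
) -> float:
    """Residual difference-density score around the selected atoms.

    Per atom: Z = (observed - model) / sigma over a `radius` Å mask, scored
    as |mean Z| * sqrt(N); the result is the maximum over atoms.  Zero when
    observed equals the model density; under a correct model with matching
    sigma it behaves like the max of ~|N(0,1)| draws.
    """
    if len(atoms) == 0:
        raise ValueError("no atoms selected")
    sig = sigma_map.values if isinstance(sigma_map, DensityMap) else np.asarray(sigma_map, dtype=float)
    diff = observed.values - model_density.values
    score = 0.0
    for atom in atoms:
        mask = _atom_mask(atom.position[None], observed, radius)
        mask &= ~np.isnan(diff)
        n = int(mask.sum())
        if n == 0:
            continue
        sig_vals = sig[mask] if sig.ndim else np.full(n, float(sig))
        if np.any(sig_vals <= 0):
            raise ValueError("sigma_map must be positive over the atom mask")
        z = diff[mask] / sig_vals
        score = max(score, abs(float(z.mean())) * np.sqrt(n))
    return score


def bfactor_ratio(ligand: StructureModel, environment: StructureModel,
                  radius: float = 4.0) -> float:
    """Mean B of the changed atoms over mean B of nearby side-chain atoms.

    Side chain = protein atoms other than backbone N/CA/C/O, within
    `radius` Å of any changed atom.  Values near 1 indicate consistency;
    above ~1.5 suggest refinement/modelling problems and above 3 poor
    evidence for the model.
    """
    if len(ligand) == 0:
        raise ValueError("no changed atoms")
    lig_keys = {(a.chain, a.resnum, a.name) for a in ligand}
    tree = cKDTree(ligand.coordinates())
    env_atoms = []
    for a in environment:
        if a.name in BACKBONE_NAMES:
            continue
        if (a.chain, a.resnum, a.name) in lig_keys:
            continue
        d, _ = tree.query(a.position, k=1)
        if d <= radius:
            env_atoms.append(a)
    if not env_atoms:
        raise NoEnvironmentError(
            f"no side-chain atoms within {radius} Å of the changed atoms"
        )
    return float(np.mean([a.b_factor for a in ligand])
                 / np.mean([a.b_factor for a in env_atoms]))


def coord_rmsd(before: StructureModel, after: StructureModel) -> float:
    """RMSD over matching non-hydrogen atom keys, no re-superposition (both
    models live in the same crystal frame)."""
    b = {k: a for k, a in before.by_key().items() if a.element != "H"}
    a_ = {k: a for k, a in after.by_key().items() if a.element != "H"}
    common = sorted(set(b) & set(a_))
    if not common:
        raise ValueError("no common atoms between models")
    d2 = [np.sum((b[k].position - a_[k].position) ** 2) for k in common]
    return float(np.sqrt(np.mean(d2)))


def validate(
    changed_atoms: StructureModel,
    ensemble: EnsembleModel,
    refined: StructureModel,
    observed: DensityMap,
    model_density: DensityMap,
    sigma_map: DensityMap | float,
) -> ValidationReport:
    """Run all four metrics; per-metric failures are collected, not fatal."""
    report = ValidationReport()
    try:
        report.rscc = rscc(changed_atoms, observed)
    except (ValueError, NoEnvironmentError) as exc:
        report.errors["rscc"] = str(exc)
    try:
        report.rszd = rszd(changed_atoms, observed, model_density, sigma_map)
    except (ValueError, NoEnvironmentError) as exc:
        report.errors["rszd"] = str(exc)
    try:
        report.b_ratio = bfactor_ratio(changed_atoms, ensemble.model)
    except (ValueError, NoEnvironmentError) as exc:
        report.errors["b_ratio"] = str(exc)
    try:
        built = extract_changed_state(ensemble)
        report.rmsd = coord_rmsd(built, refined)
    except ValueError as exc:
        report.errors["rmsd"] = str(exc)
    return report


def restraint_table(ensemble: EnsembleModel, max_distance: float = 4.0,
                    sigma: float = 0.1) -> list[dict]:
    """Generic distance-restraint table stabilizing the two-state ensemble:
    pairs of nearby atoms within each conformer with their current distance
    as the target.  Program-agnostic; exported as CSV by the pipeline."""
    rows = []
    for conformer in ("", ensemble.ground_conformer, ensemble.changed_conformer):
        atoms = [a for a in ensemble.model if a.altloc == conformer]
        if len(atoms) < 2:
            continue
        coords = np.array([a.position for a in atoms])
        tree = cKDTree(coords)
        for i, j in sorted(tree.query_pairs(max_distance)):
            rows.append({
                "atom1": "/".join(map(str, atoms[i].key)),
                "atom2": "/".join(map(str, atoms[j].key)),
                "target_distance": float(np.linalg.norm(coords[i] - coords[j])),
                "sigma": sigma,
            })
    return rows
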