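"""Flexible structure alignment and map warping.

Crystals in a screen are nearly, but not exactly, isomorphous.  To make map
voxels comparable across datasets, each dataset's model is aligned to a
reference model with a *flexible* scheme: a rigid least-squares superposition
is fitted independently for every residue on a sliding window of Cα atoms,
so that slow deformations of the molecule are absorbed residue by residue.
The per-residue transforms are then used to pull each dataset's density back
onto the reference grid.

Conventions
-----------
A residue's transform ``(R, t)`` maps *moving-frame* coordinates into the
*reference frame*: ``x_ref ≈ R @ x_mov + t``.  Warping therefore samples the
moving map at ``R.T @ (x - t)`` for a reference-frame voxel at ``x``.  Each
voxel uses the transform of the nearest reference Cα; voxels with no residue
within ``max_residue_distance`` or falling outside the moving map's support
are marked missing (NaN), not zero-filled — zero-filling would bias the
ensemble mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from .grid_io import DensityMap, StructureModel

__all__ = [
    "AlignmentError",
    "LocalAlignment",
    "superpose",
    "flexible_alignment",
    "warp_map",
]


class AlignmentError(ValueError):
    pass


def superpose(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of points P onto points Q (Kabsch).

    Returns ``(R, t, rmsd)`` with ``R @ P[i] + t ≈ Q[i]`` and the post-fit
    root-mean-square deviation in Å.  Requires N ≥ 3 non-degenerate points.
    """
    P = np.asarray(P, dtype=float).reshape(-1, 3)
    Q = np.asarray(Q, dtype=float).reshape(-1, 3)
    if P.shape != Q.shape:
        raise AlignmentError("point sets must be paired (same shape)")
    n = P.shape[0]
    if n < 3:
        raise AlignmentError("need at least 3 paired points")
    cP, cQ = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cP, Q - cQ
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    # collinear/degenerate clouds leave the rotation underdetermined
    if S[1] < 1e-9 * max(S[0], 1e-30):
        raise AlignmentError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cQ - R @ cP
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return R, t, rmsd


@dataclass
class LocalAlignment:
    """Per-residue rigid transforms from a moving model into a reference frame.

    ``transforms`` maps residue key ``(chain, resnum)`` to ``(R, t)``.
    ``reference_ca`` holds the reference-frame Cα position for each residue,
    used to assign each voxel to its nearest residue during warping.
    """

    transforms: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]]
    reference_ca: dict[tuple[str, int], np.ndarray]
    reference_id: str = ""
    window: int = 7
    rmsd: dict[tuple[str, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, (R, t) in self.transforms.items():
            if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
                raise ValueError(f"non-orthonormal rotation for residue {key}")
            if not np.isclose(np.linalg.det(R), 1.0, atol=1e-6):
                raise ValueError(f"improper rotation for residue {key}")

    def inverse(self) -> "LocalAlignment":
        """The alignment mapping reference-frame coordinates back, with the
        residue anchors moved accordingly (useful for round-trip checks)."""
        inv_tr = {}
        inv_ca = {}
        for key, (R, t) in self.transforms.items():
            Rinv = R.T
            tinv = -R.T @ t
            inv_tr[key] = (Rinv, tinv)
            inv_ca[key] = Rinv @ self.reference_ca[key] + tinv
        return LocalAlignment(inv_tr, inv_ca, self.reference_id, self.window)


def _ca_table(model: StructureModel) -> dict[tuple[str, int], np.ndarray]:
    table: dict[tuple[str, int], np.ndarray] = {}
    for a in model.ca_atoms():
        table[(a.chain, a.resnum)] = a.position
    return table


def flexible_alignment(
    moving: StructureModel,
    reference: StructureModel,
    window: int = 7,
    reference_id: str = "",
) -> LocalAlignment:
    """Fit one rigid transform per residue on a sliding Cα window.

    The window (odd, ≥ 3 residues) is centered on each residue and truncated
    at chain ends.  Residue correspondence is by (chain, residue number);
    both models must share numbering.
    """
    if window < 3 or window % 2 == 0:
        raise AlignmentError("window must be odd and >= 3")
    mov_ca = _ca_table(moving)
    ref_ca = _ca_table(reference)
    common = [k for k in ref_ca if k in mov_ca]
    missing = [k for k in ref_ca if k not in mov_ca]
    if missing and len(missing) == len(ref_ca):
        raise AlignmentError("no residue correspondence between models")
    chains: dict[str, list[tuple[str, int]]] = {}
    for key in sorted(common):
        chains.setdefault(key[0], []).append(key)
    half = window // 2
    transforms = {}
    rmsds = {}
    for chain_keys in chains.values():
        if len(chain_keys) < window:
            raise AlignmentError(
                f"chain {chain_keys[0][0]!r} has {len(chain_keys)} aligned "
                f"residues, fewer than window {window}"
            )
        for i, key in enumerate(chain_keys):
            lo = max(0, i - half)
            hi = min(len(chain_keys), i + half + 1)
            keys = chain_keys[lo:hi]
            P = np.array([mov_ca[k] for k in keys])
            Q = np.array([ref_ca[k] for k in keys])
            R, t, r = superpose(P, Q)
            transforms[key] = (R, t)
            rmsds[key] = r
    return LocalAlignment(
        transforms=transforms,
        reference_ca={k: ref_ca[k] for k in transforms},
        reference_id=reference_id,
        window=window,
        rmsd=rmsds,
    )


def warp_map(
    density: DensityMap,
    alignment: LocalAlignment,
    reference_grid: DensityMap,
    interpolation: str = "trilinear",
    max_residue_distance: float = 10.0,
) -> DensityMap:
    """Resample a moving-frame map onto the reference grid.

    Every reference voxel is assigned the transform of its nearest residue
    (by reference-frame Cα distance) and the moving map is interpolated at
    the back-transformed position.  Voxels farther than
    ``max_residue_distance`` Å from any Cα, or landing outside the moving
    map's support, come back as NaN.
    """
    order = {"trilinear": 1, "tricubic": 3}.get(interpolation)
    if order is None:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    keys = sorted(alignment.transforms)
    ca = np.array([alignment.reference_ca[k] for k in keys])
    tree = cKDTree(ca)
    positions = reference_grid.grid_positions().reshape(-1, 3)
    dist, nearest = tree.query(positions, k=1)
    out = np.full(len(positions), np.nan)
    reachable = dist <= max_residue_distance
    # group voxels by assigned residue so each group is one affine resample
    rotations = np.array([alignment.transforms[k][0] for k in keys])
    translations = np.array([alignment.transforms[k][1] for k in keys])
    values = density.values
    filled = np.nan_to_num(values, nan=0.0)
    nanmask = np.isnan(values).astype(float)
    shape = np.array(density.shape, dtype=float)
    for ridx in np.unique(nearest[reachable]):
        sel = reachable & (nearest == ridx)
        R, t = rotations[ridx], translations[ridx]
        mov_pos = (positions[sel] - t) @ R  # == R.T @ (x - t), row-wise
        idx = density.position_to_index(mov_pos)
        inside = np.all((idx >= -1e-9) & (idx <= shape - 1 + 1e-9), axis=1)
        vals = map_coordinates(filled, idx.T, order=order, mode="nearest")
        # voxels whose interpolation stencil touches a missing voxel
        touched = map_coordinates(nanmask, idx.T, order=1, mode="constant",
                                  cval=0.0)
        vals[touched > 1e-12] = np.nan
        vals[~inside] = np.nan
        out[sel] = vals
    return reference_grid.like(out.reshape(reference_grid.shape),
                               label=f"warped:{density.label}")
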