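"""Resolution management: dataset binning and common low-pass truncation.

Crystals in a screen diffract to different resolutions, but voxels can only
be compared between maps computed at the same level of detail.  Datasets are
therefore grouped into resolution bins: each dataset is *analysed* once, in
the finest bin whose ceiling accommodates it, while contributing to the
*characterization* (ensemble statistics) of every coarser bin.  Before
statistics are accumulated at a bin, every contributing map is low-pass
filtered to the bin ceiling so all maps share one information content; maps
coarser than a bin are excluded from it entirely.

The low-pass filter zeroes all discrete Fourier coefficients with spatial
frequency above ``1/d_min`` (spherical cutoff, the crystallographic
resolution convention) and back-transforms — emulating truncation of the
reflection list at ``d_min``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grid_io import DensityMap

__all__ = [
    "AnalysisPlan",
    "ResolutionError",
    "assign_bins",
    "lowpass_truncate",
    "frequency_mask",
    "common_support",
    "apply_support",
]

logger = logging.getLogger(__name__)


class ResolutionError(ValueError):
    pass


@dataclass
class AnalysisPlan:
    """Which datasets are analysed / used for characterization at each bin.

    ``bins`` are resolution ceilings in Å, ascending (finest first).
    ``analysis[d]`` lists indices analysed at ceiling ``d`` (each dataset
    appears exactly once, in the finest bin with ceiling ≥ its resolution);
    ``characterization[d]`` lists indices contributing statistics at ``d``
    (every dataset at least as fine as the ceiling).
    """

    bins: list[float]
    analysis: dict[float, list[int]] = field(default_factory=dict)
    characterization: dict[float, list[int]] = field(default_factory=dict)
    excluded: list[int] = field(default_factory=list)


def assign_bins(resolutions: list[float], bin_ceilings: list[float]) -> AnalysisPlan:
    """Assign datasets to resolution bins.

    A 1.2 Å dataset with bins (1.0, 1.5, 2.0, 2.5) is analysed at 1.5 Å and
    additionally characterizes the 2.0 and 2.5 Å bins.  Datasets coarser than
    the coarsest ceiling are excluded with a warning.
    """
    ceilings = [float(b) for b in bin_ceilings]
    if any(b2 <= b1 for b1, b2 in zip(ceilings, ceilings[1:])):
        raise ResolutionError("bin ceilings must be strictly increasing")
    if any(not d > 0 for d in resolutions):
        raise ResolutionError("resolutions must be positive")
    plan = AnalysisPlan(
        bins=ceilings,
        analysis={b: [] for b in ceilings},
        characterization={b: [] for b in ceilings},
    )
    for i, d in enumerate(resolutions):
        eligible = [b for b in ceilings if b >= d]
        if not eligible:
            logger.warning(
                "dataset %d at %.2f Å is coarser than the coarsest bin "
                "(%.2f Å); excluded", i, d, ceilings[-1],
            )
            plan.excluded.append(i)
            continue
        plan.analysis[eligible[0]].append(i)
        for b in eligible:
            plan.characterization[b].append(i)
    return plan


def _radial_frequency(shape: tuple[int, ...], spacing: float) -> np.ndarray:
    """|k| in 1/Å on the rfftn frequency grid."""
    freqs = [np.fft.fftfreq(n, d=spacing) for n in shape[:-1]]
    freqs.append(np.fft.rfftfreq(shape[-1], d=spacing))
    grids = np.meshgrid(*freqs, indexing="ij")
    return np.sqrt(sum(g**2 for g in grids))


def frequency_mask(shape: tuple[int, ...], spacing: float, d_min: float) -> np.ndarray:
    """Boolean keep-mask on the rfftn grid: True where |k| ≤ 1/d_min."""
    if d_min < 2 * spacing:
        raise ResolutionError(
            f"d_min {d_min} Å below the grid Nyquist limit {2 * spacing} Å"
        )
    return _radial_frequency(shape, spacing) <= 1.0 / d_min + 1e-12


def lowpass_truncate(density: DensityMap, d_min: float) -> DensityMap:
    """Zero all Fourier coefficients beyond 1/d_min and back-transform.

    A linear projection: idempotent, and maps band-limited inputs to
    themselves.  Missing voxels are not supported here (truncation happens
    before warping introduces any).
    """
    mask = frequency_mask(density.shape, density.spacing, d_min)
    if np.isnan(density.values).any():
        raise ValueError("cannot Fourier-truncate a map with missing voxels")
    coeffs = np.fft.rfftn(density.values)
    coeffs[~mask] = 0.0
    out = np.fft.irfftn(coeffs, s=density.shape, axes=(0, 1, 2))
    return density.like(out, label=f"{density.label}@{d_min:.2f}A")


def common_support(masks: list[np.ndarray]) -> np.ndarray:
    """Element-wise intersection of Fourier keep-masks (identical grids)."""
    if not masks:
        raise ValueError("no masks given")
    shape = masks[0].shape
    for m in masks[1:]:
        if m.shape != shape:
            raise ValueError("masks are on mismatched frequency grids")
    out = np.ones(shape, dtype=bool)
    for m in masks:
        out &= m
    return out


def apply_support(density: DensityMap, keep: np.ndarray) -> DensityMap:
    """Restrict a map's Fourier representation to a keep-mask."""
    coeffs = np.fft.rfftn(density.values)
    if keep.shape != coeffs.shape:
        raise ValueError("keep-mask does not match the map's frequency grid")
    coeffs[~keep] = 0.0
    return density.like(np.fft.irfftn(coeffs, s=density.shape, axes=(0, 1, 2)))
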