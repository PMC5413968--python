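"""Per-voxel normal–normal model of the ground-state ensemble, and Z-maps.

The observed density of dataset *i* at voxel *m* is modelled as

    rho_im ~ N(mu_m, s_m^2 + sigma_i^2)

where ``mu_m`` is the mean ground-state density, ``s_m >= 0`` the standard
deviation of the "true" density across crystals (natural variation — crystal
contacts, flexible loops), and ``sigma_i >= 0`` the measurement uncertainty
of dataset *i*.  Note ``s_m`` enters as a standard deviation so the variance
components add; see docs/methods.md for the unit convention.

Fitting proceeds in three steps: ``mu`` as the unweighted voxel mean over
the characterization datasets; ``sigma_i`` as the central slope of a normal
Q-Q plot of the mean-difference map (robust to the sparse genuine signal in
the tails); ``s_m`` by per-voxel maximum likelihood with the boundary s=0
handled explicitly.  Standardizing a dataset against the fitted model gives
its Z-map, Z = (rho - mu) / sqrt(sigma_i^2 + s_m^2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .grid_io import DensityMap

__all__ = [
    "StatisticalModel",
    "ZMap",
    "DegenerateVarianceError",
    "mean_map",
    "estimate_sigma",
    "estimate_s",
    "estimate_s_map",
    "fit_model",
    "zmap",
]

logger = logging.getLogger(__name__)

CONVERGENCE_N = 30  # below this many characterization datasets, warn


class DegenerateVarianceError(ValueError):
    pass


@dataclass
class StatisticalModel:
    mu: DensityMap
    s: DensityMap
    sigma: dict[str, float] = field(default_factory=dict)
    n_char: int = 0

    def __post_init__(self) -> None:
        if self.n_char < 2:
            raise ValueError("model underdetermined with fewer than 2 datasets")
        if self.mu.shape != self.s.shape:
            raise ValueError("mu and s must share one grid")
        s = self.s.values
        if np.nanmin(s) < 0:
            raise ValueError("s must be non-negative")
        if any(v < 0 for v in self.sigma.values()):
            raise ValueError("sigma values must be non-negative")


@dataclass
class ZMap:
    values: np.ndarray
    dataset_id: str
    spacing: float
    origin: np.ndarray

    def as_map(self) -> DensityMap:
        return DensityMap(self.values, self.spacing, self.origin,
                          label=f"zmap:{self.dataset_id}")


def mean_map(maps: list[DensityMap]) -> DensityMap:
    """Unweighted per-voxel mean; a voxel missing in more than half the
    inputs is marked missing in the output."""
    if len(maps) == 0:
        raise ValueError("no maps given")
    if len(maps) < 2:
        raise ValueError("need at least 2 maps")
    stack = np.stack([m.values for m in maps])
    n_obs = np.sum(~np.isnan(stack), axis=0)
    with np.errstate(invalid="ignore"):
        mu = np.where(n_obs > 0, np.nansum(stack, axis=0) / np.maximum(n_obs, 1),
                      np.nan)
    mu[n_obs <= len(maps) / 2] = np.nan
    return maps[0].like(mu, label="mean")


def estimate_sigma(map_i: DensityMap, mu: DensityMap,
                   central: float = 1.5) -> float:
    """Dataset uncertainty from the central slope of a normal Q-Q plot.

    The mean-difference map ``map_i - mu`` is sorted and plotted against
    standard-normal quantiles; the least-squares slope over theoretical
    quantiles in [-central, +central] estimates sigma_i.  Restricting to the
    centre makes the estimate robust against the heavy tails produced by
    genuine signal or gross outliers.
    """
    diff = (map_i.values - mu.values).ravel()
    diff = diff[~np.isnan(diff)]
    if diff.size < 1000:
        raise ValueError(f"only {diff.size} overlapping voxels; need >= 1000")
    diff = np.sort(diff)
    n = diff.size
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    sel = np.abs(theo) <= central
    if sel.sum() < 100:
        raise ValueError("fewer than 100 points in the central Q-Q region")
    slope, _ = np.polyfit(theo[sel], diff[sel], 1)
    return float(max(slope, 0.0))


def _neg_loglik(s: float, values: np.ndarray, mu_m: float,
                sigma: np.ndarray) -> float:
    var = s * s + sigma**2
    return float(0.5 * np.sum(np.log(2 * np.pi * var)
                              + (values - mu_m) ** 2 / var))


def estimate_s(values: np.ndarray, mu_m: float, sigma: np.ndarray) -> float:
    """Maximum-likelihood natural variation at one voxel.

    Maximizes the marginal likelihood over ``s >= 0`` by bounded scalar
    search; returns 0 when the optimum sits at the boundary (spread fully
    explained by the per-dataset uncertainties).
    """
    values = np.asarray(values, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if values.size < 2 or values.size != sigma.size:
        raise ValueError("need >= 2 values with matching sigma")
    if not (np.all(np.isfinite(values)) and np.all(np.isfinite(sigma))):
        raise ValueError("non-finite inputs")
    hi = 10.0 * max(float(np.std(values)), float(np.max(sigma)), 1e-6)
    res = optimize.minimize_scalar(
        _neg_loglik, bounds=(0.0, hi), args=(values, float(mu_m), sigma),
        method="bounded", options={"xatol": 1e-8},
    )
    best = float(res.x)
    # the bounded search can stall away from the boundary; test s = 0 explicitly
    if _neg_loglik(0.0, values, float(mu_m), sigma) <= res.fun + 1e-12:
        return 0.0
    return best


def estimate_s_map(
    stack: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
    coarse_points: int = 64,
    refine_iters: int = 32,
) -> np.ndarray:
    """Vectorized per-voxel ML fit of s over a whole grid.

    ``stack`` is (n_datasets, ...) of aligned densities, ``mu`` the mean map
    and ``sigma`` the per-dataset uncertainties.  For every voxel the
    negative log-likelihood is scanned on a coarse s-grid and the best cell
    refined by golden-section search; agrees with the scalar
    :func:`estimate_s` to high accuracy.  Voxels with any missing
    observation are returned as NaN.
    """
    stack = np.asarray(stack, dtype=float)
    n = stack.shape[0]
    sigma = np.asarray(sigma, dtype=float).reshape((n,) + (1,) * (stack.ndim - 1))
    flat_shape = stack.shape[1:]
    sq = (stack - mu[None]) ** 2

    def nll(s):
        # s broadcastable against voxel shape
        var = s * s + sigma**2
        return 0.5 * np.sum(np.log(var) + sq / var, axis=0)

    any_obs = ~np.isnan(sq).all(axis=0)
    if not any_obs.any():
        return np.full(flat_shape, np.nan)
    with np.errstate(invalid="ignore"):
        rms = np.sqrt(np.nanmean(sq[:, any_obs], axis=0))
    smax = 10.0 * max(float(np.nanmax(rms)), float(np.max(sigma)), 1e-6)
    grid = np.linspace(0.0, smax, coarse_points)
    best_val = np.full(flat_shape, np.inf)
    best_idx = np.zeros(flat_shape, dtype=np.int64)
    with np.errstate(invalid="ignore"):
        for k, s in enumerate(grid):
            v = nll(s)
            upd = v < best_val
            best_val = np.where(upd, v, best_val)
            best_idx[upd] = k
    lo = grid[np.maximum(best_idx - 1, 0)]
    hi = grid[np.minimum(best_idx + 1, coarse_points - 1)]
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    with np.errstate(invalid="ignore"):
        for _ in range(refine_iters):
            c = b - invphi * (b - a)
            d = a + invphi * (b - a)
            take_c = nll(c) < nll(d)
            b = np.where(take_c, d, b)
            a = np.where(take_c, a, c)
        s_hat = (a + b) / 2.0
        # boundary: prefer s = 0 whenever it is at least as likely
        at_zero = nll(np.zeros(flat_shape))
        s_hat = np.where(at_zero <= nll(s_hat) + 1e-12, 0.0, s_hat)
    missing = np.isnan(stack).any(axis=0)
    s_hat = np.where(missing, np.nan, s_hat)
    return s_hat


def fit_model(
    maps: list[DensityMap],
    ids: list[str],
    restrict_ground: set[str] | None = None,
) -> StatisticalModel:
    """Fit mu, sigma_i and s_m from a characterization set of aligned maps.

    By default every dataset in the set contributes (genuine changed states
    are rare enough not to distort the ensemble); pass ``restrict_ground``
    to use only explicitly labelled ground-state datasets.
    """
    if restrict_ground is not None:
        keep = [(m, i) for m, i in zip(maps, ids) if i in restrict_ground]
        maps = [m for m, _ in keep]
        ids = [i for _, i in keep]
    if len(maps) < 2:
        raise ValueError("need at least 2 characterization maps")
    if len(maps) < CONVERGENCE_N:
        logger.warning(
            "only %d characterization datasets; ensemble statistics "
            "typically require ~%d for full convergence", len(maps),
            CONVERGENCE_N,
        )
    mu = mean_map(maps)
    sigma = {i: estimate_sigma(m, mu) for m, i in zip(maps, ids)}
    stack = np.stack([m.values for m in maps])
    s_values = estimate_s_map(stack, mu.values,
                              np.array([sigma[i] for i in ids]))
    s = mu.like(s_values, label="s")
    return StatisticalModel(mu=mu, s=s, sigma=sigma, n_char=len(maps))


def zmap(map_i: DensityMap, model: StatisticalModel, dataset_id: str) -> ZMap:
    """Standardized deviation of one dataset from the ensemble mean."""
    if dataset_id not in model.sigma:
        raise KeyError(f"no sigma for dataset {dataset_id!r}")
    if map_i.shape != model.mu.shape:
        raise ValueError("grid mismatch between map and model")
    sigma_i = model.sigma[dataset_id]
    var = sigma_i**2 + model.s.values**2
    finite = ~np.isnan(var) & ~np.isnan(map_i.values) & ~np.isnan(model.mu.values)
    if np.any(finite & (var <= 0)):
        vox = tuple(int(v) for v in
                    np.argwhere(finite & (var <= 0))[0])
        raise DegenerateVarianceError(
            f"sigma_i^2 + s_m^2 = 0 at voxel {vox}; Z undefined there"
        )
    with np.errstate(invalid="ignore"):
        z = (map_i.values - model.mu.values) / np.sqrt(var)
    return ZMap(values=z, dataset_id=dataset_id, spacing=map_i.spacing,
                origin=map_i.origin.copy())
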