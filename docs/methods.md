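# Methods

## The statistical model

The package treats a screen of near-identical crystals as repeated noisy
observations of one underlying "ground state" density field. After local
alignment onto a common isotropic Cartesian grid, the observed density of
dataset *i* at voxel *m* is modelled as

    ρ_im = t_m + ε_i,    t_m ~ N(μ_m, s_m²),    ε_i ~ N(0, σ_i²)

so marginally ρ_im ~ N(μ_m, s_m² + σ_i²). Here

- **μ_m** is the mean ground-state density, estimated as the unweighted
  per-voxel average over the characterization datasets;
- **σ_i** (map units) is the uncertainty of dataset *i*, estimated as the
  least-squares slope of the central portion (theoretical quantiles in
  [−1.5, +1.5]) of a normal Q–Q plot of the mean-difference map ρ_i − μ.
  Restricting to the centre makes the estimate robust to the heavy tails
  contributed by genuine signal: 1% of gross outliers at ±10 shifts the
  plain standard deviation by ≈ 40% but the Q–Q slope by < 5%;
- **s_m ≥ 0** (map units) is the *natural variation* of the true density
  across crystals — crystal contacts, mobile loops — fitted per voxel by
  maximizing the marginal likelihood over s with μ and σ fixed. A unit
  note: s_m is used throughout as a **standard deviation**, so that the
  denominator of the Z-score is √(σ_i² + s_m²) with consistent units; the
  alternative reading of s_m as a variance would make the sum dimensionally
  inconsistent.

Z-maps standardize each dataset against the ensemble:
Z_im = (ρ_im − μ_m) / √(σ_i² + s_m²). On calibrated synthetic ensembles the
Z histogram of a hit-free dataset is standard normal to within a few percent
(verified in the test suite), which is what makes fixed contour thresholds
transferable across datasets.

### Numerical details of the s fit

The per-voxel likelihood maximization is solved two ways, cross-checked
against each other and against a 1000-point grid scan of the
log-likelihood:

- `estimate_s` (scalar): bounded Brent minimization of the negative
  log-likelihood on s ∈ [0, 10·max(sample sd, max σ_i)], tolerance 1e-8,
  with the boundary s = 0 compared explicitly (the optimum is frequently on
  the boundary — most voxels show no variation beyond measurement noise).
- `estimate_s_map` (whole grid): a vectorized 64-point coarse scan followed
  by 32 golden-section iterations per voxel, all in array arithmetic. For a
  48³ grid and 40 datasets the fit takes a few seconds.

In the homoscedastic case the ML solution has the closed form
ŝ² = max(0, mean((ρ−μ)²) − σ²), which the search reproduces to 1e-6.

## Resolution management

Datasets are analysed once each, in the finest resolution bin whose ceiling
is at least their own resolution, and contribute to the ensemble statistics
of every coarser bin. Before statistics are accumulated at a bin, each
contributing map is low-pass filtered to the bin ceiling by zeroing Fourier
coefficients with |k| > 1/d (spherical cutoff, the crystallographic
convention; the filter is an idempotent linear projection). Maps coarser
than a bin are excluded from it. Real inputs are expected to come from a
refinement pipeline with Fc-filling of missing reflections enabled;
`common_support` is provided to intersect Fourier supports when that
assumption fails.

## Event detection and background correction

Blobs are connected components (26-neighbour connectivity, so thin diagonal
features are not split) of {Z ≥ 2.5}, kept if peak Z ≥ 3 and volume ≥ 10 Å³,
then merged transitively when closer than 5 Å (minimum voxel-center
distance). Components are filtered *before* merging; the order matters for
fragmented signal and follows the method's published defaults.

The background density correction for an event is found by a contrast scan:
for β on a 0.01-step grid, D_β = ρ − β·μ is correlated with μ over the
local region (the blob dilated by 1 Å, grown until it holds ≥ 20 voxels)
and over a global region, and BDC = argmax (global − local), ties toward
smaller β. Two design choices deserve note:

- **Global region.** The global curve is meant to be a signal-to-noise
  normalization: how fast correlation-to-mean decays for density that *is*
  ground state. Computed over the whole box it is diluted by bulk-solvent
  voxels that carry no ground-state structure; for weak events this pushes
  the local curve *above* the global one everywhere and the scan saturates
  at the grid edge. The global region is therefore restricted to
  density-bearing voxels (μ above its 75th percentile) outside the local
  region; `density_quantile=None` restores the whole-box behaviour.
- **Bias.** The contrast maximum systematically lands at or above the true
  ground fraction (the local correlation's zero crossing); the method is
  used for its monotone response to occupancy, not as an unbiased occupancy
  estimator. Events whose best contrast is below 0.05 are flagged
  `low_contrast`.

The event map is E = (ρ − BDC·μ)/(1 − BDC). The normalization is forced by
the endpoint conditions (BDC = 0 must return the observed map; the exact
two-state identity E = ν when ρ = (1−g)·ν + g·μ and BDC = g) and is
verified as an algebraic identity in the tests.

## Ensemble models and validation

Bound states exist at partial occupancy, so the deposited model carries
both states: atoms identical in both (within 0.1 Å) stay once with a blank
conformer label; ground-only/moved atoms become conformer C with occupancy
1 − q; changed-only/moved atoms become conformer D with occupancy
q = clamp(2·(1 − BDC), 0.05, 1.0). The clamp keeps occupancy-refinement
groups non-degenerate when BDC ≈ 1. The merge keeps changed-state
coordinates for shared atoms so `extract_changed_state` is an exact inverse.
A generic distance-restraint table (atom pairs within 4 Å per conformer)
is exported for downstream refinement stabilization.

Validation metrics: RSCC (Pearson correlation between the observed map and
a model density of atom-centered Gaussians with variance B/(8π²) + blur²
and amplitude occupancy × electron count, over voxels within 1.5 Å of the
scored atoms; pass > 0.7); RSZD (per-atom |mean Z|·√N of the standardized
difference density over a 1.5 Å mask, maximized over atoms; pass < 3);
B-factor ratio (mean B of changed atoms over mean B of side-chain atoms
within 4 Å; warn > 1.5, fail > 3); coordinate RMSD between built and
refined positions without re-superposition (pass < 1 Å). The RSZD here is a
documented surrogate for the EDSTATS score — it is calibrated so a correct
model with known noise scores below 3 in ≥ 95% of trials, but it is **not
bit-compatible with EDSTATS**.

## The synthetic screen generator

`simulate_screen` produces ensembles that satisfy the model's assumptions
by construction: each map is lowpass_d(structure) + s_field·ξ + σ_i·ε with
ξ, ε per-voxel standard normal. The per-dataset resolution low-pass applies
to the *structural* density only; variation and noise are injected
afterwards so that the recorded truth σ_i and s are exactly the standard
deviations present in the final map — the quantities the estimators are
tested against. (Truncating white noise would silently shrink it by the
kept-frequency fraction.)

Default study conditions, chosen once as a realistic desk-scale screen:

| parameter | default | rationale |
|---|---|---|
| n_ground | 40 | above the ≈ 30-dataset convergence scale for ensemble statistics |
| grid | 48³ at 0.5 Å | a 24 Å box; minutes-scale pipelines |
| σ_i | U(0.05, 0.15) | ≈ 5–15% of a well-ordered carbon peak at these resolutions |
| resolutions | U(1.8, 2.2) Å | typical fragment-screen range; exercises binning |
| protein | 60-residue self-avoiding Cα walk | smallest system with enough context for alignment windows |
| pockets | 3, each 4 ordered waters ringing a site at 2.8 Å | fragments bind solvent-exposed pockets and displace ordered solvent |
| bound state | compact bonded carbon cluster replacing the pocket waters; host side chain shifted 1.5 Å | largely dissimilar ground/changed densities at the site, contiguous positive difference density |
| s-field | one spherical region, radius 3 Å, s = 0.1 | a single naturally-variable patch |

Pocket directions are chosen to maximize clearance from the rest of the
chain: binding sites buried in protein density make the ground and changed
densities locally near-collinear, which degrades *any* contrast-based
background estimator — real fragment sites are solvent-exposed.

What the generator does **not** emulate: Fourier-space noise correlations
(noise is white per voxel), solvent flattening, anisotropy, radiation
damage, non-Gaussian variation, and model-phase bias (approximated only by
`degrade_reference`, which blends maps toward the density of a
coordinate-jittered model). Passing tests therefore demonstrate the
statistical machinery under the model's own assumptions, not performance on
real screens.

## Pipeline behaviour and problem sizes

The pipeline aligns every model to the highest-resolution ground dataset,
warps maps per resolution bin, fits the model per bin on the bin's
characterization set (all datasets by default — hits are rare; a
`ground_only` flag restricts to labelled ground datasets), and analyses
each dataset once. Datasets failing a stage are quarantined and reported;
bins with fewer than 30 characterization datasets trigger a convergence
warning (detection power visibly degrades in such bins, which is the
expected behaviour, not a defect). A full default screen (45 datasets, 48³
grid, single bin) runs in well under five minutes on one CPU; the test
suite and worked examples use these sizes throughout.

## Known limitations

- Alignment assumes shared chain/residue numbering and one crystal form;
  cross-form comparison is out of scope.
- The BDC scan brackets rather than pinpoints the ground fraction; event
  maps for very high BDC amplify noise by 1/(1 − BDC).
- RSZD is a surrogate (see above); absolute values should not be compared
  against EDSTATS outputs.
- Reciprocal-space refinement, structure-factor calculation and σA
  weighting are upstream of this tool.
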