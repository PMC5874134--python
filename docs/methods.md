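# Methods

## The signal model behind the synthetic generator

Every voxel series is a variance-weighted sum of three zero-mean,
unit-variance Gaussian sources:

    x_i = sqrt(a_I)·g_I + sqrt(b)·h + sqrt(1 − a_I − b)·ε_i ,  i ∈ I

with `g_I` a latent shared by all voxels of ROI `I`, `h` an optional
brain-wide (global-signal) latent, and `ε_i` voxel-unique noise. The ROI
latents carry a configurable correlation matrix `R` (applied through the
symmetric matrix square root of `R`; a non-positive-semidefinite `R` is
rejected rather than repaired). This is the minimal model in which ROIs
can be individually inconsistent while still sharing a common component —
exactly the regime in which ROI averaging manufactures strong ROI-level
correlations out of weak voxel-level ones.

All downstream statistics then have closed forms, which serve as the
oracle for every pipeline stage:

| quantity | population value |
|---|---|
| consistency φ\*(I) | a_I + b |
| C\*_vox(I,J) | sqrt(a_I·a_J)·R_IJ + b |
| variance of X_I | v_I = a_I + b + (1 − a_I − b)/N_I |
| C\*_roi(I,J) | C\*_vox / sqrt(v_I·v_J) |

The identity-line bound `C_vox ≤ (φ_I + φ_J)/2` follows from AM–GM with
`|R| ≤ 1`, and the amplification `C_roi ≥ C_vox` from `v_I < 1`.

Sequences are serially independent by default; an AR(1) coefficient
(stationary unit variance, 100-sample burn-in) is available but defaults
to 0 because none of the computed statistics depends on temporal
autocorrelation — only their sampling error does. Randomness uses one
master seed with per-source substreams (one per ROI latent, one per ROI
noise block, one global), so resizing one ROI does not reshuffle any
other ROI's draws, and regeneration is bit-identical.

ROIs are embedded as contiguous axis-aligned blocks, packed shelf-wise
largest-first into the grid; an ROI size with no block factorization
fitting the grid is a capacity error. Blocks are the simplest geometry
that still exercises spatial smoothing across ROI boundaries; they do
not emulate anatomical ROI shapes.

## The reference study (`study_spec`)

The `analysis/` drivers use one fixed synthetic session meant to resemble
a single-subject resting-state acquisition at desk scale: 30 ROIs with
sizes 8–216 voxels (anatomical atlases have broad right-skewed size
distributions with medians near 10²), T = 212 time points (a ~6 min
session at TR 1.7 s after trimming), 4 mm isotropic voxels. The
shared-signal fraction decreases smoothly with ROI size,
`a_I = 0.08 + 0.42/(1 + N_I/40)`, reproducing the empirical tendency of
small ROIs to be more consistent; a weak global component `b = 0.05` is
included; latent correlations are a common baseline plus a decaying term,
`R_IJ = 0.25 + 0.35·0.7^|I−J|` (positive semidefinite as the sum of a
constant and a Kac–Murdock–Szegő matrix). The size list is shuffled with
a fixed permutation so that ROI index — which orders the decay in `R` —
is not a proxy for ROI size.

What the generator does *not* emulate: hemodynamic response shapes,
physiological noise spectra, motion, spatial autocorrelation of the
noise, multi-subject anatomy, or any co-variation between a node's
consistency and the strength of its latent coupling to other nodes. The
last point matters for the consistency–centrality analysis: in this
model, averaging de-attenuates the shared component almost completely
for large ROIs, so when `R` is independent of `a`, node strength is
nearly independent of consistency (the reference study even shows a
weakly negative relation, because small high-consistency ROIs suffer
more residual attenuation). A positive consistency→centrality relation,
as observed empirically, emerges when nodes differ in `a` at comparable
sizes — the regime the network tests exercise — or when latent coupling
itself rises with consistency. Passing tests therefore validate the
estimators and their closed-form targets, not any claim that this
particular latent structure is what real cortex does.

## Estimator and procedure choices

* **Consistency** is the mean of the strict upper triangle of the
  within-ROI voxel correlation matrix; the ordered-pair double sum with
  `1/(N(N−1))` normalization is identical. Correlations are averaged
  raw — no Fisher-z before averaging — because the statistic is defined
  as a mean of correlations.
* **Zero-variance (dead) voxels** make Pearson undefined; pairs
  involving them are skipped with the pair count adjusted and a warning.
  The 2 % power filter removes such voxels up front in normal use, so
  this path only fires on degenerate input. φ for an ROI with fewer than
  two voxels is reported missing (NaN), never silently dropped.
* **Signal power** for the exclusion filter is the variance of the voxel
  time series — scale-free in the mean offset, which is the natural
  reading for data whose raw intensity units are arbitrary. The filter
  runs before detrending in the packaged pipeline and records its
  absolute threshold, making re-application idempotent. The default
  fraction is 0.02 of the mean voxel power.
* **Detrending** subtracts each voxel's least-squares line (intercept +
  slope), leaving residuals exactly orthogonal to constant and linear
  regressors.
* **Smoothing** uses an isotropic Gaussian with
  `σ = FWHM/(2·sqrt(2·ln 2))`, truncated at 4σ, and is renormalized over
  in-mask voxels: kernel mass falling outside the brain mask is dropped
  and the remaining weights rescaled to sum to one, so a spatially
  constant field is preserved exactly and no power artifactually leaks
  across the brain boundary. FWHM 0 is the identity. Supported kernel
  sizes of interest are 5, 8 and 12 mm.
* **Permutation t test**: pooled-variance two-sample t on the observed
  labeling; `p = (1 + #{|t_perm| ≥ |t_obs|})/(1 + n)`. All labelings are
  enumerated exhaustively when there are at most 20 000 of them (the
  observed labeling then counts itself); otherwise 10 000 Monte-Carlo
  permutations by default, with the `+1` smoothing keeping p valid
  (never anti-conservative) at any permutation count. Equality at the
  threshold uses a 1e-12 guard against floating-point ties.
* **Density thresholding** keeps the top `m = round(d·M)` links by
  *signed* weight (`M = N(N−1)/2`), which automatically excludes
  negative correlations at sparse densities. Rounding is half-up —
  `d·M = 1.5` keeps two links — and ties at the cutoff weight are broken
  deterministically by lexicographic node-pair order and logged.
  Degenerate requests (`m = 0`) are errors; the density sweep marks such
  grid points as skipped.
* **Binning**: consistency-vs-size uses logarithmically spaced size bins
  (ROI sizes span orders of magnitude); pairwise relations use
  equal-width bins on the x variable. Bin SDs use ddof = 1 and are NaN
  for singleton bins. Overall correlations accompany every binned table.
* **Pair budgets**: between-ROI pair pooling and per-pair voxel
  enumeration are exact up to a configurable budget (default 10⁷ pairs);
  beyond it a seed-reproducible uniform subsample is used. The analysis
  drivers cap pooled between-pairs at 2×10⁵ and use 1 000 permutations,
  which resolves p ≥ 10⁻³ — sufficient for the single headline test they
  report.
* **Numerics**: correlations are clipped to [−1, 1], and values within
  10⁻¹⁴ of ±1 are snapped to exactly ±1. Identical series reach that
  window through rounding alone (matrix products and norms accumulate in
  different orders), and at double precision such values are
  indistinguishable from the theoretical extreme, so snapping keeps
  `φ = 1` and `C_vox = 1` exact in the limiting cases.

## Pipeline and reproducibility

`run_pipeline` executes input → power filter → detrend → one analysis
branch per smoothing FWHM → consistency, distributions and permutation
test → pair table and identity-bound check → adjacency, thresholding and
the consistency–centrality sweep. Every output is TSV or JSON; the run
manifest records a hash of the scientific configuration (output path
excluded), the seed, package versions, per-stage timings and all
collected warnings. Re-running from the serialized config reproduces
every table byte-for-byte; all randomness (permutations, subsampling,
synthesis) derives from the single configured seed. Multi-subject
studies run the single-subject pipeline per subject and pool afterwards:
per-ROI consistencies are averaged across subjects, raw pair values are
concatenated.

## Problem sizes

The test suite and drivers run at desk scale by design: the reference
study has ~2 400 voxels; oracle-equivalence checks enumerate ROIs of up
to 12 voxels; parameter recovery uses T = 2 000 and the amplification
experiment T = 5 000 with 150 voxels per ROI; permutation calibration
uses 1 000 null replicates of 199 permutations each. Tolerances for
sampling-based checks are 3 Fisher-z standard errors, `3/sqrt(T − 3)`.

## Known limitations

* The blockwise parcellation cannot represent ROI sizes whose factor
  triples exceed the grid (e.g. large primes on small grids).
* The shared/unique variance-fraction parameterization is one consistent
  formalization of "voxels share a common component"; alternatives
  (e.g. multiple shared components per ROI, spatially decaying voxel
  coupling) would change the closed forms.
* Probabilistic atlases must be thresholded to deterministic labels
  before use; the reader accepts only integer label volumes.
* No temporal filtering, nuisance regression or motion handling — inputs
  are assumed preprocessed.
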