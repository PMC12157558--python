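# Methods

This note records the models behind `centroscreen`, the parameters that
matter, the synthetic data the tests rely on, and the design choices made
where more than one reasonable construction existed.

## Coordinates and units

All spot coordinates are continuous, in micrometres, ordered (y, x) to
match raster indexing. The pixel with index (i, j) covers
[i, i+1) × [j, j+1) in pixel units, so its centre is at (i + 0.5) ×
pixel_size. The default pixel size is 0.108 μm, the effective pixel size of
a 60× / sCMOS high-content acquisition; every function takes it explicitly.
Fixing this convention once avoids off-by-half-pixel disagreements between
detection and the spatial statistics.

## Clustering score

The per-cell clustering statistic is the radius-averaged, CSR-standardized
deviation of Ripley's K inside the nuclear mask:

* K̂(r) = A/(n(n−1)) · Σ_{i≠j} 1[d_ij ≤ r], uncorrected.
* The CSR baseline is Monte Carlo: `n_mc` (default 100, minimum 20)
  independent uniform point sets of the same n in the same mask give
  μ_CSR(r) and σ_CSR(r) per radius. Because observation and baseline share
  the mask, boundary truncation affects both identically and cancels in the
  standardization — no analytic (isotropic) edge correction is needed, and
  the construction is exact for arbitrarily irregular masks.
* Radii are fractions of the equivalent radius R_eq = √(A/π), default 10
  points on 0.05–0.5. Relative radii make the score invariant under joint
  rescaling of mask and spots; the per-n baseline makes it robust to the
  spot count.
* The score is the mean over radii of (K̂_obs − μ_CSR)/σ_CSR. σ_CSR is
  floored at 1e−9·A to keep degenerate radii finite.
* Cells with fewer than `min_spots` (default 3) spots carry a flagged
  missing score, never a silent zero.
* Baselines are cached on (mask hash, n, radii, n_mc, seed). The cache is
  exact, not interpolated.

Standardizing one CSR draw against an independent CSR baseline has
expectation zero regardless of the skewness of K̂, so the score is centred
under the null by construction; the residual scatter of a 500-cell mean is
Monte-Carlo noise of order 0.05 (shared-baseline correlations included).

The uniform sampler picks a mask pixel uniformly and adds a sub-pixel
offset, which is exactly uniform over the rasterized support.

## Mean normalized radial distance

Per spot: distance from the nuclear centroid divided by the
centroid-to-boundary distance along the ray through the spot, then averaged
over spots. The boundary distance is the largest ray parameter still inside
the mask (marching at 0.25 px steps), which stays well defined for
non-convex masks and for centroids that fall outside the foreground. A spot
at the centroid contributes 0; values are clipped to [0, 1] against raster
discreteness. Ray normalization (rather than dividing by the equivalent
radius) makes the boundary exactly 1 in every direction for any shape; for
uniform spots in a disk the population mean is 2/3.

## Image formation and spot detection

Rendered cells are two channels: DAPI (filled mask) and spots (sum of
isotropic Gaussians, default σ_psf = 0.15 μm ≈ 1.4 px, diffraction-limited
foci), plus additive Gaussian noise with SD = amplitude/SNR. Two equal
Gaussians closer than 2σ have a single summed maximum, so pairs below that
separation are flagged merged in the ground truth — the flag is the
analytic resolvability condition, not a tuned constant.

Segmentation is classical: Gaussian smoothing (0.5 μm) → Otsu → hole
filling → optional distance-transform watershed for touching nuclei
(plateau maxima are merged into single markers). Border-touching nuclei are
excluded by default because truncation biases area and the spatial
statistics. Precomputed label masks from any external segmenter are
accepted via `records_from_labels`, so the in-package segmenter is a
default, not a dependency of the pipeline contract.

LoG detection computes the scale-normalized response −σ²∇²G∗I at a single
scale matched to the expected spot radius (multi-scale was not needed for
diffraction-limited foci of near-constant size). The detection threshold is
adaptive: mean + k·SD of the response inside nuclei, default k = 5. Each
local maximum seeds a focus segmented as the connected response region
above half the seed response; the reported coordinate is the
intensity-weighted centroid of that focus in the raw channel. Spots are
assigned to nuclei through a 2 px label expansion so that boundary foci
survive sub-pixel segmentation erosion; detections farther outside every
nucleus are discarded.

Measured behaviour: on noiseless well-separated foci, recall and precision
are 1.0 with localization error ≤ 0.3 px. At SNR 3 the default k = 5
trades recall for precision: precision stays ≈1.0 while recall drops to
≈0.25 as dim foci fall below the adaptive threshold; k = 3 recovers
recall ≈0.95 at precision ≈0.93. The default favours specificity because
screen metrics average hundreds of cells per well and false foci bias the
clustering score systematically, whereas missed foci mostly add noise.

## Cell-cycle gating

DNA content doubles from G1 to G2/M, so log2 integrated DAPI shows two
modes one unit apart. `fit_gates` fits the modes on EdU-negative cells
(two-component Gaussian mixture by default; histogram-valley/Otsu as the
alternative) and rejects fits whose separation is not 1 ± 0.35 log2 units —
a unimodal population cannot be gated and raises with a diagnostic.
Windows default to ±3 fitted component SDs. EdU positivity is an Otsu
two-class split on log2 EdU ("detectable EdU" operationalized as a
data-driven threshold). Assignment: EdU-positive → S; EdU-negative inside
the G1 (G2/M) window → G1 (G2M); below the G1 window → excluded (subG1
debris); above the G2/M window → excluded (>4N); EdU-negative between
windows → unassigned by default (configurable nearest-window), kept out of
phase-stratified summaries to avoid contaminating G1/G2M with mis-gated
S-phase cells.

The synthetic mixture draws G1 DAPI at mean m with CV 0.06, G2/M at exactly
2m, S uniform between (replication in progress), EdU log-normal around
well-separated positive/negative means, and true spot counts that double
from G1 to G2/M. Optional subG1 (0.4m) and >4N (4m, modelling 8N
doublets/polyploid debris) outlier fractions exist for exclusion tests. A
separability warning is recorded when the CV is large enough that the 2N/4N
log2 modes come within 6 SD of each other.

## Screen model and statistics

The screen simulator emulates the study conditions of an arrayed
high-content CRISPR screen: 384-well (16×24) plates, controls in column 1
(scrambled / non-expressed-gene neutral / essential-gene lethal /
condensin-II-like clustering), the library filling the remaining wells, two
biological replicates, ~200 cells per well (Poisson), 1064 genes by
default. Per-cell features are Gaussian around well-level means; planted
effects are expressed in units of the expected robust SD of neutral well
means (√(σ_well² + σ_cell²/n̄)), so a "+4" effect corresponds to an
expected downstream robust Z of ≈ +4 by construction. Plate artifacts are
additive row/column offsets on the well-mean scale — the structure the
B-score removes. Lethal controls only reduce cell counts (viability
controls); 2% of cells are dysmorphic/micronucleus-like so the QC filter is
exercised.

Analysis chain:

1. **QC** — drop cells with solidity < 0.85 or area < 30 μm² (strict
   inequalities; boundary values are retained).
2. **Well means** — arithmetic mean per well over QC-passing cells (median
   behind a flag); empty wells carry flagged missing means.
3. **B-score** — per plate: centre on the median of library wells, two-way
   median polish with row/column medians computed over library wells only
   (extreme controls are scored but never drive the fit), residuals scaled
   by 1.4826·MAD of library residuals. MAD ≈ 0 (including the
   float-epsilon case after an exact polish) falls back to the SD; a fully
   constant plate raises. Default 10 sweeps at tol 1e−6; convergence to
   machine-level row/column medians takes ~30 sweeps on pure noise, but the
   residual medians after 10 are already two orders below the noise scale.
4. **Robust Z** — (x − median)/(1.4826·MAD) against all library wells of
   one replicate pooled across plates.
5. **Replicate merge** — mean and sample SD per perturbation (for two
   replicates the SD is |z₁ − z₂|/√2); single-replicate SDs are flagged
   missing.
6. **Hit calling** — exclusions first: cytotoxic (cell-number mean Z
   < −2.5), dysmorphic-excess (perturbation's QC-failure fraction > 0.5),
   and per-metric inconsistency (|mean Z| < replicate SD). Survivors are
   hits when |mean Z| ≥ 2.5 on clustering score or spot count. Directions
   follow the sign; both-metric hits map to phenotype categories
   (clustering↑ count↓ = higher overall clustering; clustering↓ count↑ =
   overall dispersion; both ↓ = global dispersion with local clustering
   into fewer larger clusters; both ↑ = more numerous local clusters).

The cell-number Z is computed from QC-passing counts per well and
normalized exactly like the feature metrics.

## What the synthetic data does and does not show

The generators provide exact ground truth (process labels, planted effects,
phase labels), which is what makes recovery tests meaningful. They do not
model several features of real screen data: field-to-field illumination and
focus variation within a well, spatial cell-density effects, segmentation
errors on touching or apoptotic nuclei, spot-intensity heterogeneity of
real immunofluorescence foci (the amplitude distribution is configurable
but not calibrated to any antibody), chromatic offsets between channels, or
editing-efficiency heterogeneity between cells of one well. Passing tests
therefore demonstrate the correctness and calibration of the statistics
under the stated generative model, not the end-to-end accuracy of any
specific microscope + segmenter combination; the precomputed-mask entry
point exists so real segmentations can be swapped in.

## Numerical choices and problem sizes

Monte-Carlo baselines default to 100 draws; a 500-cell CSR calibration then
has ≈0.05 residual noise in its mean. Acceptance-style checks run at 200
Ripley fixtures, 500 CSR cells over spot counts 10–92, 100 size-scaling
fixtures, 100 cells per monotonicity condition, 10⁴ points for the radial
limit, 15 rendered cells per SNR for detection, 5000 cells for gating, and
1000-gene screens for hit recovery — sizes chosen so the whole battery
completes in well under a minute each while keeping binomial/Monte-Carlo
error comfortably inside the asserted bounds. All randomness flows through
explicit integer seeds; equal seeds give bit-identical outputs end to end,
including the CSV artifacts of the CLI pipeline.

## Known limitations

* The clustering score's Monte-Carlo baseline makes single-cell scores
  noisy at very low spot counts; the `min_spots = 3` floor is a practical
  lower bound, not a statistical guarantee.
* The hard-core sampler is sequential rejection, which realizes a slightly
  different process than an equilibrium Gibbs hard-core model; for the
  purpose of providing "more regular than CSR" fixtures this is immaterial.
* Median polish on plates with very few library wells per row/column is
  fragile; at least 2 occupied library rows and columns are required.
* The radial-distance ray march resolves the boundary to ~0.25 px, which
  biases the disk mean by ≲0.005 at the default resolution.
* Field-level batch effects within wells are neither simulated nor
  corrected; wells are the smallest statistical unit.
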