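# Methods

## Data model and units

All coordinates are micrometres and all times seconds; pixel coordinates are
converted once, at the I/O or detection boundary, using the pixel size.
Frames are 0-based integers. Tracks must contain at least two localizations
with strictly increasing frames; frame gaps (from gap-closed linking) are
preserved and never interpolated, since interpolation would deterministically
understate displacement variance and bias the MSD. The default frame
interval is 0.03 s, matching 30 ms camera exposures; the default pixel size
is 0.1 µm/px (a typical 100×/EM-CCD configuration) and is a required,
explicit parameter everywhere it matters because it cannot be inferred from
track tables.

## Motion statistics

**MSD and diffusion coefficient.** The time-averaged MSD at lag kΔt uses
*all* overlapping frame pairs (i, i+k) present in the track — maximal data
use and standard SPT practice; pairs spanning a gap are simply absent. Each
track receives a single D as the unweighted mean over available lags of
MSD(τ)/(qτ) with q = 4 for 2D imaging. Averaging over all of a track's lags
controls the bias that variable track lengths would otherwise introduce, at
the cost of imprecision for non-Brownian tracks: directed motion adds a
(vτ)² term that grows quadratically with lag, and localization noise adds a
4σ² floor whose D contribution scales as σ²/τ (largest at the shortest
lag) — so the estimator is biased *upward* by noise and drift, never
truncated below zero. The `max_lag` option restricts the average to short
lags; the pipeline defaults to 0.3 s (10 lags) because long-lag MSDs rest on
very few pairs and, for drift-dominated tracks, the quadratic term would
otherwise dominate any pooled-range binning of D. With this cap, the median
per-track D of simulated Brownian populations is within ~3% of truth; with
all lags included the heavy right skew of few-pair lag estimates pulls the
*median* roughly 16% below the (unbiased) mean.

**Confinement ratio.** R = (d_net/d_tot)·t_track in the default
`as_printed` mode. The duration product makes R dimensional (seconds) and
able to exceed 1 for long straight tracks, which conflicts with interpreting
it on a [0, 1] scale; rather than silently reinterpreting the formula, the
`sqrt_duration` mode (Beltman-style, × √t_track) and the dimensionless
`plain` mode (d_net/d_tot) are selectable by configuration, and every output
records which mode produced it. A fully stationary path (d_tot = 0) is
defined as maximally confined (R = 0) with a logged warning. Duration is
the frame *span* times Δt, so gapped tracks are not shortened by missing
detections.

**Motion profiles and circularity.** A cell's motion profile pools the
origin-zeroed displacement points of all its tracks. The outline is the
convex hull — deterministic and parameter-free — with area by the shoelace
formula and perimeter as summed edge lengths; r_circ = 4πA/p². The hull
biases r_circ upward for concave clouds (it cannot see indentations), which
is acceptable for comparing stages against each other but should be kept in
mind for absolute values. An exactly collinear cloud has zero area and is
reported as r_circ = 0 without error. Direction vector diagrams bin the
atan2 angle of each track's net displacement into equal sectors (sector 0
centred on +x); zero-net tracks carry no direction and are excluded but
counted.

## Synthetic data generator

The generator emulates sparse photoswitched-emitter imaging: per track, a
motion model drawn from a mixture; Brownian per-axis steps N(0, √(2DΔt));
directed motion adds a constant drift·Δt; confined motion reflects off a
circular corral centred on the track's start. Cell geometries (rectangular
process, small/large disc) reflect at their walls via path folding (exact
for axis-aligned walls, a good approximation for discs when steps are much
smaller than the radius). Track lengths are geometric — memoryless
photobleaching — truncated to [2, max_frames] with max_frames = 2500 (a
2500-frame acquisition), and the default per-frame bleach probability 0.03
gives a mean track length of ~33 frames, i.e. photobleaching-limited tracks
of around one second. Localization error is applied to coordinates
(independent N(0, σ), default σ = 20 nm per axis) *before* any rendering, and
the camera model (Gaussian PSF of FWHM 3 px, Poisson shot noise on
signal+background, Gaussian read noise, 16-bit clipping) is applied
separately at render time — so trajectory-level analyses can bypass imaging
entirely, and imaging-level tests can compare against exact ground truth.

**Stage presets.** The per-stage motion mixtures are package fixtures chosen
to reproduce a qualitative developmental signature — median circularity
OPC > eOL > mOL, median confinement ratio eOL > OPC > mOL, and a
fast-diffusive subpopulation present in OPC and mOL but absent in eOL — not
estimates of real per-stage motion parameters, and they are deliberately
never matched to any published median. OPC is an isotropic Brownian mixture
(D from 0.001 to 0.05 µm²/s, 7% fast) in a 2×10 µm process; eOL removes the
fast fraction and adds a 30% gently directed component (0.24 µm/s) in a
2 µm-radius bubble; mOL is 60% tightly confined (corral 0.05 µm), 28%
strongly directed (2.0 µm/s) and 12% fast Brownian in an 8 µm-radius sheet.
Within one simulated cell all directed tracks share a drift axis drawn from
the cell's seed — the anisotropy that elongates a motion profile is a
cell-level property, as it is in maturing sheets where transport is biased
toward the cell periphery. With 1300 simulated tracks per cell, the
<10-localization filter leaves roughly 950–1000 tracks, inside the 650–1500
band typical of one imaged process or sheet.

What the generator does *not* model: photoswitching/blinking kinetics,
anomalous (non-Brownian) diffusion exponents, motion in z, spatially varying
background, and within-cell heterogeneity of motion parameters. Passing the
ordering tests therefore demonstrates that the *analysis* recovers known
population structure from trajectories with realistic noise, bleaching and
geometry — not that real cells have these parameter values.

## Detection and linking

Detection is LoG-style: a difference-of-Gaussian band-pass at the expected
spot scale (FWHM 3 px → σ = 3/2.355), strict local maxima gated by a robust
intensity threshold, background = median and robust SD = 1.4826·MAD of the
raw frame (appropriate for sparse bright spots on a dark background, where
mean/SD would be inflated by the spots themselves). Subpixel positions come
from per-axis Gaussian (log-parabola) interpolation of the 3-point stencil
around each maximum — exact for Gaussian spots, whereas a windowed intensity
centroid showed ~24% shrinkage toward pixel centres with half-pixel
discontinuities; measured localization RMSE on rendered ground truth is
≤0.07 px at the default SNR. Linking is greedy mutual-nearest-neighbour per
frame pair, distance-sorted with deterministic tie-breaks (smaller distance,
then lower detection index), links rejected beyond `max_disp_px`, and
unmatched track ends kept alive for `max_gap` frames (default 1). The
short-track filter counts localizations (not frame span) and is inclusive at
the threshold: with the default `min_frames = 10`, a 10-point track
survives. Localization precision is estimated exactly as a bead calibration
would: per stationary particle, the sample SD of x and y across a 20-frame
series, reported as mean (± SD) across particles in nanometres; calibration
fields place beads at least 6 PSF-σ apart, since overlapping tails corrupt
the interpolation stencil.

## Distributions and categories

Binning grids are shared across conditions: the pooled values of all
conditions set the range, divided into equal-width bins (10 for confinement,
12 for diffusion), left-inclusive/right-exclusive except the last bin, which
is right-inclusive so the pooled maximum is counted. Frequency tables report
percent of the full population; the option to suppress a dominant first bin
affects *only* the graphed output — the bin still counts toward every
percentage and all statistics always use the full population. Category
labels (slow/intermediate/fast; highly/moderately/lightly confined) are a
visualization aid and provably never touch any statistic. The pipeline's
default diffusion-category boundaries are bins (1–2 | 3–4 | 5–12) rather
than equal thirds: per-track D is extremely right-skewed, so equal thirds of
the linear pooled range would label almost no particle fast; the chosen
boundaries align the colour groups with the slow (~10⁻³), intermediate
(~10⁻²) and fast (~5×10⁻²  µm²/s) mobility classes. Note that published
descriptions of such binning can be internally inconsistent (a quoted
"slowest bin" width an order of magnitude below the pooled-range/12 width);
bin counts and boundaries are therefore configurable throughout.

## Statistics

Group location is summarized as median plus IQR (linear-interpolation
quartiles) with a distribution-free 95% CI for the median from the binomial
order-statistic method — conservative (coverage ≥ 95%), falling back to the
sample extremes for very small n. The one-sample KS screen against a fitted
Normal is deliberately approximate (no Lilliefors correction): it only
routes the analysis to nonparametric tests, and a constant sample rejects
outright. Two-sample comparisons of full distributions use the two-sample
KS test with the asymptotic Kolmogorov p-value at effective sample size
n_a·n_b/(n_a+n_b); exact small-sample p-values are out of scope, so p-values
for tiny groups are approximate. Because each group enters two pairwise
comparisons in a three-stage design, the KS alpha is Bonferroni-corrected by
2 (0.05 → 0.025, 0.001 → 0.0005). Multi-group location differences use
Kruskal–Wallis (mid-rank ties, tie-corrected H, χ² p with k−1 df; an
all-identical input returns H = 0, p = 1 rather than an error) with Dunn's
post hoc: z from the mean-rank difference with the pooled tie term,
two-sided normal p, Bonferroni-adjusted over all pairs — the standard Dunn
adjustment. Per-particle and per-cell replication levels are both
implemented and are never mixed within a single test.

## Pipeline and reproducibility

The default pipeline path feeds simulated trajectories directly into the
metrics stage; rendering movies and re-tracking them is opt-in, so detection
noise only enters analyses that ask for it. All randomness derives from one
seeded generator per run (cell seeds drawn sequentially from it), making the
JSON report byte-identical across repeats of the same configuration and
independent of the output directory. Reports carry the seed and a hash of
the analysis parameters. Stage failures abort with the stage and cell
identity. Test and benchmark problem sizes — 10 cells per stage at 1300
simulated tracks per cell for ordering checks, 500 tracks × 100 frames for
estimator recovery, 500 permutation replicates for the KS type-I check —
are the package's chosen desk-scale defaults; they complete in well under a
minute each on one core.

## Known limitations

- Eq.-style duration correction (`as_printed`) produces values outside
  [0, 1] for long straight tracks; use `plain` for a bounded statistic.
- The convex-hull outline overestimates circularity of concave profiles; an
  alpha-shape alternative would require a scale parameter and is not
  included.
- The greedy linker has no merging/splitting or multiple-hypothesis logic;
  at high densities or with crossing trajectories it will swap identities
  where a JPDAF/LAP tracker might not. All closed-loop guarantees are stated
  for sparse fields.
- Asymptotic KS p-values only; Dunn p-values use the standard Bonferroni
  adjustment (other software may default to unadjusted or Holm-adjusted
  values).
- No anomalous-diffusion exponent fitting, rolling-window diffusion states
  or HMM segmentation; per-track D assumes the linear MSD of normal
  diffusion.
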