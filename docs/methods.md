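# Methods

This note documents the models and procedures implemented in `octachorio`,
the parameter choices that matter, what the synthetic generators do and do
not emulate, and the numerical conventions.

## Flow-deficit quantification

The choriocapillaris en face slab shows a granular pattern of bright
(flowing) and dark (flow-deficit) regions. The pipeline is:

1. **Large-vessel masking.** The retinal composite slab is binarised at a
   fixed threshold (default 0.6 on [0, 1]; the threshold is recorded in the
   output). The mask removes the shadow cast by large retinal vessels onto
   the CC slab: masked pixels take no part in clustering, are forced to
   background in the deficit map, and their area is subtracted from the
   analysed area, so FD density is relative to the shadow-free field. An
   option (`exclude=None`) retains the full field for sensitivity analysis.
   No mask dilation is applied by default.
2. **Fuzzy C-means.** Standard FCM on the included scalar intensities:
   memberships u_ik ∝ d_ik^(−2/(m−1)) normalised over clusters, centroids
   as u^m-weighted means, iterated until the largest centroid shift falls
   below `tol`. Defaults: 2 clusters (flowing vasculature vs deficit),
   fuzziness m = 2, tol = 1e-5, max_iter = 300. Centroids are initialised
   deterministically at evenly spaced intensity percentiles (10th…90th), so
   the default pipeline is seed-free and bit-reproducible; random
   initialisation is available and is the only consumer of the seed. A
   constant included field raises a degenerate-input error; non-convergence
   returns the result flagged `converged=False`. Pixels are hard-assigned
   by maximal membership and the darkest-centroid cluster is the deficit
   map. Whether more than one dark cluster should be pooled when
   `clusters > 2` is left to the caller (only the darkest is used).
3. **Component filter.** Deficit components are labelled with
   8-connectivity. A component of pixel area A (µm²) has equivalent
   diameter d = 2·√(A/π); components with d below 24 µm — about the
   intercapillary distance, below which "deficits" are indistinguishable
   from normal intercapillary spacing — are discarded. A component at
   exactly the cutoff is retained; the comparison uses a 1e-9-µm slop so
   that an area whose diameter equals the cutoff analytically is not
   dropped by floating-point rasterisation.
4. **Indices.** Mean FD size = ΣA / count (NaN when no component remains);
   FD density = 100·ΣA / analysed area.

Filter monotonicity (raising the cutoff never increases count or density,
never decreases mean size), mask exclusion, membership normalisation and
scale equivariance are enforced by property tests; FCM is checked against
an independent loop implementation to 1e-6.

## Sector grids

Macular grid: concentric circles of 1, 3 and 6 mm diameter about the fovea;
the central disc is the fovea zone, the 1–3 mm (parafoveal) and 3–6 mm
(perifoveal) annuli are each split into superior / inferior / nasal /
temporal quadrants by the two 45° diagonals (the classic X-shaped ETDRS
division). Peripapillary grid: the optic-disc circle plus an annulus
extending 2 mm radially outward from the disc *boundary*, split into eight
45° sectors whose boundaries lie on the vertical/horizontal axes (sector k
covers [45k°, 45(k+1)°) from the nasal axis; names are
hemifield-then-half, e.g. NS = nasal hemifield, superior half). The source
protocol says only "a ring 2 mm wide centred on the disc"; measuring from
the disc edge was chosen because a fixed-radius ring would make the
measured region depend on disc size in the opposite way; the disc radius is
a parameter (default 750 µm, a typical disc).

Conventions: pixel membership by pixel-centre distance, 0-based (row, col)
coordinates, half-open angular intervals [lo, hi) as the deterministic
tie-break on sector boundaries. Laterality: for OD the nasal side is the
image right; OS grids are exact mirror images across the vertical axis.
Zone areas agree with the analytic circle/annulus areas to within one
boundary-pixel ring; the zone partition conserves pixel counts exactly.
Fovea/disc centres are inputs — there is no auto-detection.

## Choroidal thickness and vascularity

CT at each A-scan is (CSI row − Bruch row) × axial scale; it depends only
on the boundary traces, never on image content. Crossing traces raise an
error naming the offending A-scan.

CVI is the luminal fraction of the choroid band. The device's binarisation
is proprietary, so the package uses Niblack local thresholding
(T = m − k·s over a 51-px window, k = −0.05), the de-facto standard in the
CVI literature; pixels darker than T inside the band are lumen. A 1e-6
epsilon on the comparison prevents perfectly uniform windows from
classifying themselves as lumen through convolution round-off. When a
ground-truth luminal mask accompanies the stack the binarisation is
skipped.

Regional values pool pixels: per macular zone, CVI = luminal pixels /
band pixels over all A-scans assigned to the zone (not a per-B-scan average
— pooling weights every A-scan by its actual band height), and CT is the
arithmetic zone mean of the thickness map. B-scans are taken as evenly
spaced rows of the 6 × 6 mm field; the grid label map is resampled to the
stack raster by nearest neighbour.

## Vessel density

Vessel density per zone is 100 × vessel pixels / zone pixels after
binarising the slab. Global Otsu is the default (parameter-free,
reproducible, recorded in the result); a fixed threshold is available. The
exact device algorithm is unknown; Otsu reproduces it only qualitatively.

## Synthetic data

The generators emulate the study conditions so the pipeline can be tested
with known truth.

**CC images** (default 512 × 512 px over 6 × 6 mm, 11.719 µm/px — typical
swept-source sampling): deficits are discs with log-normal diameters
(default mean 40 µm, SD 10 µm — flow-void scales reported for healthy CC,
and safely above the 24-µm filter), rejection-placed without overlap and
with a 1.5-px edge gap so 8-connected labelling keeps every planted disc a
separate component. Planting stops when the pixel-measured density is
within ±0.5 percentage points of the target (the closing disc is shrunk to
land inside the band); an unreachable target raises an infeasible-density
error. Default density 8.05 % with deficit intensity 0.2 on background
0.7 and additive Gaussian noise (SD 0.02). Ground truth records every disc
with its pixel area, so recorded areas equal label-map pixel counts times
the pixel area exactly.

**Retina images**: a branching vessel tree (random-walk segments, width
tapering at bifurcations) stamped at intensity 0.9 on background 0.3 with
hard edges — a noise-free image binarises exactly back to the ground-truth
mask at the default 0.6 threshold.

**B-scan stacks**: flat Bruch trace, CSI trace at the requested per-A-scan
thickness (rounded to axial pixels, default 3 µm). The luminal texture is a
jittered square lattice of 3-px-radius dark discs whose pitch is sized so
per-cell coverage equals the requested fraction — coverage is then
spatially uniform rather than merely uniform on average, and the small
edge-clipping deficit is topped up with scattered 1.5-px discs. Lumen is
0.2 on stroma 0.8, and the whole B-scan outside the band is stroma-bright,
which keeps every Niblack window bimodal so noise-free binarisation is
pixel-exact.

**Cohort tables**: two populations (`pop1`, `pop2`, 25 subjects each by
default) with per-variable normal marginals (mean, SD per population) read
from the packaged parameter table (`data/study_parameters.yaml`, one entry
per source-table cell), clipped at physical bounds (CVI to [0, 1],
densities to [0, 100], concentrations and thicknesses ≥ 0). Dependence is a
one-factor Gaussian copula anchored on aMT6s: each metric's latent normal
is ρ·z_aMT6s + √(1−ρ²)·ε, so metric–metric correlations are those implied
by conditional independence given aMT6s, and the latent matrix is positive
semi-definite whenever |ρ| ≤ 1 (a non-PSD matrix raises; eigenvalue
clipping can be enabled explicitly).

Two calibrations make the *configured* quantities the *observed* ones:

* The configured correlation is the pooled (study-level) Pearson r. Because
  the populations differ in their means, the within-group latent ρ that
  reproduces a pooled r is solved from the two-group normal-mixture
  identities Var(x) = mean(σ_g²) + (Δμ/2)² and
  Cov = ρ·mean(σ_x,g σ_y,g) + Δμ_x Δμ_y/4, clamping ρ to [−1, 1] when the
  target is unattainable.
* Clipping at a binding bound shifts the observed mean away from the latent
  location (for aMT6s in pop1 by ≈ +0.7 pg/ml); the generator inverts the
  closed-form clipped-normal mean so that sample means converge to the
  configured values.

On the flow-deficit pair the parameter table follows the study's stated
direction — the low-melatonin population carries the lower FD size
(25.80 ± 2.01 vs 32.22 ± 4.60 µm²) and density (6.03 ± 1.44 vs
8.05 ± 1.93 %). The source prints the pair once in the opposite order while
calling it "lower"; the stated direction is also the only assignment
consistent with the positive pooled aMT6s–FD-size correlation it reports
(with the opposite assignment the between-group covariance term alone caps
the achievable pooled r at 0.296 < 0.318, for any generator).

What the generators do **not** emulate: OCT speckle statistics, projection
and motion artifacts, drusen or other shadowing pathology, non-normal or
skewed biological marginals, disc-size variation, or any dependence of the
image texture on the cohort columns (mean FD size enters the cohort as the
printed per-subject summary statistic, whose scale is not self-consistent
with the 24-µm filter — an image with that mean component size would
contain no retainable component — so the image path and the statistics path
are deliberately decoupled). Passing tests therefore demonstrate the
correctness of the measurement and statistics machinery under the
configured conditions, not robustness to real-device artifacts.

## Statistics

Shapiro–Wilk (α = 0.05) gates every parametric choice: two-group
comparisons use the equal-variance t-test when both groups pass (Welch by
flag), else the two-sided Mann–Whitney U; correlations use Pearson when
both pooled variables pass, else Spearman (the gate is applied to the
pooled sample because the source does not state the grouping; at very
large simulated n the gate detects the two-population mixture and routes to
Spearman — recovery tests that specifically target the copula's Pearson
parameter force `method="pearson"`). Sex is compared by chi-square.
Multivariable models are OLS of a metric on age + axial length + spherical
equivalent + aMT6s with two-sided coefficient p-values; rank-deficient
designs raise. No multiple-testing correction is applied by default,
matching the source analysis; a Bonferroni flag exists on the report
helpers. All tests are two-sided with significance at 0.05.

## Problem sizes and reproducibility

Test and acceptance workloads use 256-px images for planted-truth recovery,
128-B-scan stacks for zonal CVI, 10,000 subjects per population for
parameter recovery and 200 Monte-Carlo replicates for power checks — sizes
at which sampling error is well inside the asserted tolerances while the
whole suite runs in well under a minute. Every stochastic component draws
from `numpy.random.default_rng(seed)`; identical configuration and seed
reproduce every output byte (run logs carry timestamps only).

## Known limitations

* The FCM cluster count, the fixed vessel threshold, the Niblack window/k
  and the Otsu choice stand in for unspecified or proprietary device
  algorithms; absolute values will differ from device output even when the
  group contrasts are preserved.
* CVI pools pixels per zone; devices that average per-B-scan CVI values
  weight thin and thick A-scans differently.
* The copula induces dependence only through the aMT6s factor; real
  metric–metric correlations (e.g. between neighbouring zones) are not
  represented.
* One eye per subject is assumed throughout; there is no eye-level
  clustering or mixed modelling.
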