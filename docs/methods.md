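# Methods

This note documents the models, defaults and numerical choices behind
`lungspatial`, and what the synthetic validation does and does not
demonstrate about real data.

## Capture-array model

Visium arrays are modeled as a parity hex lattice: a spot exists at
(array_row, array_col) iff row + col is even, and its six neighbors are
(r, c±2), (r±1, c±1). Physical constants: 55 µm spot diameter, 100 µm
center spacing (hence a 45 µm interstitial gap), hex row pitch
100·√3/2 µm. The default image scale is 10/3 µm/px, chosen so the
500 µm peripheral threshold equals exactly 150 px. Position tables
store integer pixel centers (the Space Ranger convention);
`make_hex_grid(..., round_pixels=False)` exposes the exact lattice,
which the geometry oracles use because the irrational row pitch makes
integer rounding perturb nearest-neighbor distances by up to ~0.9 px.

## Synthetic study generator

The generator emulates the statistical structure the analysis assumes,
not lung histology. Defaults describe a 12-sample design: six
pseudoglandular samples (weeks 13–16) and six canalicular (17–20),
mixed sexes (5 male / 7 female) and four trisomy-21 cases spread across
stages, on a 40 × 60 array (~1200 spots, ~640 inside a disk-shaped
tissue mask; 5% of tissue spots are planted tissue-sparse).

**Type field.** 100 cluster centers are placed uniformly over the
lattice bounding box; the per-type center count follows the target
composition by largest-remainder allocation. A spot takes the type of
its nearest center under independent Gaussian positional noise per
spot-center comparison, with scale `clustering_dispersion` (µm). Small
dispersions yield crisp Voronoi-like type domains (~300 µm across at
the default center density); as the dispersion grows the winning center
becomes uniform, so labels converge to independent multinomial draws of
the composition — the property the frequency-recovery tests rely on.
Defaults: 300 µm (pseudoglandular) vs 150 µm (canalicular), encoding
the tighter spatial compartmentalization of the later stage; the
canalicular composition also shifts distal parenchyma +0.15 and
mesenchymal parenchyma −0.15, the developmental signal the composition
tests are expected to recover. The spatial processes of real sections
are not known quantitatively; this field is a stand-in with a single
clustering knob, not a fit.

**Counts.** Negative-binomial with dispersion θ = 2: 2000 genes = 10
types × 20 markers (mean 6 in their own type, 0.25 elsewhere) + the 7
Y-signature genes (mean 3 iff the sample is male, exactly zero
otherwise) + background (mean 0.25). Expected spot total ≈ 615,
comfortably above the 200-count QC threshold; tissue-sparse spots have
all means shrunk ×0.1 (expected total ≈ 62), so the count filter and
the image filter agree on them.

**Images.** Per-pixel stain concentrations (eosin from a shifted gamma
with mean 1.3 OD and a hard floor at 0.78, hematoxylin independent with
mean 0.1, sparse spots at ≤ 0.04) are rendered by Beer–Lambert:
I_c = I0 · 10^(−Σ_s C_s S_{s,c}), 8-bit by truncation (so a unit OD
maps 255 → 25), I0 = 255. Stain vectors are the Ruifrok–Johnston
absorbance directions. The floor/trace separation makes the planted
sparse spots unambiguous (≥ 30× in q90 OD), which is what lets the QC
recovery criterion demand precision = recall = 1; real sections have a
continuum, where the Otsu default is only a starting point.

## Spot QC

OD conversion uses −log10((I + 1)/I0) clipped at zero; the +1 guard is
below the 8-bit quantization step. A pixel is non-transparent iff all
three OD channels exceed β = 0.15 (the Macenko convention). The eosin
direction is the largest eigenvector of the non-transparent pixel
covariance, sign-fixed to positive mean projection; estimation is
per-image. Normalization rescales the eosin projection so its 0.99
quantile over non-transparent pixels equals 1.0 (the reference pixel
value is not standardized across tools; any fixed quantile/value pair
gives exposure invariance, which is the property that matters).
Spot summaries use the linear-interpolation quantile (q = 0.90) over
pixels in the capture disk. The default sparse cut is the Otsu split of
the per-spot q90 distribution; because histogram Otsu returns a bin
center that can sit below values of its own bin, the threshold is
snapped to the midpoint of the data gap at the cut, making the
partition exact under the `q90 < t` rule. Filter order: vendor
in-tissue flag → q90 sparse filter → 200-count filter; edge labels
(≥ 1 of the six lattice neighbors background or off-array) are computed
on the final retained set.

## Border and periphery

The automated border is the outer boundary of the largest connected
tissue component: tissue spots adjacent to background reachable from
off-array space (interior hole rims are excluded). Manual border files
(one barcode per line) remain the faithful mode, since pleural-surface
selection is a judgment call; listed ids must be edge spots. Distances
are Euclidean center-to-center in full-resolution pixels; the µm/px
scale is the mean of 55/spot-diameter-px and 85/fiducial-diameter-px
(85 µm is the vendor fiducial constant), with a warning if the two
channels disagree by > 5%. The peripheral rule is inclusive
(distance · scale ≤ 500 µm); a fixed 150 px mode is provided for
workflows that used the pixel form.

## Ripley statistics

The uncorrected estimator is the default — on a fixed, fully observed
spot lattice the random-labeling null uses the same window, so edge
bias cancels in the comparison; a translation correction is available
(pairs with no valid translation get weight zero). The radius grid is
50 equally spaced radii from 0 to half the window's shorter side;
window area is the bounding box of retained spot centers (convex hull
optional). The null conditions on the observed lattice by permuting
labels rather than simulating Poisson points, because spot density is
fixed by the array, not by cells. Envelopes are pointwise percentile
bands (2.5/97.5) over ≥ 39 label permutations; a single null curve is
strongly correlated across radii, so calibration statements are about
coverage averaged over trials, not any single curve. Stage aggregation
pools all (r, L) points of a (stage, type) cell in micron units and
applies a tricube-weighted local-linear fit (span 0.75; ties at a query
point fall back to the local mean; windows with < 2 distinct x give
NaN). The smoother matches `statsmodels` lowess (it = 0) to machine
precision, which a test pins.

When comparing stages that differ only in clustering intensity, the
informative radii run from one lattice spacing (100 µm) to roughly
three type-domain diameters (~1000 µm): below that the lattice itself
dominates, above it the curves converge for any labeling. Note that a
composition shift moves L in the opposite direction to a dispersion
tightening (a type occupying more area is less clustered relative to
CSR), so clustering comparisons between groups with different
compositions confound the two effects.

## Composition statistics

Frequencies are per-sample spot-type proportions over retained spots.
Stage comparisons use the Wilcoxon rank-sum test with full enumeration
of label assignments for combined n ≤ 12 (mid-ranks under ties;
two-sided p = min(1, 2·min(P≤, P≥))), which removes approximation error
at the 6-vs-6 scale; larger samples use the tie-corrected normal
approximation. Benjamini–Hochberg adjustment is applied across the 10
types (raw p also reported). The condition comparison is an omnibus
permutation test with statistic T = Σ_types (mean freq₁ − mean freq₂)²,
uniform sample-label permutations, and the add-one p-value correction;
an exact mode enumerates all distinct splits. The peripheral comparison
defaults to a paired t across samples (each sample contributes both
regions); identical pairs are an error because t is undefined at zero
variance. Pseudobulk aggregation is an exact integer group-sum over
(sample, cluster); conservation of the grand total is asserted, not
assumed. The sex signature is scored UCell-style with r_max = 1500 and
mid-rank ties (ranks beyond r_max clamp to r_max + 1); scores are in
[0, 1] and the male call threshold is 0.2 — male samples in the
generator score ≈ 1.0 and female ≈ 0.002 (the formula's floor), so the
call is insensitive to the threshold over a wide range.

## Pipeline

Stages are pure functions of (inputs, config, seed); YAML configs are
schema-checked (unknown keys rejected) and hashed into the run
manifest, and reruns at a fixed seed are byte-identical. Spot types for
the Ripley and composition stages come from the bundle's annotation
table (the generator's ground truth, or a user-supplied equivalent);
deriving types by expression clustering is deliberately out of scope,
as are deconvolution and differential-expression model fitting — the
pipeline produces the pseudobulk and composition inputs those tools
consume.

## Problem sizes and limitations

Validation sizes were chosen to exercise each property at the study's
own scale: full 40 × 60 samples for image QC and stain estimation
(stain-vector error grows on very small images, where the strict
all-channel transparency mask leaves few pixels), ~2000-spot samples
for the 6-vs-6 power study (50 replicates), 1000 trials for permutation
calibration, and brute-force cross-checks up to n = 300 points.

Passing these tests shows the implementation is correct and calibrated
under the generator's assumptions — independent NB counts, a
single-scale clustering process, two-stain Beer–Lambert images with a
clean sparse/dense separation. They do not demonstrate robustness to
real-tissue phenomena: stain batch variation and uneven illumination,
continuous tissue-density gradients, spatially correlated expression
within domains, doublet-like mixed spots, or annotation error in the
spot types. The automated border is a proxy for expert pleural
selection and will include non-pleural outer boundary segments on
sections where the pleura is only part of the tissue edge.
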