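# Methods

This note records the models, parameter choices and numerical conventions
behind `radioprot`, and what the synthetic-data experiments do and do not
demonstrate.

## Texture maps

Masked intensities are quantized per patient: values are clipped to the
1st–99th percentile range of all tumor voxels and rescaled linearly onto
levels 1..32 with rounding, so the clipped minimum maps to level 1 and the
clipped maximum to level 32. Rounding (rather than floor-binning) makes an
exact integer ramp 0..31 at 32 levels map to the identity, which is the
easiest regime to reason about; percentile clipping keeps single HU outliers
from stretching the level grid. Background voxels are never quantized.

GLCMs are built per voxel from the window intersected with the voxel's own
site, so boundary voxels never mix texture across sites or with background.
Windows are 2D in-plane with radius 2 (5×5) by default: at the 5 mm slice
thickness typical of abdominal CT a 3D neighborhood is strongly anisotropic
(one slice step spans five in-plane steps). A 3D window is available via
`planar=False`. Offsets are the four axial unit directions (0°, 45°, 90°,
135°), symmetric GLCMs, features averaged over the offsets that produced at
least one valid voxel pair. A voxel with no valid pair in any offset is
imputed from its nearest (physical distance) defined voxel of the same
site; a site smaller than two voxels stays undefined, is excluded from
clustering, and is logged.

The four features on the normalized GLCM P: energy Σ P², entropy
−Σ P log₂ P (0·log 0 = 0), contrast Σ (i−j)² P, homogeneity Σ P/(1+|i−j|).
Energy and homogeneity lie in (0, 1]; entropy and contrast are ≥ 0.

## Kernel K-means

Features are z-scored per feature over the patient's masked voxels
(constant features become zeros) before kernel evaluation. Squared
kernel-space distances to cluster means are computed purely from the Gram
matrix; with the linear kernel the objective is algebraically identical to
Lloyd's within-cluster sum of squares, which the tests exploit as an
oracle. Defaults: K = 4 sub-regions, RBF kernel with bandwidth equal to the
median pairwise distance of a seeded ≤ 1000-voxel subsample (gamma =
1/(2σ²)), K-means++-style seeding in kernel space, best of 5 restarts,
empty clusters repaired by splitting off the worst-fitting point.
Everything is deterministic given the seed. K is fixed rather than selected
per patient so the heterogeneity metrics are comparable across patients.

## IISTH metrics

With S sites, p_s the site's cluster-composition vector, w_s its voxel
fraction, and V_s its volume in mL:

* cluSE = −Σ_{s,k} q_{s,k} log₂ q_{s,k} with q = w_s p_{s,k}: the joint
  site-by-cluster entropy, ≤ log₂(S·K), in bits.
* cluSD = population SD (ddof = 0) over clusters of the total cluster
  volume Σ_s V_s p_{s,k}; ddof = 0 makes the degenerate single-cluster
  case exactly 0.
* cluDiss = Σ_{s<t} √(V_s V_t) ‖p_s − p_t‖₂: volume-weighted pairwise
  divergence of compositions, 0 when S = 1 or all compositions coincide.

These functional forms are this package's committed reconstructions of the
named quantities; they live behind a single interface
(`iisth_from_proportions`) so alternative definitions can be swapped
without touching the rest of the pipeline. One consequence worth knowing:
as sites diverge, clusters align with sites, so cluDiss *increases* while
cluSE (an entropy of mixing) tends to *decrease* toward Σ −w log₂ w. The
dose-response experiments therefore use cluDiss as the heterogeneity
readout.

## Phantoms

Each site is a connected 6-connected blob grown by seeded random accretion
(sites kept one voxel apart), filled with a unit-variance Gaussian random
field smoothed at a per-site scale σ_s and scaled by a per-site amplitude
around a common mean of 40 HU over a constant −50 HU background. The
default grid is 48×48×6 voxels at 1×1×5 mm with 3 sites of 120–260 voxels —
small enough that the full texture stage runs in well under a second per
phantom, while each site still contains hundreds of GLCM windows.

The `heterogeneity` knob h ∈ [0, 1] sets log σ_s = log σ₀ + h·0.9·δ_s and
log amp_s = log amp₀ + h·0.5·δ_{S+1−s} with δ evenly spaced in [−1, 1]; at
h = 0 all sites share identical texture parameters, and the declared
divergence functional (variance of per-site log parameters) grows as h².
Smoothing scale and amplitude directly move GLCM contrast/homogeneity, so
the knob translates into cluster compositions that separate by site.

What the phantoms do *not* emulate: anatomy, partial-volume effects,
scanner noise spectra, or contrast-enhancement physics. Passing the
dose-response test shows the metric chain is monotone in a controlled
texture-divergence parameter — not that it is calibrated on real CT.

## Synthetic omics and traits

Site transcript values are μ_g(1 + cv_g z), z ~ N(0,1): the empirical CV
concentrates near the planted cv_g. Conserved genes draw |N(0.05, 0.01)|,
the rest lognormal around 0.5 (log-SD 0.35) — a bimodal split wide enough
that CV ranks separate planted from background almost perfectly, which is
deliberate: the funnel tests measure the selection logic, not a detection
limit. Patient transcripts are standard normal; proteins are
ρ·t + √(1−ρ²)·ε (Gaussian copula), planted ρ = 0.8, null ρ = 0. The default
cohort mirrors the study conditions: 500 genes, 5 sites (primary + 4
metastatic), 107 patients with matched transcript and protein profiles, and
a 20-patient imaging cohort.

Traits follow a declared schema (binary, count, ordinal with explicit level
order, quantitative). Planted effects act on the link scale through the
standardized protein profile: logistic for binary, log-linear Poisson for
counts, latent-threshold for ordinal, linear for lengths; magnitude 0
reduces exactly to independence. Two synthetic readers perturb the
consolidated truth — symmetric label flips at a configurable disagreement
rate (default 0.1) for categorical traits, additive N(0, 3 mm) noise for
lengths — and the arbitration table is the truth itself, exercising both
consolidation rules.

## Prioritization funnel

CV = sample SD / |mean| over site columns; |mean| < 1e−8 marks the gene
undefined (the sign of expression makes a ratio meaningless there).
Spearman ρ uses pairwise-complete observations and average ranks, requiring
≥ 3 complete pairs. The Box-Cox step shifts values by max(0, 1e−6 − min) to
positive support, fits λ by maximum likelihood, and converts each
transformed value to a one-sided tail probability under the normal with the
transformed sample's mean and SD. The tail-selection construction was a
genuinely open design point; the one-sided per-gene tail p against the
fitted normal was chosen because it directly expresses "select the stably
expressed / highly correlated extreme" and exposes both the sidedness and
the threshold in configuration. Under pure rescaling x → a·x the Box-Cox
log-likelihood shifts by a constant, so λ̂, the z-scores, and the selected
set are exactly invariant (property-tested); an additive offset changes the
positivity shift and is only approximately invariant. Selection is
rank-monotone: the transform is increasing for every λ, so the selected set
is always a tail of the raw ranking.

## Association layer

Exactness cutoff n ≤ 25 without ties for both tests covers the 20-patient
imaging cohort, where exact inference is the difference between printing
p = 0.0002 and p ≈ 0.0004. Two-sided exact p-values are the doubled smaller
tail of the enumerated null (scipy); asymptotic fallbacks use tie-corrected
variances (and a continuity correction for U). AUC direction: the
trait-present group high ⇒ AUC > 0.5. Ordinal traits are coded by their
declared level order; the direction convention is configuration-exposed.
BH families: per feature across proteins (default) or the whole grid — with
16 proteins and one feature family, an exact p of 2×10⁻⁴ adjusts to ≈ 0.003
× (rank structure), and the choice of family is recorded in every report.

The null calibration experiment (500 replicates of 16 proteins × 7 traits
on 20 patients) measures the per-test rejection rate at α = 0.05. Exact
tests are conservative on discrete null distributions — the attainable
level is the largest achievable p below α — so the measured rate sits
slightly below 0.05 (≈ 0.044) rather than at it; the acceptance band
0.05 ± 0.01 accommodates exactly this discreteness.

## Degenerate inputs and numerical conventions

* Mask label gaps are compacted to 1..S with a logged mapping; site index
  is positional everywhere downstream.
* Duplicate gene rows are averaged element-wise with missing values
  excluded per cell; all-missing rows are kept (flagged NaN) with a warning.
* Constant readers leave Cohen's κ undefined (NaN), never 0.
* Constant x or y leaves Kendall τ undefined; identical constant groups
  give AUC = 0.5.
* All tabular outputs are tab-delimited UTF-8 with `#` metadata lines
  embedding the configuration hash and seed; floats are written with 17
  significant digits so write/read round-trips are exact.

## Problem sizes in the shipped experiments

The test suite and the acceptance script run the dose-response at 5
heterogeneity levels × 12–20 phantom replicates on 48×48×6 grids, the
funnel recovery at 10 seeds × 500 genes × 107 patients, and the null
calibration at 500 replicates × ~110 tests. These sizes give stable
statistics (Monte-Carlo SE well inside every asserted margin) at
minutes-scale runtimes.

## Known limitations

* The IISTH functional forms are committed reconstructions (see above);
  magnitudes are not comparable to values computed with other definitions
  or normalizations.
* Phantom realism is deliberately limited to what the texture chain
  measures (see Phantoms).
* The pathway-narrowing step of the funnel is represented by a
  user-supplied gene-set filter, not by a pathway-enrichment computation.
* Kernel K-means is O(n²) in masked voxels per patient; very large masks
  should be subsampled upstream (the shipped phantom sizes do not need it).
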