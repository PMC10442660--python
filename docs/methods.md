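# Methods

This note records the models, conventions and design choices behind
`nirhsi`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic experiments do and do not show.

## Analysis pipeline

**Calibration.** Reflectance is computed per pixel and band as
`R = (Ir − Id)/(Iw − Id)` and absorbance as `A = −log10 max(R, ε)` with
`ε = 1e−9`. Pixels whose calibration span `Iw − Id` is not positive in
some band are flagged and excluded (recorded as shadow) rather than
producing non-finite values; a single degenerate pixel can never abort a
specimen.

**Wavelength window.** Bands with λ > 1400 nm are removed before SNV;
the window is inclusive (λ = 1400 nm would be retained). On the camera
grid used throughout (1000–2350 nm in 6.3 nm steps, 215 bands) this
leaves 64 bands, the last at 1396.9 nm.

**SNV.** Each pixel spectrum is transformed to zero mean, unit standard
deviation along the band axis. The standard deviation uses the sample
convention (ddof = 1, configurable). For a fixed band count the ddof = 0
alternative rescales every pixel by the same constant, so the choice
cannot affect classification; it does affect the numeric values of
difference spectra, hence it is documented and fixed.

**Validity mask.** A pixel is excluded if it (a) lies outside the
pathologically evaluated area, (b) is necrotic, (c) has reflectance
above 0.70 (highlight) or below 0.10 (shadow) at the band nearest
1300 nm (ties resolve to the lower wavelength; the thresholds are strict
inequalities, so R = 0.70 exactly is kept), or (d) falls within 5 pixels
Chebyshev distance of a boundary polyline — freehand lines carry
isotropic pixel uncertainty, so the margin is a square structuring
element applied to both sides of the line. When several reasons apply,
the recorded reason follows the precedence outside > necrosis >
highlight/shadow > margin. The exclusion is monotone in the margin
radius: growing the margin never re-validates a pixel.

**Classifier.** The two-class task (normal vs tumor, tumor positive) is
solved by a standard soft-margin kernel SVM. The multiclass formulation
this assay is usually written in reduces, for k = 2, to the binary
soft-margin problem up to scaling, so the binary specialization is
implemented; a brute-force dual-QP oracle in the test suite pins the
decision function to 1e−3 on small training sets. The quadratic program
itself is solved by scikit-learn's SVC (any convergent solver is
acceptable given the oracle agreement); `C = 1`; the RBF bandwidth σ² is
the exact median of all pairwise squared Euclidean distances of the
fold's own training matrix (≈ 6.5 M pairs for 3600 rows — computed
exactly, no subsampling). A decision value of exactly 0 is assigned to
normal, favouring specificity.

**Sampling and LOOCV.** Training pixels are drawn uniformly without
replacement among valid pixels, per class (tumor pools exposed and
unexposed pixels), 200 per class per specimen by default, from the
evaluated area only. Each specimen is predicted by a model trained on
the pooled samples of all other specimens. Per-specimen sampling seeds
are derived from the master seed and a hash of the specimen id (not its
position), so prediction maps are invariant to cohort ordering; this
strengthens the usual index-offset scheme, which would silently change
results on reordering.

**Metrics.** Confusion counts are restricted to valid pixels.
Cohort summaries report the unweighted mean ± population SD (ddof = 0)
of per-specimen percentages: recomputing both conventions from the
reference cohort's printed per-specimen counts shows the population SD
is the one that reproduces the published totals. Pooled-count metrics
(computed on summed counts) are available separately and differ whenever
specimen sizes differ. Metrics with zero denominators, and regions a
specimen does not have, propagate as missing and are excluded from
means, never coerced to 0. Display rounding is one decimal, ties away
from zero; internal values keep full precision.

**Thickness analysis.** Identified area = TP pixels, unidentified = FN
pixels; the report gives (min, max) tumor thickness over each set. The
80 %-sensitivity rule (above 80 %: a histological reader would measure
identified areas only; below: both) is recorded as `rule`, but on
synthetic data both ranges are always computable, so both are reported
with the rule's selection flagged.

## Synthetic specimen generator

The generator emulates the statistical structure the pipeline relies on,
not tissue optics. Per pixel, absorbance is a convex mixture of two
smooth endmember spectra (sums of Gaussian bands),

    A(λ) = A_normal(λ) + w · (A_tumor(λ) − A_normal(λ)),
    w = (1 − exp(−k_t·t_tumor)) · exp(−k_cover·t_cover),

a two-layer Beer–Lambert-style rule: tumor signal saturates with tumor
thickness `t_tumor` (finite optical sampling depth, rate `k_t`, default
0.45 /mm) and decays exponentially with covering-mucosa thickness
`t_cover` (rate `attenuation_k`, default 0.9 /mm). Raw frames invert the
calibration, `Ir = Id + (Iw − Id)·10^(−A) + noise`, under a halogen-like
lamp profile and spatial vignette (white ≈ 14 800 counts, dark 600,
14-bit scale), with additive Gaussian sensor noise (σ = 60 counts).

The endmembers are fixed shapes with a small seeded amplitude jitter,
constructed so the SNV-domain tumor−normal difference on the analysis
window is negative near 1050–1100 nm and 1380–1400 nm and positive near
1250–1350 nm — the qualitative contrast pattern reported for gastric
carcinoma versus normal mucosa in this window. No quantitative
absorbance contrast is published for this tissue pair, so the amplitudes
are calibrated only to that sign pattern.

**Geometry.** The tumor is an ellipse (white line = its boundary) with
an exposed concentric core (yellow line) at relative radius
`core_fraction` (0.5 when an unexposed rim is present; 1.0 for fully
exposed specimens). Thickness follows an elliptical dome
`t = t_max·sqrt(1 − ρ²)`; within one random angular wedge (40°) the dome
is replaced by a linear taper reaching the 0.15 mm floor at ρ = 0.85.
The wedge is what makes the detection limit observable: a pure dome only
thins inside the boundary margin, which is excluded from analysis, so
without it no valid pixel would ever be near the detection threshold.
Covering mucosa ramps linearly from 0 at the yellow line to
`cover_max_mm` at the white line. A per-pixel Gaussian jitter on `w`
(`bio_sd = 0.12`) models compositional heterogeneity along the
tumor-normal contrast axis; it is the main source of genuine class
overlap, without which the SVM separates the classes perfectly at any
thickness. Highlight/shadow blobs override the tissue signal at ≈ 0.92
and 0.04 reflectance, and necrosis blobs inside the core are labelled
and rendered as baseline tissue.

Cohorts vary geometry, maximum thickness (5–12 mm) and cover (0.8–1.8 mm)
across specimens; by default 6 of 10 specimens carry an unexposed rim.
Everything derives deterministically from one master seed.

**Calibration of defaults.** Defaults were chosen once so that, on the
default cohort, (i) recovery is strong but imperfect (cohort mean
sensitivity ≈ 95 %, specificity ≈ 98 %), (ii) unexposed-region
sensitivity is visibly lower than exposed (≈ 89 % vs ≈ 100 %), and
(iii) a detection transition exists inside the generated thickness
continuum (≈ 0.7 mm for exposed tumor). The transition is a property of
these synthetic conditions — a tunable consequence of `k_t`, `bio_sd`
and the noise floor — not a claim about tissue; in the clinical setting
this assay's detection limit is reported around 2 mm.

**Detection-transition statistic.** The transition is located by sweeping
noiseless exposed single-pixel probes of increasing thickness
(0.1 mm grid) through preprocessing and a trained fold model, taking the
thickness above which every thicker probe is called tumor, and the
median across folds. It is compared against the median across specimens
of the per-specimen minimum identified (TP) thickness. Medians are used
because the cohort-wide minimum is an extreme-value statistic whose
fluctuations reflect single noisy pixels, not the detection limit.

**What passing synthetic tests does not show.** The generator has no
scattering, no camera point-spread function, no spatially correlated
illumination drift, no inter-patient spectral variability beyond
amplitude jitter, and its two endmembers are idealised. Synthetic
recovery rates therefore say nothing about clinical performance; they
validate the pipeline's mechanics (calibration identities, masking,
fold isolation, metric arithmetic) and its qualitative behaviour
(thin/covered tumor degrades detection monotonically).

## Problem sizes

Default specimens are 96 × 128 pixels with 215 bands (float32 frames);
a full 10-specimen simulate→preprocess→LOOCV→evaluate run takes well
under a minute on one CPU. The test suite uses 64 × 88 specimens and
reduced per-class sample counts where full scale adds nothing to the
property under test.

## Known limitations

* ENVI support covers BSQ interleave with little-endian numeric types —
  sufficient for interchange of the cubes this package writes, not a
  general ENVI reader.
* The annotation container stores boundary polylines as pixel coordinate
  sets; no sub-pixel geometry.
* The 80 %-rule is reported but has no behavioural consequence on
  synthetic data (both thickness ranges are always measurable there).
* Difference spectra use the balanced training sample's normal mean, not
  all normal pixels of the training folds; with 200 px per specimen the
  difference is negligible but nonzero.
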