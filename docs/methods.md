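# Methods

This note documents the models behind `tissuedyn`, the defaults and why
they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that make runs reproducible.

## The measurement problem

Immunofluorescence of tissue sections gives, per field, a DAPI nuclear
counterstain, one or more stained channels (the signal of interest,
e.g. p53 after irradiation, plus optional co-stains such as Ki67 or
γ-H2AX), and ideally an unstained control channel. The quantities of
interest are per-cell: how much signal does each nucleus carry, where
does that cell sit along the crypt axis, and how do tissue-level
summaries evolve over hours after a genotoxic insult. The obstacles are
instrumental (smooth illumination gradients of tens of percent across a
stitched slide, additive camera/optics background) and biological
(autofluorescent cells — typically erythrocytes — that are bright in
every channel and would otherwise masquerade as strongly positive).

## Synthetic tissue generator

The generator is the test bed for every downstream stage, so its
structure mirrors the assumptions the analysis makes, not histological
appearance.

**Geometry.** Nuclei are discs with radius ~ N(mean 5 px, sd 0.8 px),
clipped to mean ± 2 sd, placed on a jittered lattice of vertical
columns: one column per crypt, position index 0 at the bottom
(crypt base) increasing upward. Jitter is 10% of the lattice spacing
and radii are capped, which *proves* non-overlap rather than relying on
rejection sampling; parameter combinations whose lattice cannot
guarantee this raise immediately. Cells per crypt defaults to 30
(crypt-to-villus columns in sections typically hold a few tens of
cells); 10 crypts per image.

**Intensity model.** Inside a nucleus, before noise:

    I = base_level · class_gain · decay^position · field(x, y) + background

- The crypt-axis gradient `decay^position` (default 0.9/cell) applies to
  the signal channel only, emulating the basal concentration of
  signal-positive cells.
- A designated fraction of cells (default 10%) is "positive" with a 5×
  signal gain; a disjoint fraction (default 5%) is "autofluorescent"
  with a 10× gain in *every non-DAPI channel*. Class counts are
  `round(fraction · n_cells)`, drawn without replacement, so truth
  counts are exact and testable.
- DAPI is independent of the positive class (staining for the target
  does not change DNA content).
- The illumination field is an off-center Gaussian bump, normalized to
  mean 1, with peak-to-trough ratio `illumination_amplitude`
  (default 1.5), multiplying all channels.
- Noise is Poisson on the photon-scale intensities by default
  (fluorescence counting statistics); Gaussian and noise-free variants
  exist for calibration and exactness tests.

Default levels (DAPI 400, signal 200, co-stain 150, control 100,
background 10 counts) put the dimmest structures ~10× above background,
a conservative stand-in for a reasonably stained slide; they are free
parameters, not calibrated claims about any particular microscope.

**What it does not emulate:** overlapping or aspherical nuclei, 3-D
sectioning artifacts, anatomically curved crypts, spectral bleed-through,
or spatially correlated noise. Passing tests therefore demonstrate
correctness of the measurement pipeline under its stated assumptions,
not segmentation performance on difficult real histology.

**Time courses.** Two induction schedules set the signal level as a
function of hours post-insult: a *transient* Gaussian pulse peaking at
2 h (decayed close to baseline by 5 h) and a *sustained* saturating rise
(elevated from ~2 h through 7 h), mirroring intestine-like and
spleen-like dynamics. The pipeline can render full images per timepoint;
a summary-level simulator (schedule value + Gaussian sample noise,
sd 0.2 on a baseline of 1 and amplitude of 4) generates large cohorts of
time courses cheaply for classifier validation.

**qPCR.** Ct tables follow `Ct_target = Ct_ref + ΔCt_baseline −
log2(fold_change) + ε`, ε ~ N(0, sd 0.2 cycles per well), duplicates per
reaction, reference gene (ACTB role) pinned at fold change 1.

## Pipeline stages and defaults

**Correction order.** Background subtraction (clamped at zero) precedes
flat-field division. With a multiplicative field applied to structures
and an additive background on top — the generator's model and the usual
physical reading — this order recovers cell intensities exactly;
dividing first would leave a position-dependent background residual.
The field is rescaled to mean 1 before division so corrected images
keep their intensity scale. When no reference field is available it is
estimated retrospectively by large-kernel (σ = 50 px) Gaussian smoothing
of the control channel; the background default is the 1st percentile of
non-nucleus pixels. Both are configuration-switchable and echoed in the
run manifest.

**Stitching.** Tiles carry their grid offsets; overlaps are blended by
averaging, which is symmetric and order-independent, and reproduces the
parent image exactly when overlap strips agree.

**Segmentation.** Smoothing σ = 1 px; Otsu's threshold (relative, so
label counts are invariant under global intensity scaling); watershed on
the negative distance transform with one seed per distance-maximum
plateau (peaks closer than 5 px merge); area filter 20–2000 px
(≈ radius 2.5–25 px nuclei). Watershed ties go to the nearer seed, and
exact ties resolve by label order, so segmentation is deterministic.

**Scoring.** Mean of the 10 brightest pixels per nucleus per channel.
Nuclei smaller than 10 px average all their pixels (k stays fixed; tiny
nuclei must not crash). The top-k mean is monotone in every pixel and
scale-equivariant, which the suite asserts as properties.

**Autofluorescence rule.** Flag when `topk(control) > median + 5·MAD`
of the sample's control distribution. The MAD is floored at a
machine-epsilon multiple of the median so a degenerate constant
distribution flags nothing. Five MADs is deliberately far out: on the
synthetic default the autofluorescent class sits ~8× above the normal
control spread, and the rule recovers it exactly without noise and at
sensitivity 1.0 / FPR 0.0 with Poisson noise.

**Normalization.** Ratio floor = 1% of the denominator-channel median
(explicit floor required for scalar calls), preventing division
blow-ups while leaving ordinary cells untouched.

**Summaries.** Top-percentile count is `ceil(p·n)`; 2% for crypt-bearing
tissue, 10% for lymphoid-like tissue. Replicate samples are summarized
individually; the tissue value is their mean and the SEM their sd/√n
(0 for a single sample). A sensitivity-sweep utility reports the summary
across a percentile grid without asserting a robustness range.

**Positive fractions.** One scalar cutoff per comparison set — the API
takes the whole sample collection and a single cutoff, making
per-sample cutoffs unrepresentable. Default calibration: the 99th
percentile of the normalized score in a designated negative-control
sample.

**Positional analysis.** Crypt annotations (base point + ordered labels)
are an input, as in manual practice; for synthetic data they are derived
from truth, re-expressed in segmentation labels via IoU > 0.5 matching.
Position indexing is 0-based at the crypt-base cell. The running-average
window defaults to 5 positions (odd, centered, truncated at ends).
Basal-cell selection takes positions 0–5 (six cells) per crypt and pools
across crypts and animals; shorter crypts contribute everything they
have, with a warning.

**Dynamics.** Late-to-peak ratio r with `t_late = 5 h` and threshold
0.5. The 5 h anchor is where intestine-like signals have returned to
near baseline while lymphoid-like signals remain elevated; the 0.5
threshold sits halfway between the two regimes and is config-exposed
since the transient/sustained contrast is qualitative, not a published
constant. Flat or non-induced series are *indeterminate*. r is invariant
under affine rescaling of the series. Histograms use half-open
[low, high) bins (last bin closed) with explicit under/overflow tallies.

**qPCR.** Amplification efficiency fixed at 2.0 (classical 2^−ΔΔCt, no
efficiency correction); replicates averaged on the Ct scale; the control
condition must be named explicitly — the package does not guess whether
"control" means t = 0 or untreated. Bundled primer table:
`tissuedyn.data/primers.csv` (murine ACTB, MDM2, CDKN1A, BBC3).

**Statistics.** Welch's t-test by default (pooled-variance available by
flag — the safer default when variances are unknown); one-sided tests
take the observed direction; SEM = sd(ddof 1)/√n. No multiple-testing
correction is applied anywhere, and results objects carry an explicit
`adjusted=False` marker.

**Reproducibility.** Every run writes a manifest with the package
version, the full configuration echo, per-sample seeds derived by
hashing (seed, sample indices) into [0, 2³¹), and SHA-256 hashes of all
outputs, with no timestamps — re-running a configuration reproduces the
cell tables and manifest byte for byte.

## Validation problem sizes

The validation battery (test suite and `scripts/acceptance.py`) runs on
sizes chosen to be statistically meaningful while staying desk-scale:
200-nucleus images for segmentation recovery; 1000 random inputs per
statistic for oracle agreement; ~1000-cell fields (32×32 lattice) for
tumor-mode positive-fraction recovery at true fractions 0.1 and 0.3;
20 crypts × 30 cells for gradient recovery; 20 + 20 simulated cohorts
for dynamics classification; and 200 Ct tables for qPCR recovery.

## Known limitations

- The nearest-neighbor automatic crypt orderer assumes well-separated,
  roughly monotone crypt columns; it is for synthetic data only.
- Otsu-based segmentation assumes a bimodal DAPI histogram; sparse or
  very dense fields may need the exposed smoothing/area knobs.
- Control-ratio normalization cancels only fields that are *shared*
  across channels; channel-specific vignetting is not corrected.
- The dynamics classifier needs the late timepoint to be sampled; it
  does not interpolate, and with sparse in-vivo sampling it cannot
  detect oscillations.
- Fold-change estimation assumes perfect doubling per cycle; primer
  efficiency calibration is out of scope.
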