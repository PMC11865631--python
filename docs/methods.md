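# Methods

## Scope and model

`mretrap` implements the manual-caliper analysis chain of muscle MRE as
an automated, seeded pipeline, together with a synthetic-data generator
that stands in for in-vivo acquisitions. The physical model is
deliberately minimal: a single oblique-axial slice, a monochromatic
plane shear wave, and the standard relation μ = ρ c² with c = λ f
connecting shear stiffness to the measured wavelength. (The stiffness
relation is sometimes typeset ambiguously as "ρλf²"; the implementation
uses μ = ρ(λf)², the only dimensionally consistent reading — at 4.25 kPa
and 60 Hz it gives λ ≈ 34 mm ≈ 24 pixels on an 18 cm / 128 grid, while
the literal alternative would imply a sub-pixel wavelength.)

## Synthetic phantoms

The displacement field at phase offset k of N is

    u(x, t_k) = A exp(−α d) cos(2π k/N − 2π d/λ),

with d the projection of the pixel position onto the propagation
direction. Phase images are `encoding_scale · u` plus a static
background phase; the complex image `magnitude · exp(i·phase)` receives
independent zero-mean Gaussian noise of SD `noise_sigma` in each
channel **before** magnitude/phase extraction, so magnitude noise is
Rician (background SD ≈ 0.655 σ, mean ≈ σ√(π/2)) and phase noise is
signal-dependent — the noise structure of real gradient-echo data.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| grid / spacing | 128 × 128, 1.40625 mm | 18 cm FOV on a 128 matrix |
| phase offsets | 4 | typical clinical protocol; 8 frames resampled from the harmonic |
| amplitude × encoding | 50 µm × 0.02 rad/µm = 1 rad | large signal while staying clear of ±π phase wraps (plus 0.2 rad background) |
| attenuation α | 0.015 /mm | amplitude ratio ≈ 0.13 across the 135 mm ROI: visible decay, but waves remain scoreable across the whole ROI as in score-4/5 clinical images. (Stronger decay, e.g. 0.05 /mm, drives the far ROI below the phase-noise floor and every noisy dataset scores 1, contradicting the data the phantom emulates.) |
| noise_sigma | 2.0 (tissue level 100) | magnitude SNR ≈ 50, comfortably above the ≥ 20 floor reported for such acquisitions |
| ROI | 44 × 96 px band | UT-like band holding ≥ 2.5 wavelengths at all study stiffnesses/frequencies |

Ground-truth dispersion is modelled as a power law
μ(f) = μ0 (f/f0)^γ; no functional form is implied by the measurements
being emulated, and the power law is the simplest positive,
monotone choice whose exponent can be fitted to three reported means.

A cylindrical-wave variant (`make_radial_phantom`) exists solely to
exercise the "coherent but not planar" branch of the quality rubric.

## Wave processing

The first harmonic is computed with the `exp(+i2πk/N)` convention, so
that `arg H` *increases* along the propagation direction (phase delay),
frame synthesis `Re{H exp(−i2πj/8)}` animates in the physical travel
direction, and frames → harmonic re-extraction is an exact round trip.
The bandpass is a radial annulus in spatial frequency with unit gain
inside the passband, Gaussian roll-offs (σ = cut/3.5 low, cut/4 high)
and a hard DC null; the default band (4 px to 2× image extent) only
strips DC and near-Nyquist noise. The optional directional filter keeps
the half-plane cone of wave vectors within a given angle of the
propagation direction with a raised-cosine edge; it is off by default,
matching the analysis chain being emulated.

Propagation direction is the principal eigenvector of the
amplitude-weighted structure tensor of the local phase gradient, where
gradients are computed as `arg(H_neighbour · conj(H))` — immune to 2π
wraps without global unwrapping — and signed toward increasing phase
delay.

## Caliper and quality rubric

Profiles are sampled with bilinear interpolation at pixel/4 steps along
a line through the ROI centroid (clipped to the ROI bounding box).
Extrema are detected with a prominence threshold of 10% of the trace
range and refined to sub-sample positions by local parabolic
interpolation; the wavelength is the mean of consecutive peak-to-peak
and trough-to-trough spacings (full wavelengths, never half-wavelength
doubling). Fewer than two like extrema yields an absent measurement
with a reason, not a number. Exponential amplitude decay shifts all
extrema of `exp(−αx)cos(kx)` by the same constant, so spacings are
unbiased under attenuation.

The 5-point wave-quality score is automated as: (1) coherence — mean
|H| (or frame RMS·√2) in the ROI must exceed 3× the estimated noise
floor, where the floor comes from the median 3×3-mean-filter residual
of H *inside the tissue mask* (outside the body the phase of a
magnitude image is meaningless); (2) planarity — the circular variance
of doubled local gradient angles must not exceed 0.3; (3–5) the
wavelength count W = ROI extent along propagation × median projected
phase gradient / 2π is binned at W < 1, 1 ≤ W < 2, W ≥ 2. The
dataset-level score is the maximum over the eight frames (the clearest
frame), while quality gating of wavelengths (score ≥ 3) is per frame.
Human scoring is by eye; these thresholds are surrogates, not a
reconstruction of any observer's judgement.

## Synthetic study and simulated observers

The study crosses 2 actuator positions × 3 frequencies (60/80/100 Hz)
× 2 sides × 9 subjects = 108 datasets, each measured by two simulated
observers. Ground truths per (subject, side): a lognormal subject
factor (CV 0.25, shared by both positions and all frequencies —
a subject with stiff muscle is stiff however you insonify it) scales
the published reference means (along-fibre 60 Hz mean for VAP with a
subject-specific dispersion exponent γ ~ N(γ_fit, 0.2) truncated at
0.2, where γ_fit ≈ 1.34 (left) / 1.74 (right) reproduces the published
frequency means; frequency-averaged mean for HAP with γ = 0). A
per-dataset lognormal session factor (CV 0.05) adds within-subject
variability. This correlation structure is what makes the qualitative
findings reproducible at n = 9 with exact Wilcoxon tests: along-fibre
frequency contrasts are consistently signed within subjects, while
cross-fibre contrasts contain no real effect at all.

Observers perturb the caliper geometry (profile endpoints, Gaussian SD
1.5 mm; extremum positions, SD 0.5 mm), apply a per-dataset lognormal
reading error (CV 0.08) to their mean wavelength, and mis-record the
quality score by ±1 with probability 0.15. The reading-error magnitude
is sized from published limits of agreement (LoA/mean ≈ 0.22–0.45
implies a per-observer reading SD of roughly 8–16%); published κ/ICC/LoA
cannot be calibrated exactly because per-subject data are not available,
so the defaults aim for the reported qualitative bands (substantial
κ where scores vary, good-to-excellent ICC) rather than the printed
values. Note the per-pair CV% this model produces (~6–15%) is smaller
than published CV columns, which are mutually inconsistent with the
published LoA under the per-pair definition used here; CV is therefore
reported but not calibrated. With near-constant quality scores across
a 9-subject cell, κ is an unstable statistic (0, 1 or undefined); cells
where both observers give identical, variance-free scores report κ = 1
by the perfect-agreement convention, and otherwise-degenerate cells
report an explicit "undefined" rather than a number.

Seeding: one master seed; every subject/cell/observer stream is derived
through `numpy.random.SeedSequence` keyed by the cell indices, so any
subset of the study regenerates bit-identically.

## Statistics

κ, ICC, Bland–Altman, CV, Friedman and Wilcoxon are implemented from
their defining formulas (they are the deliverable, not a convenience):
unweighted κ with the conventional six bands; ICC(3,1) consistency from
the two-way ANOVA decomposition (absolute agreement behind a flag; the
"two-way mixed" label alone does not pin the form down, and consistency
is the most common reading); LoA = 1.96·SD with a t-based CI for the
bias; per-pair CV averaged across pairs (a pooled variant is exposed);
Friedman with mid-ranks and the standard tie correction referred to
χ²(k−1); Wilcoxon signed-rank with zero removal, exact enumeration of
all 2ⁿ sign assignments for n ≤ 12 and a continuity- and tie-corrected
normal approximation beyond; Bonferroni adjustment min(1, m·p). The
implementations are verified in the test suite against independent
brute-force enumeration/permutation oracles and against reference
values frozen from R 4.3.3 (`friedman.test`, paired `wilcox.test`),
scikit-learn (κ) and pingouin (ICC(C,1)).

Numerical note: the χ² approximation to Friedman's p (the standard
choice in R and elsewhere) agrees with the exact permutation
distribution to ~0.01 only in the small-p tail; in the mid-p range it
can differ by 0.05–0.14 at small n. Tests therefore pin the statistic
exactly and check p against permutation enumeration in the
decision-relevant tail.

The qualitative findings checker tests: VAP > HAP per frequency × side
(paired Wilcoxon, Bonferroni over 6); monotone VAP dispersion (three
frequency contrasts per side, Bonferroni over 3 — the family structure
implied by reported adjusted p-values such as 0.012 = 3 × 1/2⁸);
no HAP frequency effect (Friedman per side); and left/right symmetry
(Wilcoxon on per-subject condition means). SNR is analysed with the
same Friedman machinery; a full three-way repeated-measures ANOVA
engine is out of scope.

## Problem sizes

Tests and the acceptance script synthesize everything at run time:
128×128 phantoms (512×512 only for the Rician background property, to
give >10⁵ background pixels), one full 108-dataset study per seeded
run (~4 s), 10⁶ Monte-Carlo samples for the Rician factor, and
enumeration oracles up to 2¹² sign assignments / 6⁵ block permutations.

## What passing tests do and do not show

The generator emulates plane waves with exponential decay, Rician
magnitude noise, fiducial markers and a rectangular UT-like band. It
does **not** simulate reflections at bone, mode conversion, fibre
curvature, through-plane propagation, B0/B1 artefacts, or genuinely
human scoring behaviour. Passing recovery and agreement tests therefore
validate the measurement chain and the statistics on data satisfying
the plane-wave model, not the accuracy of caliper MRE on real muscle.
Elastogram inversion (per-pixel stiffness maps), viscoelastic moduli
and 3D acquisitions are explicitly out of scope.
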