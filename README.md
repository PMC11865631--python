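# mretrap

Shear-wave magnetic resonance elastography (MRE) analysis of the upper
trapezius (UT) muscle: synthetic phantom generation, temporal-harmonic
wave-image processing, electronic-caliper wavelength measurement with
automated 5-point wave-quality scoring, Rician-corrected SNR, and the
two-observer reproducibility / factorial statistics of a full
actuator-position × frequency × body-side study design.

It is written for muscle-MRE researchers who want a tested, fully
synthetic sandbox for the *manual caliper* analysis chain: every stage
that a human observer performs on clinical wave images is reproduced by
an automated, seeded surrogate with known ground truth.

## The model

A vibration source drives a plane shear wave through the muscle. The
scanner samples tissue phase at `N` offsets over one vibration period;
the complex first temporal harmonic of the phase stack,

    H(x, y) = (2/N) Σ_k p_k(x, y) exp(i 2π k / N),

is the *wave image*, from which eight real frames
`Re{H exp(−i 2π j/8)}` are synthesized for animation and caliper
measurement. The caliper records the distance λ between successive
like extrema (peaks or troughs) of a 1D profile drawn along the
propagation direction, and shear stiffness follows from

    μ = ρ (λ f)²     (ρ = 1000 kg/m³, λ in metres, f in Hz).

Wavelengths are only trusted for frames whose wave-quality score
reaches 3 on the 5-point rubric (1 — no coherent wave, 2 — no planar
wave, 3/4/5 — less than one / one-to-two / two-or-more wavelengths
across the UT region of interest). Magnitude-image SNR uses the Rician
background correction

    SNR = 0.655 · S_ROI / σ_bg,

0.655 = √(2 − π/2) being the ratio of the background magnitude SD to
the per-channel complex noise SD.

Agreement between two observers is quantified exactly as reproducibility
studies report it: unweighted Cohen's κ on the ordinal scores, a
two-way-mixed consistency ICC(3,1) on stiffness, Bland–Altman bias and
limits of agreement (1.96·SD), per-pair CV%, and the factorial effects
with Friedman's test (tie-corrected) plus pairwise exact Wilcoxon
signed-rank tests with Bonferroni correction.

## Worked example

Simulate one noisy dataset at a ground-truth stiffness of 4.25 kPa
(60 Hz, waves along the muscle fibres), then measure it back:

```bash
cat > cfg.yaml <<EOF
phantom:
  mu0_pa: 4250
  noise_sigma: 2.0
acquisition:
  frequency_hz: 60
EOF
mretrap simulate --config cfg.yaml --out ds/
mretrap caliper ds/ --roi ds/roi_ut.nii.gz --out res.csv
mretrap snr ds/ --roi-m ds/roi_ut.nii.gz --roi-bg ds/roi_bg.nii.gz
```

prints

```
wrote dataset to ds (true mu = 4.25 kPa)
lambda = 34.43 mm, mu = 4.27 kPa, quality = 5 -> res.csv
SNR = 54.4 (S = 100.0, sigma_bg = 1.20)
```

i.e. the measured mean wavelength of 34.43 mm across the
quality-gated wave frames gives 4.27 kPa against the 4.25 kPa truth
(λ_true = √(μ/ρ)/f = 34.36 mm), the wave shows ≥ 2 wavelengths in the
ROI (score 5), and the magnitude SNR estimates signal over per-channel
noise (100/2 = 50): the background magnitude SD measured here, 1.20,
sits near its Rayleigh expectation 0.655·σ_c = 1.31, and the 0.655
factor in the SNR formula cancels exactly that inflation.

The full 108-dataset two-observer factorial study
(2 actuator positions × 3 frequencies × 2 sides × 9 subjects):

```bash
mretrap study --seed 2 --out study/
```

```
study complete: 108 datasets, Friedman chi2 = 83.60 (df = 11, p = 2.96e-13);
findings: {'vap_greater_than_hap': True, 'vap_dispersion': True,
           'hap_no_dispersion': True, 'no_asymmetry': True}
```

`study/table1.csv` holds the per-condition summary (mean score, κ,
stiffness mean ± SD, ICC, LoA, bias, CV%), `study/measurements.csv`
every individual observer measurement. The findings flags are the
study's qualitative conclusions: stiffness along the fibres (VAP)
exceeds stiffness across them (HAP) at every frequency and side;
apparent stiffness rises with frequency only along the fibres
(dispersion); and the two body sides do not differ significantly.

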