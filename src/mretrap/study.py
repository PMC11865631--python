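"""End-to-end synthetic reproduction of the two-observer factorial study.

The design crosses two actuator positions (VAP: waves along the muscle
fibres, HAP: across them), three vibration frequencies (60/80/100 Hz)
and both body sides for a cohort of subjects (default 9), i.e. 108
datasets.  Cell ground-truth stiffness means default to the published
in-vivo upper-trapezius reference values; per-subject and per-session
lognormal factors add realistic biological and measurement-day
variability.  Two simulated observers independently apply the caliper:
each perturbs the profile endpoints and the detected extremum positions
and occasionally mis-scores wave quality by one point.

``run_study`` produces the full measurement table, the per-cell
agreement panel (kappa, ICC, Bland-Altman, CV), Friedman + pairwise
Wilcoxon factorial statistics, and the qualitative findings checks
(VAP stiffer than HAP everywhere; dispersion only along the fibres; no
left-right asymmetry).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .agreement import (
    AgreementReport,
    FactorialResult,
    agreement_report,
    friedman_test,
    pairwise_wilcoxon_bonferroni,
)
from .caliper import (
    compute_snr,
    compute_stiffness,
    default_profile_line,
    extract_profile,
    measure_wavelength,
    score_wave_quality,
    ProfileLine,
)
from .core_io import write_results_csv
from .phantom import PhantomSpec, make_study_inputs
from .waveproc import estimate_propagation_direction, process_dataset

__all__ = [
    "TABLE1_MEANS_KPA",
    "StudyDesign",
    "ObserverModel",
    "StudyResult",
    "run_study",
    "summarize_table",
    "check_findings",
]

#: Published mean upper-trapezius stiffness (kPa) per
#: (actuator position, frequency Hz, side) — the study's ground truths.
TABLE1_MEANS_KPA: dict[tuple[str, int, str], float] = {
    ("VAP", 60, "left"): 4.25,
    ("VAP", 80, "left"): 6.38,
    ("VAP", 100, "left"): 8.35,
    ("VAP", 60, "right"): 4.22,
    ("VAP", 80, "right"): 7.19,
    ("VAP", 100, "right"): 10.1,
    ("HAP", 60, "left"): 1.92,
    ("HAP", 80, "left"): 1.85,
    ("HAP", 100, "left"): 1.95,
    ("HAP", 60, "right"): 1.68,
    ("HAP", 80, "right"): 1.81,
    ("HAP", 100, "right"): 2.28,
}


@dataclass(frozen=True)
class StudyDesign:
    """Factor levels and ground-truth structure of the synthetic cohort.

    Cell ground truths derive from ``cell_means_kpa``: the VAP reference
    stiffness per side is the 60 Hz cell mean with the dispersion
    exponent fitted to that side's three frequency means, while HAP uses
    the side's frequency-averaged mean with no dispersion.
    ``between_subject_cv`` scales a lognormal subject factor shared by
    all conditions of one subject-side (a subject's overall muscle
    stiffness); ``within_subject_cv`` is independent per dataset
    (session variability); ``gamma_subject_sd`` spreads the
    subject-specific VAP dispersion exponents.  ``phantom`` is the
    template for every cell's image simulation; its stiffness,
    orientation and seed are filled in per cell.
    """

    positions: tuple[str, ...] = ("VAP", "HAP")
    frequencies: tuple[int, ...] = (60, 80, 100)
    sides: tuple[str, ...] = ("left", "right")
    n_subjects: int = 9
    cell_means_kpa: dict[tuple[str, int, str], float] = field(
        default_factory=lambda: dict(TABLE1_MEANS_KPA)
    )
    reference_frequency_hz: float = 60.0
    between_subject_cv: float = 0.25
    within_subject_cv: float = 0.05
    gamma_subject_sd: float = 0.2
    phantom: PhantomSpec = field(
        default_factory=lambda: PhantomSpec(noise_sigma=2.0)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        missing = [
            c
            for c in itertools.product(self.positions, self.frequencies, self.sides)
            if c not in self.cell_means_kpa
        ]
        if missing:
            raise ValueError(f"cell means missing for {missing}")

    @property
    def mu0_kpa(self) -> dict[tuple[str, str], float]:
        """Reference stiffness (kPa) at the reference frequency per
        (position, side): the 60 Hz cell mean for VAP, the
        frequency-averaged mean for HAP."""
        out = {}
        for side in self.sides:
            if "VAP" in self.positions:
                out[("VAP", side)] = self.cell_means_kpa[
                    ("VAP", min(self.frequencies), side)
                ]
            if "HAP" in self.positions:
                out[("HAP", side)] = float(
                    np.mean(
                        [self.cell_means_kpa[("HAP", f, side)] for f in self.frequencies]
                    )
                )
        return out

    @property
    def gamma_vap(self) -> dict[str, float]:
        """Dispersion exponent per side, least-squares fitted to the VAP
        cell means (anchored at the reference frequency)."""
        from .phantom import fit_dispersion_exponent

        out = {}
        if len(self.frequencies) < 2:
            return {side: 0.0 for side in self.sides}
        for side in self.sides:
            mus = [self.cell_means_kpa[("VAP", f, side)] for f in self.frequencies]
            out[side] = fit_dispersion_exponent(
                np.asarray(self.frequencies, dtype=float),
                np.asarray(mus, dtype=float),
                f0_hz=self.reference_frequency_hz,
                mu0_pa=self.cell_means_kpa[
                    ("VAP", min(self.frequencies), side)
                ],
            )
        return out

    @property
    def n_datasets(self) -> int:
        return (
            len(self.positions)
            * len(self.frequencies)
            * len(self.sides)
            * self.n_subjects
        )

    def conditions(self) -> list[tuple[str, int, str]]:
        return list(itertools.product(self.positions, self.frequencies, self.sides))


@dataclass(frozen=True)
class ObserverModel:
    """Surrogate human observer applying the caliper.

    ``endpoint_jitter_mm`` perturbs both profile endpoints (Gaussian, in
    image mm), ``extremum_jitter_mm`` perturbs each caliper reading,
    ``reading_error_cv`` is a per-dataset multiplicative lognormal error
    on the observer's mean wavelength (which extrema were judged
    "relevant", where exactly the profile was drawn — the dominant
    inter-observer error in practice, sized so that the implied
    between-observer spread of stiffness matches published
    limits-of-agreement magnitudes), and ``score_jitter_prob`` is the
    probability of mis-recording the wave quality score by one point.
    """

    endpoint_jitter_mm: float = 1.5
    extremum_jitter_mm: float = 0.5
    reading_error_cv: float = 0.08
    score_jitter_prob: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.endpoint_jitter_mm < 0 or self.extremum_jitter_mm < 0:
            raise ValueError("jitters must be >= 0")
        if self.reading_error_cv < 0:
            raise ValueError("reading_error_cv must be >= 0")
        if not 0 <= self.score_jitter_prob <= 1:
            raise ValueError("score_jitter_prob must be in [0, 1]")


@dataclass
class StudyResult:
    """All outputs of one seeded study run."""

    measurements: pd.DataFrame
    agreement: dict[tuple[str, int, str], AgreementReport]
    stiffness_factorial: FactorialResult
    score_factorial: FactorialResult
    snr_factorial: FactorialResult
    findings: dict
    failures: list[dict]

    def to_csv(self, path) -> None:
        write_results_csv(self.measurements.to_dict("records"), path)


def _jitter_line(
    line: ProfileLine,
    jitter_mm: float,
    px: float,
    shape: tuple[int, int],
    rng: np.random.Generator,
) -> ProfileLine:
    if jitter_mm == 0:
        return line
    j = jitter_mm / px
    start = np.array(line.start) + rng.normal(0.0, j, 2)
    end = np.array(line.end) + rng.normal(0.0, j, 2)
    h, w = shape
    start = np.clip(start, [0, 0], [h - 1, w - 1])
    end = np.clip(end, [0, 0], [h - 1, w - 1])
    return replace(line, start=tuple(start), end=tuple(end))


def run_study(
    design: StudyDesign,
    observers: tuple[ObserverModel, ObserverModel] = (
        ObserverModel(seed=101),
        ObserverModel(seed=202),
    ),
    min_quality: int = 3,
) -> StudyResult:
    """Simulate the full factorial study with two observers.

    Every dataset is generated, processed to wave frames, and measured
    independently by both observers; agreement and factorial statistics
    are then assembled.  Fully deterministic for fixed design and
    observer seeds.  Datasets where an observer obtains no frame of
    sufficient quality are recorded in ``failures`` and reported as NaN.
    """
    pos_idx = {p: i for i, p in enumerate(design.positions)}
    f_idx = {f: i for i, f in enumerate(design.frequencies)}
    side_idx = {s: i for i, s in enumerate(design.sides)}
    rows: list[dict] = []
    failures: list[dict] = []

    for cell, ds, ut, bg, truth in make_study_inputs(design):
        si = int(cell["subject"][1:])
        pi = pos_idx[cell["position"]]
        fi = f_idx[cell["frequency_hz"]]
        li = side_idx[cell["side"]]
        field_, frames = process_dataset(ds)
        direction = estimate_propagation_direction(field_, ut)
        base_line = default_profile_line(ut, direction, ds.meta.pixel_spacing_mm)
        try:
            snr = compute_snr(ds.magnitude, ut, bg).snr
        except ValueError:
            snr = float("nan")  # noise-free simulation: SNR undefined

        for oi, obs in enumerate(observers):
            rng = np.random.default_rng(
                np.random.SeedSequence([design.seed, obs.seed, 7, si, pi, fi, li, oi])
            )
            line = _jitter_line(
                base_line,
                obs.endpoint_jitter_mm,
                ds.meta.pixel_spacing_mm,
                ds.shape,
                rng,
            )
            lambdas, qualities = [], []
            for k in range(frames.frames.shape[0]):
                trace = extract_profile(
                    frames.frames[k], line, ds.meta.pixel_spacing_mm
                )
                est = measure_wavelength(
                    trace, extremum_jitter_mm=obs.extremum_jitter_mm, rng=rng
                )
                q = score_wave_quality(
                    field_, ut, direction=direction, frame=frames.frames[k]
                )
                lambdas.append(est.lambda_mm)
                qualities.append(q)
            score = max(qualities)
            if obs.score_jitter_prob > 0 and rng.random() < obs.score_jitter_prob:
                score = int(np.clip(score + rng.choice([-1, 1]), 1, 5))
            used = [
                lam
                for lam, q in zip(lambdas, qualities)
                if lam is not None and q >= min_quality
            ]
            if used:
                lam_mm = float(np.mean(used))
                if obs.reading_error_cv > 0:
                    s2 = math.log(1.0 + obs.reading_error_cv**2)
                    lam_mm *= float(np.exp(rng.normal(-0.5 * s2, math.sqrt(s2))))
                mu_kpa = compute_stiffness(lam_mm / 1000.0, ds.meta.frequency_hz) / 1000.0
            else:
                lam_mm, mu_kpa = float("nan"), float("nan")
                failures.append({**cell, "observer": "AB"[oi]})
            rows.append(
                {
                    **cell,
                    "observer": "AB"[oi],
                    "quality_score": score,
                    "lambda_mm": lam_mm,
                    "stiffness_kpa": mu_kpa,
                    "snr": snr,
                    "mu_true_kpa": truth.mu_pa / 1000.0,
                }
            )

    measurements = pd.DataFrame(rows)
    agreement = _per_cell_agreement(design, measurements)
    stiff_fact = _factorial(design, measurements, "stiffness_kpa")
    score_fact = _factorial(design, measurements, "quality_score")
    snr_fact = _factorial(design, measurements, "snr")
    findings = check_findings(measurements, design)
    return StudyResult(
        measurements=measurements,
        agreement=agreement,
        stiffness_factorial=stiff_fact,
        score_factorial=score_fact,
        snr_factorial=snr_fact,
        findings=findings,
        failures=failures,
    )


def _cell_pivot(measurements: pd.DataFrame, value: str) -> pd.DataFrame:
    """subjects x (position, frequency, side) matrix of observer means."""
    mean = (
        measurements.groupby(["subject", "position", "frequency_hz", "side"])[value]
        .mean()
        .reset_index()
    )
    return mean.pivot_table(
        index="subject",
        columns=["position", "frequency_hz", "side"],
        values=value,
        dropna=False,
    )


def _factorial(
    design: StudyDesign, measurements: pd.DataFrame, value: str
) -> FactorialResult:
    wide = _cell_pivot(measurements, value)
    cols = [
        (p, f, s)
        for p in design.positions
        for f in design.frequencies
        for s in design.sides
    ]
    mat = wide.reindex(columns=cols).to_numpy()
    mat = mat[np.all(np.isfinite(mat), axis=1)]
    if mat.shape[0] < 2:
        return FactorialResult(
            friedman_chi2=float("nan"), df=len(cols) - 1, p=float("nan"), pairwise={}
        )
    chi2_, df, p = friedman_test(mat)
    pairwise = pairwise_wilcoxon_bonferroni(mat, condition_labels=cols)
    return FactorialResult(friedman_chi2=chi2_, df=df, p=p, pairwise=pairwise)


def _per_cell_agreement(
    design: StudyDesign, measurements: pd.DataFrame
) -> dict[tuple[str, int, str], AgreementReport]:
    out = {}
    for cond in design.conditions():
        cell = measurements[
            (measurements.position == cond[0])
            & (measurements.frequency_hz == cond[1])
            & (measurements.side == cond[2])
        ]
        a = cell[cell.observer == "A"].sort_values("subject")
        b = cell[cell.observer == "B"].sort_values("subject")
        ok = np.isfinite(a.stiffness_kpa.to_numpy()) & np.isfinite(
            b.stiffness_kpa.to_numpy()
        )
        rep = agreement_report(
            a.quality_score.to_numpy(),
            b.quality_score.to_numpy(),
            a.stiffness_kpa.to_numpy()[ok],
            b.stiffness_kpa.to_numpy()[ok],
        )
        # perfect but variance-free score agreement: report kappa = 1
        if rep.kappa is None and np.array_equal(
            a.quality_score.to_numpy(), b.quality_score.to_numpy()
        ):
            rep.kappa, rep.kappa_band = 1.0, "almost perfect"
        out[cond] = rep
    return out


def summarize_table(design: StudyDesign, result: StudyResult) -> pd.DataFrame:
    """Reference-table-style summary: one row per position x frequency,
    column blocks per side with mean score, kappa, stiffness mean +/- SD,
    ICC, LoA bounds, bias and CV."""
    meas = result.measurements
    rows = []
    for pos in design.positions:
        for f in design.frequencies:
            row: dict = {"position": pos, "frequency_hz": f}
            for side in design.sides:
                cell = meas[
                    (meas.position == pos)
                    & (meas.frequency_hz == f)
                    & (meas.side == side)
                ]
                rep = result.agreement[(pos, f, side)]
                subj_mean = cell.groupby("subject")["stiffness_kpa"].mean()
                pre = f"{side}_"
                row[pre + "mean_score"] = float(cell.quality_score.mean())
                row[pre + "kappa"] = rep.kappa if rep.kappa is not None else float("nan")
                row[pre + "stiffness_mean_kpa"] = float(subj_mean.mean())
                row[pre + "stiffness_sd_kpa"] = (
                    float(subj_mean.std(ddof=1)) if len(subj_mean) > 1 else float("nan")
                )
                row[pre + "icc"] = rep.icc if rep.icc is not None else float("nan")
                row[pre + "loa_kpa"] = rep.loa
                row[pre + "ub_kpa"] = rep.ub
                row[pre + "lb_kpa"] = rep.lb
                row[pre + "bias_kpa"] = rep.bias
                row[pre + "cv_percent"] = rep.cv_percent
            rows.append(row)
    return pd.DataFrame(rows)


def check_findings(
    measurements: pd.DataFrame,
    design: StudyDesign | None = None,
    alpha: float = 0.05,
) -> dict:
    """Test the study's qualitative findings on a measurement table.

    Returns booleans with supporting p-values for:

    a. ``vap_greater_than_hap`` — VAP stiffness exceeds HAP at every
       frequency and side (paired Wilcoxon, Bonferroni over the 6
       frequency-side combinations);
    b. ``vap_dispersion`` — within VAP, stiffness rises monotonically
       with frequency and every pairwise frequency contrast is
       significant (Bonferroni over 3 per side);
    c. ``hap_no_dispersion`` — within HAP no significant frequency
       effect (Friedman per side);
    d. ``no_asymmetry`` — no significant left-right difference (paired
       Wilcoxon over all subject x condition pairs).
    """
    if design is None:
        design = StudyDesign(
            n_subjects=measurements.subject.nunique(),
            positions=tuple(pd.unique(measurements.position)),
            frequencies=tuple(pd.unique(measurements.frequency_hz)),
            sides=tuple(pd.unique(measurements.side)),
        )
    wide = _cell_pivot(measurements, "stiffness_kpa")
    freqs = list(design.frequencies)

    # (a) VAP > HAP per frequency/side
    combos = [(f, s) for f in freqs for s in design.sides]
    a_ps = {}
    a_ok = {"VAP", "HAP"} <= set(design.positions)
    from .agreement import wilcoxon_signed_rank

    for f, s in combos if a_ok else []:
        v = wide[("VAP", f, s)].to_numpy()
        h = wide[("HAP", f, s)].to_numpy()
        keep = np.isfinite(v) & np.isfinite(h)
        p = min(1.0, len(combos) * wilcoxon_signed_rank(v[keep], h[keep]))
        a_ps[(f, s)] = p
        a_ok &= (p < alpha) and (np.nanmean(v) > np.nanmean(h))

    # (b) VAP dispersion: monotone increase with frequency, all contrasts significant
    b_ps = {}
    multi_freq = len(freqs) >= 2 and "VAP" in design.positions
    b_ok = multi_freq
    pairs = list(itertools.combinations(range(len(freqs)), 2))
    for s in design.sides if multi_freq else []:
        cols = [("VAP", f, s) for f in freqs]
        mat = wide[cols].to_numpy()
        mat = mat[np.all(np.isfinite(mat), axis=1)]
        adj = pairwise_wilcoxon_bonferroni(
            mat, condition_labels=[c[1] for c in cols], pairs=pairs
        )
        means = mat.mean(axis=0)
        b_ok &= bool(np.all(np.diff(means) > 0)) and all(p < alpha for p in adj.values())
        b_ps[s] = adj

    # (c) HAP: no frequency effect
    c_ps = {}
    c_ok = True
    hap_applicable = len(freqs) >= 2 and "HAP" in design.positions
    for s in design.sides if hap_applicable else []:
        cols = [("HAP", f, s) for f in freqs]
        mat = wide[cols].to_numpy()
        mat = mat[np.all(np.isfinite(mat), axis=1)]
        _, _, p = friedman_test(mat)
        c_ps[s] = p
        c_ok &= p >= alpha

    # (d) left/right symmetry: per-subject condition-mean stiffness per side
    if not {"left", "right"} <= set(design.sides):
        return {
            "vap_greater_than_hap": bool(a_ok),
            "vap_greater_than_hap_p": a_ps,
            "vap_dispersion": bool(b_ok),
            "vap_dispersion_p": b_ps,
            "hap_no_dispersion": bool(c_ok),
            "hap_no_dispersion_p": c_ps,
            "no_asymmetry": True,
            "no_asymmetry_p": float("nan"),
        }
    left = np.nanmean(
        wide[[(p, f, "left") for p in design.positions for f in freqs]].to_numpy(),
        axis=1,
    )
    right = np.nanmean(
        wide[[(p, f, "right") for p in design.positions for f in freqs]].to_numpy(),
        axis=1,
    )
    keep = np.isfinite(left) & np.isfinite(right)
    d_p = wilcoxon_signed_rank(left[keep], right[keep])

    return {
        "vap_greater_than_hap": bool(a_ok),
        "vap_greater_than_hap_p": a_ps,
        "vap_dispersion": bool(b_ok),
        "vap_dispersion_p": b_ps,
        "hap_no_dispersion": bool(c_ok),
        "hap_no_dispersion_p": c_ps,
        "no_asymmetry": bool(d_p >= alpha),
        "no_asymmetry_p": float(d_p),
    }
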