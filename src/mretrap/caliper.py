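"""Electronic-caliper wavelength measurement, wave-quality scoring,
stiffness and SNR.

The measurement chain emulates how an observer works through a wave
image series: draw a 1D profile along the propagation direction, locate
successive peaks (or troughs) of the wave trace on each of the eight
frames, record the like-extremum spacings as wavelengths, score each
frame on the 5-point wave-quality rubric, average the wavelengths of
frames scoring 3 or above, and convert the mean wavelength to shear
stiffness through

    mu = rho (lambda f)^2        [Pa; rho in kg/m^3, lambda in m, f in Hz]

Image SNR uses the Rician-background correction

    SNR = 0.655 * S_roi / sigma_bg

where S_roi is the mean magnitude in the tissue ROI and sigma_bg the
sample SD of the magnitude in a signal-free background ROI (for pure
complex Gaussian noise of per-channel SD sigma_c, the background
magnitude SD is sqrt(2 - pi/2) sigma_c ~ 0.655 sigma_c, so SNR
estimates S_roi / sigma_c).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.ndimage as ndi
from scipy.signal import find_peaks

from .core_io import MREDataset, ROIMask
from .waveproc import (
    WaveField,
    estimate_propagation_direction,
    local_phase_gradient,
    process_dataset,
)

__all__ = [
    "ProfileLine",
    "ProfileTrace",
    "WavelengthEstimate",
    "WavelengthMeasurement",
    "StiffnessResult",
    "SNRResult",
    "QualityThresholds",
    "RICIAN_FACTOR",
    "extract_profile",
    "measure_wavelength",
    "score_wave_quality",
    "compute_stiffness",
    "estimate_stiffness",
    "compute_snr",
    "default_profile_line",
    "roi_extent_px",
]

RICIAN_FACTOR = 0.655


@dataclass(frozen=True)
class ProfileLine:
    """Straight caliper line in continuous (row, col) pixel coordinates."""

    start: tuple[float, float]
    end: tuple[float, float]
    sampling_step_mm: float

    def length_px(self) -> float:
        return math.hypot(self.end[0] - self.start[0], self.end[1] - self.start[1])


@dataclass
class ProfileTrace:
    """Equally spaced amplitude samples along a caliper line."""

    distances_mm: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.distances_mm = np.asarray(self.distances_mm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.distances_mm.shape != self.values.shape:
            raise ValueError("distances and values must have equal length")
        if self.distances_mm.size < 2:
            raise ValueError("trace needs at least 2 samples")
        d = np.diff(self.distances_mm)
        if not np.all(d > 0):
            raise ValueError("distances must be strictly increasing")


@dataclass
class WavelengthEstimate:
    """Result of one caliper application to one trace."""

    lambda_mm: float | None
    reason: str = ""
    peaks_mm: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    troughs_mm: np.ndarray = dc_field(default_factory=lambda: np.empty(0))


@dataclass
class WavelengthMeasurement:
    """Per-frame caliper results over the 8-frame wave series."""

    per_frame_lambda_mm: list[float | None]
    per_frame_quality: list[int]
    extrema_positions: list[dict]

    @property
    def dataset_quality(self) -> int:
        """Score of the clearest frame (the reported wave-quality score)."""
        return max(self.per_frame_quality)


@dataclass
class StiffnessResult:
    """Quality-gated mean wavelength and the stiffness it implies."""

    lambda_mean_m: float
    f_hz: float
    rho_kg_m3: float
    mu_pa: float
    frames_used: list[int]


@dataclass
class SNRResult:
    s_roi: float
    sigma_bg: float

    @property
    def snr(self) -> float:
        return RICIAN_FACTOR * self.s_roi / self.sigma_bg


@dataclass(frozen=True)
class QualityThresholds:
    """Cut-points of the automated 5-point wave-quality rubric.

    coherence_ratio: minimum wave-amplitude / noise-floor ratio for any
    coherent wave to be considered present (below -> score 1).
    max_circular_variance: maximum circular variance of local
    propagation directions for the wave to count as planar (above ->
    score 2).  Scores 3-5 then count wavelengths across the ROI.
    """

    coherence_ratio: float = 3.0
    max_circular_variance: float = 0.3


def extract_profile(
    image: np.ndarray, line: ProfileLine, pixel_spacing_mm: float
) -> ProfileTrace:
    """Sample an image along a caliper line with bilinear interpolation."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2D")
    h, w = img.shape
    for p in (line.start, line.end):
        if not (0 <= p[0] <= h - 1 and 0 <= p[1] <= w - 1):
            raise ValueError(f"profile endpoint {p} outside image bounds {img.shape}")
    length_mm = line.length_px() * pixel_spacing_mm
    if length_mm <= 0:
        raise ValueError("profile line has zero length")
    n = max(int(round(length_mm / line.sampling_step_mm)) + 1, 2)
    t = np.linspace(0.0, 1.0, n)
    rows = line.start[0] + t * (line.end[0] - line.start[0])
    cols = line.start[1] + t * (line.end[1] - line.start[1])
    vals = ndi.map_coordinates(img, np.vstack([rows, cols]), order=1, mode="nearest")
    return ProfileTrace(distances_mm=t * length_mm, values=vals)


def _refined_positions(trace: ProfileTrace, idx: np.ndarray) -> np.ndarray:
    """Sub-sample extremum positions by local parabolic interpolation."""
    y = trace.values
    step = trace.distances_mm[1] - trace.distances_mm[0]
    out = np.empty(len(idx))
    for j, i in enumerate(idx):
        if 0 < i < len(y) - 1:
            denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
            delta = 0.5 * (y[i - 1] - y[i + 1]) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        out[j] = trace.distances_mm[i] + delta * step
    return out


def measure_wavelength(
    trace: ProfileTrace,
    min_prominence_frac: float = 0.1,
    extremum_jitter_mm: float = 0.0,
    rng: np.random.Generator | None = None,
) -> WavelengthEstimate:
    """Caliper wavelength: mean spacing of successive like extrema.

    Peaks and troughs are detected with a prominence threshold of
    *min_prominence_frac* times the trace range; the wavelength is the
    mean of consecutive peak-to-peak and trough-to-trough distances
    (full wavelengths).  Returns an absent estimate, with the reason,
    when fewer than two peaks and fewer than two troughs are found.

    *extremum_jitter_mm* perturbs each detected extremum position with
    Gaussian noise — the simulated-observer hook.
    """
    y = trace.values
    if y.size == 0 or not np.all(np.isfinite(y)):
        raise ValueError("trace is empty or contains non-finite values")
    rng_span = float(y.max() - y.min())
    if rng_span == 0:
        return WavelengthEstimate(None, reason="flat trace")
    prom = min_prominence_frac * rng_span
    pk, _ = find_peaks(y, prominence=prom)
    tr, _ = find_peaks(-y, prominence=prom)
    peaks_mm = _refined_positions(trace, pk)
    troughs_mm = _refined_positions(trace, tr)
    if extremum_jitter_mm > 0:
        if rng is None:
            rng = np.random.default_rng()
        peaks_mm = peaks_mm + rng.normal(0.0, extremum_jitter_mm, peaks_mm.shape)
        troughs_mm = troughs_mm + rng.normal(0.0, extremum_jitter_mm, troughs_mm.shape)
    spacings: list[float] = []
    if len(peaks_mm) >= 2:
        spacings.extend(np.diff(np.sort(peaks_mm)))
    if len(troughs_mm) >= 2:
        spacings.extend(np.diff(np.sort(troughs_mm)))
    if not spacings:
        return WavelengthEstimate(
            None,
            reason="insufficient extrema",
            peaks_mm=peaks_mm,
            troughs_mm=troughs_mm,
        )
    return WavelengthEstimate(
        float(np.mean(spacings)), peaks_mm=peaks_mm, troughs_mm=troughs_mm
    )


def _noise_floor_amplitude(harmonic: np.ndarray, mask: np.ndarray) -> float:
    """Estimate the mean |H| a pure-noise field would show inside *mask*.

    The per-channel noise SD is estimated from the median magnitude of
    the residual after a 3x3 mean filter (which removes the smooth wave
    but keeps ~sqrt(8/9) of white noise), then converted to the Rayleigh
    mean amplitude sigma * sqrt(pi/2).  Restricting to the tissue mask
    matters: outside the body the phase of a magnitude image is
    meaningless (uniformly random), which would swamp the estimate.
    """
    re = ndi.uniform_filter(harmonic.real, size=3)
    im = ndi.uniform_filter(harmonic.imag, size=3)
    resid = harmonic - (re + 1j * im)
    med = float(np.median(np.abs(resid)[mask]))
    # Rayleigh median = sigma sqrt(2 ln 2); residual channel SD = sigma sqrt(8/9)
    sigma_c = med / (math.sqrt(2.0 * math.log(2.0)) * math.sqrt(8.0 / 9.0))
    return sigma_c * math.sqrt(math.pi / 2.0)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    return float(v[np.searchsorted(cw, 0.5 * cw[-1])])


def roi_extent_px(roi: ROIMask, direction: tuple[float, float]) -> float:
    """Extent of the ROI (pixels) along a unit direction in (row, col) space."""
    rr, cc = np.nonzero(roi.mask)
    proj = rr * direction[0] + cc * direction[1]
    return float(proj.max() - proj.min())


def score_wave_quality(
    field: WaveField,
    roi: ROIMask,
    direction: tuple[float, float] | None = None,
    frame: np.ndarray | None = None,
    thresholds: QualityThresholds = QualityThresholds(),
) -> int:
    """Automated 5-point wave-quality score of a wave image.

    1 — no coherent wave (ROI amplitude below the coherence threshold
    relative to the estimated noise floor); 2 — coherent but not planar
    (local propagation directions too dispersed); 3/4/5 — planar wave
    with < 1, 1 to 2, or >= 2 wavelengths across the ROI along the
    propagation direction.  When *frame* is given, the coherence test
    uses that frame's amplitude; geometry always comes from the
    harmonic.
    """
    m = roi.mask
    if not m.any():
        raise ValueError("empty ROI")
    h = field.harmonic
    floor = _noise_floor_amplitude(h, m)
    if frame is not None:
        amp = math.sqrt(2.0) * float(np.sqrt(np.mean(np.asarray(frame)[m] ** 2)))
    else:
        amp = float(np.mean(np.abs(h)[m]))
    if amp < thresholds.coherence_ratio * max(floor, 1e-30):
        return 1

    g_row, g_col, w = local_phase_gradient(h)
    wm = w[m]
    if wm.sum() <= 0:
        return 1
    ang = np.arctan2(g_row[m], g_col[m])
    # doubled angles: wave direction is axial (theta and theta+pi identical)
    resultant = np.abs(np.sum(wm * np.exp(2j * ang))) / wm.sum()
    if 1.0 - resultant > thresholds.max_circular_variance:
        return 2

    if direction is None:
        direction = estimate_propagation_direction(field, roi)
    proj = g_row[m] * direction[0] + g_col[m] * direction[1]
    k_med = abs(_weighted_median(proj, wm))  # rad / pixel
    n_wavelengths = roi_extent_px(roi, direction) * k_med / (2.0 * math.pi)
    if n_wavelengths < 1.0:
        return 3
    if n_wavelengths < 2.0:
        return 4
    return 5


def compute_stiffness(lambda_m: float, f_hz: float, rho_kg_m3: float = 1000.0) -> float:
    """Shear stiffness mu = rho (lambda f)^2 in Pa (lambda in metres)."""
    if lambda_m <= 0 or f_hz <= 0 or rho_kg_m3 <= 0:
        raise ValueError("lambda, f and rho must all be positive")
    return rho_kg_m3 * (lambda_m * f_hz) ** 2


def default_profile_line(
    roi: ROIMask,
    direction: tuple[float, float],
    pixel_spacing_mm: float,
    sampling_step_mm: float | None = None,
) -> ProfileLine:
    """Caliper line through the ROI centroid along *direction*, clipped to
    the ROI bounding box."""
    rr, cc = np.nonzero(roi.mask)
    centre = np.array([rr.mean(), cc.mean()])
    d = np.asarray(direction, dtype=float)
    d = d / np.hypot(*d)
    lo = np.array([rr.min() + 0.01, cc.min() + 0.01])
    hi = np.array([rr.max() - 0.01, cc.max() - 0.01])
    t_min, t_max = -np.inf, np.inf
    for ax in range(2):
        if abs(d[ax]) < 1e-12:
            continue
        t1 = (lo[ax] - centre[ax]) / d[ax]
        t2 = (hi[ax] - centre[ax]) / d[ax]
        t_min = max(t_min, min(t1, t2))
        t_max = min(t_max, max(t1, t2))
    if not np.isfinite(t_min) or not np.isfinite(t_max) or t_max <= t_min:
        raise ValueError("cannot place a profile line inside the ROI bounding box")
    start = tuple(centre + t_min * d)
    end = tuple(centre + t_max * d)
    if sampling_step_mm is None:
        sampling_step_mm = pixel_spacing_mm / 4.0
    return ProfileLine(start=start, end=end, sampling_step_mm=sampling_step_mm)


def estimate_stiffness(
    ds: MREDataset,
    roi: ROIMask,
    line: ProfileLine | None = None,
    direction: tuple[float, float] | None = None,
    band_mm: tuple[float, float] | None = None,
    min_prominence_frac: float = 0.1,
    min_quality: int = 3,
    extremum_jitter_mm: float = 0.0,
    rng: np.random.Generator | None = None,
    rho_kg_m3: float = 1000.0,
    thresholds: QualityThresholds = QualityThresholds(),
) -> tuple[StiffnessResult, WavelengthMeasurement]:
    """End-to-end stiffness measurement of one dataset.

    Runs the standard processing chain, places the caliper line (along
    the estimated propagation direction through the ROI centroid unless
    one is given), measures the wavelength and scores the quality of
    each of the eight frames, averages the wavelengths of frames whose
    score reaches *min_quality*, and converts to stiffness.

    Raises ``ValueError`` ("insufficient wave quality") if no frame
    qualifies.
    """
    field, frames = process_dataset(ds, band_mm=band_mm)
    if direction is None:
        direction = estimate_propagation_direction(field, roi)
    if line is None:
        line = default_profile_line(roi, direction, ds.meta.pixel_spacing_mm)
    lambdas: list[float | None] = []
    qualities: list[int] = []
    extrema: list[dict] = []
    for k in range(frames.frames.shape[0]):
        trace = extract_profile(frames.frames[k], line, ds.meta.pixel_spacing_mm)
        est = measure_wavelength(
            trace,
            min_prominence_frac=min_prominence_frac,
            extremum_jitter_mm=extremum_jitter_mm,
            rng=rng,
        )
        q = score_wave_quality(
            field, roi, direction=direction, frame=frames.frames[k], thresholds=thresholds
        )
        lambdas.append(est.lambda_mm)
        qualities.append(q)
        extrema.append({"peaks_mm": est.peaks_mm, "troughs_mm": est.troughs_mm})
    measurement = WavelengthMeasurement(
        per_frame_lambda_mm=lambdas,
        per_frame_quality=qualities,
        extrema_positions=extrema,
    )
    used = [
        k
        for k, (lam, q) in enumerate(zip(lambdas, qualities))
        if lam is not None and q >= min_quality
    ]
    if not used:
        raise ValueError("insufficient wave quality: no frame scored >= 3 with extrema")
    lam_mean_m = float(np.mean([lambdas[k] for k in used])) / 1000.0
    mu = compute_stiffness(lam_mean_m, ds.meta.frequency_hz, rho_kg_m3)
    result = StiffnessResult(
        lambda_mean_m=lam_mean_m,
        f_hz=ds.meta.frequency_hz,
        rho_kg_m3=rho_kg_m3,
        mu_pa=mu,
        frames_used=used,
    )
    return result, measurement


def compute_snr(
    magnitude: np.ndarray, roi_m: ROIMask, roi_bg: ROIMask, min_bg_pixels: int = 30
) -> SNRResult:
    """Rician-corrected SNR of a magnitude image (mean tissue signal over
    background SD, scaled by 0.655)."""
    if (roi_m.mask & roi_bg.mask).any():
        raise ValueError("tissue and background ROIs overlap")
    if roi_bg.n_pixels < min_bg_pixels:
        raise ValueError(
            f"background ROI has {roi_bg.n_pixels} pixels, need >= {min_bg_pixels}"
        )
    mag = np.asarray(magnitude, dtype=float)
    s = float(mag[roi_m.mask].mean())
    sigma = float(mag[roi_bg.mask].std(ddof=1))
    if sigma == 0:
        raise ValueError("background ROI has zero variance")
    return SNRResult(s_roi=s, sigma_bg=sigma)
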