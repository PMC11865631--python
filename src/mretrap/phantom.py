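"""Synthetic shear-wave MRE phantoms with known ground truth.

Each phantom is a single oblique-axial slice: a body region of uniform
magnitude carrying a propagating plane shear wave encoded in the phase
images, three bright fiducial markers, and complex Gaussian noise added
to the complex image so that the magnitude noise is Rician and the phase
noise is signal-dependent — the noise structure of real GRE magnitude /
phase data.

The displacement field at phase offset ``k`` of ``N`` is

    u(x, t_k) = A exp(-alpha d) cos(2 pi k / N - 2 pi d / lambda)

where ``d`` is the projection of the pixel position onto the propagation
direction (mm from the source edge), ``A`` the source-edge displacement
amplitude (um), ``alpha`` the exponential attenuation rate and
``lambda`` the shear wavelength implied by the ground-truth stiffness
through mu = rho (lambda f)^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Iterator, NamedTuple

import numpy as np

from .core_io import (
    DEFAULT_PIXEL_SPACING_MM,
    AcquisitionMeta,
    MREDataset,
    ROIMask,
)

if TYPE_CHECKING:  # pragma: no cover
    from .study import StudyDesign

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "dispersion_law",
    "fit_dispersion_exponent",
    "wavelength_from_stiffness",
    "stiffness_from_wavelength",
    "make_phantom",
    "make_radial_phantom",
    "make_study_inputs",
    "rician_background_sd_ratio",
]

#: Rayleigh SD / per-channel sigma: sqrt(2 - pi/2), printed as 0.655
RAYLEIGH_SD_FACTOR = math.sqrt(2.0 - math.pi / 2.0)


def wavelength_from_stiffness(mu_pa: float, f_hz: float, rho_kg_m3: float = 1000.0) -> float:
    """Shear wavelength in mm from mu = rho (lambda f)^2."""
    if mu_pa <= 0 or f_hz <= 0 or rho_kg_m3 <= 0:
        raise ValueError("mu, f and rho must all be positive")
    return math.sqrt(mu_pa / rho_kg_m3) / f_hz * 1000.0


def stiffness_from_wavelength(lambda_mm: float, f_hz: float, rho_kg_m3: float = 1000.0) -> float:
    """Shear stiffness in Pa from mu = rho (lambda f)^2."""
    if lambda_mm <= 0 or f_hz <= 0 or rho_kg_m3 <= 0:
        raise ValueError("lambda, f and rho must all be positive")
    return rho_kg_m3 * (lambda_mm / 1000.0 * f_hz) ** 2


def dispersion_law(mu0_pa: float, f_hz: float, f0_hz: float, gamma: float) -> float:
    """Power-law stiffness dispersion mu(f) = mu0 (f / f0)^gamma.

    ``gamma = 0`` gives frequency-independent stiffness, the behaviour
    observed for waves travelling across the muscle fibres; ``gamma > 0``
    emulates the rise of apparent stiffness with vibration frequency
    seen along the fibres.
    """
    if f_hz <= 0 or f0_hz <= 0:
        raise ValueError("frequencies must be positive")
    if mu0_pa <= 0:
        raise ValueError("mu0 must be positive")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    return mu0_pa * (f_hz / f0_hz) ** gamma


def fit_dispersion_exponent(
    freqs_hz: np.ndarray, mus_pa: np.ndarray, f0_hz: float, mu0_pa: float | None = None
) -> float:
    """Least-squares power-law exponent from (frequency, stiffness) pairs.

    Fits ``log mu = log mu0 + gamma log(f/f0)``.  If *mu0_pa* is given it
    is held fixed; otherwise the intercept is free and gamma is the
    log-log regression slope.
    """
    f = np.asarray(freqs_hz, dtype=float)
    m = np.asarray(mus_pa, dtype=float)
    if np.any(f <= 0) or np.any(m <= 0):
        raise ValueError("frequencies and stiffnesses must be positive")
    x = np.log(f / f0_hz)
    y = np.log(m)
    if mu0_pa is not None:
        y = y - math.log(mu0_pa)
        return float(np.dot(x, y) / np.dot(x, x))
    x_c = x - x.mean()
    return float(np.dot(x_c, y - y.mean()) / np.dot(x_c, x_c))


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth and nuisance parameters of a synthetic phantom.

    ``roi_geometry`` is ``(row0, row1, col0, col1)`` (half-open) of the
    rectangular band standing in for the upper-trapezius ROI.
    """

    mu0_pa: float = 4250.0
    gamma: float = 0.0
    f0_hz: float = 60.0
    rho_kg_m3: float = 1000.0
    propagation_angle_deg: float = 0.0
    amplitude_um: float = 50.0
    attenuation_per_mm: float = 0.015
    noise_sigma: float = 0.0
    shape: tuple[int, int] = (128, 128)
    roi_geometry: tuple[int, int, int, int] = (42, 86, 16, 112)
    marker_positions: tuple[tuple[int, int], ...] = ((6, 40), (6, 64), (6, 88))
    tissue_level: float = 100.0
    background_phase_rad: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu0_pa <= 0:
            raise ValueError("mu0_pa must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.attenuation_per_mm < 0:
            raise ValueError("attenuation_per_mm must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


class GroundTruth(NamedTuple):
    """True stiffness, wavelength and propagation direction of a phantom."""

    mu_pa: float
    lambda_mm: float
    direction: tuple[float, float]  # (d_row, d_col) unit vector


def _body_mask(shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    return ((rr - (h - 1) / 2) / (0.41 * h)) ** 2 + (
        (cc - (w - 1) / 2) / (0.41 * w)
    ) ** 2 <= 1.0


def _background_roi(shape: tuple[int, int], radius: int = 9) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - 12) ** 2 + (cc - 12) ** 2 <= radius**2


def make_phantom(
    spec: PhantomSpec, meta: AcquisitionMeta
) -> tuple[MREDataset, ROIMask, ROIMask, GroundTruth]:
    """Build a plane-wave phantom dataset.

    Returns the dataset, the tissue ("UT") ROI, a pure-background ROI for
    noise estimation, and the ground truth at the acquisition frequency
    (stiffness via the dispersion law, wavelength via mu = rho (lambda f)^2).
    """
    h, w = spec.shape
    px = meta.pixel_spacing_mm
    mu = dispersion_law(spec.mu0_pa, meta.frequency_hz, spec.f0_hz, spec.gamma)
    lam_mm = wavelength_from_stiffness(mu, meta.frequency_hz, spec.rho_kg_m3)
    if lam_mm < 3.0 * px:
        raise ValueError(
            f"wavelength {lam_mm:.2f} mm is below the resolvable limit of "
            f"3 pixels ({3 * px:.2f} mm)"
        )
    r0, r1, c0, c1 = spec.roi_geometry
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"ROI geometry {spec.roi_geometry} outside {spec.shape} image")

    theta = math.radians(spec.propagation_angle_deg)
    # angle 0 propagates along +col (VAP-like); 90 along +row (HAP-like)
    d_row, d_col = math.sin(theta), math.cos(theta)

    rr, cc = np.mgrid[0:h, 0:w]
    proj_mm = (rr * d_row + cc * d_col) * px
    dist_mm = proj_mm - proj_mm.min()

    body = _body_mask(spec.shape)
    amp_um = spec.amplitude_um * np.exp(-spec.attenuation_per_mm * dist_mm)
    phase_amp = meta.encoding_scale_rad_per_um * amp_um

    magnitude = np.where(body, spec.tissue_level, 0.0)
    for mr, mc in spec.marker_positions:
        rr_m = (rr - mr) ** 2 + (cc - mc) ** 2 <= 4
        magnitude = np.where(rr_m, 2.0 * spec.tissue_level, magnitude)

    n = meta.n_offsets
    phi_d = 2.0 * math.pi * dist_mm / lam_mm
    rng = np.random.default_rng(spec.seed)
    phase_stack = np.empty((n, h, w), dtype=np.float32)
    mag_out = None
    for k in range(n):
        u = phase_amp * np.cos(2.0 * math.pi * k / n - phi_d)
        phase_k = np.where(body, u + spec.background_phase_rad, 0.0)
        z = magnitude * np.exp(1j * phase_k)
        if spec.noise_sigma > 0:
            z = z + spec.noise_sigma * (
                rng.standard_normal((h, w)) + 1j * rng.standard_normal((h, w))
            )
        phase_stack[k] = np.angle(z).astype(np.float32)
        if k == 0:
            mag_out = np.abs(z).astype(np.float32)

    ds = MREDataset(magnitude=mag_out, phase_stack=phase_stack, meta=meta)
    roi = np.zeros((h, w), dtype=bool)
    roi[r0:r1, c0:c1] = True
    roi &= body
    if not roi.any():
        raise ValueError("ROI does not intersect the body region")
    ut = ROIMask(mask=roi, label="UT")
    bg = ROIMask(mask=_background_roi(spec.shape) & ~body, label="background")
    truth = GroundTruth(mu_pa=mu, lambda_mm=lam_mm, direction=(d_row, d_col))
    return ds, ut, bg, truth


def make_radial_phantom(
    spec: PhantomSpec, meta: AcquisitionMeta, source_rc: tuple[float, float] | None = None
) -> tuple[MREDataset, ROIMask, ROIMask, GroundTruth]:
    """Plane-wave phantom variant with a cylindrical wave from a point source.

    The wavefronts are circles centred on *source_rc* (default: the ROI
    centroid), so the local propagation direction varies across the ROI.
    Used to exercise the "no planar waves" branch of the quality rubric.
    """
    h, w = spec.shape
    px = meta.pixel_spacing_mm
    r0, r1, c0, c1 = spec.roi_geometry
    if source_rc is None:
        source_rc = ((r0 + r1) / 2.0, (c0 + c1) / 2.0)
    mu = dispersion_law(spec.mu0_pa, meta.frequency_hz, spec.f0_hz, spec.gamma)
    lam_mm = wavelength_from_stiffness(mu, meta.frequency_hz, spec.rho_kg_m3)

    rr, cc = np.mgrid[0:h, 0:w]
    dist_mm = np.hypot(rr - source_rc[0], cc - source_rc[1]) * px
    body = _body_mask(spec.shape)
    phase_amp = meta.encoding_scale_rad_per_um * spec.amplitude_um * np.exp(
        -spec.attenuation_per_mm * dist_mm
    )
    magnitude = np.where(body, spec.tissue_level, 0.0)

    n = meta.n_offsets
    phi_d = 2.0 * math.pi * dist_mm / lam_mm
    rng = np.random.default_rng(spec.seed)
    phase_stack = np.empty((n, h, w), dtype=np.float32)
    mag_out = None
    for k in range(n):
        u = phase_amp * np.cos(2.0 * math.pi * k / n - phi_d)
        phase_k = np.where(body, u + spec.background_phase_rad, 0.0)
        z = magnitude * np.exp(1j * phase_k)
        if spec.noise_sigma > 0:
            z = z + spec.noise_sigma * (
                rng.standard_normal((h, w)) + 1j * rng.standard_normal((h, w))
            )
        phase_stack[k] = np.angle(z).astype(np.float32)
        if k == 0:
            mag_out = np.abs(z).astype(np.float32)

    ds = MREDataset(magnitude=mag_out, phase_stack=phase_stack, meta=meta)
    roi = np.zeros((h, w), dtype=bool)
    roi[r0:r1, c0:c1] = True
    roi &= body
    ut = ROIMask(mask=roi, label="UT")
    bg = ROIMask(mask=_background_roi(spec.shape) & ~body, label="background")
    return ds, ut, bg, GroundTruth(mu_pa=mu, lambda_mm=lam_mm, direction=(0.0, 0.0))


def rician_background_sd_ratio(
    n_samples: int = 1_000_000, sigma: float = 1.0, seed: int = 0
) -> float:
    """Monte-Carlo SD of |complex Gaussian noise| divided by per-channel sigma.

    The analytic value is sqrt(2 - pi/2) ~ 0.6551, the Rician-background
    correction factor applied in the magnitude-image SNR formula.
    """
    rng = np.random.default_rng(seed)
    z = sigma * (rng.standard_normal(n_samples) + 1j * rng.standard_normal(n_samples))
    return float(np.abs(z).std(ddof=1) / sigma)


def make_study_inputs(
    design: "StudyDesign", seed: int | None = None
) -> Iterator[tuple[dict, MREDataset, ROIMask, ROIMask, GroundTruth]]:
    """Yield one phantom per cell of the factorial design.

    Ground-truth structure per (subject, side): a lognormal subject
    factor (the subject's overall muscle stiffness, shared by both
    actuator positions and all frequencies) scales the design's
    reference stiffness at 60 Hz; VAP cells then follow the power-law
    dispersion along the fibres with a subject-specific exponent
    (``gamma > 0``), while HAP cells are frequency-independent
    (``gamma = 0``) — the anisotropy/dispersion contrast the study
    design exists to detect.  An independent per-dataset lognormal
    factor adds session-to-session variability.  Propagation is along
    the image columns for VAP and along the rows for HAP.

    Deterministic for a fixed design seed; each dataset's random stream
    is keyed by its cell indices, so any subset regenerates identically.

    Yields ``(cell, dataset, ut_roi, bg_roi, truth)`` where ``cell`` is
    a dict with keys subject, position, frequency_hz, side.
    """
    master = design.seed if seed is None else seed

    def _lognorm(rng: np.random.Generator, cv: float) -> float:
        if cv <= 0:
            return 1.0
        s2 = math.log(1.0 + cv * cv)
        return float(np.exp(rng.normal(-0.5 * s2, math.sqrt(s2))))

    for si in range(design.n_subjects):
        for pi, pos in enumerate(design.positions):
            for fi, f in enumerate(design.frequencies):
                for li, side in enumerate(design.sides):
                    subj_rng = np.random.default_rng(
                        np.random.SeedSequence([master, 1, si, li])
                    )
                    cell_rng = np.random.default_rng(
                        np.random.SeedSequence([master, 2, si, pi, fi, li])
                    )
                    subject_factor = _lognorm(subj_rng, design.between_subject_cv)
                    gamma_ref = design.gamma_vap[side]
                    gamma_subj = max(
                        0.2, subj_rng.normal(gamma_ref, design.gamma_subject_sd)
                    )
                    if pos == "VAP":
                        mu0 = design.mu0_kpa[("VAP", side)] * 1000.0
                        gamma = gamma_subj
                    else:
                        mu0 = design.mu0_kpa[("HAP", side)] * 1000.0
                        gamma = 0.0
                    mu0 *= subject_factor * _lognorm(
                        cell_rng, design.within_subject_cv
                    )
                    angle = 0.0 if pos == "VAP" else 90.0
                    spec = replace(
                        design.phantom,
                        mu0_pa=mu0,
                        gamma=gamma,
                        f0_hz=design.reference_frequency_hz,
                        propagation_angle_deg=angle,
                        seed=int(cell_rng.integers(2**31)),
                    )
                    meta = AcquisitionMeta(
                        frequency_hz=f,
                        n_offsets=4,
                        pixel_spacing_mm=DEFAULT_PIXEL_SPACING_MM,
                        actuator_position=pos,
                        side=side,
                        subject_id=f"S{si:02d}",
                    )
                    ds, ut, bg, truth = make_phantom(spec, meta)
                    cell = {
                        "subject": meta.subject_id,
                        "position": pos,
                        "frequency_hz": f,
                        "side": side,
                    }
                    yield cell, ds, ut, bg, truth
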