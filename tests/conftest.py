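import math

import numpy as np
import pytest

from mretrap import (
    AcquisitionMeta,
    PhantomSpec,
    StudyDesign,
    make_phantom,
    run_study,
    stiffness_from_wavelength,
)
from mretrap.waveproc import WaveField


@pytest.fixture
def meta60() -> AcquisitionMeta:
    return AcquisitionMeta(frequency_hz=60)


def build_plane_field(
    lambda_px: float,
    angle_deg: float = 0.0,
    shape: tuple[int, int] = (128, 128),
    amplitude: float = 1.0,
    meta: AcquisitionMeta | None = None,
) -> WaveField:
    """Analytic plane-wave harmonic: H = A exp(i 2 pi d / lambda)."""
    if meta is None:
        meta = AcquisitionMeta(frequency_hz=60)
    theta = math.radians(angle_deg)
    d_row, d_col = math.sin(theta), math.cos(theta)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    d = rr * d_row + cc * d_col
    return WaveField(
        harmonic=amplitude * np.exp(1j * 2 * math.pi * d / lambda_px), meta=meta
    )


def noise_free_phantom(mu_kpa: float, f_hz: float, angle_deg: float = 0.0, **kw):
    """Plane-wave phantom without noise at the given ground truth."""
    meta = AcquisitionMeta(frequency_hz=f_hz)
    spec = PhantomSpec(
        mu0_pa=mu_kpa * 1000.0,
        f0_hz=f_hz,
        propagation_angle_deg=angle_deg,
        noise_sigma=0.0,
        **kw,
    )
    return make_phantom(spec, meta)


def phantom_with_n_wavelengths(n_wavelengths: float, f_hz: float = 60.0):
    """Noise-free phantom whose ROI holds exactly n wavelengths along the
    propagation direction."""
    from mretrap.caliper import roi_extent_px

    meta = AcquisitionMeta(frequency_hz=f_hz)
    probe, ut, _, _ = make_phantom(PhantomSpec(noise_sigma=0.0), meta)
    extent_mm = roi_extent_px(ut, (0.0, 1.0)) * meta.pixel_spacing_mm
    lam_mm = extent_mm / n_wavelengths
    mu = stiffness_from_wavelength(lam_mm, f_hz)
    return make_phantom(PhantomSpec(mu0_pa=mu, f0_hz=f_hz, noise_sigma=0.0), meta)


@pytest.fixture(scope="session")
def default_study():
    """One full 108-dataset two-observer study run (seed 0), shared across
    tests that only read from it."""
    design = StudyDesign(seed=0)
    return design, run_study(design)
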