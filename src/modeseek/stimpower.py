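"""Orientation power profiles and classification images.

The analysis reduces each noise image to the power of its 2-D Fourier
spectrum on the circle at the signal's spatial frequency, binned by
orientation into 60 axial bins of 3 degrees covering [0, 180). A vertical
grating maps to the 90-degree bin, clockwise tilts to larger angles.
Classification images are bin-wise differences between the mean profile on
alarm trials and on rejection trials; their polar centroid (the "average
vector") summarizes where the difference points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import (
    ConfigurationError,
    InsufficientDataError,
    UndefinedValueError,
)
from .synth import ExperimentDesign, StimulusImage, gaussian_envelope

__all__ = [
    "OrientationPowerProfile",
    "ClassificationImage",
    "AverageVector",
    "N_BINS",
    "BIN_WIDTH_DEG",
    "bin_centers",
    "apply_envelope",
    "orientation_power_profile",
    "orientation_power_profiles",
    "relative_band_power",
    "classification_image",
    "average_vector",
    "conditional_shift",
]

N_BINS = 60
BIN_WIDTH_DEG = 3.0


def bin_centers() -> np.ndarray:
    """Bin-centre orientations in degrees: 0, 3, ..., 177."""
    return np.arange(N_BINS) * BIN_WIDTH_DEG


@dataclass
class OrientationPowerProfile:
    """Spectral power by orientation at one spatial frequency.

    ``power[i]`` is the power at the orientation ``bin_centers()[i]``; the
    spectrum's conjugate-symmetric half-planes are folded so orientations
    live on the axial range [0, 180).
    """

    power: np.ndarray
    spatial_freq: float

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (N_BINS,):
            raise ConfigurationError(f"profile must have {N_BINS} bins")


@dataclass
class ClassificationImage:
    """Alarm-minus-rejection mean orientation-power profile."""

    delta_power: np.ndarray
    n_alarm: int
    n_reject: int
    condition: str = "all"


@dataclass
class AverageVector:
    """Polar summary of a classification image.

    ``angle`` is in degrees on [0, 180); angles above 90 denote clockwise
    displacement from vertical. ``magnitude`` is in the units of the
    classification image's delta power.
    """

    angle: float
    magnitude: float


# ---------------------------------------------------------------------------
# Spectral profiles
# ---------------------------------------------------------------------------

def apply_envelope(image: StimulusImage, design: ExperimentDesign) -> StimulusImage:
    """Multiply an image pixel-wise by the Gaussian stimulus envelope."""
    env = gaussian_envelope(design)
    if env.shape != image.pixels.shape:
        raise ConfigurationError("image grid does not match the design grid")
    return StimulusImage(
        pixels=image.pixels * env,
        pixels_per_degree=image.pixels_per_degree,
        gabor_orientation=image.gabor_orientation,
        gabor_contrast=image.gabor_contrast,
        gabor_phase=image.gabor_phase,
        rng_seed=image.rng_seed,
    )


def _sample_ring_interp(power: np.ndarray, radius_px: float, phi_rad: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of a (batched) fftshifted power array on a ring.

    ``power`` has shape (..., n, n); returns shape (..., len(phi_rad)).
    """
    n = power.shape[-1]
    cx = n // 2
    fx = cx + radius_px * np.cos(phi_rad)
    fy = cx + radius_px * np.sin(phi_rad)
    x0 = np.floor(fx).astype(int)
    y0 = np.floor(fy).astype(int)
    if np.any(x0 < 0) or np.any(y0 < 0) or np.any(x0 + 1 >= n) or np.any(y0 + 1 >= n):
        raise ConfigurationError("target spatial frequency beyond the Nyquist limit")
    wx = fx - x0
    wy = fy - y0
    p00 = power[..., y0, x0]
    p01 = power[..., y0, x0 + 1]
    p10 = power[..., y0 + 1, x0]
    p11 = power[..., y0 + 1, x0 + 1]
    return (
        p00 * (1 - wy) * (1 - wx)
        + p01 * (1 - wy) * wx
        + p10 * wy * (1 - wx)
        + p11 * wy * wx
    )


def _sample_ring_annulus(power: np.ndarray, radius_px: float) -> np.ndarray:
    """Average power over an annulus of +-0.5 px around the ring, by angle bin."""
    n = power.shape[-1]
    cx = n // 2
    ii = np.arange(n) - cx
    yy, xx = np.meshgrid(ii, ii, indexing="ij")
    rr = np.hypot(xx, yy)
    ring = np.abs(rr - radius_px) <= 0.5
    phi = np.rad2deg(np.arctan2(yy, xx))  # FFT angle in degrees
    theta = np.mod(phi + 90.0, 180.0)  # grating-orientation scale
    idx = np.mod(np.round(theta / BIN_WIDTH_DEG).astype(int), N_BINS)
    out_shape = power.shape[:-2] + (N_BINS,)
    out = np.zeros(out_shape)
    counts = np.zeros(N_BINS)
    flat_idx = idx[ring]
    vals = power[..., ring]
    for b in range(N_BINS):
        sel = flat_idx == b
        counts[b] = sel.sum()
        if counts[b]:
            out[..., b] = vals[..., sel].mean(axis=-1)
    return out


def orientation_power_profiles(
    pixels: np.ndarray, design: ExperimentDesign, method: str = "interp"
) -> np.ndarray:
    """Profiles for a stack of images at once.

    ``pixels`` has shape (n_images, n, n) (already enveloped). Returns an
    (n_images, 60) array of power by orientation bin at the design's Gabor
    spatial frequency. ``method`` is ``"interp"`` (bilinear interpolation of
    |FFT|^2 at exact polar coordinates) or ``"annulus"`` (nearest-bin pooling
    over a one-pixel-wide ring).
    """
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim == 2:
        pixels = pixels[None]
    n = pixels.shape[-1]
    radius_px = design.spatial_freq * design.field_size  # cycles per image
    if radius_px >= n / 2:
        raise ConfigurationError(
            f"spatial frequency {design.spatial_freq} cpd is beyond Nyquist for a "
            f"{n}-pixel grid over {design.field_size} d.v.a."
        )
    spec = np.fft.fftshift(np.fft.fft2(pixels), axes=(-2, -1))
    power = np.abs(spec) ** 2
    if method == "interp":
        theta = np.deg2rad(bin_centers())
        phi = theta - np.pi / 2  # spectral energy axis is perpendicular to stripes
        half1 = _sample_ring_interp(power, radius_px, phi)
        half2 = _sample_ring_interp(power, radius_px, phi + np.pi)
        return 0.5 * (half1 + half2)
    if method == "annulus":
        return _sample_ring_annulus(power, radius_px)
    raise ConfigurationError(f"unknown sampling method {method!r}")


def orientation_power_profile(
    image: StimulusImage, design: ExperimentDesign, method: str = "interp"
) -> OrientationPowerProfile:
    """Profile of a single (already enveloped) image."""
    prof = orientation_power_profiles(image.pixels, design, method=method)[0]
    return OrientationPowerProfile(power=prof, spatial_freq=design.spatial_freq)


def simulate_noise_profiles(
    design: ExperimentDesign,
    n_images: int,
    seed: int | np.random.Generator,
    method: str = "interp",
    chunk: int = 256,
) -> np.ndarray:
    """Profiles of freshly rendered, enveloped white-noise images.

    Renders ``n_images`` noise images, applies the Gaussian envelope and
    reduces each to its orientation-power profile, processing in chunks so
    pixel data never accumulates in memory. Returns an (n_images, 60) array.
    """
    from .synth import render_noise

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    env = gaussian_envelope(design)
    out = np.empty((n_images, N_BINS))
    for start in range(0, n_images, chunk):
        stop = min(start + chunk, n_images)
        pix = np.stack(
            [render_noise(design, rng).pixels for _ in range(stop - start)]
        )
        out[start:stop] = orientation_power_profiles(pix * env, design, method=method)
    return out


# ---------------------------------------------------------------------------
# Relative band power
# ---------------------------------------------------------------------------

def relative_band_power(
    profile: OrientationPowerProfile | np.ndarray,
    band: tuple[float, float] = (60.0, 120.0),
    mode: str = "mean",
) -> float | np.ndarray:
    """Band power relative to total power.

    Default is the ratio of the mean power over bins whose centres fall in
    ``band`` to the mean power over all bins, so a flat profile scores exactly
    1. ``mode="sum"`` uses the ratio of sums instead (a flat profile then
    scores the band fraction). Accepts a single profile or an (n, 60) array
    and is vectorized over rows.
    """
    power = profile.power if isinstance(profile, OrientationPowerProfile) else np.asarray(profile, dtype=float)
    lo, hi = band
    if not (0.0 <= lo <= hi <= 180.0):
        raise ConfigurationError(f"band must lie within [0, 180], got {band}")
    in_band = (bin_centers() >= lo) & (bin_centers() <= hi)
    if not in_band.any():
        raise ConfigurationError(f"no bin centres fall inside the band {band}")
    total = power.mean(axis=-1)
    if np.any(total <= 0):
        raise UndefinedValueError("relative band power undefined for zero total power")
    band_stat = power[..., in_band].mean(axis=-1)
    if mode == "sum":
        ratio = power[..., in_band].sum(axis=-1) / power.sum(axis=-1)
    elif mode == "mean":
        ratio = band_stat / total
    else:
        raise ConfigurationError(f"mode must be 'mean' or 'sum', got {mode!r}")
    return float(ratio) if np.ndim(ratio) == 0 else ratio


# ---------------------------------------------------------------------------
# Classification images and average vectors
# ---------------------------------------------------------------------------

def classification_image(
    profiles: np.ndarray,
    alarms: np.ndarray,
    mask: np.ndarray | None = None,
    condition: str = "all",
) -> ClassificationImage:
    """Bin-wise alarm-mean minus rejection-mean of orientation-power profiles.

    ``profiles`` is (n_trials, 60); ``alarms`` a boolean alarm flag per trial;
    ``mask`` optionally restricts the trials entering the difference (e.g.
    noise-only trials in one mode after clockwise inducers).
    """
    profiles = np.asarray(profiles, dtype=float)
    alarms = np.asarray(alarms, dtype=bool)
    if mask is None:
        mask = np.ones(len(alarms), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    sel_alarm = mask & alarms
    sel_reject = mask & ~alarms
    n_a, n_r = int(sel_alarm.sum()), int(sel_reject.sum())
    if n_a == 0 or n_r == 0:
        raise InsufficientDataError(
            f"classification image needs both classes (alarms={n_a}, rejections={n_r})"
        )
    delta = profiles[sel_alarm].mean(axis=0) - profiles[sel_reject].mean(axis=0)
    return ClassificationImage(delta_power=delta, n_alarm=n_a, n_reject=n_r,
                               condition=condition)


def average_vector(
    ci: ClassificationImage | np.ndarray, negative: str = "shift"
) -> AverageVector:
    """Centroid of the classification image's polar endpoints.

    Each bin contributes an endpoint at (radius, bin-centre angle) in polar
    coordinates over the half-circle [0, 180). Radii must be nonnegative:
    ``negative="shift"`` (default) subtracts the minimum bin value when any
    bin is negative, ``negative="clip"`` zeroes negative bins. The centroid of
    the endpoints gives the average vector; its angle is folded to [0, 180).
    """
    delta = ci.delta_power if isinstance(ci, ClassificationImage) else np.asarray(ci, dtype=float)
    if np.allclose(delta, 0.0):
        raise UndefinedValueError("average vector undefined for an all-zero profile")
    if negative == "shift":
        radii = delta - min(delta.min(), 0.0)
    elif negative == "clip":
        radii = np.clip(delta, 0.0, None)
    else:
        raise ConfigurationError(f"negative must be 'shift' or 'clip', got {negative!r}")
    if np.allclose(radii, 0.0):
        raise UndefinedValueError("average vector undefined: all radii are zero")
    theta = np.deg2rad(bin_centers())
    cx = float(np.mean(radii * np.cos(theta)))
    cy = float(np.mean(radii * np.sin(theta)))
    angle = np.rad2deg(np.arctan2(cy, cx)) % 180.0
    return AverageVector(angle=float(angle), magnitude=float(np.hypot(cx, cy)))


def conditional_shift(angle_cw: float, angle_ccw: float) -> float:
    """Signed displacement of the average vector toward the preceding inducer.

    Positive values mean the classification image shifted toward the inducer
    orientation: above 90 degrees after clockwise inducers and below 90 after
    counter-clockwise ones.
    """
    return 0.5 * ((angle_cw - 90.0) + (90.0 - angle_ccw))
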