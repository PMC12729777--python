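"""Synthetic inputs for the compression-analysis pipeline.

Every stage of the pipeline (orientation quantification, device signal
fitting, damage statistics) can be exercised without any experimental data:
this module generates fluorescence-like single-cell images with known
filament orientation, sinusoidal actuator voltage traces, linear-elastic
gel stress--strain curves, and binomial live/dead viability counts.  All
generators are pure functions of their parameters and an integer seed.

Image convention (used across the whole package): images are row-major 2-D
arrays with the origin at the top-left; a point is ``(x, y)`` with ``x`` the
column and ``y`` the row; angles are measured in degrees from the +x (column)
axis toward +y.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter


class GeometryError(ValueError):
    """A requested filament or shape does not fit inside the cell body."""


class AliasingError(ValueError):
    """Sampling rate too low for the requested signal frequency."""


@dataclass
class GroundTruth:
    """Exact parameters used to draw a synthetic cell image.

    Filament angles are relative to the cell long axis and lie in [0, 90]
    degrees; ``axis_angle`` is the in-image direction of the long axis in
    [0, 180).  Carrying these values alongside the image lets any downstream
    estimate be scored exactly.
    """

    ellipse_center: tuple[float, float]
    semi_major: float
    semi_minor: float
    axis_angle: float
    filament_angles: list[float] = field(default_factory=list)
    filament_endpoints: list[tuple[tuple[float, float], tuple[float, float]]] = field(
        default_factory=list
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError("require semi_major >= semi_minor > 0")
        for a in self.filament_angles:
            if not (0.0 <= a <= 90.0):
                raise ValueError(f"filament angle {a} outside [0, 90]")
        self.axis_angle = float(self.axis_angle) % 180.0


@dataclass
class CellImage:
    """A grayscale intensity image with physical pixel size."""

    pixels: np.ndarray
    pixel_size: float = 0.25  # micrometres per pixel

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("non-finite intensities")


@dataclass
class VoltageSignal:
    """A sampled sinusoidal drive voltage V(t) = A sin(2πf (t + t0)) + C."""

    times: np.ndarray
    volts: np.ndarray
    V_amplitude: float
    V_offset: float
    f: float
    t0: float


def _inside_ellipse(p: np.ndarray, center: np.ndarray, a: float, b: float,
                    theta_deg: float) -> bool:
    c, s = math.cos(math.radians(theta_deg)), math.sin(math.radians(theta_deg))
    d = p - center
    u = c * d[0] + s * d[1]
    v = -s * d[0] + c * d[1]
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _draw_thick_segment(img: np.ndarray, p0: np.ndarray, p1: np.ndarray,
                        thickness: float, value: float) -> None:
    # Paint a capsule (segment dilated by thickness/2) by distance test on a
    # local bounding box; sub-pixel soft edge gives mild anti-aliasing.
    r = thickness / 2.0
    lo = np.floor(np.minimum(p0, p1) - r - 1).astype(int)
    hi = np.ceil(np.maximum(p0, p1) + r + 1).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.array([img.shape[1] - 1, img.shape[0] - 1]))
    if np.any(hi < lo):
        return
    xs = np.arange(lo[0], hi[0] + 1)
    ys = np.arange(lo[1], hi[1] + 1)
    X, Y = np.meshgrid(xs, ys)
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0:
        return
    t = ((X - p0[0]) * d[0] + (Y - p0[1]) * d[1]) / L2
    t = np.clip(t, 0.0, 1.0)
    dx = X - (p0[0] + t * d[0])
    dy = Y - (p0[1] + t * d[1])
    dist = np.hypot(dx, dy)
    cov = np.clip(r + 0.5 - dist, 0.0, 1.0)  # coverage ramp over one pixel
    img[lo[1]:hi[1] + 1, lo[0]:hi[0] + 1] = np.maximum(
        img[lo[1]:hi[1] + 1, lo[0]:hi[0] + 1], value * cov
    )


def generate_cell_image(
    shape: tuple[int, int] = (256, 256),
    center: tuple[float, float] | None = None,
    semi_major: float = 100.0,
    semi_minor: float = 40.0,
    axis_angle: float = 0.0,
    filament_angles: list[float] | None = None,
    filament_length_frac: float = 0.75,
    filament_thickness: float = 3.0,
    body_intensity: float = 100.0,
    filament_intensity_ratio: float = 1.5,
    noise_sd: float = 0.0,
    psf_sigma: float = 1.0,
    seed: int = 0,
) -> tuple[CellImage, GroundTruth]:
    """Draw one adherent cell: a filled ellipse plus bright linear filaments.

    Filaments are straight capsule-shaped segments at ``filament_intensity_ratio``
    times the body intensity (default 1.5x, 3 px thick), each making its listed
    angle with the ellipse major axis.  The image is blurred with a Gaussian of
    ``psf_sigma`` pixels and Gaussian noise of standard deviation ``noise_sd``
    is added.  Identical parameters and seed give byte-identical images.

    Returns the image together with the :class:`GroundTruth` used to draw it.

    Raises
    ------
    GeometryError
        If a requested filament cannot be placed inside the ellipse.
    """
    if semi_minor <= 0 or semi_major < semi_minor:
        raise ValueError("require semi_major >= semi_minor > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if filament_angles is None:
        filament_angles = []
    h, w = shape
    if center is None:
        center = (w / 2.0, h / 2.0)
    rng = np.random.default_rng(seed)
    ctr = np.asarray(center, dtype=float)

    img = np.zeros((h, w), dtype=float)
    Y, X = np.mgrid[0:h, 0:w]
    c, s = math.cos(math.radians(axis_angle)), math.sin(math.radians(axis_angle))
    U = c * (X - ctr[0]) + s * (Y - ctr[1])
    V = -s * (X - ctr[0]) + c * (Y - ctr[1])
    body = (U / semi_major) ** 2 + (V / semi_minor) ** 2 <= 1.0
    img[body] = body_intensity

    endpoints = []
    fil_val = body_intensity * filament_intensity_ratio
    for alpha in filament_angles:
        if not (0.0 <= alpha <= 90.0):
            raise ValueError(f"filament angle {alpha} outside [0, 90]")
        theta = math.radians(axis_angle + alpha)
        d = np.array([math.cos(theta), math.sin(theta)])
        # place the filament midpoint off-centre but keep both ends inside
        length = filament_length_frac * semi_minor / max(
            math.sin(math.radians(alpha)) * 1.0, semi_minor / semi_major
        )
        length = min(length, 1.6 * semi_major)
        placed = False
        for _ in range(200):
            off_u = rng.uniform(-0.5, 0.5) * semi_major
            off_v = rng.uniform(-0.5, 0.5) * semi_minor
            mid = ctr + np.array([c * off_u - s * off_v, s * off_u + c * off_v])
            p0 = mid - d * length / 2.0
            p1 = mid + d * length / 2.0
            if _inside_ellipse(p0, ctr, semi_major, semi_minor, axis_angle) and \
               _inside_ellipse(p1, ctr, semi_major, semi_minor, axis_angle):
                placed = True
                break
        if not placed:
            raise GeometryError(
                f"filament of length {length:.1f}px at alpha={alpha} does not fit "
                "inside the ellipse"
            )
        _draw_thick_segment(img, p0, p1, filament_thickness, fil_val)
        endpoints.append(((float(p0[0]), float(p0[1])), (float(p1[0]), float(p1[1]))))

    if psf_sigma > 0:
        img = gaussian_filter(img, psf_sigma)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None)

    truth = GroundTruth(
        ellipse_center=(float(ctr[0]), float(ctr[1])),
        semi_major=float(semi_major),
        semi_minor=float(semi_minor),
        axis_angle=float(axis_angle),
        filament_angles=[float(a) for a in filament_angles],
        filament_endpoints=endpoints,
        seed=seed,
    )
    return CellImage(pixels=img), truth


def generate_voltage_signal(
    V_amplitude: float,
    V_offset: float,
    f: float,
    t0: float = 0.0,
    duration: float = 10.0,
    sample_rate: float = 100.0,
) -> VoltageSignal:
    """Sample V(t) = V_amplitude * sin(2*pi*f*(t + t0)) + V_offset.

    Noiseless; the returned samples satisfy the defining expression to
    machine precision.  ``sample_rate`` must exceed twice the frequency.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if f > 0 and sample_rate <= 2.0 * f:
        raise AliasingError(
            f"sample_rate {sample_rate} Hz <= Nyquist limit for f={f} Hz"
        )
    n = int(round(duration * sample_rate))
    times = np.arange(n) / sample_rate
    omega = 2.0 * math.pi * f
    volts = V_amplitude * np.sin(omega * (times + t0)) + V_offset
    return VoltageSignal(times=times, volts=volts, V_amplitude=V_amplitude,
                         V_offset=V_offset, f=f, t0=t0)


def generate_stress_strain_samples(
    E_true: float,
    strain_max: float = 0.2,
    n_points: int = 50,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Linear-elastic stress--strain samples: stress = E_true * strain + noise.

    Returns an ``(n_points, 2)`` array of (strain, stress) with strains
    ascending from 0.  Emulates the linear portion of an unconfined gel
    compression test.
    """
    if E_true <= 0:
        raise ValueError("E_true must be positive")
    if not (0 < strain_max < 1):
        raise ValueError("strain_max must lie in (0, 1)")
    if n_points < 2:
        raise ValueError("need at least 2 points")
    rng = np.random.default_rng(seed)
    strain = np.linspace(0.0, strain_max, n_points)
    stress = E_true * strain
    if noise_sd > 0:
        stress = stress + rng.normal(0.0, noise_sd, size=n_points)
    return np.column_stack([strain, stress])


def generate_viability_counts(
    death_prob: float, T: int, seed: int = 0
) -> tuple[int, int]:
    """Draw a dead-cell count ND ~ Binomial(T, death_prob); returns (ND, T)."""
    if not (0.0 <= death_prob <= 1.0):
        raise ValueError("death_prob must lie in [0, 1]")
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    nd = int(rng.binomial(T, death_prob))
    return nd, T
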