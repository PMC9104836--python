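"""FPM forward model: geometry, pupils, Fourier-domain sampling, simulation.

A Fourier ptychographic microscope captures a stack of low-resolution (LR)
intensity images, one per LED of a programmable array. Each oblique
illumination angle shifts the object's spectrum so that a different circular
sub-aperture (the objective pupil) of the high-resolution (HR) Fourier plane
is sampled:

    I_j = | F^H { p . Q_j F u } |^2

where ``u`` is the complex HR object, ``F`` the unitary 2-D Fourier
transform, ``Q_j`` the windowed downsampling of the centered HR spectrum for
the j-th illumination, and ``p`` the complex pupil transfer function on the
LR grid. This module builds all of these pieces and simulates measurement
stacks from a known ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._fft import ft2, ift2
from .zernike import zernike_phase

__all__ = [
    "OpticalConfig",
    "Illumination",
    "Pupil",
    "GroundTruth",
    "MeasurementSet",
    "SpectrumWindow",
    "led_illuminations",
    "make_pupil",
    "sampling_window",
    "forward_intensity",
    "simulate_dataset",
]


@dataclass(frozen=True)
class OpticalConfig:
    """Imaging geometry and sampling grids of an LED-array FPM platform.

    Defaults reproduce a standard simulation platform: 6.5 um sensor pixels
    behind a 4x / 0.1 NA objective, a 15 x 15 LED array 86 mm above the
    sample with 4 mm pitch, 632 nm illumination, 128 x 128 LR patches
    reconstructed on a 384 x 384 HR grid.

    Parameters
    ----------
    wavelength_um : illumination wavelength, micrometres.
    magnification : objective magnification (dimensionless).
    objective_na : objective numerical aperture, in (0, 1).
    sensor_pixel_um : physical sensor pixel pitch, micrometres.
    led_rows, led_cols : LED array dimensions.
    led_pitch_mm : spacing between adjacent LEDs, millimetres.
    led_height_mm : LED array height above the sample, millimetres.
    lr_side : measurement (LR) grid side, pixels; must be even.
    hr_side : reconstruction (HR) grid side, pixels; must be even.
    """

    wavelength_um: float = 0.632
    magnification: float = 4.0
    objective_na: float = 0.1
    sensor_pixel_um: float = 6.5
    led_rows: int = 15
    led_cols: int = 15
    led_pitch_mm: float = 4.0
    led_height_mm: float = 86.0
    lr_side: int = 128
    hr_side: int = 384

    def __post_init__(self) -> None:
        if self.wavelength_um <= 0:
            raise ValueError("wavelength must be positive")
        if not 0 < self.objective_na < 1:
            raise ValueError("objective NA must lie in (0, 1)")
        if self.hr_side < self.lr_side:
            raise ValueError("hr_side must be >= lr_side")
        if self.lr_side % 2 or self.hr_side % 2:
            raise ValueError("grid sides must be even")
        if self.sensor_pixel_um <= 0 or self.magnification <= 0:
            raise ValueError("sensor pixel and magnification must be positive")
        # Nyquist advisory: the HR grid pixel must resolve the synthetic
        # aperture; violations degrade quality but are not fatal.
        f_max = (self.objective_na + self.max_illum_na) / self.wavelength_um
        hr_pixel = self.object_pixel_um * self.lr_side / self.hr_side
        if hr_pixel > 1.0 / (2.0 * f_max):
            warnings.warn(
                "HR grid undersamples the synthetic aperture "
                f"(pixel {hr_pixel:.3f} um > Nyquist {1.0 / (2 * f_max):.3f} um)",
                stacklevel=2,
            )

    @property
    def object_pixel_um(self) -> float:
        """Object-plane pixel size of the LR grid (sensor pixel / magnification)."""
        return self.sensor_pixel_um / self.magnification

    @property
    def freq_step(self) -> float:
        """Fourier-grid spacing, cycles/um. Identical for the LR and HR grids."""
        return 1.0 / (self.lr_side * self.object_pixel_um)

    @property
    def aperture_radius_px(self) -> float:
        """Pupil aperture radius on the Fourier grid, in pixels (may be fractional)."""
        return self.objective_na / (self.wavelength_um * self.freq_step)

    @property
    def n_leds(self) -> int:
        return self.led_rows * self.led_cols

    @property
    def max_illum_na(self) -> float:
        """Illumination NA of the corner LED."""
        dx = (self.led_cols - 1) / 2.0 * self.led_pitch_mm
        dy = (self.led_rows - 1) / 2.0 * self.led_pitch_mm
        r = np.hypot(dx, dy)
        return float(r / np.hypot(r, self.led_height_mm))


@dataclass(frozen=True)
class Illumination:
    """One LED's plane-wave illumination of the sample.

    ``tilt_frequency`` is the spatial-frequency offset (fy, fx) in cycles/um
    imparted by the oblique plane wave; ``pixel_shift`` is that offset
    rounded to the nearest HR Fourier-grid bin. ``regime`` is brightfield
    when the illumination NA does not exceed the objective NA.
    """

    led_index: tuple[int, int]
    tilt_frequency: tuple[float, float]
    pixel_shift: tuple[int, int]
    illum_na: float
    regime: str  # "brightfield" | "darkfield"


@dataclass(frozen=True)
class Pupil:
    """Complex pupil transfer function on the LR Fourier grid.

    Unit modulus inside the circular aperture, zero outside; the phase
    inside is a Zernike expansion of the objective's aberration.
    """

    values: np.ndarray
    aperture_mask: np.ndarray
    aberration: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.values.shape != self.aperture_mask.shape:
            raise ValueError("pupil values and mask shapes differ")


@dataclass(frozen=True)
class GroundTruth:
    """Complex object ``u = amplitude * exp(i phase)`` on the HR grid."""

    amplitude: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        if self.amplitude.shape != self.phase.shape:
            raise ValueError("amplitude and phase shapes differ")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude must be nonnegative")
        # store phase wrapped to (-pi, pi]; leave in-range values untouched
        # so that the wrap is exactly idempotent
        out_of_range = (self.phase > np.pi) | (self.phase <= -np.pi)
        if np.any(out_of_range):
            wrapped = np.where(
                out_of_range, -np.angle(np.exp(-1j * self.phase)), self.phase
            )
            object.__setattr__(self, "phase", wrapped)

    @property
    def complex_object(self) -> np.ndarray:
        return self.amplitude * np.exp(1j * self.phase)


@dataclass
class MeasurementSet:
    """Per-LED LR intensity stack plus illumination metadata."""

    intensities: np.ndarray  # (N, m, m), nonnegative
    illuminations: list[Illumination]
    config: OpticalConfig
    noise_record: dict = field(
        default_factory=lambda: {
            "model": "none",
            "level": 0.0,
            "seed": None,
            "affected_indices": [],
        }
    )

    def __post_init__(self) -> None:
        if self.intensities.ndim != 3:
            raise ValueError("intensity stack must be 3-D (N, m, m)")
        if len(self.illuminations) != self.intensities.shape[0]:
            raise ValueError("one illumination per intensity image required")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")

    @property
    def amplitudes(self) -> np.ndarray:
        """Measured moduli A_j = sqrt(I_j), the quantity the solvers fit."""
        return np.sqrt(self.intensities)


@dataclass(frozen=True)
class SpectrumWindow:
    """An lr_side^2 window on the centered HR spectrum, displaced from DC.

    ``crop`` applies the downsampling operator Q_j; ``embed`` applies its
    adjoint Q_j^T (zero-padded embedding), so crop(embed(r)) == r.
    """

    hr_side: int
    lr_side: int
    shift: tuple[int, int]  # (dy, dx) in HR Fourier bins

    @property
    def r0(self) -> int:
        return self.hr_side // 2 + self.shift[0] - self.lr_side // 2

    @property
    def c0(self) -> int:
        return self.hr_side // 2 + self.shift[1] - self.lr_side // 2

    def __post_init__(self) -> None:
        m = self.lr_side
        if not (0 <= self.r0 and self.r0 + m <= self.hr_side):
            raise ValueError(f"window rows [{self.r0}, {self.r0 + m}) off the HR grid")
        if not (0 <= self.c0 and self.c0 + m <= self.hr_side):
            raise ValueError(f"window cols [{self.c0}, {self.c0 + m}) off the HR grid")

    def crop(self, spectrum: np.ndarray) -> np.ndarray:
        m = self.lr_side
        return spectrum[self.r0 : self.r0 + m, self.c0 : self.c0 + m]

    def embed(self, patch: np.ndarray) -> np.ndarray:
        out = np.zeros((self.hr_side, self.hr_side), dtype=patch.dtype)
        m = self.lr_side
        out[self.r0 : self.r0 + m, self.c0 : self.c0 + m] = patch
        return out

    def add_into(self, accumulator: np.ndarray, patch: np.ndarray) -> None:
        """In-place adjoint accumulation (for building normal-equation sums)."""
        m = self.lr_side
        accumulator[self.r0 : self.r0 + m, self.c0 : self.c0 + m] += patch


def led_illuminations(config: OpticalConfig) -> list[Illumination]:
    """Enumerate the illuminations of every LED in the array, row-major.

    The LED at grid position (r, c) sits at lateral offset
    ((c - (cols-1)/2), (r - (rows-1)/2)) * pitch from the optical axis; its
    plane wave tilts the spectrum by (sin_theta_y, sin_theta_x)/wavelength.

    Raises
    ------
    ValueError
        If any LED's sampling window would fall off the HR grid.
    """
    out: list[Illumination] = []
    for r in range(config.led_rows):
        for c in range(config.led_cols):
            dy_mm = (r - (config.led_rows - 1) / 2.0) * config.led_pitch_mm
            dx_mm = (c - (config.led_cols - 1) / 2.0) * config.led_pitch_mm
            r3 = float(np.sqrt(dy_mm**2 + dx_mm**2 + config.led_height_mm**2))
            sin_y, sin_x = dy_mm / r3, dx_mm / r3
            illum_na = float(np.hypot(sin_y, sin_x))
            tilt = (sin_y / config.wavelength_um, sin_x / config.wavelength_um)
            shift = (
                int(np.rint(tilt[0] / config.freq_step)),
                int(np.rint(tilt[1] / config.freq_step)),
            )
            illum = Illumination(
                led_index=(r, c),
                tilt_frequency=tilt,
                pixel_shift=shift,
                illum_na=illum_na,
                regime="brightfield" if illum_na <= config.objective_na else "darkfield",
            )
            # validates the window fits; converts failure to a config error
            try:
                sampling_window(illum, config)
            except ValueError as exc:
                raise ValueError(
                    f"LED {illum.led_index}: sampling window off the HR grid ({exc})"
                ) from exc
            out.append(illum)
    return out


def make_pupil(config: OpticalConfig, zernike: list[float] | tuple[float, ...] = ()) -> Pupil:
    """Circular-aperture pupil with a Zernike-parameterized phase aberration.

    ``zernike`` lists Noll-ordered coefficients (radians) starting at j=1;
    an empty list gives the ideal binary aperture.
    """
    if not np.all(np.isfinite(zernike)):
        raise ValueError("Zernike coefficients must be finite")
    m = config.lr_side
    radius = config.aperture_radius_px
    if radius >= m / 2:
        raise ValueError(
            f"pupil aperture radius {radius:.1f} px exceeds the {m}-pixel Fourier grid"
        )
    yy, xx = np.mgrid[0:m, 0:m].astype(float)
    yy -= m // 2
    xx -= m // 2
    rho_px = np.hypot(yy, xx)
    mask = rho_px <= radius
    phase = np.zeros((m, m))
    if len(zernike):
        rho = np.where(mask, rho_px / radius, 0.0)
        theta = np.arctan2(yy, xx)
        phase = np.where(mask, zernike_phase(list(zernike), rho, theta), 0.0)
    values = np.where(mask, np.exp(1j * phase), 0.0).astype(complex)
    return Pupil(values=values, aperture_mask=mask, aberration=tuple(zernike))


def sampling_window(illumination: Illumination, config: OpticalConfig) -> SpectrumWindow:
    """The Fourier-domain downsampling window Q_j for one illumination."""
    return SpectrumWindow(
        hr_side=config.hr_side, lr_side=config.lr_side, shift=illumination.pixel_shift
    )


def forward_intensity(
    truth: GroundTruth | np.ndarray, pupil: Pupil, window: SpectrumWindow
) -> np.ndarray:
    """LR intensity image I = |F^H{ p . Q_j F u }|^2 for one illumination."""
    u = truth.complex_object if isinstance(truth, GroundTruth) else truth
    if u.shape != (window.hr_side, window.hr_side):
        raise ValueError("object grid does not match the window's HR grid")
    if pupil.values.shape != (window.lr_side, window.lr_side):
        raise ValueError("pupil grid does not match the window's LR grid")
    field_lr = ift2(pupil.values * window.crop(ft2(u)))
    return np.abs(field_lr) ** 2


def simulate_dataset(
    config: OpticalConfig,
    truth: GroundTruth,
    pupil: Pupil,
    noise_spec: tuple[str, float] | None = None,
    seed: int | None = 0,
    normalize: bool = True,
) -> MeasurementSet:
    """Simulate the full per-LED measurement stack from a known ground truth.

    The stack is scaled so the brightest brightfield image has mean
    intensity 1.0 (``normalize=True``), which anchors the darkfield noise
    threshold used by the noise models. ``noise_spec`` is ``("gaussian",
    level)`` or ``("poisson", sigma)``; noise injection is reproducible
    given ``seed``.
    """
    if truth.amplitude.shape != (config.hr_side, config.hr_side):
        raise ValueError("ground truth must live on the HR grid")
    illums = led_illuminations(config)
    spectrum = ft2(truth.complex_object)
    stack = np.empty((len(illums), config.lr_side, config.lr_side))
    for i, il in enumerate(illums):
        w = sampling_window(il, config)
        stack[i] = np.abs(ift2(pupil.values * w.crop(spectrum))) ** 2
    if normalize:
        bf_means = [
            stack[i].mean() for i, il in enumerate(illums) if il.regime == "brightfield"
        ]
        scale = max(bf_means) if bf_means else stack.mean(axis=(1, 2)).max()
        if scale > 0:
            stack /= scale
    ms = MeasurementSet(intensities=stack, illuminations=illums, config=config)
    if noise_spec is not None:
        from .noise import add_gaussian_noise, add_poisson_noise

        model, level = noise_spec
        if model == "gaussian":
            ms = add_gaussian_noise(ms, level=level, seed=seed)
        elif model == "poisson":
            ms = add_poisson_noise(ms, sigma=level, seed=seed)
        elif model not in ("none", None):
            raise ValueError(f"unknown noise model {model!r}")
    return ms
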