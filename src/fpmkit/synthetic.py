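"""Procedural ground-truth objects for simulation studies.

Generates a pair of distinct natural-image-like textures for amplitude and
phase. Each image is a random-phase field with a power-law amplitude
spectrum (|S(f)| ~ f^-slope, the classical statistics of natural scenes
and micrographs), plus a few Gaussian blobs for recognizable low-frequency
structure. Power-law images carry substantial energy beyond the objective
passband, so the darkfield frames contain genuine high-resolution signal
and noise robustness is actually exercised -- a deliberately realistic
regime for synthetic-aperture reconstruction.

Images are built in the Fourier domain and are therefore periodic,
matching the FFT-based forward model. The phase image is scaled to
[0, pi/2] by default (weak-phase regime of thin biological sections); the
amplitude stays away from zero so amplitude and phase information remain
separable.
"""

from __future__ import annotations

import numpy as np

from .optics import GroundTruth

__all__ = ["synthetic_ground_truth", "textured_image"]


def textured_image(
    side: int,
    rng: np.random.Generator,
    slope: float = 1.2,
    n_blobs: int = 8,
) -> np.ndarray:
    """One procedural image in [0, 1]: power-law texture + blobs, periodic."""
    fy = np.fft.fftfreq(side)[:, None]
    fx = np.fft.fftfreq(side)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = 1.0 / side  # keep the DC amplitude finite
    spectrum = f ** (-slope) * np.exp(1j * rng.uniform(0, 2 * np.pi, (side, side)))
    img = np.real(np.fft.ifft2(spectrum))
    img = (img - img.mean()) / img.std()
    yy, xx = np.mgrid[0:side, 0:side]
    for _ in range(n_blobs):
        cy, cx = rng.integers(0, side, 2)
        w = rng.uniform(side / 40, side / 12)
        # periodic distance so blobs wrap cleanly across edges
        dy = np.minimum(np.abs(yy - cy), side - np.abs(yy - cy))
        dx = np.minimum(np.abs(xx - cx), side - np.abs(xx - cx))
        img += rng.uniform(-1.2, 1.2) * np.exp(-(dy**2 + dx**2) / (2 * w**2))
    img -= img.min()
    peak = img.max()
    return img / peak if peak > 0 else img


def synthetic_ground_truth(
    side: int,
    seed: int = 0,
    phase_max: float = np.pi / 2,
    amp_range: tuple[float, float] = (0.4, 1.0),
) -> GroundTruth:
    """Seeded amplitude/phase pair on a ``side x side`` HR grid.

    Amplitude spans ``amp_range``; phase spans ``[0, phase_max]``. The two
    images are drawn independently so that amplitude-phase crosstalk in a
    reconstruction is detectable.
    """
    rng = np.random.default_rng(seed)
    lo, hi = amp_range
    amplitude = lo + (hi - lo) * textured_image(side, rng)
    phase = phase_max * textured_image(side, rng)
    return GroundTruth(amplitude=amplitude, phase=phase)
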