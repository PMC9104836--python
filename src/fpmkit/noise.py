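"""Noise models for simulated FPM stacks.

Darkfield frames carry weak high-angle signal and are the first casualties
of sensor noise, so both models perturb only images whose mean intensity
falls below a threshold (default 0.2 on stacks normalized so the brightest
brightfield image has mean 1):

* Gaussian ("readout") noise: zero-mean, with standard deviation equal to
  ``level`` times the image's mean intensity; negative results are clipped
  to zero since detectors report nonnegative counts.
* Poisson ("shot-like") noise: each pixel value I is replaced by
  ``sigma * Poisson(I / sigma)``, a mean-preserving construction in which
  ``sigma`` is the intensity quantum per photon count: the variance is
  ``sigma * I``, so larger sigma means fewer effective photons and more
  noise, and sigma -> 0 recovers the noiseless image.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .optics import MeasurementSet

__all__ = ["add_gaussian_noise", "add_poisson_noise", "DARKFIELD_THRESHOLD"]

DARKFIELD_THRESHOLD = 0.2


def _affected(ms: MeasurementSet, threshold: float) -> list[int]:
    means = ms.intensities.mean(axis=(1, 2))
    return [int(i) for i in np.nonzero(means < threshold)[0]]


def add_gaussian_noise(
    ms: MeasurementSet,
    level: float,
    threshold: float = DARKFIELD_THRESHOLD,
    seed: int | None = 0,
) -> MeasurementSet:
    """Add proportional Gaussian noise to below-threshold (darkfield) images.

    ``level`` is the noise proportion: per affected image the noise standard
    deviation is ``level * mean(image)``.
    """
    if level < 0:
        raise ValueError("noise level must be nonnegative")
    rng = np.random.default_rng(seed)
    stack = ms.intensities.copy()
    affected = _affected(ms, threshold)
    if level > 0:
        for i in affected:
            sigma = level * stack[i].mean()
            stack[i] = np.clip(stack[i] + rng.normal(0.0, sigma, stack[i].shape), 0.0, None)
    record = {
        "model": "gaussian",
        "level": float(level),
        "threshold": float(threshold),
        "seed": seed,
        "affected_indices": affected,
    }
    return replace(ms, intensities=stack, noise_record=record)


def add_poisson_noise(
    ms: MeasurementSet,
    sigma: float,
    threshold: float = DARKFIELD_THRESHOLD,
    seed: int | None = 0,
) -> MeasurementSet:
    """Apply mean-preserving Poisson noise to below-threshold images.

    Each affected pixel becomes ``sigma * Poisson(I / sigma)``; smaller
    ``sigma`` means more photon counts per intensity unit and hence *less*
    noise (variance sigma * I).
    """
    if sigma <= 0:
        raise ValueError("Poisson noise parameter sigma must be positive")
    rng = np.random.default_rng(seed)
    stack = ms.intensities.copy()
    affected = _affected(ms, threshold)
    for i in affected:
        stack[i] = sigma * rng.poisson(stack[i] / sigma).astype(float)
    record = {
        "model": "poisson",
        "level": float(sigma),
        "threshold": float(threshold),
        "seed": seed,
        "affected_indices": affected,
    }
    return replace(ms, intensities=stack, noise_record=record)
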