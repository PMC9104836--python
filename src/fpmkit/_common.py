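"""Shared solver plumbing: NA ordering, error metric, result container."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ._fft import ift2
from .optics import MeasurementSet, Pupil, SpectrumWindow, sampling_window

__all__ = [
    "SolveResult",
    "DivergenceError",
    "na_ordering",
    "ordered_problem",
    "normalized_data_error",
]

DIVERGENCE_FACTOR = 1e6


class DivergenceError(RuntimeError):
    """Raised when a solver's normalized error metric blows up."""


@dataclass
class SolveResult:
    """Output bundle shared by every solver.

    Attributes
    ----------
    object : complex HR image u (spatial domain).
    pupil : recovered pupil transfer function.
    history : per-iteration scalars, keyed by name ("E_p", "E_d", ...).
    n_iter : iterations actually executed.
    stop_reason : "tolerance" | "max_iter".
    method : solver identifier.
    params : the parameter object the solver ran with.
    """

    object: np.ndarray
    pupil: Pupil
    history: dict[str, list[float]]
    n_iter: int
    stop_reason: str
    method: str
    params: Any = None
    extras: dict = field(default_factory=dict)

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.object)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.object)


def na_ordering(ms: MeasurementSet) -> list[int]:
    """Indices sorted by ascending illumination NA ("NA order").

    Updates sweep the Fourier plane from the center outward. Ties (LEDs at
    equal radius) break by (row, col) of the LED index.
    """
    return sorted(
        range(len(ms.illuminations)),
        key=lambda i: (ms.illuminations[i].illum_na, ms.illuminations[i].led_index),
    )


def ordered_problem(
    ms: MeasurementSet,
) -> tuple[np.ndarray, list[SpectrumWindow]]:
    """Measured amplitudes and sampling windows in NA-ascending order."""
    order = na_ordering(ms)
    amps = ms.amplitudes[order]
    windows = [sampling_window(ms.illuminations[i], ms.config) for i in order]
    return amps, windows


def normalized_data_error(
    s: np.ndarray,
    p: np.ndarray,
    amps: np.ndarray,
    windows: list[SpectrumWindow],
) -> float:
    """Normalized data misfit sum_j || |F^H(p . Q_j s)| - A_j ||^2 / sum_j ||A_j||^2."""
    num = 0.0
    for a, w in zip(amps, windows):
        num += float(np.sum((np.abs(ift2(p * w.crop(s))) - a) ** 2))
    den = float(np.sum(amps**2))
    return num / den if den > 0 else 0.0
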