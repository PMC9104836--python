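"""Reconstruction quality metrics: SSIM, evaluation alignment, profiles.

Blind phase retrieval recovers the object only up to a global phase, a
global intensity scale, and (potentially) an integer translation, so every
comparison against ground truth first removes those ambiguities
(:func:`align_for_eval`) and only then scores structural similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity
from skimage.registration import phase_cross_correlation

from .optics import GroundTruth

__all__ = [
    "SSIMConfig",
    "ssim",
    "global_ssim",
    "align_for_eval",
    "align_complex",
    "evaluate_reconstruction",
    "pupil_phase_correlation",
    "line_profile",
    "iterations_to_convergence",
    "iterations_to_error_level",
]


@dataclass(frozen=True)
class SSIMConfig:
    """SSIM stabilization constants and windowing choice.

    C1 = (k1 L)^2 and C2 = (k2 L)^2 with L the dynamic range; ``windowed``
    selects the conventional local-window mean of the index (the default),
    while False computes the single global statistic over the whole image.
    """

    k1: float = 0.01
    k2: float = 0.03
    data_range: float | None = None  # None: max(x.max(), y.max())
    windowed: bool = True

    def constants(self, data_range: float) -> tuple[float, float]:
        return (self.k1 * data_range) ** 2, (self.k2 * data_range) ** 2


def global_ssim(x: np.ndarray, y: np.ndarray, c1: float, c2: float) -> float:
    """Single-statistic SSIM over the whole image pair."""
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = ((x - mx) * (y - my)).mean()
    return float(
        (2 * mx * my + c1) * (2 * cov + c2) / ((mx**2 + my**2 + c1) * (vx + vy + c2))
    )


def ssim(x: np.ndarray, y: np.ndarray, cfg: SSIMConfig | None = None) -> float:
    """Structural similarity between two aligned nonnegative images.

    Symmetric in its arguments, 1.0 for structurally identical inputs;
    meaningful only after :func:`align_for_eval` has removed the phase-
    retrieval ambiguities.
    """
    cfg = cfg or SSIMConfig()
    if x.shape != y.shape:
        raise ValueError("SSIM requires equal image shapes")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("SSIM is defined for nonnegative images")
    dr = cfg.data_range if cfg.data_range is not None else float(max(x.max(), y.max()))
    if dr == 0:
        return 1.0  # two identically zero images
    if cfg.windowed:
        return float(structural_similarity(x, y, data_range=dr, K1=cfg.k1, K2=cfg.k2))
    c1, c2 = cfg.constants(dr)
    return global_ssim(x, y, c1, c2)


def align_complex(recon: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Remove translation, global phase, and global scale from a complex field.

    Integer translation is estimated by cross-correlating the moduli, the
    global phase by the angle of <recon, truth>, and the (real, positive)
    scale by least squares on the moduli.
    """
    if recon.shape != truth.shape:
        raise ValueError("shapes must match")
    shift, _, _ = phase_cross_correlation(
        np.abs(truth), np.abs(recon), upsample_factor=1
    )
    aligned = np.roll(recon, tuple(int(round(v)) for v in shift), axis=(0, 1))
    inner = np.vdot(aligned, truth)  # sum conj(aligned) * truth
    if np.abs(inner) > 0:
        aligned = aligned * np.exp(1j * np.angle(inner))
    denom = float(np.sum(np.abs(aligned) ** 2))
    if denom > 0:
        scale = float(np.sum(np.abs(truth) * np.abs(aligned)) / denom)
        aligned = aligned * scale
    return aligned


def align_for_eval(
    recon: np.ndarray, truth: np.ndarray, kind: str = "amplitude"
) -> tuple[np.ndarray, np.ndarray]:
    """Prepare one reconstructed image and its truth for SSIM scoring.

    kind="amplitude": integer-translation registration plus a global
    least-squares intensity scale on the reconstruction.
    kind="phase": registration plus removal of the global phase offset;
    both maps are then shifted by a common constant into the nonnegative
    range that SSIM requires.
    """
    if recon.shape != truth.shape:
        raise ValueError("shapes must match")
    shift, _, _ = phase_cross_correlation(truth, recon, upsample_factor=1)
    moved = np.roll(recon, tuple(int(round(v)) for v in shift), axis=(0, 1))
    if kind == "amplitude":
        denom = float(np.sum(moved**2))
        scale = float(np.sum(truth * moved) / denom) if denom > 0 else 1.0
        return scale * moved, truth
    if kind == "phase":
        offset = float(np.angle(np.mean(np.exp(1j * (truth - moved)))))
        moved = moved + offset
        lo = min(float(moved.min()), float(truth.min()))
        return moved - lo, truth - lo
    raise ValueError(f"unknown kind {kind!r}")


def evaluate_reconstruction(
    obj: np.ndarray, truth: GroundTruth, cfg: SSIMConfig | None = None
) -> dict[str, float]:
    """Amplitude and phase SSIM of a complex reconstruction vs ground truth."""
    aligned = align_complex(obj, truth.complex_object)
    amp_r, amp_t = np.abs(aligned), truth.amplitude
    # amplitude: scale already removed by align_complex; re-fit defensively
    amp_r, amp_t = align_for_eval(amp_r, amp_t, kind="amplitude")
    amp_r = np.clip(amp_r, 0.0, None)
    amplitude_ssim = ssim(amp_r, amp_t, cfg)
    ph_r, ph_t = align_for_eval(np.angle(aligned), truth.phase, kind="phase")
    phase_ssim = ssim(np.clip(ph_r, 0.0, None), np.clip(ph_t, 0.0, None), cfg)
    return {"amplitude_ssim": amplitude_ssim, "phase_ssim": phase_ssim}


def pupil_phase_correlation(
    recovered: np.ndarray, true: np.ndarray, mask: np.ndarray
) -> float:
    """Pearson correlation of pupil phase maps inside the aperture support."""
    pr = np.angle(recovered)[mask]
    pt = np.angle(true)[mask]
    pr = pr - pr.mean()
    pt = pt - pt.mean()
    denom = np.sqrt(np.sum(pr**2) * np.sum(pt**2))
    if denom == 0:
        return 1.0 if np.allclose(pr, pt) else 0.0
    return float(np.sum(pr * pt) / denom)


def line_profile(
    image: np.ndarray, row: int, background_cols: slice | None = None
) -> tuple[np.ndarray, float]:
    """Pixel values along a horizontal section, plus the background std.

    Used to compare residual noise fluctuation between reconstructions; the
    std is taken over ``background_cols`` (whole row by default).
    """
    if not 0 <= row < image.shape[0]:
        raise IndexError("row out of range")
    values = np.asarray(image[row], dtype=float).copy()
    seg = values[background_cols] if background_cols is not None else values
    return values, float(seg.std())


def iterations_to_error_level(e_history: list[float], level: float = 1e-3) -> int:
    """First iteration at which the normalized error metric falls below level.

    A common accuracy-based rule for comparing convergence speed across
    solvers whose own stopping criteria differ: the iteration count to
    reach the same practical data-misfit level. Returns
    ``len(e_history) - 1`` (the cap) if the level is never reached.
    """
    for k, v in enumerate(e_history):
        if v < level:
            return k
    return len(e_history) - 1


def iterations_to_convergence(e_history: list[float], eps: float = 1e-3) -> int:
    """First iteration whose relative error change falls below eps.

    A common post-hoc stopping rule used to compare convergence speed
    across solvers on the same footing: the first k >= 1 with
    ``|E^k - E^{k-1}| / E^k < eps`` (history indexed from the pre-iteration
    value at position 0). Returns ``len(e_history) - 1`` if never met.
    """
    e = [v for v in e_history]
    for k in range(1, len(e)):
        if e[k] != 0 and abs(e[k] - e[k - 1]) / abs(e[k]) < eps:
            return k
    return len(e) - 1
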