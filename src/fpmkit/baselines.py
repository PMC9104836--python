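"""Sequential comparison solvers: adaptive-step Gauss-Newton and momentum PIE.

Both solvers sweep the illuminations one at a time in NA-ascending order,
enforcing the measured modulus in the spatial domain and writing a
second-order (Gauss-Newton) or rPIE-style correction back into the object
spectrum window and the pupil. They share the forward model, data
container, NA ordering and normalized error metric with the ADMM solver so
that the three methods can be compared fairly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._common import (
    DIVERGENCE_FACTOR,
    DivergenceError,
    SolveResult,
    normalized_data_error,
    ordered_problem,
)
from ._fft import ft2, ift2
from .optics import MeasurementSet, Pupil

__all__ = [
    "GNParams",
    "MPIEParams",
    "adapt_step",
    "gauss_newton_run",
    "mpie_run",
    "upsampled_center_spectrum",
]


@dataclass
class GNParams:
    """Adaptive-step sequential Gauss-Newton parameters.

    alpha0/beta0 are the initial object/pupil step sizes; each is halved
    whenever the normalized error metric's relative increase exceeds
    ``eps_step`` after a sweep, which lets the solver take large early
    steps and then settle. ``reg_object``/``reg_pupil`` are the relative
    Tikhonov floors of the quotient updates (fractions of the squared
    modulus maxima).
    """

    alpha0: float = 1.0
    beta0: float = 1.0
    eps_step: float = 0.01
    max_iter: int = 100
    reg_object: float = 1e-3
    reg_pupil: float = 1e-3
    order: str = "na_ascending"

    def __post_init__(self) -> None:
        if self.alpha0 <= 0 or self.beta0 <= 0:
            raise ValueError("initial step sizes must be positive")


@dataclass
class MPIEParams:
    """Momentum-accelerated PIE parameters (rPIE-style denominators).

    alpha/beta control how strongly weak-modulus pixels are regularized in
    the object/pupil quotient updates (smaller alpha = more aggressive
    object steps). gamma is the friction applied to the velocity step;
    eta_obj/eta_pupil are the momentum decay weights; pupil updates are
    suppressed until the global illumination counter reaches ``t_pupil``
    (delayed probe release, counted across the first sweep).
    """

    alpha: float = 0.1
    beta: float = 0.8
    gamma: float = 1.0
    eta_obj: float = 0.9
    eta_pupil: float = 0.3
    t_pupil: int = 15
    max_iter: int = 100
    order: str = "na_ascending"


def upsampled_center_spectrum(ms: MeasurementSet) -> np.ndarray:
    """HR spectrum of the center-LED amplitude, embedded in the central window.

    The customary warm start: the square root of the on-axis brightfield
    image, upsampled by zero-padding its spectrum into the HR grid
    (nearest-window upsampling in Fourier space). The n/m factor keeps the
    spatial brightness unchanged under the unitary transforms.
    """
    cfg = ms.config
    center = min(range(len(ms.illuminations)), key=lambda i: ms.illuminations[i].illum_na)
    amp = np.sqrt(ms.intensities[center])
    s_lr = ft2(amp.astype(complex))
    n, m = cfg.hr_side, cfg.lr_side
    s = np.zeros((n, n), dtype=complex)
    r0 = n // 2 - m // 2
    s[r0 : r0 + m, r0 : r0 + m] = s_lr * (n / m)
    return s


def adapt_step(e_history: list[float], step_prev: float, eps: float) -> float:
    """Self-adaptive step rule: halve on a relative error increase above eps.

        step_k = step_{k-1}/2   if (E^k - E^{k-1}) / E^k > eps
                 step_{k-1}     otherwise

    Requires at least two recorded error values.
    """
    if len(e_history) < 2:
        raise ValueError("adapt_step needs at least two error values")
    ek, ekm1 = e_history[-1], e_history[-2]
    rel = (ek - ekm1) / ek if ek != 0 else 0.0
    return step_prev / 2.0 if rel > eps else step_prev


def gauss_newton_run(
    ms: MeasurementSet, pupil0: Pupil, params: GNParams | None = None
) -> SolveResult:
    """Sequential Gauss-Newton blind reconstruction with self-adaptive steps.

    Per illumination: form the exit spectrum ``psi = p . Q_j s``, replace
    the modulus of its spatial field by the measurement, and distribute the
    spectral correction ``dpsi`` through pupil-weighted quotient updates

        s_w += alpha_k |p| conj(p) dpsi / ( |p|_max (|p|^2 + d1) )
        p   += beta_k |S_w| conj(S_w) dpsi / ( |S_w|_max (|S_w|^2 + d2) )

    After each full sweep the normalized error metric is recorded and both
    step sizes pass through :func:`adapt_step`.
    """
    params = params or GNParams()
    amps, windows = ordered_problem(ms)
    mask = pupil0.aperture_mask
    s = upsampled_center_spectrum(ms)
    p = pupil0.values.astype(complex)
    alpha_k, beta_k = params.alpha0, params.beta0
    e_hist = [normalized_data_error(s, p, amps, windows)]
    steps = [(alpha_k, beta_k)]
    n_done = 0
    for k in range(1, params.max_iter + 1):
        for j, w in enumerate(windows):
            sw = w.crop(s)
            psi = p * sw
            e_field = ift2(psi)
            mag = np.abs(e_field)
            phase = np.where(mag > 0, e_field / np.where(mag > 0, mag, 1.0), 1.0)
            dpsi = ft2(amps[j] * phase) - psi
            pmax = np.abs(p).max()
            p2 = np.abs(p) ** 2
            s_step = (
                np.abs(p) * np.conj(p) * dpsi
                / (pmax * (p2 + params.reg_object * pmax**2))
            )
            swmax = np.abs(sw).max()
            sw2 = np.abs(sw) ** 2
            p_step = (
                np.abs(sw) * np.conj(sw) * dpsi
                / (swmax * (sw2 + params.reg_pupil * swmax**2))
            )
            w.add_into(s, alpha_k * s_step)
            p = np.where(mask, p + beta_k * p_step, 0.0)
        n_done = k
        e_hist.append(normalized_data_error(s, p, amps, windows))
        if e_hist[-1] > DIVERGENCE_FACTOR * max(e_hist[0], 1e-300):
            raise DivergenceError(f"Gauss-Newton diverged at iteration {k}")
        alpha_k = adapt_step(e_hist, alpha_k, params.eps_step)
        beta_k = adapt_step(e_hist, beta_k, params.eps_step)
        steps.append((alpha_k, beta_k))
    pupil = Pupil(values=p, aperture_mask=mask.copy(), aberration=())
    history = {
        "E_p": e_hist,
        "alpha_step": [a for a, _ in steps],
        "beta_step": [b for _, b in steps],
    }
    return SolveResult(
        object=ift2(s),
        pupil=pupil,
        history=history,
        n_iter=n_done,
        stop_reason="max_iter",
        method="gauss_newton",
        params=params,
    )


def mpie_run(
    ms: MeasurementSet, pupil0: Pupil, params: MPIEParams | None = None
) -> SolveResult:
    """Momentum-accelerated PIE blind reconstruction.

    Sequential rPIE quotient updates

        s_w += conj(p) dpsi / ( (1-alpha) |p|^2 + alpha |p|^2_max )
        p   += conj(S_w) dpsi / ( (1-beta) |S_w|^2 + beta |S_w|^2_max )

    followed, after each full sweep, by a safeguarded velocity step with
    decay eta and friction gamma:

        v <- eta v + (1 - eta) (x - x_sweep_start);   x <- x + gamma v

    applied independently to the object spectrum (eta_obj) and the pupil
    (eta_pupil). The velocity step is accepted only if it does not increase
    the normalized error metric; otherwise it is reverted and both
    velocities reset (adaptive restart), which keeps the extrapolation from
    amplifying the slow object/pupil ambiguity drift. eta = 0 disables
    momentum entirely (plain sequential rPIE). Pupil updates start only at
    the ``t_pupil``-th illumination position.
    """
    params = params or MPIEParams()
    amps, windows = ordered_problem(ms)
    mask = pupil0.aperture_mask
    s = upsampled_center_spectrum(ms)
    p = pupil0.values.astype(complex)
    v_s = np.zeros_like(s)
    v_p = np.zeros_like(p)
    e_hist = [normalized_data_error(s, p, amps, windows)]
    counter = 0  # global illumination counter for the delayed pupil release
    n_done = 0
    for k in range(1, params.max_iter + 1):
        s_sweep_start = s.copy()
        p_sweep_start = p.copy()
        for j, w in enumerate(windows):
            counter += 1
            sw = w.crop(s)
            psi = p * sw
            e_field = ift2(psi)
            mag = np.abs(e_field)
            phase = np.where(mag > 0, e_field / np.where(mag > 0, mag, 1.0), 1.0)
            dpsi = ft2(amps[j] * phase) - psi
            p2 = np.abs(p) ** 2
            s_step = np.conj(p) * dpsi / ((1 - params.alpha) * p2 + params.alpha * p2.max())
            w.add_into(s, s_step)
            if counter >= params.t_pupil:
                sw2 = np.abs(sw) ** 2
                p_step = (
                    np.conj(sw) * dpsi
                    / ((1 - params.beta) * sw2 + params.beta * sw2.max())
                )
                p = np.where(mask, p + p_step, 0.0)
        n_done = k
        momentum_on = params.eta_obj > 0 or params.eta_pupil > 0
        e_sweep = normalized_data_error(s, p, amps, windows)
        if momentum_on:
            s_try, p_try = s, p
            if params.eta_obj > 0:
                v_s = params.eta_obj * v_s + (1 - params.eta_obj) * (s - s_sweep_start)
                s_try = s + params.gamma * v_s
            if params.eta_pupil > 0 and counter >= params.t_pupil:
                v_p = params.eta_pupil * v_p + (1 - params.eta_pupil) * (p - p_sweep_start)
                p_try = np.where(mask, p + params.gamma * v_p, 0.0)
            e_try = normalized_data_error(s_try, p_try, amps, windows)
            if e_try <= e_sweep:
                s, p = s_try, p_try
                e_hist.append(e_try)
            else:  # reject the extrapolation and restart the velocities
                v_s = np.zeros_like(v_s)
                v_p = np.zeros_like(v_p)
                e_hist.append(e_sweep)
        else:
            e_hist.append(e_sweep)
        if e_hist[-1] > DIVERGENCE_FACTOR * max(e_hist[0], 1e-300):
            raise DivergenceError(f"mPIE diverged at iteration {k}")
    pupil = Pupil(values=p, aperture_mask=mask.copy(), aberration=())
    return SolveResult(
        object=ift2(s),
        pupil=pupil,
        history={"E_p": e_hist},
        n_iter=n_done,
        stop_reason="max_iter",
        method="mpie",
        params=params,
    )
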