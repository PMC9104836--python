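"""Blind FPM phase retrieval by the alternating direction method of multipliers.

The reconstruction is posed as a constrained splitting: per-illumination
auxiliary spectra ``q_j`` are tied to the physical model through
``q_j = p . Q_j s`` (pupil times windowed object spectrum), while the data
enter only through the measured-modulus fidelity ``|| |F^H q_j| - A_j ||^2``
with ``A_j = sqrt(I_j)``. A Tikhonov anchor ``(gamma/2) ||s - delta||^2``
toward the spectrum of a flat light field stabilizes the weak-phase
object/pupil separation. The scaled-form ADMM sweep is:

    q_j <- relaxed projection of (p . Q_j s - w_j) onto the modulus set
    s   <- [ gamma d/alpha + sum_j Q_j^T( conj(p) (q_j + w_j) ) ]
           / [ gamma/alpha + sum_j Q_j^T |p|^2 ]          (elementwise)
    p   <- [ sum_j conj(Q_j s) (q_j + w_j) ] / [ sum_j |Q_j s|^2 + beta ]
    w_j <- w_j + eta (q_j - p . Q_j s)

with scaled multipliers ``w_j = lambda_j / alpha``. Because each update is a
closed form over the whole batch of illuminations, the method is a global
solver with a high degree of structural parallelism. Convergence is
monitored through normalized primal (data-misfit) and dual (iterate-change)
error metrics; there is no theoretical convergence guarantee for this
non-convex problem, but the iteration is empirically stable and markedly
noise-robust.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._common import (
    DIVERGENCE_FACTOR,
    DivergenceError,
    SolveResult,
    ordered_problem,
)
from ._fft import ft2, ift2
from .optics import MeasurementSet, Pupil, SpectrumWindow

__all__ = [
    "ADMMParams",
    "ADMMState",
    "initialize",
    "update_q",
    "update_s",
    "update_p",
    "update_omega",
    "residuals",
    "splitting_residual",
    "error_metrics",
    "run",
]


@dataclass
class ADMMParams:
    """Tunables of the ADMM solver.

    alpha : penalty coupling the auxiliary spectra to the physical model
        (suggested range 0.5-1).
    beta : pupil-update regularizer; larger values slow the pupil down.
        Quoted on the unnormalized-DFT scale conventional in the FPM
        literature; see ``effective_beta``.
    gamma : Tikhonov weight anchoring the object spectrum to a flat field
        (suggested range 0.1-0.5).
    eta : multiplier step size.
    eps_tol : stopping tolerance on the relative change of both normalized
        error metrics.
    max_iter : iteration cap.
    init_mode : "ones" (flat-field start, the recommended choice here) or
        "upsampled_center" (Fourier-embedded center-LED image).
    schedule : "batch" updates all q_j, then s, p, and all w_j once per
        iteration; "sequential" nests the s/p updates inside the per-
        illumination loop (slower, provided for comparison).
    """

    alpha: float = 0.5
    beta: float = 1000.0
    gamma: float = 0.3
    eta: float = 1.0
    eps_tol: float = 1e-3
    max_iter: int = 100
    init_mode: str = "ones"
    order: str = "na_ascending"
    schedule: str = "batch"

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0 or self.eta <= 0:
            raise ValueError("alpha, beta and eta must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        if self.init_mode not in ("ones", "upsampled_center"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")
        if self.schedule not in ("batch", "sequential"):
            raise ValueError(f"unknown schedule {self.schedule!r}")

    def effective_beta(self, lr_side: int) -> float:
        """beta translated to this package's unitary-transform convention.

        The customary beta ~ 1000 is calibrated against spectra produced by
        unnormalized DFTs, which are ``lr_side`` times larger than unitary
        ones; the denominator term |Q_j s|^2 therefore carries a factor
        ``lr_side**2`` between the two conventions.
        """
        return self.beta / lr_side**2


# Backwards-compatible alias: the solver parameter block.
SolverParams = ADMMParams


@dataclass
class ADMMState:
    """All iterates of the ADMM solver, in NA-ascending illumination order."""

    s: np.ndarray  # complex HR spectrum (centered)
    p: np.ndarray  # complex pupil values on the LR grid
    q: np.ndarray  # (N, m, m) auxiliary spectra
    omega: np.ndarray  # (N, m, m) scaled multipliers
    delta: np.ndarray  # spectrum of the unit flat field (fixed)
    amplitudes: np.ndarray  # (N, m, m) measured moduli A_j
    windows: list[SpectrumWindow]
    aperture_mask: np.ndarray
    ep_history: list[float] = field(default_factory=list)
    ed_history: list[float] = field(default_factory=list)
    k: int = 0


def initialize(
    ms: MeasurementSet, pupil0: Pupil, params: ADMMParams | None = None
) -> ADMMState:
    """Build the starting state: s0, p0, q_j0 = p0 . Q_j s0, w_j0 = 0.

    The flat-field ("ones") start works best for this solver; the
    center-LED upsampling start used by the sequential baselines is also
    available.
    """
    params = params or ADMMParams()
    cfg = ms.config
    if pupil0.values.shape != (cfg.lr_side, cfg.lr_side):
        raise ValueError("pupil grid does not match the measurement grid")
    amps, windows = ordered_problem(ms)
    # Flat light field matched to the measured brightness: a uniform object
    # of amplitude a0 produces a brightfield image of mean intensity
    # (a0 * hr/lr)^2 under unitary transforms, so anchor the Tikhonov term
    # (and the flat-field start) at a0 = (lr/hr) * sqrt(max brightfield mean).
    bf_means = [
        ms.intensities[i].mean()
        for i, il in enumerate(ms.illuminations)
        if il.regime == "brightfield"
    ]
    peak_mean = max(bf_means) if bf_means else float(ms.intensities.mean(axis=(1, 2)).max())
    a0 = (cfg.lr_side / cfg.hr_side) * float(np.sqrt(peak_mean))
    delta = ft2(np.full((cfg.hr_side, cfg.hr_side), a0, dtype=complex))
    if params.init_mode == "ones":
        s = delta.copy()
    else:
        from .baselines import upsampled_center_spectrum

        s = upsampled_center_spectrum(ms)
    p = pupil0.values.astype(complex)
    q = np.stack([p * w.crop(s) for w in windows])
    omega = np.zeros_like(q)
    state = ADMMState(
        s=s,
        p=p,
        q=q,
        omega=omega,
        delta=delta,
        amplitudes=amps,
        windows=windows,
        aperture_mask=pupil0.aperture_mask.copy(),
    )
    rp, _ = residuals(state.q, None, amps)
    ep, _ = error_metrics(rp, None, amps, omega, params.alpha, params.eta)
    state.ep_history.append(ep)
    state.ed_history.append(math.nan)
    return state


def update_q(
    s: np.ndarray,
    p: np.ndarray,
    omega_j: np.ndarray,
    amp_j: np.ndarray,
    window: SpectrumWindow,
    alpha: float,
) -> np.ndarray:
    """Closed-form q-subproblem: relaxed projection onto the modulus set.

    With ``qt = p . Q_j s - w_j`` and spatial field ``e = F^H qt``,

        q_j <- qt + (F[ A_j . e/|e| ] - qt) / (1 + alpha)

    i.e. alpha = 0 replaces the modulus of e by the measurement exactly,
    while alpha -> inf leaves qt untouched. Zero-magnitude pixels take
    phase 0 by convention.
    """
    qt = p * window.crop(s) - omega_j
    e = ift2(qt)
    mag = np.abs(e)
    phase_factor = np.where(mag > 0, e / np.where(mag > 0, mag, 1.0), 1.0)
    projected = ft2(amp_j * phase_factor)
    return qt + (projected - qt) / (1.0 + alpha)


def update_s(
    q: np.ndarray,
    omega: np.ndarray,
    p: np.ndarray,
    windows: list[SpectrumWindow],
    delta: np.ndarray,
    gamma: float,
    alpha: float,
    s_prev: np.ndarray,
) -> np.ndarray:
    """Closed-form s-subproblem (diagonal normal equations).

        s = [ gamma d/alpha + sum_j Q_j^T( conj(p) (q_j + w_j) ) ]
            / [ gamma/alpha + sum_j Q_j^T |p|^2 ]

    HR bins never covered by a window keep their previous value when
    gamma = 0 (the denominator vanishes there); with gamma > 0 they relax
    toward the flat-field spectrum delta.
    """
    n = s_prev.shape[0]
    num = np.zeros((n, n), dtype=complex)
    den = np.zeros((n, n))
    pc = np.conj(p)
    p2 = np.abs(p) ** 2
    for j, w in enumerate(windows):
        w.add_into(num, pc * (q[j] + omega[j]))
        w.add_into(den, p2)
    if gamma > 0:
        num += (gamma / alpha) * delta
        den += gamma / alpha
    out = np.where(den > 0, num / np.where(den > 0, den, 1.0), s_prev)
    return out


def update_p(
    q: np.ndarray,
    omega: np.ndarray,
    s: np.ndarray,
    windows: list[SpectrumWindow],
    beta: float,
    aperture_mask: np.ndarray,
) -> np.ndarray:
    """Closed-form p-subproblem (per-pixel scalar least squares).

        p = [ sum_j conj(Q_j s) (q_j + w_j) ] / [ sum_j |Q_j s|^2 + beta ]

    then re-masked by the aperture support (the physical pupil cannot pass
    light outside its cutoff). ``beta`` is the *effective* (unitary-scale)
    regularizer.
    """
    num = np.zeros_like(q[0])
    den = np.full(q[0].shape, float(beta))
    for j, w in enumerate(windows):
        sw = w.crop(s)
        num += np.conj(sw) * (q[j] + omega[j])
        den += np.abs(sw) ** 2
    return np.where(aperture_mask, num / den, 0.0)


def update_omega(
    omega_j: np.ndarray,
    q_j: np.ndarray,
    s: np.ndarray,
    p: np.ndarray,
    window: SpectrumWindow,
    eta: float,
) -> np.ndarray:
    """Scaled-multiplier ascent: w_j <- w_j + eta (q_j - p . Q_j s)."""
    return omega_j + eta * (q_j - p * window.crop(s))


def residuals(
    q: np.ndarray, q_prev: np.ndarray | None, amps: np.ndarray
) -> tuple[float, float | None]:
    """Primal and dual residuals.

    The primal residual is evaluated in measurement space,
    ``R_p = sum_j || |F^H q_j| - A_j ||^2``, consistent with the
    data-misfit the solver actually drives down; the dual residual is the
    iterate change ``R_d = sum_j || q_j^k - q_j^{k-1} ||^2`` and is
    unavailable before the first completed iteration (returned as None).
    """
    rp = 0.0
    for j in range(q.shape[0]):
        rp += float(np.sum((np.abs(ift2(q[j])) - amps[j]) ** 2))
    rd = float(np.sum(np.abs(q - q_prev) ** 2)) if q_prev is not None else None
    return rp, rd


def splitting_residual(
    q: np.ndarray, s: np.ndarray, p: np.ndarray, windows: list[SpectrumWindow]
) -> float:
    """Constraint violation sum_j || q_j - p . Q_j s ||^2 (splitting form)."""
    out = 0.0
    for j, w in enumerate(windows):
        out += float(np.sum(np.abs(q[j] - p * w.crop(s)) ** 2))
    return out


def error_metrics(
    rp: float,
    rd: float | None,
    amps: np.ndarray,
    omega: np.ndarray,
    alpha: float,
    eta: float,
) -> tuple[float, float | None]:
    """Normalized error metrics.

    ``E_p = R_p / sum_j ||A_j||^2`` and
    ``E_d = (alpha/eta) R_d / sum_j ||lambda_j||^2`` with
    ``lambda_j = alpha w_j``. E_d is None while the multipliers are all
    zero (nothing to normalize by) or before R_d exists.
    """
    a2 = float(np.sum(amps**2))
    ep = rp / a2 if a2 > 0 else 0.0
    if rd is None:
        return ep, None
    lam2 = float(alpha**2 * np.sum(np.abs(omega) ** 2))
    if lam2 == 0.0:
        return ep, None
    return ep, (alpha / eta) * rd / lam2


def _relative_change(curr: float, prev: float) -> float:
    if curr == 0.0:
        return 0.0
    return abs(curr - prev) / abs(curr)


def run(
    ms: MeasurementSet, pupil0: Pupil, params: ADMMParams | None = None
) -> SolveResult:
    """Run the full ADMM iteration and return the reconstruction.

    Per iteration (batch schedule): all q_j in NA-ascending order, then s,
    then p, then all multipliers; both normalized error metrics are
    appended to the history. The loop stops early when the relative change
    of E_p *and* (once available) E_d both fall below ``eps_tol``, and
    aborts with :class:`DivergenceError` if E_p exceeds 1e6 times its
    initial value. Returns the spatial object ``u = F^H s``, the recovered
    pupil, and the error histories.
    """
    params = params or ADMMParams()
    state = initialize(ms, pupil0, params)
    beta_eff = params.effective_beta(ms.config.lr_side)
    stop_reason = "max_iter"
    n_done = 0
    for _ in range(params.max_iter):
        state.k += 1
        n_done = state.k
        q_prev = state.q.copy()
        if params.schedule == "batch":
            for j, w in enumerate(state.windows):
                state.q[j] = update_q(
                    state.s, state.p, state.omega[j], state.amplitudes[j], w, params.alpha
                )
            state.s = update_s(
                state.q, state.omega, state.p, state.windows, state.delta,
                params.gamma, params.alpha, state.s,
            )
            state.p = update_p(
                state.q, state.omega, state.s, state.windows, beta_eff,
                state.aperture_mask,
            )
            for j, w in enumerate(state.windows):
                state.omega[j] = update_omega(
                    state.omega[j], state.q[j], state.s, state.p, w, params.eta
                )
        else:  # sequential: nest the s/p/w updates inside the per-j loop
            for j, w in enumerate(state.windows):
                state.q[j] = update_q(
                    state.s, state.p, state.omega[j], state.amplitudes[j], w, params.alpha
                )
                state.s = update_s(
                    state.q, state.omega, state.p, state.windows, state.delta,
                    params.gamma, params.alpha, state.s,
                )
                state.p = update_p(
                    state.q, state.omega, state.s, state.windows, beta_eff,
                    state.aperture_mask,
                )
                state.omega[j] = update_omega(
                    state.omega[j], state.q[j], state.s, state.p, w, params.eta
                )
        rp, rd = residuals(state.q, q_prev, state.amplitudes)
        ep, ed = error_metrics(
            rp, rd, state.amplitudes, state.omega, params.alpha, params.eta
        )
        state.ep_history.append(ep)
        state.ed_history.append(ed if ed is not None else math.nan)
        if ep > DIVERGENCE_FACTOR * max(state.ep_history[0], 1e-300):
            raise DivergenceError(
                f"ADMM diverged at iteration {state.k}: "
                f"E_p={ep:.3e} vs initial {state.ep_history[0]:.3e}"
            )
        # stopping: both relative-change criteria must hold; the dual-side
        # criterion participates only once two finite E_d values exist.
        ep_ok = _relative_change(ep, state.ep_history[-2]) < params.eps_tol
        ed_prev = state.ed_history[-2]
        if ed is not None and not math.isnan(ed_prev):
            ed_ok = _relative_change(ed, ed_prev) < params.eps_tol
        else:
            ed_ok = True
        if ep_ok and ed_ok:
            stop_reason = "tolerance"
            break
    recovered_pupil = Pupil(
        values=state.p, aperture_mask=state.aperture_mask, aberration=()
    )
    history = {
        "E_p": list(state.ep_history),
        "E_d": list(state.ed_history),
    }
    return SolveResult(
        object=ift2(state.s),
        pupil=recovered_pupil,
        history=history,
        n_iter=n_done,
        stop_reason=stop_reason,
        method="admm",
        params=params,
        extras={"state": state},
    )
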