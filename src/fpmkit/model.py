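"""High-level modelling interface: FPMModel -> fit() -> FPMResults.

The model object holds a measurement stack (simulated or loaded) together
with the optical configuration and an initial pupil; ``fit`` dispatches to
one of the registered solvers and wraps the output in a results object
carrying the estimates, convergence diagnostics, and evaluation helpers.
"""

from __future__ import annotations

from typing import Any

import numpy as np
import pandas as pd

from ._common import SolveResult
from .admm import ADMMParams
from .admm import run as admm_run
from .baselines import GNParams, MPIEParams, gauss_newton_run, mpie_run
from .metrics import (
    SSIMConfig,
    evaluate_reconstruction,
    iterations_to_convergence,
    pupil_phase_correlation,
)
from .optics import (
    GroundTruth,
    MeasurementSet,
    OpticalConfig,
    Pupil,
    make_pupil,
    simulate_dataset,
)

__all__ = ["FPMModel", "FPMResults", "SOLVERS"]

SOLVERS = {
    "admm": (admm_run, ADMMParams),
    "gauss_newton": (gauss_newton_run, GNParams),
    "mpie": (mpie_run, MPIEParams),
}


class FPMModel:
    """A blind phase-retrieval problem: measured stack + geometry + pupil guess.

    Parameters
    ----------
    measurements : the per-LED LR intensity stack with its geometry.
    pupil0 : initial pupil guess; defaults to the ideal (aberration-free)
        circular aperture of the configured objective.

    Examples
    --------
    >>> model = FPMModel.from_simulation(seed=7)
    >>> res = model.fit(method="admm")
    >>> print(res.summary())                       # doctest: +SKIP
    """

    def __init__(self, measurements: MeasurementSet, pupil0: Pupil | None = None):
        self.measurements = measurements
        self.config: OpticalConfig = measurements.config
        self.pupil0 = pupil0 if pupil0 is not None else make_pupil(self.config)
        self.truth: GroundTruth | None = None
        self.true_pupil: Pupil | None = None

    @classmethod
    def from_dataset(cls, path) -> "FPMModel":
        """Load a saved dataset container (see :mod:`fpmkit.io`)."""
        from .io import read_dataset

        ms, truth, true_pupil = read_dataset(path)
        model = cls(ms)
        model.truth = truth
        model.true_pupil = true_pupil
        return model

    @classmethod
    def from_simulation(
        cls,
        config: OpticalConfig | None = None,
        truth: GroundTruth | None = None,
        pupil: Pupil | None = None,
        noise: tuple[str, float] | None = None,
        seed: int = 0,
        truth_seed: int | None = None,
    ) -> "FPMModel":
        """Simulate a dataset and wrap it in a model.

        ``pupil`` is the *true* (possibly aberrated) pupil used by the
        simulator; the model's initial guess stays the ideal aperture, so
        aberration recovery is genuinely blind. ``truth`` defaults to a
        procedural object seeded by ``truth_seed`` (or ``seed``).
        """
        from .synthetic import synthetic_ground_truth

        config = config or OpticalConfig()
        if truth is None:
            truth = synthetic_ground_truth(
                config.hr_side, seed=seed if truth_seed is None else truth_seed
            )
        pupil = pupil if pupil is not None else make_pupil(config)
        ms = simulate_dataset(config, truth, pupil, noise_spec=noise, seed=seed)
        model = cls(ms)
        model.truth = truth
        model.true_pupil = pupil
        return model

    def fit(self, method: str = "admm", params: Any = None, **kwargs) -> "FPMResults":
        """Reconstruct object and pupil with the chosen solver.

        ``method`` is one of "admm", "gauss_newton", "mpie"; keyword
        arguments build the solver's parameter object when ``params`` is
        not given (e.g. ``fit(method="admm", max_iter=50)``).
        """
        if method not in SOLVERS:
            raise ValueError(f"unknown solver {method!r}; choose from {sorted(SOLVERS)}")
        runner, param_cls = SOLVERS[method]
        if params is None:
            params = param_cls(**kwargs)
        elif kwargs:
            raise TypeError("pass either params or keyword overrides, not both")
        result = runner(self.measurements, self.pupil0, params)
        return FPMResults(self, result)


class FPMResults:
    """Reconstruction estimates, diagnostics, and evaluation helpers."""

    def __init__(self, model: FPMModel, result: SolveResult):
        self.model = model
        self._result = result

    # -- estimates ---------------------------------------------------------
    @property
    def object(self) -> np.ndarray:
        """Recovered complex HR object u."""
        return self._result.object

    @property
    def amplitude(self) -> np.ndarray:
        return self._result.amplitude

    @property
    def phase(self) -> np.ndarray:
        return self._result.phase

    @property
    def pupil(self) -> Pupil:
        return self._result.pupil

    # -- diagnostics -------------------------------------------------------
    @property
    def method(self) -> str:
        return self._result.method

    @property
    def params(self) -> Any:
        return self._result.params

    @property
    def n_iter(self) -> int:
        return self._result.n_iter

    @property
    def stop_reason(self) -> str:
        return self._result.stop_reason

    @property
    def history(self) -> pd.DataFrame:
        """Per-iteration error metrics (iteration 0 = initialization)."""
        h = self._result.history
        n = len(h["E_p"])
        data = {"iteration": np.arange(n)}
        for key, vals in h.items():
            data[key] = vals
        return pd.DataFrame(data)

    @property
    def final_error(self) -> float:
        return float(self._result.history["E_p"][-1])

    def convergence_iteration(self, eps: float = 1e-3) -> int:
        """Iterations until the normalized error metric stabilizes (common rule)."""
        return iterations_to_convergence(self._result.history["E_p"], eps)

    # -- evaluation --------------------------------------------------------
    def evaluate(
        self, truth: GroundTruth | None = None, cfg: SSIMConfig | None = None
    ) -> dict[str, float]:
        """Amplitude/phase SSIM vs ground truth (and pupil phase correlation).

        Uses the model's stored simulation truth when ``truth`` is omitted.
        """
        truth = truth if truth is not None else self.model.truth
        if truth is None:
            raise ValueError("no ground truth available for evaluation")
        out = evaluate_reconstruction(self.object, truth, cfg)
        if self.model.true_pupil is not None:
            out["pupil_phase_correlation"] = pupil_phase_correlation(
                self.pupil.values,
                self.model.true_pupil.values,
                self.model.true_pupil.aperture_mask,
            )
        return out

    def save(self, path) -> None:
        """Write the reconstruction bundle (TIFF images + history CSV + manifest)."""
        from .io import write_reconstruction

        write_reconstruction(path, self._result, self.model.config)

    def plot_history(self, ax=None):
        """Log-scale plot of the normalized error metric histories."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.history
        ax.semilogy(df["iteration"], df["E_p"], label="E_p")
        if "E_d" in df and np.isfinite(df["E_d"]).any():
            ax.semilogy(df["iteration"], df["E_d"], label="E_d")
        ax.set_xlabel("iteration")
        ax.set_ylabel("normalized error")
        ax.set_title(f"{self.method} convergence")
        ax.legend()
        return ax

    def summary(self) -> str:
        """Plain-text summary of the fit."""
        cfg = self.model.config
        lines = [
            "FPM reconstruction summary",
            "=" * 60,
            f"method:          {self.method}",
            f"iterations:      {self.n_iter} (stop: {self.stop_reason})",
            f"final E_p:       {self.final_error:.4e}",
            f"LED array:       {cfg.led_rows} x {cfg.led_cols} "
            f"({len(self.model.measurements.illuminations)} images)",
            f"grids:           {cfg.lr_side}^2 measured -> {cfg.hr_side}^2 recovered",
            f"objective:       {cfg.magnification:g}x / NA {cfg.objective_na:g}, "
            f"wavelength {cfg.wavelength_um*1000:.0f} nm",
            f"noise model:     {self.model.measurements.noise_record.get('model', 'none')}",
            f"params:          {self.params}",
        ]
        if self.model.truth is not None:
            ev = self.evaluate()
            lines.append(
                f"amplitude SSIM:  {ev['amplitude_ssim']:.4f}   "
                f"phase SSIM: {ev['phase_ssim']:.4f}"
            )
            if "pupil_phase_correlation" in ev:
                lines.append(f"pupil phase corr:{ev['pupil_phase_correlation']:.4f}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<FPMResults method={self.method} n_iter={self.n_iter} "
            f"E_p={self.final_error:.3e}>"
        )
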