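"""Least-squares recovery of ceRNA kinetic parameters from trajectory data.

``CircuitTrajectoryFit`` is a small statsmodels-flavoured model object: it is
built from noisy observations of a circuit time course, its :meth:`fit`
estimates the free ceRNA parameters (by default the free-mRNA degradation
rate ``g_f`` and the transcription rate ``k_f``) by nonlinear least squares
on log abundances, and it returns a results object carrying the estimates,
their standard errors (Gauss-Newton approximation) and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from ..io_formats import ValidationError
from .model import EmtCircuit
from .params import IDX, CircuitParams, Protocol

_LOG_FLOOR = 1e-9


class CircuitTrajectoryFit:
    """Fit free circuit parameters to observed species trajectories.

    Parameters
    ----------
    observations : DataFrame
        Columns ``time_h`` plus one column per observed species (a subset of
        the circuit species); strictly positive noisy abundances.
    params : CircuitParams
        Circuit parameterization supplying every non-free parameter.
    protocol : Protocol
        Signal schedule the observations were generated under.
    free : sequence of str
        Names of scalar CircuitParams fields to estimate
        (default ``("g_f", "k_f")``).
    init : ndarray, optional
        Initial state of the simulated trajectory (default: all zero).
    """

    def __init__(
        self,
        observations: pd.DataFrame,
        params: CircuitParams,
        protocol: Protocol,
        free=("g_f", "k_f"),
        init=None,
    ):
        if "time_h" not in observations.columns:
            raise ValidationError("observations need a time_h column")
        self.species = [c for c in observations.columns if c != "time_h"]
        unknown = [c for c in self.species if c not in IDX]
        if unknown:
            raise ValidationError(f"unknown observed species: {unknown}")
        if not self.species:
            raise ValidationError("no observed species columns")
        self.observations = observations.sort_values("time_h").reset_index(drop=True)
        self.params = params
        self.protocol = protocol
        self.free = tuple(free)
        for name in self.free:
            if name not in CircuitParams.__dataclass_fields__:
                raise ValidationError(f"unknown parameter {name!r}")
            if not isinstance(getattr(params, name), float):
                raise ValidationError(f"parameter {name!r} is not a scalar rate")
        self.init = init
        self.times = self.observations["time_h"].to_numpy(dtype=float)
        self._y_log = np.log(
            np.clip(self.observations[self.species].to_numpy(dtype=float), _LOG_FLOOR, None)
        )

    def _predict_log(self, theta_log: np.ndarray) -> np.ndarray:
        values = dict(zip(self.free, np.exp(theta_log)))
        circuit = EmtCircuit(replace(self.params, **values))
        traj = circuit.simulate(
            self.protocol,
            (0.0, self.times[-1]),
            init=self.init,
            rtol=1e-7,
            atol=1e-9,
            n_points=max(101, len(self.times)),
        )
        cols = [IDX[s] for s in self.species]
        pred = np.empty((len(self.times), len(cols)))
        for j, ci in enumerate(cols):
            pred[:, j] = np.interp(self.times, traj.times, traj.states[:, ci])
        return np.log(np.clip(pred, _LOG_FLOOR, None))

    def _residuals(self, theta_log: np.ndarray) -> np.ndarray:
        return (self._predict_log(theta_log) - self._y_log).ravel()

    def fit(self, start: dict | None = None) -> "CircuitFitResults":
        """Estimate the free parameters; optimization runs in log space."""
        start = start or {}
        theta0 = np.log(
            [start.get(name, getattr(self.params, name)) for name in self.free]
        )
        sol = least_squares(self._residuals, theta0, method="lm", xtol=1e-12, ftol=1e-12)
        theta = np.exp(sol.x)
        # Gauss-Newton covariance on the log scale, delta-method back-transform
        m, n = sol.fun.size, sol.x.size
        dof = max(m - n, 1)
        sigma2 = float(sol.fun @ sol.fun) / dof
        JtJ = sol.jac.T @ sol.jac
        try:
            cov_log = sigma2 * np.linalg.inv(JtJ)
        except np.linalg.LinAlgError:
            cov_log = np.full((n, n), np.nan)
        bse = theta * np.sqrt(np.clip(np.diag(cov_log), 0.0, None))
        return CircuitFitResults(
            model=self,
            estimates=dict(zip(self.free, theta)),
            bse=dict(zip(self.free, bse)),
            cost=float(sol.cost),
            success=bool(sol.success),
            nobs=m,
        )


@dataclass(frozen=True)
class CircuitFitResults:
    """Estimates, uncertainties and diagnostics from a trajectory fit."""

    model: CircuitTrajectoryFit
    estimates: dict
    bse: dict
    cost: float
    success: bool
    nobs: int

    def relative_error(self, truth: dict) -> dict:
        """|estimate - truth| / truth for each free parameter."""
        return {
            k: abs(self.estimates[k] - truth[k]) / truth[k] for k in self.estimates
        }

    def summary(self) -> str:
        lines = [
            "Circuit trajectory fit (nonlinear least squares, log scale)",
            f"  observed species: {', '.join(self.model.species)}",
            f"  n observations:   {self.nobs}",
            f"  converged:        {self.success}",
            f"  residual cost:    {self.cost:.6g}",
            "",
            f"  {'parameter':<12}{'estimate':>14}{'std err':>14}",
        ]
        for k in self.estimates:
            lines.append(f"  {k:<12}{self.estimates[k]:>14.6g}{self.bse[k]:>14.3g}")
        return "\n".join(lines)
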