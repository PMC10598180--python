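"""Asymptotic frequentist uncertainty for parameters and model responses.

With Sigma-hat the estimated diagonal error covariance and S-hat the
waveform Jacobian with respect to the log-parameters at the optimum, the
asymptotic parameter covariance is

    C = (S^T Sigma^-1 S)^-1

and 95% intervals follow from the two-sided t quantile with
N_tot - N_par degrees of freedom:

    log-parameter CI:  theta_i +/- t * sqrt(C_ii)      (exponentiated)
    response CI:       Y +/- t * sqrt(s_t^T C s_t)
    response PI:       Y +/- t * sqrt(sigma_i^2 + s_t^T C s_t)

Prediction intervals add the observation variance of the sample's stream,
so they contain the confidence intervals pointwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .circulation import CALIBRATION_STREAMS, SolverConfig
from .inference import FitResult
from .sensitivity import SensitivityMatrix, output_sensitivity

__all__ = ["IntervalSet", "parameter_confidence", "response_intervals",
           "CollinearityError"]


class CollinearityError(RuntimeError):
    """Raised when S^T Sigma^-1 S is numerically singular."""


@dataclass
class IntervalSet:
    """Parameter and pointwise response intervals from one calibrated fit."""

    names: List[str]
    theta_log: np.ndarray
    ci_log_lower: np.ndarray
    ci_log_upper: np.ndarray
    covariance: np.ndarray          # C on the log scale
    t_quantile: float
    dof: int
    # response part (filled by response_intervals)
    y_hat: Optional[np.ndarray] = None
    ci_lower: Optional[np.ndarray] = None
    ci_upper: Optional[np.ndarray] = None
    pi_lower: Optional[np.ndarray] = None
    pi_upper: Optional[np.ndarray] = None

    @property
    def estimate_natural(self) -> np.ndarray:
        return np.exp(self.theta_log)

    @property
    def ci_natural(self) -> np.ndarray:
        """Exponentiated log-intervals, shape (k, 2); asymmetric about the
        natural-scale estimate."""
        return np.exp(np.column_stack([self.ci_log_lower, self.ci_log_upper]))

    @property
    def correlation(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.covariance))
        return self.covariance / np.outer(d, d)

    def parameter_frame(self) -> pd.DataFrame:
        ci = self.ci_natural
        return pd.DataFrame({
            "estimate": self.estimate_natural,
            "lower": ci[:, 0],
            "upper": ci[:, 1],
        }, index=self.names)


def _weighted_covariance(S: np.ndarray, sigma2_stack: np.ndarray,
                         names: List[str]) -> np.ndarray:
    w = 1.0 / sigma2_stack
    A = S.T @ (S * w[:, None])
    # detect numerical singularity before inverting
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1.0e14:
        corr = np.corrcoef(S, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise CollinearityError(
            "information matrix is numerically singular; most collinear "
            f"pair: {names[i]} and {names[j]} (r = {corr[i, j]:.4f})")
    return np.linalg.inv(A)


def _sigma2_stack(fit: FitResult) -> np.ndarray:
    n = fit.data.n_per_stream
    return np.repeat(fit.sigma2, n)


def _jacobian(fit: FitResult, S: Optional[SensitivityMatrix],
              config: Optional[SolverConfig], h: float = 0.01
              ) -> SensitivityMatrix:
    """Centered-difference Jacobian of the observed model output with
    respect to the fitted log-parameters, at the optimum."""
    if S is not None:
        return S
    pred = fit.predictor()
    f0 = pred.vector_at(fit.theta_log)
    if f0 is None:
        raise RuntimeError("forward model failed at the fitted optimum")
    cols = np.empty((f0.size, fit.n_par))
    for i in range(fit.n_par):
        th = fit.theta_log.copy()
        th[i] += h
        fp = pred.vector_at(th)
        th[i] -= 2 * h
        fm = pred.vector_at(th)
        if fp is None or fm is None:
            raise RuntimeError("forward model failed during the Jacobian")
        cols[:, i] = (fp - fm) / (2.0 * h)
    return SensitivityMatrix(cols, list(fit.names), h, f0, scaled=False)


def parameter_confidence(fit: FitResult,
                         S: Optional[SensitivityMatrix] = None,
                         level: float = 0.95,
                         config: Optional[SolverConfig] = None
                         ) -> IntervalSet:
    """Asymptotic confidence intervals for the fitted log-parameters.

    ``S`` is the model-output Jacobian with respect to the log-parameters
    at the optimum (computed by centered differences when not supplied).
    The log-scale intervals are exponentiated for reporting, so they are
    asymmetric about the natural-scale estimate.
    """
    if not fit.converged:
        import warnings
        warnings.warn("confidence intervals from a non-converged fit")
    S = _jacobian(fit, S, config)
    C = _weighted_covariance(S.S, _sigma2_stack(fit), list(fit.names))
    dof = fit.n_total - fit.n_par
    t_q = float(stats.t.ppf(0.5 + level / 2.0, dof))
    half = t_q * np.sqrt(np.diag(C))
    return IntervalSet(
        names=list(fit.names),
        theta_log=fit.theta_log.copy(),
        ci_log_lower=fit.theta_log - half,
        ci_log_upper=fit.theta_log + half,
        covariance=C,
        t_quantile=t_q,
        dof=dof,
    )


def response_intervals(fit: FitResult,
                       S: Optional[SensitivityMatrix] = None,
                       level: float = 0.95,
                       config: Optional[SolverConfig] = None
                       ) -> IntervalSet:
    """Pointwise confidence and prediction bands for the model output.

    The CI half-width at sample t is t_q * sqrt(s_t^T C s_t); the PI adds
    the sample's stream error variance inside the square root, hence
    PI >= CI pointwise with equality only at zero error variance.
    """
    S = _jacobian(fit, S, config)
    iv = parameter_confidence(fit, S=S, level=level, config=config)
    sigma2_stack = _sigma2_stack(fit)
    var_ci = np.einsum("ti,ij,tj->t", S.S, iv.covariance, S.S)
    var_ci = np.maximum(var_ci, 0.0)
    y_hat = S.baseline
    half_ci = iv.t_quantile * np.sqrt(var_ci)
    half_pi = iv.t_quantile * np.sqrt(var_ci + sigma2_stack)
    iv.y_hat = y_hat
    iv.ci_lower = y_hat - half_ci
    iv.ci_upper = y_hat + half_ci
    iv.pi_lower = y_hat - half_pi
    iv.pi_upper = y_hat + half_pi
    return iv
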