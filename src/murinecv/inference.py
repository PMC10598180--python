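"""Weighted maximum-likelihood calibration with iteratively reweighted
per-stream error variances.

The data vector stacks the five heartbeat-averaged calibration streams
(p_RV, V_RV, p_LV, V_LV, p_SA).  Measurement errors are modeled as
independent Gaussians with one variance per stream, giving the negative
log-likelihood

    -LL(theta) = sum_i [ (N_i/2) ln(2 pi sigma_i^2) + RSS_i(theta)/(2 sigma_i^2) ]

minimized over natural-log parameters of the identifiable subset.  At
fixed Sigma the minimization is a weighted nonlinear least-squares
problem, solved here by trust-region least squares with finite-difference
Jacobians; the variances are then refreshed from the per-stream residuals
(sigma_i^2 = RSS_i/N_i) and the two steps alternate to a joint fixed point.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .circulation import (CALIBRATION_STREAMS, SimulationError, SolverConfig,
                          SimulationResult, simulate)
from .registry import ModelParameters

__all__ = ["CalibrationData", "neg_log_likelihood", "nll_from_residuals",
           "irwls_update", "fit_parameters", "FitResult"]

#: Relative variance floor against degenerate zero-residual streams.
VAR_FLOOR_REL = 1.0e-12


@dataclass
class CalibrationData:
    """Beat-averaged measurement streams on a common beat grid.

    ``streams`` maps each calibration stream name to an equal-length array
    in internal units (kPa for pressures, mL for volumes).

    ``native_samples`` and ``smooth_window`` describe the acquisition the
    data went through (samples per beat at the recording rate and the
    smoothing window applied); when set, model predictions are passed
    through the same observation operator before comparison, so the
    residual reflects measurement noise rather than resampling and
    smoothing distortion.
    """

    streams: Dict[str, np.ndarray]
    native_samples: Optional[int] = None
    smooth_window: Optional[int] = None

    def __post_init__(self) -> None:
        lengths = {s: len(self.streams[s]) for s in CALIBRATION_STREAMS
                   if s in self.streams}
        if set(lengths) != set(CALIBRATION_STREAMS):
            missing = set(CALIBRATION_STREAMS) - set(lengths)
            raise ValueError(f"missing calibration streams: {sorted(missing)}")
        if len(set(lengths.values())) != 1:
            raise ValueError("all streams must share one beat grid")
        for s in CALIBRATION_STREAMS:
            if not np.all(np.isfinite(self.streams[s])):
                raise ValueError(f"stream {s} contains non-finite samples")

    @property
    def n_per_stream(self) -> int:
        return len(self.streams[CALIBRATION_STREAMS[0]])

    @property
    def n_total(self) -> int:
        return 5 * self.n_per_stream

    def vector(self) -> np.ndarray:
        return np.concatenate([self.streams[s] for s in CALIBRATION_STREAMS])

    def split(self, stacked: np.ndarray) -> Dict[str, np.ndarray]:
        n = self.n_per_stream
        return {s: stacked[i * n:(i + 1) * n]
                for i, s in enumerate(CALIBRATION_STREAMS)}


def nll_from_residuals(residuals: Dict[str, np.ndarray],
                       sigma2: np.ndarray) -> float:
    """Exact independent-Gaussian negative log-likelihood."""
    total = 0.0
    for i, s in enumerate(CALIBRATION_STREAMS):
        r = residuals[s]
        n_i = r.size
        total += 0.5 * n_i * math.log(2.0 * math.pi * sigma2[i])
        total += 0.5 * float(r @ r) / sigma2[i]
    return total


def irwls_update(residuals: Dict[str, np.ndarray],
                 data: Optional[CalibrationData] = None) -> np.ndarray:
    """Per-stream error-variance estimates sigma_i^2 = RSS_i / N_i.

    Zero-residual streams are floored at a small fraction of the stream's
    own variance (or machine tiny for a constant stream).
    """
    sigma2 = np.empty(len(CALIBRATION_STREAMS))
    for i, s in enumerate(CALIBRATION_STREAMS):
        r = residuals[s]
        sigma2[i] = float(r @ r) / r.size
        if data is not None:
            floor = VAR_FLOOR_REL * float(np.var(data.streams[s]))
        else:
            floor = 0.0
        sigma2[i] = max(sigma2[i], floor, 1.0e-300)
    return sigma2


def _circular_gaussian_smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Unit-sum Gaussian smoothing of a periodic (one-beat) signal."""
    from scipy.signal import windows as sp_windows
    w = int(min(window, x.size))
    if w < 3:
        return x
    kern = sp_windows.gaussian(w, (w - 1) / 5.0)
    kern /= kern.sum()
    half = (w - 1) // 2
    xp = np.concatenate([x[-(w - 1 - half):], x, x[:half]]) \
        if half else np.concatenate([x, x[:w - 1]])
    return np.convolve(xp, kern, mode="valid")


def observation_operator(streams: Dict[str, np.ndarray],
                         native_samples: Optional[int],
                         smooth_window: Optional[int]
                         ) -> Dict[str, np.ndarray]:
    """Degrade a model beat through the acquisition chain of the data.

    Linear sampling at the recording rate (``native_samples`` per beat),
    the same Gaussian smoothing as the pipeline, and resampling back to
    the beat grid — all treating the beat as periodic.
    """
    if not native_samples:
        return streams
    out = {}
    for k, x in streams.items():
        n = x.size
        ph_g = np.arange(n) / n
        ph_n = np.arange(native_samples) / native_samples
        xs = np.interp(ph_n, ph_g, x, period=1.0)
        if smooth_window:
            xs = _circular_gaussian_smooth(xs, smooth_window)
        out[k] = np.interp(ph_g, ph_n, xs, period=1.0)
    return out


def _best_circular_shift(model: np.ndarray, data: np.ndarray) -> float:
    """Fractional circular shift of ``model`` best matching ``data``.

    Maximizes the circular cross-correlation (computed by FFT) with
    parabolic sub-sample refinement of the peak; the returned shift feeds
    :func:`murinecv.circulation.circular_shift`.
    """
    n = model.size
    m = model - model.mean()
    d = data - data.mean()
    # c[s] = sum_i d[i] * m[(i + s) mod n]
    c = np.fft.irfft(np.conj(np.fft.rfft(d)) * np.fft.rfft(m), n)
    k = int(np.argmax(c))
    a, b_, cc = c[(k - 1) % n], c[k], c[(k + 1) % n]
    denom = a - 2.0 * b_ + cc
    off = 0.0 if denom == 0 else 0.5 * (a - cc) / denom
    return (k + float(np.clip(off, -0.5, 0.5))) % n


class _ModelCache:
    """Warm-started forward evaluations of the stacked calibration vector."""

    def __init__(self, params: ModelParameters, names: Sequence[str],
                 config: Optional[SolverConfig],
                 data: Optional[CalibrationData] = None):
        self.params = params
        self.names = list(names)
        self.config = config
        self.data = data
        self.init = None
        self.n_eval = 0
        self.n_fail = 0
        self.last_result: Optional[SimulationResult] = None

    def simulate_at(self, theta_log: np.ndarray
                    ) -> Optional[SimulationResult]:
        values = dict(zip(self.names, np.exp(theta_log)))
        self.n_eval += 1
        try:
            res = simulate(self.params.with_values(values),
                           config=self.config, init=self.init)
        except (SimulationError, ValueError):
            self.n_fail += 1
            return None
        self.init = (res.final_state, res.final_u)
        self.last_result = res
        return res

    def vector_at(self, theta_log: np.ndarray) -> Optional[np.ndarray]:
        res = self.simulate_at(theta_log)
        if res is None:
            return None
        streams = {s: res.stream(s) for s in CALIBRATION_STREAMS}
        if self.data is not None:
            streams = observation_operator(streams,
                                           self.data.native_samples,
                                           self.data.smooth_window)
            # the segmentation phase of the data is arbitrary: profile it
            # out by aligning the model beat to the data by circular
            # cross-correlation of the LV pressure (smooth in theta,
            # unlike an argmax-anchor rule)
            shift = _best_circular_shift(streams["p_LV"],
                                         self.data.streams["p_LV"])
            from .circulation import circular_shift
            streams = {k: circular_shift(v, shift)
                       for k, v in streams.items()}
            # the volume channels carry their own catheter phase, which the
            # pipeline re-anchors per beat; profile it out the same way
            for s in ("V_LV", "V_RV"):
                vs = _best_circular_shift(streams[s], self.data.streams[s])
                streams[s] = circular_shift(streams[s], vs)
        else:
            from .circulation import align_streams_to_upstroke
            streams, _ = align_streams_to_upstroke(streams)
        return np.concatenate([streams[s] for s in CALIBRATION_STREAMS])


def neg_log_likelihood(theta_log: np.ndarray, data: CalibrationData,
                       sigma2: np.ndarray, names: Sequence[str],
                       params: ModelParameters,
                       config: Optional[SolverConfig] = None,
                       _cache: Optional[_ModelCache] = None) -> float:
    """-LL at log-parameters ``theta_log`` for the subset ``names``.

    A failed forward simulation returns a large-but-finite penalty so that
    line searches can back away gracefully.
    """
    cache = _cache or _ModelCache(params, names, config, data=data)
    f = cache.vector_at(np.asarray(theta_log, dtype=float))
    if f is None:
        return 1.0e12 * (1.0 + float(np.sum(np.square(theta_log))))
    res = data.split(data.vector() - f)
    return nll_from_residuals(res, np.asarray(sigma2, dtype=float))


@dataclass
class FitResult:
    """Outcome of the IRWLS maximum-likelihood calibration."""

    names: List[str]
    theta_log: np.ndarray
    sigma2: np.ndarray
    nll: float
    converged: bool
    n_outer: int
    n_eval: int
    n_fail: int
    history: List[Dict]
    data: CalibrationData
    params: ModelParameters            # full parameter set at the optimum
    config: Optional[SolverConfig]
    result: Optional[SimulationResult]  # converged beat at the optimum

    @property
    def theta_natural(self) -> np.ndarray:
        return np.exp(self.theta_log)

    def predictor(self) -> "_ModelCache":
        """A warm-started evaluator of the observed-model vector, using the
        same observation operator and phase convention as the fit."""
        cache = _ModelCache(self.params, self.names, self.config,
                            data=self.data)
        if self.result is not None:
            cache.init = (self.result.final_state, self.result.final_u)
        return cache

    @property
    def n_total(self) -> int:
        return self.data.n_total

    @property
    def n_par(self) -> int:
        return len(self.names)

    def to_dict(self) -> Dict:
        return {
            "names": self.names,
            "theta_log": self.theta_log.tolist(),
            "theta_natural": self.theta_natural.tolist(),
            "sigma2": self.sigma2.tolist(),
            "nll": self.nll,
            "converged": self.converged,
            "n_outer": self.n_outer,
            "n_eval": self.n_eval,
            "n_fail": self.n_fail,
        }


def _fd_jacobian(cache: _ModelCache, theta: np.ndarray, f0: np.ndarray,
                 h: float = 0.01) -> np.ndarray:
    """One-sided FD Jacobian of the model vector wrt log-parameters."""
    J = np.empty((f0.size, theta.size))
    for i in range(theta.size):
        th = theta.copy()
        th[i] += h
        f = cache.vector_at(th)
        if f is None:
            th[i] = theta[i] - h
            f = cache.vector_at(th)
            if f is None:
                raise SimulationError(
                    "forward model failed during Jacobian evaluation")
            J[:, i] = (f0 - f) / h
        else:
            J[:, i] = (f - f0) / h
    return J


def _lm_weighted(cache: _ModelCache, theta: np.ndarray, f0: np.ndarray,
                 y: np.ndarray, sig_stack: np.ndarray,
                 J: Optional[np.ndarray], step_tol: float,
                 max_steps: int = 30) -> Tuple[np.ndarray, np.ndarray,
                                               np.ndarray]:
    """Damped Gauss-Newton (Levenberg-Marquardt) on the weighted residuals.

    The model Jacobian is computed by finite differences once, then kept
    up to date with Broyden rank-one updates and refreshed only when the
    damping escalates; it is also returned so the caller can reuse it
    after reweighting (the Jacobian of f does not depend on Sigma).
    Returns (theta, f(theta), J).
    """
    if J is None:
        J = _fd_jacobian(cache, theta, f0)
    lam = 1.0e-3
    cost = float(np.sum(((y - f0) / sig_stack) ** 2))
    since_refresh = 0
    for _ in range(max_steps):
        Jw = J / sig_stack[:, None]
        rw = (y - f0) / sig_stack
        g = Jw.T @ rw
        A = Jw.T @ Jw
        d = np.sqrt(np.maximum(np.diag(A), 1e-12))
        accepted = False
        for _damp in range(12):
            try:
                delta = np.linalg.solve(A + lam * np.diag(d * d), g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            f_new = cache.vector_at(theta + delta)
            if f_new is not None:
                cost_new = float(np.sum(((y - f_new) / sig_stack) ** 2))
                if cost_new < cost:
                    # Broyden rank-one update keeps J consistent
                    dd = float(delta @ delta)
                    J = J + np.outer(f_new - f0 - J @ delta, delta) / dd
                    theta = theta + delta
                    f0 = f_new
                    cost = cost_new
                    lam = max(lam / 3.0, 1.0e-10)
                    accepted = True
                    since_refresh += 1
                    break
            lam *= 4.0
        if not accepted:
            if since_refresh > 0:
                J = _fd_jacobian(cache, theta, f0)
                since_refresh = 0
                continue
            break
        if since_refresh >= 6:
            J = _fd_jacobian(cache, theta, f0)
            since_refresh = 0
        if float(np.max(np.abs(delta))) < step_tol:
            break
    return theta, f0, J


def fit_parameters(data: CalibrationData, names: Sequence[str],
                   params: ModelParameters,
                   theta0_log: Optional[np.ndarray] = None,
                   config: Optional[SolverConfig] = None,
                   max_outer: int = 20,
                   theta_tol: float = 1.0e-6,
                   sigma_tol: float = 1.0e-4,
                   method: str = "lm",
                   inner_kwargs: Optional[Dict] = None) -> FitResult:
    """Alternate weighted least squares and variance re-estimation.

    Starting from ``theta0_log`` (default: the log of the current values in
    ``params``), each outer iteration (a) minimizes -LL at fixed Sigma —
    a weighted nonlinear least-squares problem solved by damped
    Gauss-Newton with finite-difference/Broyden Jacobians
    (``method='lm'``) or quasi-Newton BFGS on -LL (``method='bfgs'``) —
    then (b) refreshes the per-stream variances from the residuals.  The
    loop stops when both the log-parameters (absolute change <
    ``theta_tol``) and the variances (relative change < ``sigma_tol``)
    have converged.
    """
    names = list(names)
    cache = _ModelCache(params, names, config, data=data)
    if theta0_log is None:
        theta0_log = np.log([params.get(n) for n in names])
    theta = np.asarray(theta0_log, dtype=float).copy()
    y = data.vector()
    n = data.n_per_stream

    f0 = cache.vector_at(theta)
    if f0 is None:
        raise SimulationError("forward model failed at the starting point")
    sigma2 = irwls_update(data.split(y - f0), data)
    sig_stack = np.repeat(np.sqrt(sigma2), n)

    history: List[Dict] = []
    converged = False
    inner_kwargs = dict(inner_kwargs or {})
    J = None
    for outer in range(1, max_outer + 1):
        if method == "lm":
            theta_new, f, J = _lm_weighted(
                cache, theta.copy(), f0, y, sig_stack, J,
                step_tol=0.1 * theta_tol,
                max_steps=int(inner_kwargs.get("max_steps", 30)))
        elif method == "bfgs":
            kw = {"options": {"maxiter": 200}}
            kw.update(inner_kwargs)

            def nll_fixed(th):
                fv = cache.vector_at(th)
                if fv is None:
                    return 1.0e12 * (1.0 + float(np.sum(np.square(th))))
                return nll_from_residuals(data.split(y - fv), sigma2)

            sol = optimize.minimize(nll_fixed, theta, method="BFGS", **kw)
            theta_new = sol.x
            f = cache.vector_at(theta_new)
            if f is None:
                warnings.warn("forward model failed at the inner optimum; "
                              "keeping previous iterate")
                theta_new = theta
                f = cache.vector_at(theta)
        else:
            raise ValueError(f"unknown inner method {method!r}")

        resid = data.split(y - f)
        sigma2_new = irwls_update(resid, data)
        d_theta = float(np.max(np.abs(theta_new - theta)))
        d_sigma = float(np.max(np.abs(sigma2_new - sigma2)
                               / np.maximum(sigma2, 1e-300)))
        history.append({"outer": outer, "d_theta": d_theta,
                        "d_sigma": d_sigma,
                        "nll": nll_from_residuals(resid, sigma2_new),
                        "sigma2": sigma2_new.copy()})
        theta = theta_new
        f0 = f
        sigma2 = sigma2_new
        sig_stack = np.repeat(np.sqrt(sigma2), n)
        if d_theta < theta_tol and d_sigma < sigma_tol:
            converged = True
            break

    final_params = params.with_values(dict(zip(names, np.exp(theta))))
    final_res = cache.simulate_at(theta)
    nll = history[-1]["nll"] if history else float("nan")
    return FitResult(names=names, theta_log=theta, sigma2=sigma2, nll=nll,
                     converged=converged, n_outer=len(history),
                     n_eval=cache.n_eval, n_fail=cache.n_fail,
                     history=history, data=data, params=final_params,
                     config=config, result=final_res)
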