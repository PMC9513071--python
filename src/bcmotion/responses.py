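"""Response-trace preprocessing, GP smoothing, and the d' preference statistic.

Raw fluorescence traces are high-pass filtered (Butterworth, 0.2 Hz, order 5)
and z-normalized.  Trial responses per stimulus condition are then smoothed
with Gaussian-process regression (RBF kernel, variance 1.1, lengthscale
0.05 s) to obtain a posterior mean and pointwise s.d. on a 50 Hz grid, with
optionally finer spacing (125 Hz) inside a warp window covering the moving-bar
epoch.  Responses whose posterior mean is nearly flat (s.d. over time below
0.1 in every condition) are flagged as non-responsive and discarded from
statistics.

The motion-preference statistic between two conditions is

    d' = (mu1 - mu2) / sqrt(0.5 * (sigma1^2 + sigma2^2)),

where mu_i is the peak of condition i's posterior mean inside the analysis
window and sigma_i the posterior s.d. at that peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel

from .errors import (
    DegenerateTraceError,
    InsufficientDataError,
    InvalidParameterError,
    MissingConditionError,
    UndefinedStatisticError,
)

__all__ = ["ResponseTrace", "SmoothedResponse", "preprocess", "smooth_response", "d_prime"]


@dataclass
class ResponseTrace:
    """A single-trial response signal sampled at ``rate_hz``."""

    values: np.ndarray
    rate_hz: float
    condition_label: str = ""
    trial_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise InvalidParameterError("trace values must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("trace values must be finite")
        if self.rate_hz <= 0:
            raise InvalidParameterError("rate_hz must be positive")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.rate_hz

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.rate_hz


@dataclass
class SmoothedResponse:
    """Posterior mean and s.d. of a condition's response on a common grid."""

    mean: np.ndarray
    sd: np.ndarray
    times_s: np.ndarray
    condition_label: str = ""
    discarded: bool = False

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if not (len(self.mean) == len(self.sd) == len(self.times_s)):
            raise InvalidParameterError("mean, sd and times must share a grid")
        if np.any(self.sd < 0):
            raise InvalidParameterError("sd must be non-negative")


def preprocess(
    trace: ResponseTrace, hp_cutoff_hz: float = 0.2, order: int = 5
) -> ResponseTrace:
    """High-pass filter (Butterworth, zero-phase) and z-normalize a trace."""
    sos = signal.butter(order, hp_cutoff_hz, btype="highpass", fs=trace.rate_hz,
                        output="sos")
    padlen = 3 * (2 * order + 1)
    if len(trace.values) <= padlen:
        raise InsufficientDataError("trace shorter than the filter warm-up")
    if np.ptp(trace.values) == 0:
        raise DegenerateTraceError("constant trace cannot be z-normalized")
    filtered = signal.sosfiltfilt(sos, trace.values)
    sd = np.std(filtered)
    if sd == 0:
        raise DegenerateTraceError("filtered trace has zero variance")
    z = (filtered - np.mean(filtered)) / sd
    return ResponseTrace(z, trace.rate_hz, trace.condition_label, trace.trial_index)


def _out_grid(
    duration_s: float,
    out_rate_hz: float,
    warp_window: tuple | None,
    warp_rate_hz: float,
) -> np.ndarray:
    grid = np.arange(0.0, duration_s, 1.0 / out_rate_hz)
    if warp_window is None:
        return grid
    w0, w1 = warp_window
    fine = np.arange(max(w0, 0.0), min(w1, duration_s), 1.0 / warp_rate_hz)
    grid = np.unique(np.concatenate([grid[(grid < w0) | (grid >= w1)], fine]))
    return grid


def smooth_response(
    traces_by_condition: dict,
    kernel_variance: float = 1.1,
    lengthscale: float = 0.05,
    out_rate_hz: float = 50.0,
    warp_window: tuple | None = None,
    warp_rate_hz: float = 125.0,
    noise_variance: float = 0.1,
    discard_sd: float = 0.1,
) -> dict:
    """GP-smooth trial responses per stimulus condition.

    Parameters
    ----------
    traces_by_condition : dict[str, list[ResponseTrace]]
        One or more trials per condition, on a common trial clock.
    kernel_variance, lengthscale : float
        RBF kernel parameters (lengthscale in seconds on the trial clock).
    out_rate_hz, warp_window, warp_rate_hz
        Output grid: ``out_rate_hz`` everywhere, refined to ``warp_rate_hz``
        inside ``warp_window`` (the moving-bar epoch).
    noise_variance : float
        Observation noise variance of the exact GP regression.
    discard_sd : float
        A ROI is flagged discarded when the s.d. over time of the posterior
        mean is below this value in *every* condition.

    Returns
    -------
    dict[str, SmoothedResponse]
    """
    if not traces_by_condition:
        raise MissingConditionError("no stimulus conditions provided")
    kernel = ConstantKernel(kernel_variance, "fixed") * RBF(lengthscale, "fixed")
    out: dict[str, SmoothedResponse] = {}
    mean_sds = []
    for label, trials in traces_by_condition.items():
        if not trials:
            raise MissingConditionError(f"condition {label!r} has no trials")
        t = np.concatenate([tr.times_s for tr in trials])
        y = np.concatenate([tr.values for tr in trials])
        duration = max(tr.duration_s for tr in trials)
        grid = _out_grid(duration, out_rate_hz, warp_window, warp_rate_hz)
        gp = GaussianProcessRegressor(kernel=kernel, alpha=noise_variance,
                                      optimizer=None, normalize_y=False)
        gp.fit(t[:, None], y)
        mean, sd = gp.predict(grid[:, None], return_std=True)
        out[label] = SmoothedResponse(mean, sd, grid, condition_label=label)
        mean_sds.append(np.std(mean))
    discarded = max(mean_sds) < discard_sd
    for resp in out.values():
        resp.discarded = discarded
    return out


def _peak_in_window(resp: SmoothedResponse, window: tuple | None) -> tuple[float, float]:
    if window is None:
        mask = np.ones(len(resp.times_s), dtype=bool)
    else:
        t0, t1 = window
        mask = (resp.times_s >= t0) & (resp.times_s <= t1)
        if not mask.any():
            raise InvalidParameterError("analysis window lies outside the grid")
    idx = np.flatnonzero(mask)[int(np.argmax(resp.mean[mask]))]
    return float(resp.mean[idx]), float(resp.sd[idx])


def d_prime(r1: SmoothedResponse, r2: SmoothedResponse, window: tuple | None = None) -> float:
    """d' between two conditions' peak responses, pooled-s.d. normalized.

    The peak is the maximum of the posterior mean (signed) inside ``window``;
    sigma is the posterior s.d. at that peak.  Raises if either response was
    flagged discarded or both sigmas are zero.
    """
    if r1.discarded or r2.discarded:
        raise UndefinedStatisticError("d' undefined for discarded (non-responsive) ROIs")
    mu1, s1 = _peak_in_window(r1, window)
    mu2, s2 = _peak_in_window(r2, window)
    pooled = np.sqrt(0.5 * (s1**2 + s2**2))
    if pooled == 0:
        raise UndefinedStatisticError("d' undefined: zero pooled standard deviation")
    return float((mu1 - mu2) / pooled)
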