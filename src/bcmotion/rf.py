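"""Space-time receptive fields: estimation and feature extraction.

A receptive field (RF) is a linear filter W(x, tau) over space and time lag
mapping stimulus contrast to response: the response at time t is
``sum_x sum_tau W[x, tau] * S[x, t - tau]``.  Lag 0 is the most recent
stimulus frame; the lag axis extends ``lag_span_s`` (default 0.5 s) into the
past.  On RFs have a positive center, Off RFs a negative center; features are
computed on polarity-corrected kernels.

``estimate_rf`` recovers a smooth RF from a stimulus/response pair by
penalized least squares (a second-difference roughness penalty over space and
lag, the penalty weight chosen by generalized cross-validation by default) --
a regularized spike-triggered average.  ``extract_features`` measures the four
center-surround descriptors used throughout the package: center-surround peak
latency, surround/center strength ratio, biphasic index of the center temporal
kernel, and the full width at half maximum (FWHM) of a Gaussian fit to the
center's spatial profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import (
    DegenerateRFError,
    InsufficientDataError,
    InvalidParameterError,
    InvalidRegionError,
    UndefinedPeakError,
)
from .stimuli import SpaceTimeStimulus

__all__ = [
    "SpaceTimeRF",
    "RFFeatures",
    "estimate_rf",
    "extract_features",
    "rf_trajectory",
    "recenter",
    "parabolic_peak",
]


@dataclass
class SpaceTimeRF:
    """Space-time receptive field over (space bin, time-lag bin).

    ``weights[x, l]`` multiplies the stimulus at spatial bin ``x`` presented
    ``l * dt`` seconds before the response.  The spatial grid follows the
    stimulus convention: bin ``i`` is centered at
    ``origin_um + (i + 0.5) * dx``.
    """

    weights: np.ndarray
    dx: float
    dt: float
    origin_um: float = 0.0
    center_um: float = 0.0
    polarity: int = +1
    ipl_depth: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.size == 0:
            raise InvalidParameterError("RF weights must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.weights)):
            raise InvalidParameterError("RF weights must be finite")
        if not (self.dx > 0 and self.dt > 0):
            raise InvalidParameterError("dx and dt must be positive")
        if self.polarity not in (+1, -1):
            raise InvalidParameterError("polarity must be +1 (On) or -1 (Off)")
        if self.ipl_depth is not None and not (0.0 <= self.ipl_depth <= 1.0):
            raise InvalidParameterError("ipl_depth must lie in [0, 1]")

    @property
    def n_space(self) -> int:
        return self.weights.shape[0]

    @property
    def n_lag(self) -> int:
        return self.weights.shape[1]

    @property
    def lag_span_s(self) -> float:
        return self.n_lag * self.dt

    @property
    def space_centers_um(self) -> np.ndarray:
        return self.origin_um + (np.arange(self.n_space) + 0.5) * self.dx

    @property
    def lags_s(self) -> np.ndarray:
        return np.arange(self.n_lag) * self.dt

    def copy(self, **overrides) -> "SpaceTimeRF":
        kw = dict(
            weights=self.weights.copy(),
            dx=self.dx,
            dt=self.dt,
            origin_um=self.origin_um,
            center_um=self.center_um,
            polarity=self.polarity,
            ipl_depth=self.ipl_depth,
            label=self.label,
        )
        kw.update(overrides)
        return SpaceTimeRF(**kw)


@dataclass(frozen=True)
class RFFeatures:
    """Center-surround descriptors of a space-time RF."""

    latency_s: float
    surround_strength: float
    biphasic_index: float
    fwhm_um: float
    center_um: float = np.nan  # fitted Gaussian center of the spatial profile


def recenter(rf: SpaceTimeRF, new_center_um: float) -> SpaceTimeRF:
    """Translate an RF so its center sits at ``new_center_um`` (grid shifts with it)."""
    shift = new_center_um - rf.center_um
    return rf.copy(origin_um=rf.origin_um + shift, center_um=new_center_um)


def parabolic_peak(y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-bin peak location and value by parabolic interpolation around index i."""
    y = np.asarray(y, dtype=float)
    if i <= 0 or i >= len(y) - 1:
        return float(i), float(y[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return float(i), float(y[i])
    off = 0.5 * (y[i - 1] - y[i + 1]) / denom
    off = float(np.clip(off, -0.5, 0.5))
    val = y[i] - 0.25 * (y[i - 1] - y[i + 1]) * off
    return i + off, float(val)


def _second_diff_penalty(n: int) -> np.ndarray:
    if n < 3:
        return np.zeros((n, n))
    d = np.zeros((n - 2, n))
    for k in range(n - 2):
        d[k, k : k + 3] = (1.0, -2.0, 1.0)
    return d.T @ d


def _as_response_array(resp, stim: SpaceTimeStimulus) -> np.ndarray:
    """Accept a ResponseTrace-like object or a plain array aligned to stim.dt."""
    if hasattr(resp, "values") and hasattr(resp, "rate_hz"):
        vals = np.asarray(resp.values, dtype=float)
        src_t = np.arange(len(vals)) / float(resp.rate_hz)
        return np.interp(stim.times_s, src_t, vals, left=vals[0], right=vals[-1])
    vals = np.asarray(resp, dtype=float)
    if len(vals) != stim.n_time:
        raise InvalidParameterError(
            "plain-array responses must share the stimulus time grid"
        )
    return vals


def estimate_rf(
    stim: SpaceTimeStimulus,
    resp,
    smoothness: float | str = "gcv",
    lag_span_s: float = 0.5,
    ridge: float = 1e-8,
) -> SpaceTimeRF:
    """Penalized least-squares RF estimate from a stimulus/response pair.

    Parameters
    ----------
    stim : SpaceTimeStimulus
        Mean-subtracted stimulus (0 = background).
    resp : ResponseTrace or array
        Response aligned to the stimulus clock (resampled by linear
        interpolation if its rate differs).
    smoothness : float or "gcv"
        Roughness penalty weight; "gcv" selects it by generalized
        cross-validation over a log-spaced grid.
    lag_span_s : float
        Temporal extent of the filter (0.5 s default).
    """
    y = _as_response_array(resp, stim)
    n_lag = max(1, int(round(lag_span_s / stim.dt)))
    n_t = stim.n_time
    if n_t <= n_lag:
        raise InsufficientDataError("response shorter than the RF lag span")
    n_x = stim.n_space
    # design matrix: X[t, x*L + l] = S[x, t - l], zero-padded before onset
    X = np.zeros((n_t, n_x * n_lag))
    S = stim.values
    for l in range(n_lag):
        X[l:, l::n_lag] = S[:, : n_t - l].T
    XtX = X.T @ X
    Xty = X.T @ y
    P = np.kron(np.eye(n_x), _second_diff_penalty(n_lag)) + np.kron(
        _second_diff_penalty(n_x), np.eye(n_lag)
    )
    # small ridge inside the penalty: the pure roughness penalty has an
    # affine null space, and shrinking to zero in the high-penalty limit
    # keeps the estimator well defined for rank-deficient designs
    P += 0.01 * max(np.trace(P) / P.shape[0], 1.0) * np.eye(P.shape[0])
    tr_xtx = np.trace(XtX)
    tr_p = max(np.trace(P), 1e-12)
    base = tr_xtx / tr_p if tr_xtx > 0 else 1.0
    reg_i = ridge * max(tr_xtx / XtX.shape[0], 1.0) * np.eye(XtX.shape[0])

    def _solve(lam: float) -> np.ndarray:
        return np.linalg.solve(XtX + lam * P + reg_i, Xty)

    if smoothness == "gcv":
        best = (np.inf, None)
        for lam in base * np.logspace(-4.0, 3.0, 8):
            A = XtX + lam * P + reg_i
            w = np.linalg.solve(A, Xty)
            df = np.trace(np.linalg.solve(A, XtX))
            rss = float(np.sum((y - X @ w) ** 2))
            denom = max(n_t - df, 1.0)
            gcv = n_t * rss / denom**2
            if gcv < best[0]:
                best = (gcv, w)
        w = best[1]
    else:
        if not np.isfinite(smoothness) or smoothness < 0:
            raise InvalidParameterError("smoothness must be non-negative or 'gcv'")
        w = _solve(float(smoothness))

    weights = w.reshape(n_x, n_lag)
    pol = +1 if weights.max() >= -weights.min() else -1
    prof = np.abs(weights).max(axis=1)
    i0 = int(np.argmax(prof))
    xi, _ = parabolic_peak(prof, i0)
    center = stim.origin_um + (xi + 0.5) * stim.dx
    return SpaceTimeRF(
        weights,
        dx=stim.dx,
        dt=stim.dt,
        origin_um=stim.origin_um,
        center_um=center,
        polarity=pol,
        label=f"rf_from_{stim.label}",
    )


def _gauss(x, a, mu, sigma):
    return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _fit_spatial_gaussian(x: np.ndarray, p: np.ndarray, i0: int) -> tuple[float, float]:
    """Gaussian (mu, sigma) fit to the central lobe of a spatial profile."""
    peak = p[i0]
    # contiguous region around the peak above 20% of it (avoids surround flanks)
    above = p > 0.2 * peak
    lo = i0
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = i0
    while hi < len(p) - 1 and above[hi + 1]:
        hi += 1
    xs, ps = x[lo : hi + 1], p[lo : hi + 1]
    dx = x[1] - x[0] if len(x) > 1 else 1.0
    w = ps / ps.sum()
    mu0 = float(np.sum(w * xs))
    sig0 = float(np.sqrt(max(np.sum(w * (xs - mu0) ** 2), (0.3 * dx) ** 2)))
    if len(xs) < 4:
        return mu0, sig0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                _gauss, xs, ps, p0=(peak, mu0, sig0), maxfev=2000
            )
        if popt[2] <= 0 or not np.isfinite(popt[1:]).all():
            return mu0, sig0
        return float(popt[1]), float(abs(popt[2]))
    except RuntimeError:
        return mu0, sig0


def _region_mask(region, x: np.ndarray) -> np.ndarray:
    if isinstance(region, np.ndarray) and region.dtype == bool:
        if len(region) != len(x):
            raise InvalidRegionError("region mask length does not match RF extent")
        return region
    lo, hi = region
    mask = (x >= lo) & (x <= hi)
    if not mask.any():
        raise InvalidRegionError("region lies outside the RF spatial extent")
    return mask


FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def extract_features(
    rf: SpaceTimeRF,
    center_region=None,
    surround_region=None,
    center_halfwidth_fwhm: float = 1.0,
    surround_inner_fwhm: float = 1.5,
    surround_outer_fwhm: float = 2.5,
) -> RFFeatures:
    """Measure latency, surround strength, biphasic index and center FWHM.

    The center temporal kernel is the spatial average of the
    polarity-corrected RF over the center region (default: within one FWHM of
    the fitted Gaussian center); the surround kernel is the average over two
    flank bands between ``surround_inner_fwhm`` and ``surround_outer_fwhm``
    FWHM from the center.  Latency is the time from
    the center kernel's peak to the surround kernel's (opposite-sign) peak;
    surround strength is the ratio of those peak magnitudes; the biphasic
    index is |max/min| of the center kernel.  All four are invariant to
    overall RF scaling.
    """
    w = rf.weights * rf.polarity
    if not (w.max() > 0) or np.ptp(w) == 0:
        raise DegenerateRFError("RF has no positive center peak")
    x = rf.space_centers_um
    i0, l0 = np.unravel_index(np.argmax(w), w.shape)
    rough = w[i0, :]
    lag_mask = rough >= 0.5 * rough.max()
    profile = w[:, lag_mask].mean(axis=1)
    mu, sigma = _fit_spatial_gaussian(x, profile, int(i0))
    fwhm = FWHM_PER_SIGMA * sigma

    if center_region is not None:
        c_mask = _region_mask(center_region, x)
    else:
        # cap the auto center half-width so flanks always remain available
        halfwidth = min(center_halfwidth_fwhm * fwhm, 0.3 * (x[-1] - x[0]))
        c_mask = np.abs(x - mu) <= halfwidth
        if not c_mask.any():
            c_mask = np.zeros(len(x), dtype=bool)
            c_mask[i0] = True
    if surround_region is not None:
        s_mask = _region_mask(surround_region, x)
        if (c_mask & s_mask).any():
            raise InvalidRegionError("center and surround regions overlap")
    else:
        d = np.abs(x - mu)
        s_mask = (d >= surround_inner_fwhm * fwhm) & (d <= surround_outer_fwhm * fwhm)
        if not s_mask.any():  # RF extent too narrow: use outer quarter flanks
            q = max(1, len(x) // 4)
            s_mask = np.zeros(len(x), dtype=bool)
            s_mask[:q] = True
            s_mask[-q:] = True
        s_mask &= ~c_mask  # auto regions never overlap the center
        if not s_mask.any():  # wide center fit: fall back to the edge bins
            s_mask = np.zeros(len(x), dtype=bool)
            s_mask[np.argmax(~c_mask)] = True
            s_mask[len(x) - 1 - np.argmax(~c_mask[::-1])] = True
            s_mask &= ~c_mask
    if not s_mask.any():
        raise InvalidRegionError("no surround region available outside the center")

    c_kernel = w[c_mask, :].mean(axis=0)
    s_kernel = w[s_mask, :].mean(axis=0)
    if not (c_kernel.max() > 0):
        raise DegenerateRFError("center temporal kernel has no positive peak")

    tc_idx = int(np.argmax(c_kernel))
    tc, c_peak = parabolic_peak(c_kernel, tc_idx)
    ts_idx = int(np.argmin(s_kernel))
    ts, s_trough = parabolic_peak(s_kernel, ts_idx)
    latency = (ts - tc) * rf.dt
    surround_strength = abs(s_trough) / c_peak if s_trough < 0 else 0.0
    c_min = c_kernel.min()
    biphasic = abs(c_kernel.max() / c_min) if c_min < 0 else np.inf
    return RFFeatures(
        latency_s=float(latency),
        surround_strength=float(surround_strength),
        biphasic_index=float(biphasic),
        fwhm_um=float(fwhm),
        center_um=float(mu),
    )


def rf_trajectory(
    rf: SpaceTimeRF,
    early_window: tuple,
    late_window: tuple,
    flat_tol: float = 1e-12,
) -> tuple[float, float]:
    """Displacement and slope of the RF peak between two lag windows.

    Finds the (space, lag) peak of the polarity-corrected RF within each lag
    window and returns ``(x2 - x1, (x2 - x1) / (t2 - t1))`` in (um, um/s),
    where window 1 is ``early_window`` (smaller lags) and window 2 is
    ``late_window``.
    """
    e0, e1 = early_window
    l0_, l1_ = late_window
    if not (0 <= e0 < e1 <= rf.lag_span_s + 1e-9 and 0 <= l0_ < l1_ <= rf.lag_span_s + 1e-9):
        raise InvalidParameterError("windows must be ordered and within the lag span")
    if max(e0, l0_) < min(e1, l1_):
        raise InvalidParameterError("early and late windows must be disjoint")
    w = rf.weights * rf.polarity
    lags = rf.lags_s

    def _peak(win):
        mask = (lags >= win[0]) & (lags < win[1])
        sub = w[:, mask]
        if sub.size == 0 or np.ptp(sub) <= flat_tol:
            raise UndefinedPeakError("RF is flat within the requested window")
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        xi, _ = parabolic_peak(sub[:, j], int(i))
        tj, _ = parabolic_peak(sub[i, :], int(j))
        x_um = rf.origin_um + (xi + 0.5) * rf.dx
        t_s = lags[mask][0] + tj * rf.dt
        return x_um, t_s

    x1, t1 = _peak(early_window)
    x2, t2 = _peak(late_window)
    if t2 == t1:
        raise UndefinedPeakError("peak times coincide; velocity undefined")
    delta = x2 - x1
    return float(delta), float(delta / (t2 - t1))
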