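"""Linear convolution model of motion responses and its preference statistics.

The response of a cell with space-time RF W to a stimulus S is modeled
linearly: each spatial bin's lag kernel is convolved with that bin's stimulus
time course and the results are summed over space,

    r(t) = sum_x sum_tau W[x, tau] * S[x, t - tau],

causal in t (no output nonlinearity; rectification exists only in the
amacrine-cell input pathway, see :mod:`bcmotion.sac`).  Predictions extend one
lag span beyond the stimulus offset so responses still developing when the
stimulus ends (e.g. to a bar arriving at the RF center) are not truncated.  On this prediction the
module computes the preference index between stimulus pairs,
``(peak1 - peak2) / (peak1 + peak2)``, radial direction-selectivity tuning
across velocities, center/surround decompositions, surround-scaling
manipulations, and the coherence scan relating motion coherence of random bar
sequences to predicted response amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .errors import (
    GridMismatchError,
    InvalidParameterError,
    InvalidRegionError,
    UndefinedCorrelationError,
    UndefinedIndexError,
)
from .rf import SpaceTimeRF, _fit_spatial_gaussian, FWHM_PER_SIGMA
from .stimuli import (
    SequenceOrder,
    SpaceTimeStimulus,
    make_apparent_sequence,
    make_looming,
    make_moving_bar,
    motion_coherence,
)

__all__ = [
    "PredictedResponse",
    "VelocityTuning",
    "conv_predict",
    "preference_index",
    "rds_tuning",
    "scale_surround",
    "decompose_center_surround",
    "validate_prediction",
    "coherence_scan",
]

PAIRINGS = ("originate_vs_terminate", "left_vs_right", "loom_vs_recede", "motion_vs_random")


@dataclass
class PredictedResponse:
    """Modeled response trace: values over time at the stimulus dt."""

    values: np.ndarray
    dt: float
    stim_label: str = ""
    rf_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("predicted response must be finite")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.dt


@dataclass
class VelocityTuning:
    """Preference index per velocity for one stimulus pairing."""

    velocities_um_s: np.ndarray
    preference: np.ndarray
    pairing: str


def _resample_rf_grid(rf: SpaceTimeRF, dx: float, dt: float) -> SpaceTimeRF:
    """Interpolate an RF onto new bin sizes, conserving the kernel integral."""
    w = rf.weights
    if abs(rf.dt - dt) > 1e-12 * max(rf.dt, dt):
        old_l = rf.lags_s
        new_l = np.arange(0.0, rf.lag_span_s - 1e-12, dt)
        w = np.stack([np.interp(new_l, old_l, row) for row in w]) * (dt / rf.dt)
    if abs(rf.dx - dx) > 1e-12 * max(rf.dx, dx):
        old_x = rf.space_centers_um
        span = rf.n_space * rf.dx
        n_new = max(1, int(round(span / dx)))
        new_x = rf.origin_um + (np.arange(n_new) + 0.5) * dx
        w = np.stack(
            [np.interp(new_x, old_x, col, left=0.0, right=0.0) for col in w.T]
        ).T * (dx / rf.dx)
    return SpaceTimeRF(
        w,
        dx=dx,
        dt=dt,
        origin_um=rf.origin_um,
        center_um=rf.center_um,
        polarity=rf.polarity,
        ipl_depth=rf.ipl_depth,
        label=rf.label,
    )


def conv_predict(
    rf: SpaceTimeRF, stim: SpaceTimeStimulus, resample: bool = True
) -> PredictedResponse:
    """Predict the response to ``stim`` by space-summed temporal convolution.

    The RF and stimulus grids must share dx/dt and be spatially aligned (the
    origin offset an integer number of bins); with ``resample=True`` the RF is
    linearly interpolated onto the stimulus bin sizes first (conserving the
    kernel integral).  Stimulus bins outside the RF extent contribute nothing,
    and the stimulus is implicitly zero before onset and after offset, so the
    output at time t only uses stimulus at times <= t and runs one lag span
    past the stimulus end (length ``n_time + n_lag - 1``).
    """
    if abs(rf.dx - stim.dx) > 1e-9 * stim.dx or abs(rf.dt - stim.dt) > 1e-12:
        if not resample:
            raise GridMismatchError("RF and stimulus bin sizes differ")
        rf = _resample_rf_grid(rf, stim.dx, stim.dt)
    off = (rf.origin_um - stim.origin_um) / stim.dx
    if abs(off - round(off)) > 1e-6:
        if not resample:
            raise GridMismatchError("RF and stimulus spatial grids are not aligned")
        # snap to the nearest stimulus column (at most dx/2 positional error)
    off = int(round(off))
    # overlap of rf rows [0, n_rf) mapped onto stim rows [off, off + n_rf)
    r_lo = max(0, -off)
    r_hi = min(rf.n_space, stim.n_space - off)
    n_out = stim.n_time + rf.n_lag - 1
    if r_hi <= r_lo:
        return PredictedResponse(np.zeros(n_out), stim.dt, stim.label, rf.label)
    W = rf.weights[r_lo:r_hi]
    S = stim.values[off + r_lo : off + r_hi]
    full = signal.fftconvolve(S, W, mode="full", axes=1)
    vals = full.sum(axis=0)
    return PredictedResponse(vals, stim.dt, stim.label, rf.label)


def _peak(resp, polarity: int = +1) -> float:
    vals = resp.values if isinstance(resp, PredictedResponse) else np.asarray(resp)
    if vals.size == 0:
        raise InvalidParameterError("response is empty")
    return float(max(np.max(polarity * vals), 0.0))


def preference_index(resp1, resp2, polarity: int = +1) -> float:
    """(peak1 - peak2) / (peak1 + peak2), peaks taken as the max over time.

    Peaks are floored at zero (a fully suppressed modeled response counts as
    no response), which keeps the index in [-1, +1].  Off-cell responses
    should be passed with ``polarity=-1`` so peaks are measured on the
    polarity-corrected (depolarizing) trace.
    """
    p1, p2 = _peak(resp1, polarity), _peak(resp2, polarity)
    if p1 + p2 == 0:
        raise UndefinedIndexError("preference undefined: both peaks are zero")
    return float((p1 - p2) / (p1 + p2))


def _rf_extent(rf: SpaceTimeRF) -> tuple:
    return (rf.origin_um, rf.origin_um + rf.n_space * rf.dx)


def _stimulus_pair(
    rf: SpaceTimeRF,
    velocity: float,
    pairing: str,
    travel_um: float,
    bar_width_um: float,
    dt: float,
    seed: int,
    n_bars: int,
    pitch_um: float,
):
    extent = _rf_extent(rf)
    c = rf.center_um
    if pairing == "originate_vs_terminate":
        # bar body starts centered on the RF center and moves out;
        # 'terminates' is the exact space-time mirror over the same footprint
        s1 = make_moving_bar(bar_width_um, velocity, travel_um, +1,
                             c + bar_width_um / 2, rf.dx, dt,
                             extent_um=extent, label="originates")
        s2 = make_moving_bar(bar_width_um, velocity, travel_um, -1,
                             c + travel_um - bar_width_um / 2, rf.dx, dt,
                             extent_um=extent, label="terminates")
    elif pairing == "left_vs_right":
        s1 = make_moving_bar(bar_width_um, velocity, 2 * travel_um, +1, c - travel_um,
                             rf.dx, dt, extent_um=extent, label="right")
        s2 = make_moving_bar(bar_width_um, velocity, 2 * travel_um, -1, c + travel_um,
                             rf.dx, dt, extent_um=extent, label="left")
    elif pairing == "loom_vs_recede":
        s1 = make_looming(10.0, 2 * travel_um, velocity, rf.dx, dt, "loom",
                          center_um=c, extent_um=extent)
        s2 = make_looming(10.0, 2 * travel_um, velocity, rf.dx, dt, "recede",
                          center_um=c, extent_um=extent)
    elif pairing == "motion_vs_random":
        dwell = pitch_um / velocity
        ordered = SequenceOrder(tuple(range(n_bars)), pitch_um, dwell)
        rng = np.random.default_rng(seed)
        rand = SequenceOrder(tuple(rng.permutation(n_bars)), pitch_um, dwell)
        origin = c - bar_width_um / 2.0
        s1 = make_apparent_sequence(ordered, n_bars, bar_width_um, rf.dx, dt,
                                    origin_um=origin, extent_um=extent)
        s2 = make_apparent_sequence(rand, n_bars, bar_width_um, rf.dx, dt,
                                    origin_um=origin, extent_um=extent)
    else:
        raise InvalidParameterError(f"unknown pairing {pairing!r}; use one of {PAIRINGS}")
    return s1, s2


def rds_tuning(
    rf: SpaceTimeRF,
    velocities,
    pairing: str = "originate_vs_terminate",
    travel_um: float = 100.0,
    bar_width_um: float = 20.0,
    dt: float = 1e-3,
    seed: int = 0,
    n_bars: int = 7,
    pitch_um: float = 20.0,
) -> VelocityTuning:
    """Preference index as a function of stimulus velocity.

    For each velocity a stimulus pair is generated anchored to the RF center:
    'originates' starts with the bar's leading edge at the center and moves
    outward over ``travel_um``; 'terminates' starts in the surround and moves
    to the center; pass-through pairs span surround-center-surround; looming
    pairs expand/contract about the center; motion_vs_random compares the
    ordered bar sequence to a seeded random order at matched apparent velocity.
    """
    velocities = np.asarray(velocities, dtype=float)
    if velocities.size == 0:
        raise InvalidParameterError("velocity list must be non-empty")
    if np.any(velocities <= 0):
        raise InvalidParameterError("velocities must be positive")
    prefs = []
    for v in velocities:
        s1, s2 = _stimulus_pair(rf, float(v), pairing, travel_um, bar_width_um,
                                dt, seed, n_bars, pitch_um)
        prefs.append(
            preference_index(conv_predict(rf, s1), conv_predict(rf, s2), rf.polarity)
        )
    return VelocityTuning(velocities, np.asarray(prefs), pairing)


def scale_surround(rf: SpaceTimeRF, factor: float) -> SpaceTimeRF:
    """Scale the RF's surround by multiplying all values of polarity opposite
    to the center (negative for On, positive for Off) by ``factor``.

    Center-polarity values are untouched; ``factor=1`` is the identity and
    ``factor=0`` removes the surround (and any opposite-sign rebound).
    """
    if factor < 0:
        raise InvalidParameterError("surround factor must be non-negative")
    w = rf.weights.copy()
    mask = (w * rf.polarity) < 0
    w[mask] *= factor
    return rf.copy(weights=w, label=f"{rf.label}_surx{factor:g}")


def _center_mask(rf: SpaceTimeRF, center_halfwidth_fwhm: float) -> np.ndarray:
    w = rf.weights * rf.polarity
    x = rf.space_centers_um
    i0, _ = np.unravel_index(np.argmax(w), w.shape)
    rough = w[int(i0), :]
    profile = w[:, rough >= 0.5 * rough.max()].mean(axis=1)
    mu, sigma = _fit_spatial_gaussian(x, profile, int(i0))
    mask = np.abs(x - mu) <= center_halfwidth_fwhm * FWHM_PER_SIGMA * sigma
    if not mask.any():
        mask = np.zeros(len(x), dtype=bool)
        mask[int(i0)] = True
    return mask


def decompose_center_surround(
    rf: SpaceTimeRF,
    stim: SpaceTimeStimulus,
    center_region=None,
    surround_region=None,
    center_halfwidth_fwhm: float = 1.0,
) -> tuple[PredictedResponse, PredictedResponse]:
    """Split the convolution prediction into center and surround contributions.

    Space is partitioned into the center region (default: within one FWHM of
    the fitted spatial center) and its complement; the two masked RFs are
    convolved separately.  By linearity the two traces sum exactly to the full
    prediction when the regions partition space.
    """
    x = rf.space_centers_um
    if center_region is None:
        c_mask = _center_mask(rf, center_halfwidth_fwhm)
    else:
        lo, hi = center_region
        c_mask = (x >= lo) & (x <= hi)
    if surround_region is None:
        s_mask = ~c_mask
    else:
        lo, hi = surround_region
        s_mask = (x >= lo) & (x <= hi)
    if (c_mask & s_mask).any():
        raise InvalidRegionError("center and surround regions overlap")
    wc, ws = rf.weights.copy(), rf.weights.copy()
    wc[~c_mask, :] = 0.0
    ws[~s_mask, :] = 0.0
    center = conv_predict(rf.copy(weights=wc, label=rf.label + "_center"), stim)
    surround = conv_predict(rf.copy(weights=ws, label=rf.label + "_surround"), stim)
    return center, surround


def validate_prediction(pred: PredictedResponse, observed) -> float:
    """Pearson correlation between a prediction and an observed response.

    ``observed`` may be a SmoothedResponse (mean + time grid) or a plain
    array on the prediction's grid; it is linearly resampled onto the
    prediction's time base first.
    """
    if hasattr(observed, "mean") and hasattr(observed, "times_s"):
        obs = np.interp(pred.times_s, observed.times_s, observed.mean)
    else:
        obs = np.asarray(observed, dtype=float)
        if len(obs) != len(pred.values):
            raise GridMismatchError("observed response length does not match prediction")
    if np.std(pred.values) == 0 or np.std(obs) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    r, _ = stats.pearsonr(pred.values, obs)
    return float(r)


def coherence_scan(
    rf: SpaceTimeRF,
    n_orders: int = 200,
    seed: int = 0,
    velocity_um_s: float = 600.0,
    n_bars: int = 7,
    pitch_um: float = 20.0,
    bar_width_um: float = 20.0,
    dt: float = 1e-3,
    include_ordered: bool = True,
) -> pd.DataFrame:
    """Predicted peak amplitude vs. motion coherence over random bar orders.

    Draws ``n_orders`` random orderings of ``n_bars`` bars anchored at the RF
    center, convolves each with the RF at the given apparent velocity, and
    returns a table with columns ``k`` (motion coherence), ``peak`` and
    ``ordered`` (True for the perfectly ordered sequence, included once when
    ``include_ordered``).
    """
    rng = np.random.default_rng(seed)
    dwell = pitch_um / velocity_um_s
    origin = rf.center_um - bar_width_um / 2.0
    extent = _rf_extent(rf)
    rows = []

    def _eval(order: SequenceOrder, ordered: bool):
        stim = make_apparent_sequence(order, n_bars, bar_width_um, rf.dx, dt,
                                      origin_um=origin, extent_um=extent)
        rows.append(
            dict(
                k=motion_coherence(order),
                peak=_peak(conv_predict(rf, stim), rf.polarity),
                ordered=ordered,
            )
        )

    if include_ordered:
        _eval(SequenceOrder(tuple(range(n_bars)), pitch_um, dwell), True)
    for _ in range(n_orders):
        _eval(SequenceOrder(tuple(rng.permutation(n_bars)), pitch_um, dwell), False)
    return pd.DataFrame(rows)
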