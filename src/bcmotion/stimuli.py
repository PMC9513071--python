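"""Space-time visual stimuli on a single spatial axis.

All stimuli are contrast fields S(x, t) in [-1, +1] with 0 equal to the mean
(background) luminance, sampled on a regular grid: space bin ``i`` is centered
at ``origin_um + (i + 0.5) * dx`` and time bin ``j`` covers the half-open
interval ``[j * dt, (j + 1) * dt)``.  A bin is lit when its *center* lies under
the object (center sampling, no anti-aliasing), which keeps frame-by-frame
oracles exact.

The module also provides the motion-coherence index ``k`` of bar-sequence
stimuli: ``k = (sum |x_j - x_i| - s_max) / (s_min - s_max)`` where the sum runs
over temporally adjacent bar positions and ``s_min``/``s_max`` are the extreme
adjacent-distance sums over all orderings of the same positions, so that
perfect apparent motion has k = 1 and the least coherent ordering has k = 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError, UndefinedIndexError

__all__ = [
    "SpaceTimeStimulus",
    "SequenceOrder",
    "make_moving_bar",
    "make_1d_noise",
    "make_looming",
    "make_apparent_sequence",
    "motion_coherence",
    "adjacent_distance_sum",
    "extreme_adjacent_sums",
    "least_coherent_order",
    "most_coherent_order",
    "apparent_velocity",
]


@dataclass
class SpaceTimeStimulus:
    """A 1-D contrast movie over (space, time).

    Parameters
    ----------
    values : ndarray, shape (n_space, n_time)
        Contrast, dimensionless in [-1, +1]; 0 is the mean luminance.
    dx : float
        Spatial bin size in micrometres.
    dt : float
        Temporal bin size in seconds.
    origin_um : float
        Physical coordinate of the left edge of space bin 0.
    label : str
        Free-text stimulus name.
    """

    values: np.ndarray
    dx: float
    dt: float
    origin_um: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise InvalidParameterError("stimulus values must be a non-empty 2-D array")
        if not (self.dx > 0 and self.dt > 0):
            raise InvalidParameterError("dx and dt must be positive")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("stimulus values must be finite")
        if np.abs(self.values).max() > 1.0 + 1e-12:
            raise InvalidParameterError("stimulus contrast must lie in [-1, +1]")

    @property
    def n_space(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_time * self.dt

    @property
    def space_centers_um(self) -> np.ndarray:
        return self.origin_um + (np.arange(self.n_space) + 0.5) * self.dx

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_time) * self.dt


@dataclass(frozen=True)
class SequenceOrder:
    """Temporal ordering of bars in an apparent-motion / random sequence.

    ``positions`` are integer bar indices presented one per dwell period; bar
    ``i`` sits at spatial position ``i * pitch_um``.
    """

    positions: tuple
    pitch_um: float = 20.0
    dwell_s: float = 1.0 / 30.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", tuple(int(p) for p in self.positions))
        if len(self.positions) == 0:
            raise InvalidParameterError("sequence must contain at least one position")
        if len(set(self.positions)) != len(self.positions):
            raise InvalidParameterError("sequence positions must be distinct")
        if min(self.positions) < 0:
            raise InvalidParameterError("sequence positions must be non-negative")
        if not (self.pitch_um > 0 and self.dwell_s > 0):
            raise InvalidParameterError("pitch_um and dwell_s must be positive")

    @property
    def x_um(self) -> np.ndarray:
        """Physical bar positions, in temporal order."""
        return np.asarray(self.positions, dtype=float) * self.pitch_um


def _space_grid(lo: float, hi: float, dx: float) -> tuple[float, int]:
    n = max(1, int(np.ceil((hi - lo) / dx - 1e-9)))
    return lo, n


def make_moving_bar(
    width_um: float = 20.0,
    speed_um_s: float = 500.0,
    distance_um: float = 100.0,
    direction: int = +1,
    start_um: float = 0.0,
    dx: float = 1.0,
    dt: float = 1e-3,
    extent_um: tuple | None = None,
    label: str | None = None,
) -> SpaceTimeStimulus:
    """Bright bar translating at constant speed.

    The bar's *leading edge* is at ``start_um + direction * speed_um_s * t``;
    the bar occupies the ``width_um`` behind it.  Duration is
    ``distance_um / speed_um_s``; background is 0, the bar is +1.

    ``extent_um = (lo, hi)`` fixes the spatial grid; by default the grid covers
    exactly the bar's footprint over the whole trajectory.
    """
    if not (width_um > 0 and speed_um_s > 0 and distance_um > 0):
        raise InvalidParameterError("width, speed and distance must be positive")
    if direction not in (+1, -1):
        raise InvalidParameterError("direction must be +1 or -1")
    duration = distance_um / speed_um_s
    n_time = max(1, int(round(duration / dt)))
    if extent_um is None:
        if direction == +1:
            extent_um = (start_um - width_um, start_um + distance_um)
        else:
            extent_um = (start_um - distance_um, start_um + width_um)
    origin, n_space = _space_grid(extent_um[0], extent_um[1], dx)
    x = origin + (np.arange(n_space) + 0.5) * dx
    t = np.arange(n_time) * dt
    lead = start_um + direction * speed_um_s * t  # (n_time,)
    # lit where direction * (lead - x) in (0, width]
    d = direction * (lead[None, :] - x[:, None])
    values = ((d > 0) & (d <= width_um)).astype(float)
    if label is None:
        label = f"bar_v{speed_um_s:g}_dir{direction:+d}"
    return SpaceTimeStimulus(values, dx=dx, dt=dt, origin_um=origin, label=label)


def make_1d_noise(
    n_bars: int = 20,
    bar_w_um: float = 20.0,
    rate_hz: float = 20.0,
    duration_s: float = 5.0,
    seed: int = 0,
    dt: float | None = None,
) -> SpaceTimeStimulus:
    """Binary dense noise: ``n_bars`` adjacent bars flipping at ``rate_hz``.

    Each bar independently takes contrast -1 or +1 (100% contrast), redrawn at
    ``rate_hz``.  The spatial grid has one bin per bar (dx = bar width); pass
    ``dt`` to subdivide the 1/rate_hz frames into finer time bins.
    Reproducible under ``seed``.
    """
    if not (n_bars >= 1 and bar_w_um > 0 and rate_hz > 0 and duration_s > 0):
        raise InvalidParameterError("noise stimulus parameters must be positive")
    rng = np.random.default_rng(seed)
    n_frames = max(1, int(round(duration_s * rate_hz)))
    frames = rng.integers(0, 2, size=(n_bars, n_frames)) * 2.0 - 1.0
    if dt is None:
        dt = 1.0 / rate_hz
        values = frames
    else:
        sub = max(1, int(round((1.0 / rate_hz) / dt)))
        dt = (1.0 / rate_hz) / sub
        values = np.repeat(frames, sub, axis=1)
    return SpaceTimeStimulus(
        values, dx=bar_w_um, dt=dt, origin_um=0.0, label=f"noise1d_seed{seed}"
    )


def make_looming(
    start_diam_um: float = 10.0,
    end_diam_um: float = 600.0,
    expansion_um_s: float = 800.0,
    dx: float = 1.0,
    dt: float = 1e-3,
    mode: str = "loom",
    center_um: float = 0.0,
    extent_um: tuple | None = None,
    rate_convention: str = "diameter",
) -> SpaceTimeStimulus:
    """1-D section through an expanding (looming) or shrinking (receding) spot.

    ``expansion_um_s`` is by default the rate of *diameter* growth (each edge
    moves at half that speed); set ``rate_convention='edge'`` to apply it per
    edge instead.  ``recede`` is the exact time reverse of ``loom``.
    """
    if not end_diam_um > start_diam_um:
        raise InvalidParameterError("end diameter must exceed start diameter")
    if expansion_um_s <= 0:
        raise InvalidParameterError("expansion rate must be positive")
    if mode not in ("loom", "recede"):
        raise InvalidParameterError("mode must be 'loom' or 'recede'")
    if rate_convention == "diameter":
        diam_rate = expansion_um_s
    elif rate_convention == "edge":
        diam_rate = 2.0 * expansion_um_s
    else:
        raise InvalidParameterError("rate_convention must be 'diameter' or 'edge'")
    duration = (end_diam_um - start_diam_um) / diam_rate
    n_time = max(1, int(round(duration / dt)))
    if extent_um is None:
        extent_um = (center_um - end_diam_um / 2, center_um + end_diam_um / 2)
    origin, n_space = _space_grid(extent_um[0], extent_um[1], dx)
    x = origin + (np.arange(n_space) + 0.5) * dx
    t = np.arange(n_time) * dt
    diam = start_diam_um + diam_rate * t
    values = (np.abs(x[:, None] - center_um) < diam[None, :] / 2).astype(float)
    if mode == "recede":
        values = values[:, ::-1].copy()
    return SpaceTimeStimulus(
        values, dx=dx, dt=dt, origin_um=origin, label=f"{mode}_{expansion_um_s:g}"
    )


def make_apparent_sequence(
    order: SequenceOrder,
    n_bars: int = 7,
    bar_w_um: float = 20.0,
    dx: float = 1.0,
    dt: float = 1e-3,
    origin_um: float = 0.0,
    extent_um: tuple | None = None,
) -> SpaceTimeStimulus:
    """Sequence of flashed bars (apparent motion / random order).

    Bar ``i`` occupies ``[origin + i * pitch, origin + i * pitch + bar_w)``.
    During the s-th dwell period exactly ``order.positions[s]`` is lit (+1).
    ``dt`` is adjusted to an integer divisor of the dwell so each bar is lit
    for exactly ``dwell_s``.
    """
    if max(order.positions) >= n_bars:
        raise InvalidParameterError("sequence positions must index into the bar array")
    bins_per_dwell = max(1, int(round(order.dwell_s / dt)))
    dt = order.dwell_s / bins_per_dwell
    if extent_um is None:
        extent_um = (origin_um, origin_um + (n_bars - 1) * order.pitch_um + bar_w_um)
    grid_origin, n_space = _space_grid(extent_um[0], extent_um[1], dx)
    x = grid_origin + (np.arange(n_space) + 0.5) * dx
    n_time = len(order.positions) * bins_per_dwell
    values = np.zeros((n_space, n_time))
    for s, idx in enumerate(order.positions):
        lo = origin_um + idx * order.pitch_um
        mask = (x >= lo) & (x < lo + bar_w_um)
        values[mask, s * bins_per_dwell : (s + 1) * bins_per_dwell] = 1.0
    return SpaceTimeStimulus(
        values, dx=dx, dt=dt, origin_um=grid_origin, label="sequence"
    )


def adjacent_distance_sum(x_um) -> float:
    """Sum of |x_(s+1) - x_s| over temporally adjacent bar positions."""
    x = np.asarray(x_um, dtype=float)
    return float(np.abs(np.diff(x)).sum())


_MAX_EXHAUSTIVE = 9


def extreme_adjacent_sums(x_um) -> tuple[float, float]:
    """(s_min, s_max): extreme adjacent-distance sums over all orderings.

    Found by exhaustive search over permutations (n <= 9; 7 positions give
    5040 orderings).
    """
    x = tuple(float(v) for v in x_um)
    if len(x) > _MAX_EXHAUSTIVE:
        raise InvalidParameterError(
            f"exhaustive ordering search supports at most {_MAX_EXHAUSTIVE} positions"
        )
    s_min, s_max = np.inf, -np.inf
    for perm in itertools.permutations(x):
        s = adjacent_distance_sum(perm)
        if s < s_min:
            s_min = s
        if s > s_max:
            s_max = s
    return float(s_min), float(s_max)


def _extreme_order(positions, pick_max: bool) -> tuple:
    best, best_s = None, None
    for perm in itertools.permutations(positions):
        s = adjacent_distance_sum(np.asarray(perm, dtype=float))
        if best is None or (s > best_s if pick_max else s < best_s):
            best, best_s = perm, s
    return tuple(best)


def least_coherent_order(order: SequenceOrder) -> SequenceOrder:
    """The ordering of the same bars maximizing the adjacent-distance sum (k = 0)."""
    if len(order.positions) > _MAX_EXHAUSTIVE:
        raise InvalidParameterError("exhaustive search supports at most 9 positions")
    perm = _extreme_order(order.positions, pick_max=True)
    return SequenceOrder(perm, pitch_um=order.pitch_um, dwell_s=order.dwell_s)


def most_coherent_order(order: SequenceOrder) -> SequenceOrder:
    """The ordering of the same bars minimizing the adjacent-distance sum (k = 1)."""
    if len(order.positions) > _MAX_EXHAUSTIVE:
        raise InvalidParameterError("exhaustive search supports at most 9 positions")
    perm = _extreme_order(order.positions, pick_max=False)
    return SequenceOrder(perm, pitch_um=order.pitch_um, dwell_s=order.dwell_s)


def motion_coherence(order: SequenceOrder) -> float:
    """Motion-coherence index k in [0, 1] of a bar sequence.

    k = (sum |x_j - x_i| - s_max) / (s_min - s_max); a perfect apparent-motion
    sequence has k = 1, the least coherent possible ordering k = 0.  If every
    ordering has the same adjacent sum (n = 2), k is defined as 1.
    """
    if len(order.positions) < 2:
        raise UndefinedIndexError("motion coherence needs at least 2 positions")
    s = adjacent_distance_sum(order.x_um)
    s_min, s_max = extreme_adjacent_sums(order.x_um)
    if s_max == s_min:
        return 1.0
    return float((s - s_max) / (s_min - s_max))


def apparent_velocity(pitch_um: float, dwell_s: float) -> float:
    """Apparent speed of a bar sequence: pitch / dwell (um/s)."""
    if dwell_s <= 0:
        raise InvalidParameterError("dwell_s must be positive")
    if pitch_um < 0:
        raise InvalidParameterError("pitch_um must be non-negative")
    return pitch_um / dwell_s
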