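"""Ball-and-stick starburst amacrine cell (SAC) dendrite model.

An iso-potential soma (7 um sphere) is coupled to a 150 um dendrite (first
10 um at 0.4 um diameter, the rest 0.2 um), discretized into 1 um
compartments.  Each compartment carries a leak conductance (R_m, E_L) and
membrane capacitance (C_m); compartments in the distal third additionally
carry a voltage-gated Ca2+ conductance, I_Ca = g_Ca_max * m^2 * (V - E_Ca),
with first-order Boltzmann gating (the gating kinetics are not constrained by
measurements in this preparation; they are configurable defaults and no
reported quantity depends on their exact values).  Intracellular Ca2+ follows

    d[Ca]/dt = -gamma_Ca * I_Ca - ([Ca] - Ca_0) / tau_Ca

per compartment.  Bipolar-cell (BC) input is mapped onto the dendrite from a
synapse-density profile and a type layout; each synapse injects a rectified,
scaled copy of its BC's convolution-model response as current.  The cable
equation is integrated with an unconditionally stable backward-Euler step
(dt = 0.1 ms), with exponential updates for gating and Ca2+.

Direction selectivity is quantified per distal compartment as
DSI = (CF - CP) / (CF + CP), where CF and CP are the peak depolarizations
above rest for centrifugal (soma->tip) and centripetal (tip->soma) bar
motion; the tuning curves report the mean over distal compartments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

from .errors import (
    CalibrationError,
    ConfigError,
    InvalidParameterError,
    NumericalInstabilityError,
    UndefinedIndexError,
)
from .motion import conv_predict, scale_surround
from .rf import SpaceTimeRF, recenter
from .stimuli import SpaceTimeStimulus, make_moving_bar
from . import synth

__all__ = [
    "SACConfig",
    "SynapseMap",
    "DriveSet",
    "SACSimResult",
    "SACModelBundle",
    "condition_rf",
    "mirror_rf",
    "build_synapse_map",
    "bc_drive",
    "calibrate_scale",
    "resting_state",
    "simulate",
    "dsi",
    "run_protocol",
    "default_bundle",
]

PATH_VARIANTS = {
    "single_dendrite": (0.0, 150.0),
    "cell_diameter": (-150.0, 150.0),
    "cell_surround": (0.0, 250.0),
}
WIRING_MODES = ("original", "all_proximal", "all_distal", "swapped")


@dataclass
class SACConfig:
    """Biophysical and numerical parameters of the SAC dendrite model.

    Electrical and Ca2+ constants follow the model parameter table; the Ca
    channel gating numbers (half-activation, slope, gating time constant,
    exponent) are package defaults, configurable and not taken from
    measurements.
    """

    r_i_ohm_cm: float = 150.0
    r_m_ohm_cm2: float = 21_700.0
    c_m_uf_cm2: float = 1.0
    e_leak_mv: float = -54.4
    e_ca_mv: float = 120.0
    g_ca_max_ms_mm2: float = 0.013
    ca_rest_nm: float = 50.0
    tau_ca_ms: float = 5.0
    gamma_ca_m_per_nc: float = 20.0
    dt_ms: float = 0.1
    soma_diam_um: float = 7.0
    dendrite_len_um: float = 150.0
    proximal_len_um: float = 10.0
    proximal_diam_um: float = 0.4
    distal_diam_um: float = 0.2
    comp_len_um: float = 1.0
    ca_region_fraction: float = 1.0 / 3.0  # distal third carries Ca channels
    ca_half_mv: float = -15.0
    ca_slope_mv: float = 10.0
    ca_tau_gate_ms: float = 1.0
    ca_gate_power: int = 2
    include_soma: bool = True
    uniform_diam_um: float | None = None  # overrides both diameters (analytics)
    g_ca_scale: float = 1.0  # 0 disables Ca channels (passive model)

    def __post_init__(self) -> None:
        for name in ("r_i_ohm_cm", "r_m_ohm_cm2", "c_m_uf_cm2", "dt_ms",
                     "soma_diam_um", "dendrite_len_um", "proximal_diam_um",
                     "distal_diam_um", "comp_len_um", "tau_ca_ms"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if not self.proximal_len_um < self.dendrite_len_um:
            raise InvalidParameterError("proximal_len_um must be < dendrite_len_um")


@dataclass
class _Compartments:
    positions_um: np.ndarray  # dendritic position of each compartment (soma < 0)
    c_nf: np.ndarray
    g_leak_us: np.ndarray
    g_axial_us: np.ndarray  # between compartment i and i+1
    g_ca_us: np.ndarray  # max Ca conductance per compartment (0 outside region)
    soma_index: int | None


def _build_compartments(cfg: SACConfig) -> _Compartments:
    n_den = max(2, int(round(cfg.dendrite_len_um / cfg.comp_len_um)))
    l_cm = cfg.comp_len_um * 1e-4
    pos = (np.arange(n_den) + 0.5) * cfg.comp_len_um
    if cfg.uniform_diam_um is not None:
        diam = np.full(n_den, cfg.uniform_diam_um)
    else:
        diam = np.where(pos < cfg.proximal_len_um, cfg.proximal_diam_um,
                        cfg.distal_diam_um)
    area = np.pi * (diam * 1e-4) * l_cm  # lateral cylinder area, cm^2
    if cfg.include_soma:
        soma_area = np.pi * (cfg.soma_diam_um * 1e-4) ** 2  # sphere
        area = np.concatenate([[soma_area], area])
        diam = np.concatenate([[cfg.soma_diam_um], diam])
        pos = np.concatenate([[-cfg.soma_diam_um / 2], pos])
        soma_index = 0
    else:
        soma_index = None
    c_nf = cfg.c_m_uf_cm2 * area * 1e3
    g_leak = area / cfg.r_m_ohm_cm2 * 1e6  # uS

    # axial conductances between neighbours (half-compartment resistances)
    n = len(area)
    radii_cm = diam * 1e-4 / 2
    half_r = cfg.r_i_ohm_cm * (l_cm / 2) / (np.pi * radii_cm**2)
    if cfg.include_soma:
        half_r[0] = 0.0  # iso-potential soma contributes no axial resistance
    r_pair = half_r[:-1] + half_r[1:]
    g_axial = 1e6 / r_pair  # uS

    # Ca channels in the distal region of the dendrite only
    g_ca = np.zeros(n)
    ca_from = cfg.dendrite_len_um * (1.0 - cfg.ca_region_fraction)
    dend_mask = pos >= ca_from
    area_mm2 = area * 100.0
    g_ca[dend_mask] = cfg.g_ca_max_ms_mm2 * cfg.g_ca_scale * area_mm2[dend_mask] * 1e3
    if cfg.include_soma:
        g_ca[0] = 0.0
    return _Compartments(pos, c_nf, g_leak, g_axial, g_ca, soma_index)


def _m_inf(v_mv: np.ndarray, cfg: SACConfig) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(v_mv - cfg.ca_half_mv) / cfg.ca_slope_mv))


@dataclass
class SynapseMap:
    """BC synapses along the dendrite: position, type identity, count."""

    positions_um: np.ndarray
    identities: list
    counts: np.ndarray
    mode: str = "original"

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if not (len(self.positions_um) == len(self.identities) == len(self.counts)):
            raise InvalidParameterError("synapse map fields must have equal length")
        if np.any(self.counts < 1):
            raise InvalidParameterError("n_synapses must be >= 1")

    @property
    def total_synapses(self) -> int:
        return int(self.counts.sum())


DEFAULT_TYPE_LAYOUT = (("proximal", 0.0, 50.0), ("distal", 50.0, 150.0))


def _layout_identity(layout, pos: float, dendrite_len: float) -> str:
    for label, lo, hi in layout:
        if lo <= pos < hi or (pos >= dendrite_len and hi >= dendrite_len):
            return label
    raise ConfigError(f"type layout does not cover position {pos:g} um")


def build_synapse_map(
    density_per_10um=None,
    type_layout=DEFAULT_TYPE_LAYOUT,
    mode: str = "original",
    dendrite_len_um: float = 150.0,
    seg_um: float = 10.0,
) -> SynapseMap:
    """Place BC synapses along the dendrite from a per-segment density.

    ``density_per_10um`` gives the synapse count in each ``seg_um`` segment
    (default: uniform, 2 per 10 um segment).  ``type_layout`` assigns a BC
    type label to each dendritic interval.  Wiring manipulations keep every
    position and count and only relabel identities: ``all_proximal`` /
    ``all_distal`` assign the type found at the soma / tip end everywhere;
    ``swapped`` exchanges the proximal and distal type labels at every
    position (an involution).
    """
    if mode not in WIRING_MODES:
        raise ConfigError(f"unknown wiring mode {mode!r}; use one of {WIRING_MODES}")
    n_seg = int(round(dendrite_len_um / seg_um))
    if density_per_10um is None:
        density_per_10um = [2] * n_seg
    if len(density_per_10um) != n_seg:
        raise ConfigError(
            f"density profile must cover [0, {dendrite_len_um:g}] um "
            f"({n_seg} segments of {seg_um:g} um)"
        )
    positions, identities = [], []
    for s, n_syn in enumerate(density_per_10um):
        a = s * seg_um
        for i in range(int(n_syn)):
            p = a + seg_um * (i + 0.5) / int(n_syn)
            positions.append(p)
            identities.append(_layout_identity(type_layout, p, dendrite_len_um))
    positions = np.asarray(positions)
    if mode == "all_proximal":
        lbl = _layout_identity(type_layout, 0.0, dendrite_len_um)
        identities = [lbl] * len(positions)
    elif mode == "all_distal":
        lbl = _layout_identity(type_layout, dendrite_len_um - 1e-9, dendrite_len_um)
        identities = [lbl] * len(positions)
    elif mode == "swapped":
        prox = _layout_identity(type_layout, 0.0, dendrite_len_um)
        dist = _layout_identity(type_layout, dendrite_len_um - 1e-9,
                                dendrite_len_um)
        exchange = {prox: dist, dist: prox}
        identities = [exchange.get(i, i) for i in identities]
    return SynapseMap(positions, identities, np.ones(len(positions), dtype=int), mode)


@dataclass
class DriveSet:
    """Per-synapse injected current time series (nA) on the stimulus clock."""

    currents_na: np.ndarray  # (n_syn, n_time)
    positions_um: np.ndarray
    dt_s: float
    label: str = ""

    def scaled(self, factor: float) -> "DriveSet":
        return DriveSet(self.currents_na * factor, self.positions_um, self.dt_s,
                        self.label)

    @property
    def duration_s(self) -> float:
        return self.currents_na.shape[1] * self.dt_s


def _synapse_predictions(rfs_by_identity: dict, syn_map: SynapseMap,
                         stim: SpaceTimeStimulus) -> list:
    preds = []
    for pos, ident in zip(syn_map.positions_um, syn_map.identities):
        if ident not in rfs_by_identity:
            raise ConfigError(f"no RF provided for BC identity {ident!r}")
        rf_i = recenter(rfs_by_identity[ident], float(pos))
        preds.append(conv_predict(rf_i, stim).values)
    n = min(len(p) for p in preds)
    return [p[:n] for p in preds]


def bc_drive(
    rfs_by_identity: dict,
    syn_map: SynapseMap,
    stim: SpaceTimeStimulus,
    baseline: float = 0.0,
    scale: float = 1.0,
    label: str = "",
) -> DriveSet:
    """Rectified BC activity as injected current per synapse.

    Each synapse's BC RF is re-centered at its dendritic position and
    convolved with the stimulus; the drive is
    ``scale * n_synapses * max(0, baseline + prediction)`` -- spontaneous
    baseline activity that center (surround) stimulation pushes up (down),
    clipped at zero because glutamate release cannot be negative.
    """
    preds = _synapse_predictions(rfs_by_identity, syn_map, stim)
    currents = np.stack([
        scale * cnt * np.clip(baseline + p, 0.0, None)
        for p, cnt in zip(preds, syn_map.counts)
    ])
    return DriveSet(currents, syn_map.positions_um.copy(), stim.dt, label=label)


@dataclass
class SACSimResult:
    """Membrane potential and Ca2+ per compartment per recorded time step."""

    v_mv: np.ndarray  # (n_comp, n_rec)
    ca_m: np.ndarray
    times_s: np.ndarray
    positions_um: np.ndarray
    config: SACConfig
    label: str = ""

    def distal_mask(self) -> np.ndarray:
        cfg = self.config
        start = cfg.dendrite_len_um * (1.0 - cfg.ca_region_fraction)
        return self.positions_um >= start


def resting_state(cfg: SACConfig) -> np.ndarray:
    """Steady-state membrane potential (mV) with zero drive.

    Solves the coupled nonlinear steady state (leak + axial + Ca window
    current) by iterating linear solves with the gating variable refreshed at
    each pass.
    """
    comp = _build_compartments(cfg)
    n = len(comp.c_nf)
    v = np.full(n, cfg.e_leak_mv)
    for _ in range(200):
        g_ca_t = comp.g_ca_us * _m_inf(v, cfg) ** cfg.ca_gate_power
        diag = comp.g_leak_us + g_ca_t
        diag[:-1] += comp.g_axial_us
        diag[1:] += comp.g_axial_us
        ab = np.zeros((3, n))
        ab[0, 1:] = -comp.g_axial_us
        ab[1, :] = diag
        ab[2, :-1] = -comp.g_axial_us
        rhs = comp.g_leak_us * cfg.e_leak_mv + g_ca_t * cfg.e_ca_mv
        v_new = solve_banded((1, 1), ab, rhs)
        if np.max(np.abs(v_new - v)) < 1e-10:
            v = v_new
            break
        v = v_new
    return v


def simulate(
    cfg: SACConfig,
    drives: DriveSet | None = None,
    duration_s: float | None = None,
    record_every: int = 1,
    label: str = "",
    v_clamp_mv=None,
) -> SACSimResult:
    """Integrate the cable + Ca2+ model under the given synaptic drives.

    Backward-Euler on the membrane potential (the Ca conductance entering the
    implicit step with the current gating value), exponential updates for
    gating and Ca2+ concentration.  Initial condition is the zero-drive
    resting state.  Raises on NaN/divergence.

    ``v_clamp_mv`` (scalar or per-step array) forces the membrane potential
    to the given value in every compartment -- a voltage-clamp mode used to
    probe the gating and Ca2+ dynamics in isolation.
    """
    comp = _build_compartments(cfg)
    n = len(comp.c_nf)
    dt = cfg.dt_ms
    if duration_s is None:
        if drives is None:
            raise InvalidParameterError("specify duration_s when no drives are given")
        duration_s = drives.duration_s
    n_steps = max(1, int(round(duration_s * 1e3 / dt)))

    inj = np.zeros((n, n_steps))
    if drives is not None:
        t_sim = np.arange(n_steps) * dt * 1e-3
        t_drv = np.arange(drives.currents_na.shape[1]) * drives.dt_s
        first_dend = 1 if cfg.include_soma else 0
        for cur, pos in zip(drives.currents_na, drives.positions_um):
            ci = first_dend + int(np.clip(pos / cfg.comp_len_um, 0,
                                          round(cfg.dendrite_len_um / cfg.comp_len_um) - 1))
            inj[ci] += np.interp(t_sim, t_drv, cur, left=cur[0], right=cur[-1])

    clamp = None
    if v_clamp_mv is not None:
        if np.ndim(v_clamp_mv) == 0:
            clamp = np.full(n_steps, float(v_clamp_mv))
        else:
            clamp = np.asarray(v_clamp_mv, dtype=float)
            if clamp.shape != (n_steps,):
                raise InvalidParameterError(
                    "v_clamp_mv must be scalar or length n_steps")

    v = resting_state(cfg) if clamp is None else np.full(len(comp.c_nf), clamp[0])
    m = _m_inf(v, cfg)
    ca = np.full(n, cfg.ca_rest_nm * 1e-9)
    gate_decay = np.exp(-dt / cfg.ca_tau_gate_ms)
    ca_decay = np.exp(-dt / cfg.tau_ca_ms)
    c_over_dt = comp.c_nf / dt
    base_diag = c_over_dt + comp.g_leak_us
    base_diag_full = base_diag.copy()
    base_diag_full[:-1] += comp.g_axial_us
    base_diag_full[1:] += comp.g_axial_us
    ab = np.zeros((3, n))
    ab[0, 1:] = -comp.g_axial_us
    ab[2, :-1] = -comp.g_axial_us

    n_rec = (n_steps + record_every - 1) // record_every
    v_rec = np.empty((n, n_rec))
    ca_rec = np.empty((n, n_rec))
    t_rec = np.empty(n_rec)
    r = 0
    for step in range(n_steps):
        m_inf = _m_inf(v, cfg)
        m = m_inf + (m - m_inf) * gate_decay
        g_ca_t = comp.g_ca_us * m**cfg.ca_gate_power
        if clamp is None:
            ab[1, :] = base_diag_full + g_ca_t
            rhs = (c_over_dt * v + comp.g_leak_us * cfg.e_leak_mv
                   + g_ca_t * cfg.e_ca_mv + inj[:, step])
            v = solve_banded((1, 1), ab, rhs)
        else:
            v = np.full_like(v, clamp[step])
        i_ca = g_ca_t * (v - cfg.e_ca_mv)  # nA, negative inward
        ca_ss = cfg.ca_rest_nm * 1e-9 - cfg.gamma_ca_m_per_nc * i_ca * 1e-3 * cfg.tau_ca_ms
        ca = ca_ss + (ca - ca_ss) * ca_decay
        np.clip(ca, 0.0, None, out=ca)
        if step % record_every == 0:
            v_rec[:, r] = v
            ca_rec[:, r] = ca
            t_rec[r] = step * dt * 1e-3
            r += 1
        if not np.all(np.isfinite(v)):
            raise NumericalInstabilityError(
                f"membrane potential diverged at t = {step * dt:.2f} ms"
            )
    return SACSimResult(v_rec[:, :r], ca_rec[:, :r], t_rec[:r],
                        comp.positions_um, cfg, label=label)


def calibrate_scale(
    cfg: SACConfig,
    unit_drives: DriveSet,
    target_mv: float = -35.0,
    tol_mv: float = 0.5,
    max_iter: int = 40,
) -> float:
    """Input scale at which peak depolarization in the most distal
    compartment reaches ``target_mv`` (default about -35 mV).

    The drive scales linearly with the factor, so peak voltage is monotone in
    it; the factor is found by bracket expansion plus bisection.
    """
    if not np.any(unit_drives.currents_na > 0):
        raise CalibrationError("drives are identically zero; cannot calibrate")

    def peak_distal(s: float) -> float:
        res = simulate(cfg, unit_drives.scaled(s), record_every=5)
        return float(res.v_mv[-1].max())

    lo, hi = 0.0, 1.0
    p_hi = peak_distal(hi)
    it = 0
    while p_hi < target_mv and it < max_iter:
        lo, hi = hi, hi * 4.0
        p_hi = peak_distal(hi)
        it += 1
    if p_hi < target_mv:
        raise CalibrationError("could not bracket the calibration target")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        p = peak_distal(mid)
        if abs(p - target_mv) <= tol_mv:
            return mid
        if p < target_mv:
            lo = mid
        else:
            hi = mid
    raise CalibrationError("calibration did not converge within tolerance")


def dsi(
    result_cf: SACSimResult,
    result_cp: SACSimResult,
    t_onset_s: float = 0.0,
    metric: str = "peak",
) -> tuple[np.ndarray, float]:
    """Direction selectivity index per distal compartment and its mean.

    Response magnitude per compartment is the peak depolarization above the
    pre-stimulus resting level (``metric='peak'``) or the integral of the
    depolarization (``metric='integral'``); DSI = (CF - CP) / (CF + CP).
    """
    if result_cf.v_mv.shape != result_cp.v_mv.shape:
        raise InvalidParameterError("CF and CP results must share compartmentalization")

    def _resp(res: SACSimResult) -> np.ndarray:
        i0 = int(np.searchsorted(res.times_s, t_onset_s))
        i0 = min(i0, res.v_mv.shape[1] - 1)
        rest = res.v_mv[:, i0]
        depol = np.clip(res.v_mv[:, i0:] - rest[:, None], 0.0, None)
        if metric == "peak":
            return depol.max(axis=1)
        if metric == "integral":
            return depol.sum(axis=1) * np.diff(res.times_s).mean()
        raise InvalidParameterError("metric must be 'peak' or 'integral'")

    mask = result_cf.distal_mask()
    cf = _resp(result_cf)[mask]
    cp = _resp(result_cp)[mask]
    denom = cf + cp
    if np.all(denom == 0):
        raise UndefinedIndexError("DSI undefined: no depolarization in either direction")
    with np.errstate(invalid="ignore", divide="ignore"):
        per_comp = np.where(denom > 0, (cf - cp) / denom, np.nan)
    return per_comp, float(np.nanmean(per_comp))


# ---------------------------------------------------------------------------
# RF conditioning for model input


def condition_rf(
    rf: SpaceTimeRF,
    space_factor: float = 20.0,
    time_factor: float = 1.6,
    rank: int = 3,
    mirror: bool = True,
) -> SpaceTimeRF:
    """Upsample and denoise an RF for use as model input.

    Singular value decomposition keeps the top ``rank`` components; the
    spatial and temporal singular vectors are linearly interpolated to
    ``space_factor`` x / ``time_factor`` x resolution before reconstruction
    (which preserves the space-time structure), and the result is mirrored
    about the center column into a fully symmetric spatial RF.
    """
    if rank < 1 or rank > min(rf.weights.shape):
        raise InvalidParameterError("rank must be between 1 and min(RF dimensions)")
    u, s, vt = np.linalg.svd(rf.weights, full_matrices=False)
    new_dx = rf.dx / space_factor
    new_dt = rf.dt / time_factor
    n_x = int(round(rf.n_space * space_factor))
    n_l = int(round(rf.n_lag * time_factor))
    old_x = rf.space_centers_um
    new_x = rf.origin_um + (np.arange(n_x) + 0.5) * new_dx
    old_l = rf.lags_s
    new_l = np.arange(n_l) * new_dt
    w = np.zeros((n_x, n_l))
    for k in range(rank):
        uk = np.interp(new_x, old_x, u[:, k])
        vk = np.interp(new_l, old_l, vt[k, :])
        w += s[k] * np.outer(uk, vk)
    w /= space_factor * time_factor  # conserve the kernel integral
    out = SpaceTimeRF(w, dx=new_dx, dt=new_dt, origin_um=rf.origin_um,
                      center_um=rf.center_um, polarity=rf.polarity,
                      ipl_depth=rf.ipl_depth, label=rf.label + "_conditioned")
    return mirror_rf(out) if mirror else out


def mirror_rf(rf: SpaceTimeRF) -> SpaceTimeRF:
    """Reflect the wider spatial half about the center into a symmetric RF."""
    ci = int(round((rf.center_um - rf.origin_um) / rf.dx - 0.5))
    ci = int(np.clip(ci, 0, rf.n_space - 1))
    right = rf.weights[ci:, :]
    left = rf.weights[: ci + 1, :][::-1, :]
    half = right if right.shape[0] >= left.shape[0] else left
    w = np.vstack([half[:0:-1, :], half])
    h = half.shape[0]
    origin = rf.center_um - (h - 0.5) * rf.dx
    return SpaceTimeRF(w, dx=rf.dx, dt=rf.dt, origin_um=origin,
                       center_um=rf.center_um, polarity=rf.polarity,
                       ipl_depth=rf.ipl_depth, label=rf.label + "_mirrored")


# ---------------------------------------------------------------------------
# Full protocol


@dataclass
class SACModelBundle:
    """Everything needed to run a directional tuning protocol."""

    config: SACConfig
    rfs_by_identity: dict
    density_per_10um: list | None = None
    type_layout: tuple = DEFAULT_TYPE_LAYOUT
    bar_width_um: float = 20.0
    baseline_frac: float = 0.1
    stim_dt_s: float = 1e-3
    target_mv: float = -35.0
    settle_s: float = 0.2
    label: str = ""


# BC synapse counts per 10 um segment: input density onto SAC dendrites is
# highest proximally and declines toward the tip (30 synapses total).
DEFAULT_DENSITY_PER_10UM = (4, 4, 3, 3, 3, 2, 2, 2, 1, 1, 1, 1, 1, 1, 1)

DEFAULT_TYPE_PARAMS = {
    # On pathway: sustained proximal type with a strong delayed surround,
    # faster/more transient distal type -- the wiring gradient described for
    # SAC-connected BC types.
    "on": {
        "proximal": dict(polarity="On", center_tau_s=0.07, biphasic_weight=0.15,
                         surround_strength=0.5, surround_latency_s=0.06),
        "distal": dict(polarity="On", center_tau_s=0.04, biphasic_weight=0.35,
                       surround_strength=0.2, surround_latency_s=0.03),
    },
    "off": {
        "proximal": dict(polarity="Off", center_tau_s=0.06, biphasic_weight=0.2,
                         surround_strength=0.45, surround_latency_s=0.06),
        "distal": dict(polarity="Off", center_tau_s=0.04, biphasic_weight=0.4,
                       surround_strength=0.25, surround_latency_s=0.03),
    },
}


def default_bundle(model: str = "on", config: SACConfig | None = None,
                   conditioned: bool = True) -> SACModelBundle:
    """Default On or Off SAC model bundle with synthetic BC cluster RFs."""
    if model not in DEFAULT_TYPE_PARAMS:
        raise ConfigError("model must be 'on' or 'off'")
    rfs = {}
    for name, kw in DEFAULT_TYPE_PARAMS[model].items():
        base = synth.make_rf(synth.SyntheticRFParams(**kw), dx=20.0, dt=0.025)
        rfs[name] = condition_rf(base) if conditioned else base
    return SACModelBundle(config=config or SACConfig(), rfs_by_identity=rfs,
                          density_per_10um=list(DEFAULT_DENSITY_PER_10UM),
                          label=f"{model}_sac")


def _protocol_stimulus(path: tuple, direction: int, velocity: float,
                       bundle: SACModelBundle, extent: tuple) -> SpaceTimeStimulus:
    lo, hi = path
    w = bundle.bar_width_um
    dist = (hi - lo) + w
    dx = next(iter(bundle.rfs_by_identity.values())).dx
    if direction == +1:  # centrifugal: soma (lo) -> tip (hi)
        return make_moving_bar(w, velocity, dist, +1, lo, dx, bundle.stim_dt_s,
                               extent_um=extent, label=f"CF_{velocity:g}")
    return make_moving_bar(w, velocity, dist, -1, hi, dx, bundle.stim_dt_s,
                           extent_um=extent, label=f"CP_{velocity:g}")


def run_protocol(
    bundle: SACModelBundle,
    velocities,
    path_variant: str = "single_dendrite",
    wiring_mode: str = "original",
    surround_factor: float = 1.0,
    record_every: int = 5,
) -> pd.DataFrame:
    """DSI-vs-velocity table for one wiring / path / surround configuration.

    For each velocity, a bright bar sweeps the selected motion path in the
    centrifugal (soma->tip) and centripetal (tip->soma) direction; the two
    stimuli are exact mirror images over the path.  Input RFs have their
    surround scaled by ``surround_factor``; the injected-current scale is
    calibrated once per configuration so the slowest centrifugal sweep peaks
    near the target depolarization (about -35 mV) in the most distal
    compartment.
    """
    velocities = sorted(float(v) for v in np.atleast_1d(velocities))
    if not velocities or min(velocities) <= 0:
        raise InvalidParameterError("velocities must be positive")
    if path_variant not in PATH_VARIANTS:
        raise InvalidParameterError(
            f"unknown path variant {path_variant!r}; use one of {tuple(PATH_VARIANTS)}")
    path = PATH_VARIANTS[path_variant]
    rfs = {
        k: (scale_surround(rf, surround_factor) if surround_factor != 1.0 else rf)
        for k, rf in bundle.rfs_by_identity.items()
    }
    syn_map = build_synapse_map(bundle.density_per_10um, bundle.type_layout,
                                mode=wiring_mode,
                                dendrite_len_um=bundle.config.dendrite_len_um)
    rf_half = max(rf.n_space * rf.dx / 2 for rf in rfs.values())
    extent = (path[0] - bundle.bar_width_um - rf_half,
              path[1] + bundle.bar_width_um + rf_half)

    # baseline level: a fraction of the strongest single-synapse modulation
    calib_stim = _protocol_stimulus(path, +1, velocities[0], bundle, extent)
    preds = _synapse_predictions(rfs, syn_map, calib_stim)
    baseline = bundle.baseline_frac * max(np.abs(p).max() for p in preds)

    def _drives(stim):
        return _pad_settle(
            bc_drive(rfs, syn_map, stim, baseline=baseline, label=stim.label),
            bundle.settle_s,
        )

    unit = _drives(calib_stim)
    scale = calibrate_scale(bundle.config, unit, target_mv=bundle.target_mv)

    rows = []
    for v in velocities:
        res = {}
        for direction, tag in ((+1, "CF"), (-1, "CP")):
            stim = _protocol_stimulus(path, direction, v, bundle, extent)
            drv = _drives(stim).scaled(scale)
            res[tag] = simulate(bundle.config, drv, record_every=record_every,
                                label=f"{tag}_{v:g}")
        _, mean_dsi = dsi(res["CF"], res["CP"], t_onset_s=bundle.settle_s)
        rows.append(dict(velocity_um_s=v, dsi=mean_dsi,
                         path=path_variant, wiring=wiring_mode,
                         surround_factor=surround_factor))
    return pd.DataFrame(rows)


def _pad_settle(drives: DriveSet, settle_s: float) -> DriveSet:
    """Prepend a hold at the first drive value so the membrane settles."""
    if settle_s <= 0:
        return drives
    n_pad = int(round(settle_s / drives.dt_s))
    pad = np.repeat(drives.currents_na[:, :1], n_pad, axis=1)
    return DriveSet(np.hstack([pad, drives.currents_na]), drives.positions_um,
                    drives.dt_s, drives.label)
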