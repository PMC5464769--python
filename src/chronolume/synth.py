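"""Synthetic recordings for circadian-behavior and sleep-EEG analyses.

This module generates the five kinds of data the analysis modules consume:
light schedules, binned locomotor-activity traces, 4-s-epoch hypnograms,
per-epoch EEG signals, and flash-ERG traces.  The generators are built so
that the quantities the analyses estimate (free-running period tau, phase
angle of entrainment psi, active-phase duration alpha, light-pulse phase
shifts, masking strength, theta-peak frequency, NREM delta power) are exact,
known parameters of the simulation and can be recovered by the estimators.

Conventions
-----------
* All times are decimal hours from the start of the recording.
* Under a light-dark cycle, Zeitgeber time ZT0 is light onset; in constant
  darkness, circadian time CT12 is activity onset.
* Phase-shift signs follow the convention "advance positive".
* Every generator is deterministic given its config and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

LIGHT = "LIGHT"
DARK = "DARK"

#: Sleep-wake states, in the order used by transition matrices.
STATES = ("W", "TDW", "NREM", "REM")

_STATE_INDEX = {s: i for i, s in enumerate(STATES)}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LightInterval:
    start_h: float
    end_h: float
    state: str  # LIGHT or DARK
    intensity_cdm2: float = 0.0

    @property
    def duration_h(self) -> float:
        return self.end_h - self.start_h


@dataclass(frozen=True)
class LightSchedule:
    """Ordered, contiguous light/dark intervals covering a recording."""

    intervals: tuple[LightInterval, ...]

    def __post_init__(self):
        if not self.intervals:
            raise ValueError("schedule must contain at least one interval")
        prev_end = self.intervals[0].start_h
        for iv in self.intervals:
            if iv.end_h <= iv.start_h:
                raise ValueError(f"interval end {iv.end_h} <= start {iv.start_h}")
            if not math.isclose(iv.start_h, prev_end, abs_tol=1e-9):
                raise ValueError("intervals must be contiguous")
            if iv.state not in (LIGHT, DARK):
                raise ValueError(f"unknown light state {iv.state!r}")
            if iv.state == DARK and iv.intensity_cdm2 != 0:
                raise ValueError("DARK intervals must have zero intensity")
            if iv.intensity_cdm2 < 0:
                raise ValueError("intensity must be >= 0")
            prev_end = iv.end_h

    @property
    def start_h(self) -> float:
        return self.intervals[0].start_h

    @property
    def end_h(self) -> float:
        return self.intervals[-1].end_h

    @property
    def duration_h(self) -> float:
        return self.end_h - self.start_h

    def is_light(self, t_h) -> np.ndarray:
        """Boolean LIGHT mask at the given times (half-open intervals)."""
        t = np.asarray(t_h, dtype=float)
        edges = np.array([iv.start_h for iv in self.intervals] + [self.end_h])
        idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0,
                      len(self.intervals) - 1)
        states = np.array([iv.state == LIGHT for iv in self.intervals])
        return states[idx]

    def shifted(self, delta_h: float) -> "LightSchedule":
        return LightSchedule(tuple(
            replace(iv, start_h=iv.start_h + delta_h, end_h=iv.end_h + delta_h)
            for iv in self.intervals))


@dataclass(frozen=True)
class ActivityTrace:
    """Binned locomotor counts; bins are half-open [t, t + bin)."""

    counts: np.ndarray
    bin_seconds: float = 300.0
    start_time_h: float = 0.0

    def __post_init__(self):
        counts = np.asarray(self.counts)
        object.__setattr__(self, "counts", counts)
        if self.bin_seconds <= 0:
            raise ValueError("bin_seconds must be > 0")
        if counts.ndim != 1 or counts.size < 1:
            raise ValueError("counts must be a non-empty 1-D sequence")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def bin_h(self) -> float:
        return self.bin_seconds / 3600.0

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def duration_h(self) -> float:
        return self.n_bins * self.bin_h

    def bin_starts_h(self) -> np.ndarray:
        return self.start_time_h + np.arange(self.n_bins) * self.bin_h

    def bin_centers_h(self) -> np.ndarray:
        return self.bin_starts_h() + 0.5 * self.bin_h

    def shifted(self, delta_h: float) -> "ActivityTrace":
        return replace(self, start_time_h=self.start_time_h + delta_h)


@dataclass(frozen=True)
class Hypnogram:
    """Sequence of sleep-wake state labels on a fixed epoch grid.

    Raw (visually scored) hypnograms use W/NREM/REM; the TDW label appears
    either as simulation ground truth or after spectral classification.
    """

    states: np.ndarray
    epoch_seconds: float = 4.0
    start_time_h: float = 0.0

    def __post_init__(self):
        states = np.asarray(self.states, dtype="U4")
        object.__setattr__(self, "states", states)
        if states.size == 0:
            raise ValueError("hypnogram must contain at least one epoch")
        bad = set(np.unique(states)) - set(STATES)
        if bad:
            raise ValueError(f"unknown states: {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return self.states.size

    @property
    def epoch_h(self) -> float:
        return self.epoch_seconds / 3600.0

    @property
    def duration_h(self) -> float:
        return self.n_epochs * self.epoch_h

    def epoch_starts_h(self) -> np.ndarray:
        return self.start_time_h + np.arange(self.n_epochs) * self.epoch_h

    def epoch_centers_h(self) -> np.ndarray:
        return self.epoch_starts_h() + 0.5 * self.epoch_h

    def time_in_state_h(self, *states: str) -> float:
        return float(np.isin(self.states, states).sum()) * self.epoch_h

    def collapse_tdw(self) -> "Hypnogram":
        """Relabel TDW epochs as W, as a visual scorer would see them."""
        states = self.states.copy()
        states[states == "TDW"] = "W"
        return replace(self, states=states)


@dataclass(frozen=True)
class ERGTrace:
    """Flash electroretinogram trace with stimulus marker."""

    time_ms: np.ndarray
    voltage_uV: np.ndarray
    stim_time_ms: float = 0.0

    def __post_init__(self):
        t = np.asarray(self.time_ms, dtype=float)
        v = np.asarray(self.voltage_uV, dtype=float)
        object.__setattr__(self, "time_ms", t)
        object.__setattr__(self, "voltage_uV", v)
        if t.ndim != 1 or t.size != v.size:
            raise ValueError("time and voltage must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if not (t[0] <= self.stim_time_ms <= t[-1]):
            raise ValueError("stimulus time outside trace")


# ---------------------------------------------------------------------------
# Simulation configs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivitySimConfig:
    """Parameters of the circadian locomotor-activity generator.

    Defaults are calibrated to a wild-type-like C57BL/6 mouse: tau just
    under 24 h, a 12-h active phase, a slightly negative phase angle of
    entrainment, and roughly 550 movements per day.
    """

    tau_h: float = 23.8                 # free-running period
    alpha_dd_h: float = 12.3            # active-phase duration in DD
    alpha_ld_h: float = 12.0            # active-phase duration under LD
    psi_h: float = -0.49                # phase angle of entrainment (signed)
    base_rate: float = 3.8              # expected counts / 5-min bin, active
    rest_rate: float = 0.25             # expected counts / bin, rest
    masking_strength: float = 0.5       # m in [0, 1]: rate *= (1 - m) in LIGHT
    dark_gain: float = 1.0              # >= 1: rate *= g in DARK rest bins
    prc_advance_h: float = 1.0          # shift (circadian h, advance +) for CT~22 pulses
    prc_delay_h: float = -1.0           # shift (circadian h, advance +) for CT~16 pulses
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.masking_strength <= 1:
            raise ValueError("masking_strength must be in [0, 1]")
        if self.tau_h <= 0:
            raise ValueError("tau_h must be > 0")
        if not 0 < self.alpha_dd_h < self.tau_h:
            raise ValueError("alpha_dd_h must lie in (0, tau_h)")
        if self.base_rate < 0 or self.rest_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.dark_gain < 0:
            raise ValueError("dark_gain must be >= 0")


@dataclass(frozen=True)
class SpectralPeak:
    center_hz: float
    width_hz: float       # sd of the per-epoch jitter of the peak centre
    amplitude_uV: float   # sinusoid amplitude


@dataclass(frozen=True)
class StateTemplate:
    """1/f background plus sinusoidal band peaks for one sleep-wake state."""

    noise_uV: float          # target rms of the 1/f background
    slope: float             # power-law exponent of the background (P ~ f^-slope)
    peaks: tuple[SpectralPeak, ...] = ()


def default_state_templates() -> dict[str, StateTemplate]:
    """EEG templates: delta-rich NREM, theta-peaked TDW and REM, broadband
    quiet wake.  TDW theta amplitude is set so the theta/total power ratio
    is ~0.5-0.6, i.e. clearly theta-dominated; quiet wake has no band peak
    so its ratio sits near the flat-spectrum floor (~0.1)."""
    return {
        "W": StateTemplate(noise_uV=15.0, slope=1.0),
        # TDW centre frequency is substituted per light condition at
        # generation time (tpf_light_hz / tpf_dark_hz).
        "TDW": StateTemplate(noise_uV=12.0, slope=1.0,
                             peaks=(SpectralPeak(8.0, 0.15, 12.0),)),
        "NREM": StateTemplate(noise_uV=18.0, slope=1.5,
                              peaks=(SpectralPeak(2.0, 0.3, 40.0),)),
        "REM": StateTemplate(noise_uV=12.0, slope=1.0,
                             peaks=(SpectralPeak(7.0, 0.15, 10.0),)),
    }


def default_transition_matrices() -> dict[str, np.ndarray]:
    """Row-stochastic 4x4 matrices (state order W, TDW, NREM, REM) at 4-s
    steps.  Light favours sleep; dark favours wake and TDW.  TDW is entered
    only from W (it is a wake sub-state), never from NREM or REM."""
    light = np.array([
        [0.960, 0.005, 0.035, 0.000],   # W
        [0.040, 0.955, 0.005, 0.000],   # TDW
        [0.010, 0.000, 0.980, 0.010],   # NREM
        [0.040, 0.000, 0.005, 0.955],   # REM
    ])
    dark = np.array([
        [0.980, 0.012, 0.008, 0.000],
        [0.025, 0.973, 0.002, 0.000],
        [0.012, 0.000, 0.978, 0.010],
        [0.045, 0.000, 0.005, 0.950],
    ])
    return {LIGHT: light, DARK: dark}


@dataclass(frozen=True)
class EEGSimConfig:
    """Parameters of the hypnogram and per-epoch EEG generators."""

    sampling_hz: int = 256
    epoch_seconds: float = 4.0
    state_templates: dict[str, StateTemplate] = field(
        default_factory=default_state_templates)
    tpf_light_hz: float = 8.0
    tpf_dark_hz: float = 8.75
    transition_matrices: dict[str, np.ndarray] = field(
        default_factory=default_transition_matrices)
    seed: int = 0

    def __post_init__(self):
        n = self.sampling_hz * self.epoch_seconds
        if abs(n - round(n)) > 1e-9:
            raise ValueError("sampling_hz * epoch_seconds must be an integer")
        for tpf in (self.tpf_light_hz, self.tpf_dark_hz):
            if not 6.5 <= tpf <= 12.0:
                raise ValueError("TPF centres must lie within 6.5-12.0 Hz")
        for key, mat in self.transition_matrices.items():
            _validate_stochastic(np.asarray(mat), key)

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.sampling_hz * self.epoch_seconds))


def _validate_stochastic(mat: np.ndarray, name: str) -> np.ndarray:
    if mat.shape != (4, 4):
        raise ValueError(f"{name} transition matrix must be 4x4")
    if np.any(mat < 0):
        raise ValueError(f"{name} transition matrix has negative entries")
    if np.any(np.abs(mat.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError(f"{name} transition matrix rows must sum to 1")
    return mat


# ---------------------------------------------------------------------------
# Light schedules
# ---------------------------------------------------------------------------

def build_light_schedule(protocol, duration_h: float,
                         intensity_cdm2: float = 6.6) -> LightSchedule:
    """Build a schedule for one of the standard lighting protocols.

    Parameters
    ----------
    protocol
        One of ``"LD12:12"``, ``"DD"``, ``"LL"``, ``"LD1:1"``, or a light
        pulse embedded in darkness given as ``("pulse", start_h, length_h)``
        or the string ``"pulse:START:LENGTH"``.
    duration_h
        Total schedule length in hours.
    intensity_cdm2
        Intensity of the LIGHT intervals (cd/m^2).
    """
    if duration_h <= 0:
        raise ValueError("duration must be > 0")
    if isinstance(protocol, str) and protocol.startswith("pulse:"):
        _, s, l = protocol.split(":")
        protocol = ("pulse", float(s), float(l))

    if protocol == "DD":
        return LightSchedule((LightInterval(0.0, duration_h, DARK, 0.0),))
    if protocol == "LL":
        return LightSchedule((LightInterval(0.0, duration_h, LIGHT,
                                            intensity_cdm2),))
    if protocol in ("LD12:12", "LD1:1"):
        half = 12.0 if protocol == "LD12:12" else 1.0
        ivs, t, state = [], 0.0, LIGHT
        while t < duration_h - 1e-9:
            end = min(t + half, duration_h)
            inten = intensity_cdm2 if state == LIGHT else 0.0
            ivs.append(LightInterval(t, end, state, inten))
            t, state = end, (DARK if state == LIGHT else LIGHT)
        return LightSchedule(tuple(ivs))
    if isinstance(protocol, tuple) and len(protocol) == 3 and protocol[0] == "pulse":
        _, start, length = protocol
        if not (0 <= start and start + length <= duration_h):
            raise ValueError("pulse lies outside the schedule duration")
        ivs = []
        if start > 0:
            ivs.append(LightInterval(0.0, start, DARK, 0.0))
        ivs.append(LightInterval(start, start + length, LIGHT, intensity_cdm2))
        if start + length < duration_h:
            ivs.append(LightInterval(start + length, duration_h, DARK, 0.0))
        return LightSchedule(tuple(ivs))
    raise ValueError(f"unknown protocol {protocol!r}")


def concatenate_schedules(schedules: Sequence[LightSchedule]) -> LightSchedule:
    """Chain protocol segments, shifting each to start where the last ended.
    Adjacent intervals with identical state and intensity are merged."""
    ivs: list[LightInterval] = []
    t = 0.0
    for sch in schedules:
        for iv in sch.intervals:
            shifted = replace(iv, start_h=iv.start_h - sch.start_h + t,
                              end_h=iv.end_h - sch.start_h + t)
            if (ivs and ivs[-1].state == shifted.state
                    and ivs[-1].intensity_cdm2 == shifted.intensity_cdm2):
                ivs[-1] = replace(ivs[-1], end_h=shifted.end_h)
            else:
                ivs.append(shifted)
        t += sch.duration_h
    return LightSchedule(tuple(ivs))


# ---------------------------------------------------------------------------
# Locomotor activity
# ---------------------------------------------------------------------------

def _entrained_days(schedule: LightSchedule) -> np.ndarray:
    """Flag each full 24-h block that is an LD12:12 cycle (light first)."""
    n = int(math.floor(schedule.duration_h / 24.0 + 1e-9))
    flags = np.zeros(n, dtype=bool)
    for k in range(n):
        probes = schedule.start_h + 24.0 * k + np.arange(0.25, 24.0, 0.5)
        flags[k] = bool(np.array_equal(schedule.is_light(probes),
                                       (probes - schedule.start_h) % 24.0 < 12.0))
    return flags


def _pulse_intervals(schedule: LightSchedule,
                     entrained: np.ndarray) -> list[LightInterval]:
    """Short LIGHT intervals outside entrained days, i.e. light pulses."""
    pulses = []
    for iv in schedule.intervals:
        if iv.state != LIGHT or iv.duration_h > 3.0:
            continue
        day = int((iv.start_h - schedule.start_h) // 24.0)
        if 0 <= day < entrained.size and entrained[day]:
            continue
        pulses.append(iv)
    return pulses


def circadian_onsets(config: ActivitySimConfig,
                     schedule: LightSchedule) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth activity-onset times and active-phase durations.

    Under entrained (LD12:12) days the expressed onset is clamped to dark
    onset; in free run the onset advances by tau per cycle, with a single
    -psi step when entrainment is released (so that the free-running onset
    series extrapolates back to the LD onset minus psi).  Light pulses in
    free run step the phase by the configured PRC shift according to the
    circadian time of the pulse.
    """
    entrained = _entrained_days(schedule)
    t0 = schedule.start_h
    dur = schedule.duration_h

    onsets: list[float] = []
    alphas: list[float] = []
    if entrained.size and entrained[0]:
        o, mode = t0 + 12.0, "LD"
    else:
        o, mode = t0 + 12.0 - config.psi_h, "FR"
    while o < t0 + dur + config.tau_h:
        onsets.append(o)
        alphas.append(config.alpha_ld_h if mode == "LD" else config.alpha_dd_h)
        if mode == "LD":
            k_next = int((o - t0) // 24.0) + 1
            if k_next < entrained.size and entrained[k_next]:
                o = t0 + 24.0 * k_next + 12.0
            else:
                o, mode = o + config.tau_h - config.psi_h, "FR"
        else:
            o_next = o + config.tau_h
            k = int((o_next - t0) // 24.0)
            if 0 <= k < entrained.size and entrained[k]:
                o_next, mode = t0 + 24.0 * k + 12.0, "LD"
            o = o_next

    onset_arr = np.array(onsets)
    alpha_arr = np.array(alphas)
    # one virtual onset before the recording so every bin has a phase
    first_cycle = 24.0 if (entrained.size and entrained[0]) else config.tau_h
    onset_arr = np.concatenate([[onset_arr[0] - first_cycle], onset_arr])
    alpha_arr = np.concatenate([[alpha_arr[0]], alpha_arr])

    # PRC steps at light pulses
    for pulse in _pulse_intervals(schedule, entrained):
        before = onset_arr[onset_arr <= pulse.start_h]
        o_last = before[-1] if before.size else onset_arr[0]
        ct = (12.0 + (pulse.start_h - o_last) * 24.0 / config.tau_h) % 24.0
        if 12.0 <= ct < 20.0:
            dphi = config.prc_delay_h
        elif ct >= 20.0 or ct < 4.0:
            dphi = config.prc_advance_h
        else:
            dphi = 0.0
        shift = dphi * config.tau_h / 24.0  # circadian h -> clock h
        onset_arr = np.where(onset_arr > pulse.start_h, onset_arr - shift,
                             onset_arr)
    return onset_arr, alpha_arr


def simulate_activity(config: ActivitySimConfig,
                      schedule: LightSchedule,
                      bin_seconds: float = 300.0) -> ActivityTrace:
    """Poisson locomotor counts gated by circadian phase, masked by light.

    Per-bin rate is ``base_rate`` inside the active phase and ``rest_rate``
    outside (a square circadian gate), multiplied by ``1 - masking_strength``
    during LIGHT and by ``dark_gain`` during DARK rest-phase bins.
    """
    if schedule.duration_h < config.tau_h:
        raise ValueError("schedule must cover at least one full cycle")
    onsets, alphas = circadian_onsets(config, schedule)

    n_bins = int(round(schedule.duration_h * 3600.0 / bin_seconds))
    bin_h = bin_seconds / 3600.0
    t = schedule.start_h + (np.arange(n_bins) + 0.5) * bin_h

    idx = np.searchsorted(onsets, t, side="right") - 1
    idx = np.clip(idx, 0, onsets.size - 1)
    active = (t - onsets[idx]) < alphas[idx]

    rate = np.where(active, config.base_rate, config.rest_rate)
    light = schedule.is_light(t)
    rate = np.where(light, rate * (1.0 - config.masking_strength), rate)
    # dark activation is a masking response to darkness against a lit
    # context: it applies to DARK rest bins with light exposure in the
    # preceding 24 h (dark phases, dark pulses), not to sustained DD
    lag = int(round(24.0 / bin_h))
    cum = np.concatenate([[0], np.cumsum(light)])
    recent_light = cum[1:] - cum[np.maximum(np.arange(n_bins) + 1 - lag, 0)] > 0
    rate = np.where(~light & ~active & recent_light,
                    rate * config.dark_gain, rate)
    if np.any(rate < 0):
        raise ValueError("negative Poisson rate")

    rng = np.random.default_rng([config.seed, 1])
    counts = rng.poisson(rate)
    return ActivityTrace(counts=counts, bin_seconds=bin_seconds,
                         start_time_h=schedule.start_h)


# ---------------------------------------------------------------------------
# Hypnograms
# ---------------------------------------------------------------------------

def simulate_hypnogram(config: EEGSimConfig, schedule: LightSchedule,
                       duration_h: float, start_state: str = "W") -> Hypnogram:
    """Markov-chain hypnogram at 4-s steps with light-dependent transitions.

    The returned hypnogram carries the ground-truth TDW label; use
    :meth:`Hypnogram.collapse_tdw` for the W/NREM/REM version a visual
    scorer would produce.
    """
    epoch_h = config.epoch_seconds / 3600.0
    n_f = duration_h / epoch_h
    if abs(n_f - round(n_f)) > 1e-6:
        raise ValueError("duration must be a multiple of the epoch length")
    n = int(round(n_f))

    mats = {k: _validate_stochastic(np.asarray(m, dtype=float), k)
            for k, m in config.transition_matrices.items()}
    cums = {k: np.cumsum(m, axis=1) for k, m in mats.items()}
    for c in cums.values():
        c[:, -1] = 1.0

    centers = schedule.start_h + (np.arange(n) + 0.5) * epoch_h
    light = schedule.is_light(np.minimum(centers, schedule.end_h - 1e-9))

    rng = np.random.default_rng([config.seed, 2])
    u = rng.random(n)
    out = np.empty(n, dtype=np.int8)
    s = _STATE_INDEX[start_state]
    cum_light, cum_dark = cums[LIGHT], cums[DARK]
    for i in range(n):
        row = cum_light[s] if light[i] else cum_dark[s]
        s = int(np.searchsorted(row, u[i], side="right"))
        out[i] = s
    states = np.array(STATES, dtype="U4")[out]
    return Hypnogram(states=states, epoch_seconds=config.epoch_seconds,
                     start_time_h=schedule.start_h)


def enforce_sleep_deprivation(h: Hypnogram,
                              window: tuple[float, float]) -> Hypnogram:
    """Relabel every epoch within ``window`` (hours) as W ('gentle handling').

    Epochs outside the window are unchanged; an empty window returns the
    input hypnogram unchanged.
    """
    start, end = window
    if end < start:
        raise ValueError("inverted sleep-deprivation window")
    if end == start:
        return h
    if start < h.start_time_h - 1e-9 or end > h.start_time_h + h.duration_h + 1e-9:
        raise ValueError("window outside recording")
    centers = h.epoch_centers_h()
    states = h.states.copy()
    states[(centers >= start) & (centers < end)] = "W"
    return replace(h, states=states)


# ---------------------------------------------------------------------------
# EEG epoch signals
# ---------------------------------------------------------------------------

def simulate_eeg_epochs(h: Hypnogram, config: EEGSimConfig,
                        schedule: LightSchedule | None = None,
                        nrem_delta_scale: np.ndarray | None = None
                        ) -> np.ndarray:
    """Per-epoch EEG signals (epochs x samples, microvolts).

    Each epoch is 1/f-shaped noise plus the sinusoidal peaks of its state's
    template.  TDW epochs use ``tpf_light_hz`` or ``tpf_dark_hz`` depending
    on the light condition of the epoch (all-light if no schedule is given).
    ``nrem_delta_scale``, if given, multiplies the amplitude of the first
    NREM template peak per epoch (for homeostatic delta modulation).
    """
    n_samp = config.samples_per_epoch
    fs = config.sampling_hz
    nyq = fs / 2.0
    for st, tpl in config.state_templates.items():
        for pk in tpl.peaks:
            if pk.center_hz >= nyq:
                raise ValueError(f"{st} template peak at or above Nyquist")

    n = h.n_epochs
    if nrem_delta_scale is not None:
        nrem_delta_scale = np.asarray(nrem_delta_scale, dtype=float)
        if nrem_delta_scale.size != n:
            raise ValueError("nrem_delta_scale must have one value per epoch")

    if schedule is None:
        light = np.ones(n, dtype=bool)
    else:
        centers = np.minimum(h.epoch_centers_h(), schedule.end_h - 1e-9)
        light = schedule.is_light(centers)

    freqs = np.fft.rfftfreq(n_samp, 1.0 / fs)
    tvec = np.arange(n_samp) / fs
    signals = np.zeros((n, n_samp))
    rng = np.random.default_rng([config.seed, 3])

    # group epochs by (state, light condition) and synthesise vectorised
    for state in STATES:
        tpl = config.state_templates.get(state)
        if tpl is None:
            raise ValueError(f"missing template for state {state}")
        for is_light in (True, False):
            sel = np.flatnonzero((h.states == state) & (light == is_light))
            if sel.size == 0:
                continue
            m = sel.size
            x = np.zeros((m, n_samp))
            if tpl.noise_uV > 0:
                shape = np.power(np.maximum(freqs, 0.5), -tpl.slope / 2.0)
                shape[0] = 0.0
                s2 = 2.0 * np.sum(shape[1:-1] ** 2) + shape[-1] ** 2
                c = tpl.noise_uV * n_samp / math.sqrt(2.0 * s2)
                z = (rng.standard_normal((m, freqs.size))
                     + 1j * rng.standard_normal((m, freqs.size)))
                z[:, 0] = 0.0
                x += np.fft.irfft(z * (c * shape), n=n_samp, axis=1)
            for j, pk in enumerate(tpl.peaks):
                center = pk.center_hz
                if state == "TDW" and j == 0:
                    center = (config.tpf_light_hz if is_light
                              else config.tpf_dark_hz)
                fc = center + rng.normal(0.0, pk.width_hz, size=m)
                phi = rng.uniform(0.0, 2.0 * np.pi, size=m)
                amp = np.full(m, pk.amplitude_uV)
                if state == "NREM" and j == 0 and nrem_delta_scale is not None:
                    amp = amp * nrem_delta_scale[sel]
                x += amp[:, None] * np.sin(2.0 * np.pi * fc[:, None]
                                           * tvec[None, :] + phi[:, None])
            signals[sel] = x
    return signals


# ---------------------------------------------------------------------------
# ERG
# ---------------------------------------------------------------------------

def _cos_bump(t: np.ndarray, t0: float, w: float) -> np.ndarray:
    """Raised-cosine bump with compact support [t0 - w, t0 + w], peak 1."""
    u = (t - t0) / w
    out = np.cos(0.5 * np.pi * u) ** 2
    out[np.abs(u) > 1.0] = 0.0
    return out


def simulate_erg(a_amp_uV: float, b_amp_uV: float, noise_sd_uV: float = 0.0,
                 seed: int = 0, sampling_khz: float = 2.0) -> ERGTrace:
    """Flash-ERG trace with prescribed a- and b-wave amplitudes.

    The a-wave is a negative trough of depth ``a_amp_uV`` at ~20 ms after
    the stimulus; the b-wave peaks at ``b_amp_uV - a_amp_uV`` above baseline
    at ~65 ms, so that (b-wave peak) - (a-wave trough) = ``b_amp_uV``.  At
    zero noise, :func:`chronolume.eeg.erg_amplitudes` recovers the requested
    amplitudes exactly.
    """
    if a_amp_uV < 0 or b_amp_uV < 0:
        raise ValueError("amplitudes must be >= 0")
    if noise_sd_uV < 0:
        raise ValueError("noise_sd must be >= 0")
    dt = 1.0 / sampling_khz
    t = np.arange(-50.0, 200.0 + dt / 2, dt)
    # disjoint supports: a on [5, 35] ms, b on [35, 95] ms
    v = (-a_amp_uV * _cos_bump(t, 20.0, 15.0)
         + (b_amp_uV - a_amp_uV) * _cos_bump(t, 65.0, 30.0))
    if noise_sd_uV > 0:
        rng = np.random.default_rng([seed, 4])
        v = v + rng.normal(0.0, noise_sd_uV, size=t.size)
    return ERGTrace(time_ms=t, voltage_uV=v, stim_time_ms=0.0)
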