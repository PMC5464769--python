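"""Per-epoch EEG spectral analysis and theta-dominated-wakefulness scoring.

The core algorithm classifies 4-s waking epochs as theta-dominated
wakefulness (TDW) when the spectral peak in the 3.5-15 Hz search band falls
within the 6.5-12 Hz theta acceptance band and the power within +-1 Hz of
that peak exceeds 0.228 of the total 3.5-45 Hz power, subject to three
contextual criteria on the neighbouring epochs.  The module also provides
state- and light-condition-resolved mean spectra, light/dark spectral
ratios, band powers, theta-peak frequency, and ERG a-/b-wave amplitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .synth import ERGTrace, Hypnogram, LightSchedule

#: Frequency bands (Hz) reported by the spectral summaries.
BANDS = {
    "delta": (1.0, 4.0),          # NREM delta, sleep-pressure index
    "waking_delta": (2.0, 3.0),   # high-delta band of the waking EEG
    "theta": (6.5, 9.5),
    "beta_gamma": (25.0, 40.0),   # high-beta / low-gamma
}


# ---------------------------------------------------------------------------
# Epoch spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EpochSpectra:
    """Epochs x frequency-bin power densities (uV^2/Hz)."""

    freqs_hz: np.ndarray
    power: np.ndarray
    epoch_seconds: float = 4.0
    start_time_h: float = 0.0

    def __post_init__(self):
        f = np.asarray(self.freqs_hz, dtype=float)
        p = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "freqs_hz", f)
        object.__setattr__(self, "power", p)
        df = np.diff(f)
        if f.ndim != 1 or np.any(df <= 0) or np.ptp(df) > 1e-9:
            raise ValueError("freqs must be strictly increasing and uniform")
        if p.ndim != 2 or p.shape[1] != f.size:
            raise ValueError("power must be epochs x len(freqs)")

    @property
    def n_epochs(self) -> int:
        return self.power.shape[0]

    @property
    def df_hz(self) -> float:
        return float(self.freqs_hz[1] - self.freqs_hz[0])

    def epoch_centers_h(self) -> np.ndarray:
        eh = self.epoch_seconds / 3600.0
        return self.start_time_h + (np.arange(self.n_epochs) + 0.5) * eh

    def band_mask(self, lo_hz: float, hi_hz: float) -> np.ndarray:
        """Bins whose centres lie in [lo, hi] inclusive."""
        return (self.freqs_hz >= lo_hz - 1e-9) & (self.freqs_hz <= hi_hz + 1e-9)


def compute_epoch_spectra(signals: np.ndarray, sampling_hz: float,
                          epoch_seconds: float = 4.0,
                          start_time_h: float = 0.0) -> EpochSpectra:
    """Hann-tapered periodogram of each epoch (single 4-s segment).

    Power is a one-sided density scaled so that ``sum(power) * df`` equals
    the taper-power-normalised variance of the windowed epoch,
    ``sum((w*x)**2) / sum(w**2)``.
    """
    x = np.asarray(signals, dtype=float)
    if x.ndim != 2:
        raise ValueError("signals must be epochs x samples")
    expected = sampling_hz * epoch_seconds
    if abs(x.shape[1] - expected) > 1e-9:
        raise ValueError(
            f"epoch length {x.shape[1]} != sampling_hz*epoch_seconds "
            f"({expected:g})")
    freqs, power = sps.periodogram(x, fs=sampling_hz, window="hann",
                                   detrend=False, scaling="density", axis=-1)
    return EpochSpectra(freqs_hz=freqs, power=power,
                        epoch_seconds=epoch_seconds, start_time_h=start_time_h)


# ---------------------------------------------------------------------------
# TDW classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TDWParams:
    """Thresholds of the TDW scoring algorithm."""

    tpf_search_hz: tuple[float, float] = (3.5, 15.0)
    tpf_accept_hz: tuple[float, float] = (6.5, 12.0)
    ratio_halfwidth_hz: float = 1.0
    total_band_hz: tuple[float, float] = (3.5, 45.0)
    ratio_threshold: float = 0.228
    context_rules: bool = True
    isolation_flank: int = 3   # rule 3: >= this many flanking W epochs

    def __post_init__(self):
        if not (self.tpf_search_hz[0] <= self.tpf_accept_hz[0]
                and self.tpf_accept_hz[1] <= self.tpf_search_hz[1]):
            raise ValueError("accept band must lie within the search band")
        if not 0 < self.ratio_threshold < 1:
            raise ValueError("ratio_threshold must be in (0, 1)")


@dataclass(frozen=True)
class TDWDetails:
    tpf_hz: np.ndarray          # per-epoch theta-peak frequency (NaN non-W)
    theta_ratio: np.ndarray     # per-epoch theta/total power ratio
    candidates: np.ndarray      # spectral pass (before context rules)
    missing_spectra: np.ndarray  # W epochs left unclassified (flag)


def theta_ratio_and_tpf(spectra: EpochSpectra, params: TDWParams | None = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch theta-peak frequency (argmax in the search band) and the
    ratio of power within +-1 Hz of it over total 3.5-45 Hz power."""
    p = params or TDWParams()
    f = spectra.freqs_hz
    search = spectra.band_mask(*p.tpf_search_hz)
    total = spectra.band_mask(*p.total_band_hz)
    if not search.any() or not total.any():
        raise ValueError("bands outside the spectral range")
    pw = spectra.power
    f_search = f[search]
    tpf = f_search[np.argmax(pw[:, search], axis=1)]
    near = (np.abs(f[None, :] - tpf[:, None])
            <= p.ratio_halfwidth_hz + 1e-9)
    theta_power = (pw * near).sum(axis=1)
    total_power = pw[:, total].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total_power > 0, theta_power / total_power, 0.0)
    return tpf, ratio


def classify_tdw(h: Hypnogram, spectra: EpochSpectra,
                 params: TDWParams | None = None,
                 return_details: bool = False):
    """Score TDW epochs in a W/NREM/REM hypnogram.

    Pass 1 (spectral): a W epoch is a candidate when its theta-peak
    frequency lies in the acceptance band and its theta/total ratio exceeds
    the threshold.  Pass 2 (forward sweep): a candidate is demoted when the
    final label of the preceding epoch is neither W nor TDW, or when the
    input label of the following epoch is NREM (the last epoch is exempt;
    the first epoch has no predecessor and cannot become TDW).  Pass 3:
    single TDW epochs flanked on both sides by >= ``isolation_flank``
    consecutive non-TDW W epochs are demoted.  NREM and REM labels are
    never altered.
    """
    p = params or TDWParams()
    if spectra.n_epochs != h.n_epochs:
        raise ValueError("epoch counts of spectra and hypnogram differ")
    labels = h.states
    tpf, ratio = theta_ratio_and_tpf(spectra, p)

    missing = np.isnan(spectra.power).any(axis=1) & (labels == "W")
    is_w = labels == "W"
    cand = (is_w & ~missing
            & (tpf >= p.tpf_accept_hz[0]) & (tpf <= p.tpf_accept_hz[1])
            & (ratio > p.ratio_threshold))

    final = labels.copy()
    n = labels.size
    if p.context_rules:
        for i in np.flatnonzero(cand):
            if i == 0:
                continue  # no in-file predecessor: rule 1 cannot be met
            if final[i - 1] not in ("W", "TDW"):
                continue  # rule 1
            if i + 1 < n and labels[i + 1] == "NREM":
                continue  # rule 2 (last epoch exempt)
            final[i] = "TDW"
        # rule 3 on a frozen copy: single application, no fixpoint iteration
        after2 = final.copy()
        fl = p.isolation_flank
        for i in np.flatnonzero(after2 == "TDW"):
            if i > 0 and after2[i - 1] == "TDW":
                continue
            if i + 1 < n and after2[i + 1] == "TDW":
                continue
            left = after2[max(0, i - fl):i]
            right = after2[i + 1:i + 1 + fl]
            if (left.size == fl and np.all(left == "W")
                    and right.size == fl and np.all(right == "W")):
                final[i] = "W"
    else:
        final[cand] = "TDW"

    out = replace(h, states=final)
    if return_details:
        tpf_out = np.where(is_w, tpf, np.nan)
        return out, TDWDetails(tpf_hz=tpf_out, theta_ratio=ratio,
                               candidates=cand, missing_spectra=missing)
    return out


# ---------------------------------------------------------------------------
# State spectra, ratios, band powers, TPF
# ---------------------------------------------------------------------------

def band_power(spectra: EpochSpectra, band_hz: tuple[float, float],
               epoch_mask: np.ndarray | None = None) -> float:
    """Mean (over selected epochs) of the power summed across the band's
    bins.  NaN for an empty epoch selection."""
    lo, hi = band_hz
    bins = spectra.band_mask(lo, hi)
    if not bins.any():
        raise ValueError("band outside the spectral range")
    pw = spectra.power if epoch_mask is None else spectra.power[epoch_mask]
    if pw.shape[0] == 0:
        return math.nan
    return float(pw[:, bins].sum(axis=1).mean())


@dataclass(frozen=True)
class TPFEstimate:
    tpf_hz: float
    tied: bool = False   # flat maximum: lowest frequency returned


def theta_peak_frequency(spectra: EpochSpectra,
                         epoch_mask: np.ndarray | None = None,
                         search_band_hz: tuple[float, float] = (3.5, 15.0)
                         ) -> TPFEstimate:
    """Frequency of the maximum of the mean spectrum in the search band.
    Ties return the lowest tied frequency, flagged."""
    pw = spectra.power if epoch_mask is None else spectra.power[epoch_mask]
    if pw.shape[0] == 0:
        raise ValueError("empty epoch selection")
    bins = spectra.band_mask(*search_band_hz)
    mean = pw[:, bins].mean(axis=0)
    i = int(np.argmax(mean))
    tied = bool(np.sum(mean == mean[i]) > 1)
    return TPFEstimate(tpf_hz=float(spectra.freqs_hz[bins][i]), tied=tied)


#: Wake partition used in the state-resolved summaries: total wakefulness,
#: its TDW and non-TDW sub-states, plus NREM and REM sleep.
SUMMARY_STATES = ("W_total", "TDW", "non_TDW", "NREM", "REM")


def _state_mask(labels: np.ndarray, state: str) -> np.ndarray:
    if state == "W_total":
        return (labels == "W") | (labels == "TDW")
    if state == "non_TDW":
        return labels == "W"
    return labels == state


@dataclass(frozen=True)
class SpectralSummary:
    freqs_hz: np.ndarray
    mean_spectra: dict      # (state, condition) -> mean spectrum or None
    n_epochs: dict          # (state, condition) -> epoch count
    ld_ratio_pct: dict      # state -> 100*(light/dark - 1) per bin, or None
    band_powers: dict       # (state, condition, band) -> mean power or NaN
    tpf_hz: dict            # (state, condition) -> TPFEstimate or None


def state_spectra_and_ratios(spectra: EpochSpectra, hypnogram: Hypnogram,
                             schedule: LightSchedule) -> SpectralSummary:
    """Mean spectra per state and light condition, light/dark ratios, band
    powers and theta-peak frequencies.

    The light/dark ratio is the linear percent difference per frequency
    bin, ``100 * (light mean / dark mean - 1)``, zero where the two
    conditions have equal power.  Empty state x condition cells are
    reported missing (None / NaN), never as zero.
    """
    if spectra.n_epochs != hypnogram.n_epochs:
        raise ValueError("epoch counts of spectra and hypnogram differ")
    labels = hypnogram.states
    centers = np.minimum(hypnogram.epoch_centers_h(), schedule.end_h - 1e-9)
    light = schedule.is_light(centers)

    mean_spectra: dict = {}
    n_epochs: dict = {}
    ld_ratio: dict = {}
    band_powers: dict = {}
    tpf: dict = {}
    for state in SUMMARY_STATES:
        sm = _state_mask(labels, state)
        for cond, cmask in (("light", light), ("dark", ~light)):
            sel = sm & cmask
            n_epochs[(state, cond)] = int(sel.sum())
            if not sel.any():
                mean_spectra[(state, cond)] = None
                tpf[(state, cond)] = None
                for b in BANDS:
                    band_powers[(state, cond, b)] = math.nan
                continue
            mean_spectra[(state, cond)] = spectra.power[sel].mean(axis=0)
            tpf[(state, cond)] = theta_peak_frequency(spectra, sel)
            for b, band in BANDS.items():
                band_powers[(state, cond, b)] = band_power(spectra, band, sel)
        lm, dm = mean_spectra[(state, "light")], mean_spectra[(state, "dark")]
        if lm is None or dm is None:
            ld_ratio[state] = None
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                ld_ratio[state] = 100.0 * (lm / dm - 1.0)
    return SpectralSummary(freqs_hz=spectra.freqs_hz,
                           mean_spectra=mean_spectra, n_epochs=n_epochs,
                           ld_ratio_pct=ld_ratio, band_powers=band_powers,
                           tpf_hz=tpf)


# ---------------------------------------------------------------------------
# ERG amplitudes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ERGAmplitudes:
    a_uV: float       # a-wave: |trough - baseline at stimulation|
    b_uV: float       # b-wave: peak after the a-wave minus the a-wave trough
    t_a_ms: float     # trough latency from stimulus
    t_b_ms: float     # peak latency from stimulus
    flagged: bool = False


def erg_amplitudes(trace: ERGTrace, flat_tol_uV: float = 1e-9,
                   smooth_ms: float = 0.0) -> ERGAmplitudes:
    """a- and b-wave amplitudes of a flash ERG.

    The a-wave amplitude is the difference between the post-stimulus trough
    and the baseline voltage at the time of stimulation; the b-wave
    amplitude is the difference between the subsequent maximum and the
    a-wave trough.  A flat trace is flagged unmeasurable.

    ``smooth_ms`` applies a moving average of that width before the
    extrema are located (extreme-value bias of raw peak picking on noisy
    traces); 0 analyses the raw trace.
    """
    t, v = trace.time_ms, trace.voltage_uV
    if smooth_ms > 0:
        dt = float(np.median(np.diff(t)))
        w = max(1, int(round(smooth_ms / dt)))
        v = np.convolve(v, np.ones(w) / w, mode="same")
    post = t >= trace.stim_time_ms
    if post.sum() < 3:
        raise ValueError("trace must extend past the stimulus")
    baseline = float(np.interp(trace.stim_time_ms, t, v))
    tp, vp = t[post], v[post]
    if float(vp.max() - vp.min()) <= flat_tol_uV:
        return ERGAmplitudes(0.0, 0.0, math.nan, math.nan, flagged=True)
    ia = int(np.argmin(vp))
    a = abs(float(vp[ia]) - baseline)
    after = vp[ia:]
    ib = ia + int(np.argmax(after))
    b = float(vp[ib]) - float(vp[ia])
    flagged = ib == ia or ia == vp.size - 1  # monotone: no peak after trough
    return ERGAmplitudes(a_uV=a, b_uV=b,
                         t_a_ms=float(tp[ia] - trace.stim_time_ms),
                         t_b_ms=float(tp[ib] - trace.stim_time_ms),
                         flagged=flagged)
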