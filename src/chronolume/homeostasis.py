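"""Sleep-homeostasis time courses.

Hourly state-time profiles, the NREM delta-power (1-4 Hz) time course
across baseline, sleep deprivation and recovery, and cumulative
recovery-minus-baseline difference curves.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .eeg import EpochSpectra, band_power
from .synth import Hypnogram, LightSchedule

DELTA_BAND = (1.0, 4.0)


def state_time_course(h: Hypnogram, bin_h: float = 1.0) -> pd.DataFrame:
    """Minutes per state per time bin.

    Returns a frame indexed by bin start (hours) with columns ``W`` (wake
    excluding TDW), ``TDW``, ``NREM``, ``REM`` and ``W_total`` (wake
    including TDW); W_total + NREM + REM sums to the bin length.  A trailing
    partial bin is dropped (``frame.attrs['dropped_partial_bin']``).
    """
    epochs_per_bin_f = bin_h * 3600.0 / h.epoch_seconds
    if abs(epochs_per_bin_f - round(epochs_per_bin_f)) > 1e-9:
        raise ValueError("bin must hold an integral number of epochs")
    epb = int(round(epochs_per_bin_f))
    n_bins = h.n_epochs // epb
    dropped = h.n_epochs % epb != 0
    lab = h.states[:n_bins * epb].reshape(n_bins, epb)
    minutes = h.epoch_seconds / 60.0
    data = {s: (lab == s).sum(axis=1) * minutes
            for s in ("W", "TDW", "NREM", "REM")}
    df = pd.DataFrame(data,
                      index=h.start_time_h + np.arange(n_bins) * bin_h)
    df["W_total"] = df["W"] + df["TDW"]
    df.index.name = "bin_start_h"
    df.attrs["bin_h"] = bin_h
    df.attrs["dropped_partial_bin"] = dropped
    return df


def delta_timecourse(spectra: EpochSpectra, h: Hypnogram,
                     schedule: LightSchedule | None = None,
                     min_nrem_epochs: int = 75,
                     reference_windows=((8.0, 12.0), (32.0, 36.0)),
                     bin_h: float = 1.0,
                     band: tuple[float, float] = DELTA_BAND) -> pd.DataFrame:
    """Hourly NREM delta-power time course, absolute and % of reference.

    Per bin, the mean 1-4 Hz band power over NREM epochs; bins with fewer
    than ``min_nrem_epochs`` NREM epochs are missing.  The percent scale
    divides by the mean NREM delta power inside ``reference_windows``
    (default: the last 4 h of the light period of two baseline LD12:12
    days, ZT8-12).  If the reference holds no NREM, the percent scale is
    unavailable and flagged.
    """
    if spectra.n_epochs != h.n_epochs:
        raise ValueError("epoch counts of spectra and hypnogram differ")
    centers = h.epoch_centers_h()
    nrem = h.states == "NREM"
    per_epoch_delta = spectra.power[:, spectra.band_mask(*band)].sum(axis=1)

    ref_mask = np.zeros(h.n_epochs, dtype=bool)
    for lo, hi in reference_windows:
        ref_mask |= (centers >= lo) & (centers < hi)
    ref_mask &= nrem
    ref_available = bool(ref_mask.any())
    ref = float(per_epoch_delta[ref_mask].mean()) if ref_available else math.nan

    n_bins = int(math.floor(h.duration_h / bin_h + 1e-9))
    rows = []
    for k in range(n_bins):
        lo = h.start_time_h + k * bin_h
        sel = nrem & (centers >= lo) & (centers < lo + bin_h)
        n = int(sel.sum())
        if n < min_nrem_epochs:
            rows.append((lo, math.nan, math.nan, n, True))
            continue
        mean_delta = float(per_epoch_delta[sel].mean())
        pct = 100.0 * mean_delta / ref if ref_available else math.nan
        rows.append((lo, mean_delta, pct, n, False))
    df = pd.DataFrame(rows, columns=["bin_start_h", "delta_abs", "delta_pct",
                                     "n_nrem_epochs", "missing"])
    df = df.set_index("bin_start_h")
    df.attrs["reference_delta_abs"] = ref
    df.attrs["reference_available"] = ref_available
    df.attrs["min_nrem_epochs"] = min_nrem_epochs
    return df


def fold_to_zt(course: pd.DataFrame, day_h: float = 24.0) -> pd.DataFrame:
    """Average a state-time course over days, indexed by ZT bin start.
    Used to collapse the two baseline days into one mean baseline day."""
    zt = np.mod(course.index.to_numpy(dtype=float), day_h)
    return course.groupby(zt).mean().rename_axis("zt_h")


def recovery_accumulation(baseline: pd.DataFrame, recovery: pd.DataFrame,
                          states=("NREM", "REM"), day_h: float = 24.0
                          ) -> pd.DataFrame:
    """Cumulative recovery-minus-baseline state minutes, hour by hour.

    ``baseline`` is a (typically day-folded) state-time course indexed by
    ZT; ``recovery`` covers the window of interest on the recording's time
    axis and is aligned to baseline by clock time (ZT = time mod 24).  The
    final cumulative value equals total recovery minus total baseline
    minutes over the window.
    """
    zt = np.mod(recovery.index.to_numpy(dtype=float), day_h)
    base_idx = baseline.index.to_numpy(dtype=float)
    pos = np.searchsorted(base_idx, zt)
    if (np.any(pos >= base_idx.size)
            or np.any(np.abs(base_idx[pos] - zt) > 1e-6)):
        raise ValueError("recovery bins do not align with baseline ZT bins")
    out = pd.DataFrame(index=recovery.index.copy())
    for s in states:
        diff = recovery[s].to_numpy() - baseline[s].to_numpy()[pos]
        out[f"diff_{s}_min"] = diff
        out[f"cum_{s}_min"] = np.cumsum(diff)
    return out
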