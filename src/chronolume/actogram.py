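"""Locomotor-activity analytics.

Onset/offset detection, the chi-square (Sokolove-Bushell) periodogram,
onset-regression period and precision estimates, phase angle of entrainment,
light-pulse phase shifts, alpha/rho durations, masking indices, and
double-plotted actogram rendering.

All estimators take :class:`chronolume.synth.ActivityTrace` /
:class:`chronolume.synth.LightSchedule` objects and report times in decimal
hours on the trace's own time axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .synth import LIGHT, ActivityTrace, Hypnogram, LightSchedule


# ---------------------------------------------------------------------------
# Onset / offset detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OnsetDetectionParams:
    """Smoothed threshold-persistence detector for activity on/offsets.

    An onset is the start of the first run of at least ``persistence_bins``
    smoothed bins above ``onset_threshold_frac`` x (cycle max of the
    smoothed trace), preceded by at least ``quiescence_bins`` bins below the
    threshold; the event time is then refined to the first pair of raw bins
    at or above the threshold near the smoothed crossing.  Offsets apply the
    time-reversed rule.
    """

    smooth_window_min: float = 30.0
    onset_threshold_frac: float = 0.25
    persistence_bins: int = 6
    quiescence_bins: int = 12

    def __post_init__(self):
        if not 0 < self.onset_threshold_frac < 1:
            raise ValueError("onset_threshold_frac must be in (0, 1)")
        if self.persistence_bins < 1 or self.quiescence_bins < 1:
            raise ValueError("windows must span at least one bin")


@dataclass(frozen=True)
class OnsetResult:
    onsets_h: np.ndarray      # one entry per cycle, NaN when undetectable
    offsets_h: np.ndarray
    cycle_idx: np.ndarray
    expected_period_h: float
    all_zero: bool = False    # warning flag for an all-zero trace


def _find_event(smooth: np.ndarray, raw: np.ndarray, thr: float,
                i0: int, i1: int, persistence: int, quiescence: int,
                refine_back: int) -> float:
    """Index (float, bins) of the first threshold-persistence event in
    [i0, i1) or NaN.  The quiescence window must lie within the data, so a
    bout truncated by the recording edge never yields an event."""
    above = smooth >= thr
    n = smooth.size
    for i in range(i0, i1):
        j1 = i + persistence
        if j1 > n or not above[i:j1].all():
            continue
        q0 = i - quiescence
        if q0 < 0 or above[q0:i].any():
            continue
        # refine the event time on the raw trace: maximum-likelihood Poisson
        # changepoint within the local window around the smoothed run start,
        # with rest/active rates estimated from the flanking bins
        lo = max(q0, i - refine_back)
        hi = min(n, i + persistence)
        # rest rate from an extended pre-event stretch for stability
        r0 = max(0, i - 4 * quiescence)
        lam0 = max(float(raw[r0:i].mean()), 1e-3)
        lam1 = max(float(raw[i:hi].mean()), lam0 + 1e-3)
        seg = raw[lo:hi]
        # log-likelihood difference of assigning each bin to active vs rest
        gain = seg * (math.log(lam1) - math.log(lam0)) - (lam1 - lam0)
        # changepoint j: bins [lo, j) rest, [j, hi) active
        ll = -np.cumsum(np.concatenate([[0.0], gain]))
        return float(lo + int(np.argmax(ll)))
    return math.nan


def detect_onsets_offsets(trace: ActivityTrace,
                          params: OnsetDetectionParams | None = None,
                          expected_period_h: float = 24.0) -> OnsetResult:
    """Per-cycle activity onsets and offsets.

    The trace is split into consecutive windows of ``expected_period_h``;
    within each, the detector returns at most one onset and one offset.
    Cycles without a detectable event get NaN, never a fabricated time.
    """
    p = params or OnsetDetectionParams()
    bin_h = trace.bin_h
    if trace.duration_h < 2 * expected_period_h:
        raise ValueError("trace must span at least two expected periods")

    w = max(1, int(round(p.smooth_window_min / (trace.bin_seconds / 60.0))))
    kernel = np.ones(w) / w
    raw = trace.counts.astype(float)
    smooth = np.convolve(raw, kernel, mode="same")

    n_cycles = int(math.floor(trace.duration_h / expected_period_h + 1e-9))
    bins_per_cycle = expected_period_h / bin_h
    onsets = np.full(n_cycles, np.nan)
    offsets = np.full(n_cycles, np.nan)

    all_zero = not np.any(raw > 0)
    if all_zero:
        return OnsetResult(onsets, offsets, np.arange(n_cycles),
                           expected_period_h, all_zero=True)

    raw_rev = raw[::-1]
    smooth_rev = smooth[::-1]
    n = raw.size
    for k in range(n_cycles):
        i0 = int(round(k * bins_per_cycle))
        i1 = min(int(round((k + 1) * bins_per_cycle)), n)
        thr = p.onset_threshold_frac * smooth[i0:i1].max()
        if thr <= 0:
            continue
        # scan starts a smoothing width early: smoothing can push the start
        # of a run across the cycle-window boundary; an event already
        # claimed by the previous cycle is not reported twice
        j = _find_event(smooth, raw, thr, max(0, i0 - w), i1,
                        p.persistence_bins, p.quiescence_bins, refine_back=w)
        if not math.isnan(j):
            t_event = trace.start_time_h + j * bin_h
            if k == 0 or t_event != onsets[k - 1]:
                onsets[k] = t_event
        # offsets: same rule on the time-reversed trace
        r0, r1 = n - i1, n - i0
        j = _find_event(smooth_rev, raw_rev, thr, max(0, r0 - w), r1,
                        p.persistence_bins, p.quiescence_bins, refine_back=w)
        if not math.isnan(j):
            t_event = trace.start_time_h + (n - j) * bin_h
            if k == 0 or t_event != offsets[k - 1]:
                offsets[k] = t_event
    return OnsetResult(onsets, offsets, np.arange(n_cycles),
                       expected_period_h)


# ---------------------------------------------------------------------------
# Chi-square periodogram
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeriodogramResult:
    periods_h: np.ndarray
    qp: np.ndarray
    signif_line: np.ndarray      # pointwise chi-square critical value
    df: np.ndarray               # degrees of freedom (K - 1) per period
    confidence: float
    flagged_constant: bool = False

    @property
    def peak_period_h(self) -> float:
        return float(self.periods_h[int(np.argmax(self.qp))])

    @property
    def qp_max(self) -> float:
        return float(np.max(self.qp))

    @property
    def peak_significant(self) -> bool:
        """Peak test at the family-wise level: the pointwise chi-square line
        is anticonservative across the ~100 tested periods, so the peak is
        compared against a Bonferroni-corrected critical value."""
        i = int(np.argmax(self.qp))
        alpha = (1.0 - self.confidence) / self.periods_h.size
        crit = stats.chi2.ppf(1.0 - alpha, df=self.df[i])
        return bool(self.qp[i] > crit)


def chi_square_periodogram(trace: ActivityTrace,
                           period_range_h: tuple[float, float] = (20.0, 28.0),
                           step_h: float | None = None,
                           confidence: float = 0.99) -> PeriodogramResult:
    """Sokolove-Bushell chi-square periodogram.

    For each candidate period of K bins the trace is folded into K columns;
    the statistic is ``Qp = sum_h N_h (Mbar_h - Mbar)^2 / sigma2`` with
    ``sigma2 = sum_i (x_i - Mbar)^2 / n``, which is chi-square distributed
    with K - 1 degrees of freedom for an arrhythmic trace.  The significance
    line is the chi-square critical value at ``confidence`` per period.
    """
    x = trace.counts.astype(float)
    n = x.size
    bin_h = trace.bin_h
    lo, hi = period_range_h
    if lo < 2 * bin_h or hi > trace.duration_h / 2:
        raise ValueError("period range must lie within (2*bin, length/2)")

    step = step_h if step_h is not None else bin_h
    k_step = max(1, int(round(step / bin_h)))
    k_lo = int(math.ceil(lo / bin_h - 1e-9))
    k_hi = int(math.floor(hi / bin_h + 1e-9))
    ks = np.arange(k_lo, k_hi + 1, k_step)

    grand = x.mean()
    denom = float(((x - grand) ** 2).sum())
    flagged = denom == 0.0

    qp = np.zeros(ks.size)
    line = np.zeros(ks.size)
    idx_all = np.arange(n)
    for i, k in enumerate(ks):
        col = idx_all % k
        sums = np.bincount(col, weights=x, minlength=k)
        cnts = np.bincount(col, minlength=k)
        means = sums / cnts
        if flagged:
            qp[i] = np.nan
        else:
            qp[i] = float((cnts * (means - grand) ** 2).sum()) * n / denom
        line[i] = stats.chi2.ppf(confidence, df=k - 1)
    return PeriodogramResult(periods_h=ks * bin_h, qp=qp, signif_line=line,
                             df=(ks - 1).astype(float), confidence=confidence,
                             flagged_constant=flagged)


# ---------------------------------------------------------------------------
# Onset regression: period, precision, phase angle, phase shifts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OnsetRegression:
    tau_h: float
    intercept_h: float     # clock time of the fitted onset at cycle 0
    r: float               # |Pearson r| of the fit (onset precision)
    z: float               # Fisher Z of r; inf (flagged) for a perfect fit
    n: int
    z_infinite: bool = False


def fit_onset_regression(onsets_h, cycle_idx=None) -> OnsetRegression:
    """Least-squares line of onset clock time against cycle index.

    ``tau_h = 24 + slope`` (hours per cycle).  ``r`` is the absolute
    correlation coefficient of the fit, the paper-style onset-precision
    index, and ``z = atanh(r)``.  Missing (NaN) onsets are dropped pairwise;
    fewer than three onsets is an error.
    """
    onsets = np.asarray(onsets_h, dtype=float)
    cyc = (np.arange(onsets.size) if cycle_idx is None
           else np.asarray(cycle_idx, dtype=float))
    ok = ~np.isnan(onsets)
    onsets, cyc = onsets[ok], cyc[ok]
    if onsets.size < 3:
        raise ValueError("need at least 3 onsets for the regression")
    clock = onsets - 24.0 * cyc
    res = stats.linregress(cyc, clock)
    r = min(abs(float(res.rvalue)), 1.0)
    z_inf = bool(r >= 1.0 - 1e-15)
    z = math.inf if z_inf else math.atanh(r)
    return OnsetRegression(tau_h=24.0 + float(res.slope),
                           intercept_h=float(res.intercept),
                           r=r, z=z, n=int(onsets.size), z_infinite=z_inf)


def reject_onset_outliers(onsets_h, cycle_idx=None,
                          sigma: float = 5.0) -> np.ndarray:
    """Set onsets with gross regression residuals to NaN (one pass).

    Automated onset detection occasionally locks onto a spurious activity
    bout; a single gross outlier can dominate the period and phase-angle
    fits.  Residuals beyond ``sigma`` robust standard deviations (MAD-based)
    of the onset-vs-cycle line are discarded, the curation step otherwise
    done by hand on actograms.
    """
    onsets = np.asarray(onsets_h, dtype=float).copy()
    cyc = (np.arange(onsets.size) if cycle_idx is None
           else np.asarray(cycle_idx, dtype=float))
    ok = ~np.isnan(onsets)
    if ok.sum() < 4:
        return onsets
    clock = onsets[ok] - 24.0 * cyc[ok]
    res = stats.linregress(cyc[ok], clock)
    resid = clock - (res.intercept + res.slope * cyc[ok])
    mad = np.median(np.abs(resid - np.median(resid)))
    scale = max(1.4826 * mad, 1e-6)
    bad = np.abs(resid - np.median(resid)) > sigma * scale
    idx = np.flatnonzero(ok)[bad]
    onsets[idx] = np.nan
    return onsets


def phase_angle(ld_onsets_h, dd_onsets_h, ld_days=None, dd_days=None,
                last_ld_day: int | None = None) -> float:
    """Phase angle of entrainment psi (hours, signed).

    The free-running (DD) onset series is regressed on day index and
    extrapolated back to the last LD day; psi is the mean LD onset clock
    time minus that extrapolated onset.  psi < 0 when the extrapolated DD
    onset falls later than the entrained onset.
    """
    ld = np.asarray(ld_onsets_h, dtype=float)
    dd = np.asarray(dd_onsets_h, dtype=float)
    ld_days = (np.arange(ld.size) if ld_days is None
               else np.asarray(ld_days, dtype=float))
    dd_days = (ld_days[-1] + 1 + np.arange(dd.size) if dd_days is None
               else np.asarray(dd_days, dtype=float))
    if last_ld_day is None:
        last_ld_day = float(ld_days[~np.isnan(ld)][-1])
    ok_ld = ~np.isnan(ld)
    ok_dd = ~np.isnan(dd)
    if ok_ld.sum() < 3 or ok_dd.sum() < 3:
        raise ValueError("need at least 3 LD and 3 DD onsets")
    clock_ld = ld[ok_ld] - 24.0 * ld_days[ok_ld]
    clock_dd = dd[ok_dd] - 24.0 * dd_days[ok_dd]
    res = stats.linregress(dd_days[ok_dd], clock_dd)
    extrapolated = float(res.intercept + res.slope * last_ld_day)
    return float(np.mean(clock_ld) - extrapolated)


@dataclass(frozen=True)
class PhaseShiftResult:
    delta_phi_h: float       # signed shift in circadian hours, advance > 0
    ct_of_pulse: float | None
    n_pre: int
    n_post: int


def phase_shift(pre_onsets_h, pre_cycles, post_onsets_h, post_cycles,
                tau_h: float, ct_of_pulse: float | None = None
                ) -> PhaseShiftResult:
    """Phase shift from pre- vs post-pulse onset series.

    Both series are projected onto a common reference with the free-running
    slope tau (onset = intercept + tau * cycle); the shift is the difference
    of intercepts converted to circadian hours (x 24/tau), advance positive.
    The caller supplies post-pulse onsets with the first post-pulse day
    already excluded.
    """
    pre = np.asarray(pre_onsets_h, dtype=float)
    post = np.asarray(post_onsets_h, dtype=float)
    cp = np.asarray(pre_cycles, dtype=float)
    cq = np.asarray(post_cycles, dtype=float)
    ok_pre, ok_post = ~np.isnan(pre), ~np.isnan(post)
    if ok_pre.sum() < 2 or ok_post.sum() < 2:
        raise ValueError("insufficient onsets around the pulse")
    b_pre = float(np.mean(pre[ok_pre] - tau_h * cp[ok_pre]))
    b_post = float(np.mean(post[ok_post] - tau_h * cq[ok_post]))
    delta = (b_pre - b_post) * 24.0 / tau_h
    return PhaseShiftResult(delta_phi_h=delta, ct_of_pulse=ct_of_pulse,
                            n_pre=int(ok_pre.sum()), n_post=int(ok_post.sum()))


def phase_shift_from_series(onsets_h, pulse_cycle: int, tau_h: float,
                            n_pre: int = 3, n_post: int = 10,
                            ct_of_pulse: float | None = None
                            ) -> PhaseShiftResult:
    """Phase shift from a per-cycle onset array around a pulse.

    Uses the ``n_pre`` onsets before the pulse cycle and ``n_post`` onsets
    starting two cycles after it: the onset on the first day after the
    pulse is not taken into account.
    """
    onsets = np.asarray(onsets_h, dtype=float)
    pre_idx = np.arange(pulse_cycle - n_pre, pulse_cycle)
    post_idx = np.arange(pulse_cycle + 2, pulse_cycle + 2 + n_post)
    if pre_idx[0] < 0 or post_idx[-1] >= onsets.size:
        raise ValueError("onset series too short around the pulse")
    return phase_shift(onsets[pre_idx], pre_idx, onsets[post_idx], post_idx,
                       tau_h, ct_of_pulse=ct_of_pulse)


# ---------------------------------------------------------------------------
# Alpha / rho
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlphaRho:
    alpha_h: np.ndarray    # per-cycle active-phase duration (NaN if missing)
    mean_alpha_h: float
    mean_rho_h: float
    cycle_h: float


def alpha_rho(onsets_h, offsets_h, cycle_h: float) -> AlphaRho:
    """Active (alpha) and rest (rho) phase durations per cycle.

    alpha = (offset - onset) mod cycle; rho = cycle - alpha.  Cycles with a
    missing onset or offset are NaN.
    """
    onsets = np.asarray(onsets_h, dtype=float)
    offsets = np.asarray(offsets_h, dtype=float)
    if onsets.shape != offsets.shape:
        raise ValueError("onsets and offsets must be paired per cycle")
    alpha = np.mod(offsets - onsets, cycle_h)
    mean_alpha = float(np.nanmean(alpha)) if np.any(~np.isnan(alpha)) else math.nan
    return AlphaRho(alpha_h=alpha, mean_alpha_h=mean_alpha,
                    mean_rho_h=cycle_h - mean_alpha, cycle_h=cycle_h)


# ---------------------------------------------------------------------------
# Masking / relative activity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaskingSummary:
    rel_activity_bins: np.ndarray          # % of baseline, per bin
    segments: list = field(default_factory=list)
    # each segment: dict(state, start_h, end_h, rel_pct, mean_counts)
    light_phase_pct: float = math.nan
    dark_phase_pct: float = math.nan
    baseline_per_bin: float = math.nan
    flagged_zero_baseline: bool = False


def mean_counts_per_bin(trace: ActivityTrace,
                        window: tuple[float, float] | None = None) -> float:
    """Mean counts per bin, optionally restricted to a time window."""
    if window is None:
        return float(trace.counts.mean())
    starts = trace.bin_starts_h()
    sel = (starts >= window[0]) & (starts + trace.bin_h <= window[1] + 1e-9)
    if not np.any(sel):
        raise ValueError("window contains no complete bins")
    return float(trace.counts[sel].mean())


def relative_activity(trace: ActivityTrace, schedule: LightSchedule,
                      baseline_per_bin: float) -> MaskingSummary:
    """Activity as percent of a 24-h LD12:12 baseline (per bin and segment).

    ``baseline_per_bin`` is the animal's mean counts per bin over the
    LD12:12 reference days (100%).  Per-interval means cover every LIGHT
    and DARK interval of the schedule (for LD1:1 these are the individual
    1-h pulses); aggregated light- and dark-phase means are also reported.
    """
    if baseline_per_bin <= 0:
        return MaskingSummary(rel_activity_bins=np.full(trace.n_bins, np.nan),
                              flagged_zero_baseline=True)
    rel = 100.0 * trace.counts / baseline_per_bin
    centers = trace.bin_centers_h()
    segments = []
    for iv in schedule.intervals:
        sel = (centers >= iv.start_h) & (centers < iv.end_h)
        if not np.any(sel):
            continue
        mean_counts = float(trace.counts[sel].mean())
        segments.append({
            "state": iv.state, "start_h": iv.start_h, "end_h": iv.end_h,
            "rel_pct": 100.0 * mean_counts / baseline_per_bin,
            "mean_counts": mean_counts,
        })
    light = schedule.is_light(centers)
    light_pct = (100.0 * trace.counts[light].mean() / baseline_per_bin
                 if np.any(light) else math.nan)
    dark_pct = (100.0 * trace.counts[~light].mean() / baseline_per_bin
                if np.any(~light) else math.nan)
    return MaskingSummary(rel_activity_bins=rel, segments=segments,
                          light_phase_pct=light_pct, dark_phase_pct=dark_pct,
                          baseline_per_bin=baseline_per_bin)


def activity_per_wake_hour(trace: ActivityTrace, hypnogram: Hypnogram,
                           window: tuple[float, float]) -> float:
    """Counts per hour scored awake (W or TDW) within ``window``.

    Returns NaN when the window contains no wakefulness (flagged missing).
    """
    start, end = window
    if end <= start:
        raise ValueError("window must have positive length")
    centers = trace.bin_centers_h()
    counts = float(trace.counts[(centers >= start) & (centers < end)].sum())
    ec = hypnogram.epoch_centers_h()
    wake = np.isin(hypnogram.states, ("W", "TDW"))
    wake_h = float((wake & (ec >= start) & (ec < end)).sum()) * hypnogram.epoch_h
    if wake_h == 0:
        return math.nan
    return counts / wake_h


# ---------------------------------------------------------------------------
# Circadian summary + actogram plot
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CircadianSummary:
    tau_h: float
    onsets_h: np.ndarray
    offsets_h: np.ndarray
    alpha_h: float
    rho_h: float
    psi_h: float
    r_precision: float
    z_precision: float
    qp_max: float
    peak_period_h: float


def summarize_circadian(trace: ActivityTrace, schedule: LightSchedule,
                        n_ld_days: int,
                        params: OnsetDetectionParams | None = None,
                        period_range_h: tuple[float, float] = (20.0, 28.0)
                        ) -> CircadianSummary:
    """One-animal circadian summary for an LD12:12 -> DD recording.

    ``n_ld_days`` is the number of initial entrained days; the remaining
    cycles are treated as free run for the period fit, phase angle, alpha
    and robustness (periodogram over the DD portion only).
    """
    det = detect_onsets_offsets(trace, params, expected_period_h=24.0)
    onsets, offsets = det.onsets_h, det.offsets_h
    ld_on = onsets[:n_ld_days]
    dd_cycles = np.arange(n_ld_days, onsets.size)
    dd_on = reject_onset_outliers(onsets[n_ld_days:], dd_cycles)
    reg = fit_onset_regression(dd_on, cycle_idx=dd_cycles)
    psi = phase_angle(ld_on, dd_on,
                      ld_days=np.arange(n_ld_days),
                      dd_days=np.arange(n_ld_days, onsets.size),
                      last_ld_day=n_ld_days - 1)
    # alpha over post-transition DD cycles: the LD->DD transition cycle has a
    # mixed cycle length and would bias the mod-cycle duration
    ar = alpha_rho(dd_on[1:], offsets[n_ld_days + 1:], cycle_h=reg.tau_h)
    dd_start_bin = int(round(n_ld_days * 24.0 / trace.bin_h))
    dd_trace = ActivityTrace(trace.counts[dd_start_bin:], trace.bin_seconds,
                             trace.start_time_h + n_ld_days * 24.0)
    pg = chi_square_periodogram(dd_trace, period_range_h)
    return CircadianSummary(tau_h=reg.tau_h, onsets_h=onsets,
                            offsets_h=offsets, alpha_h=ar.mean_alpha_h,
                            rho_h=ar.mean_rho_h, psi_h=psi,
                            r_precision=reg.r, z_precision=reg.z,
                            qp_max=pg.qp_max, peak_period_h=pg.peak_period_h)


def plot_actogram(trace: ActivityTrace, schedule: LightSchedule | None = None,
                  ax=None, period_h: float = 24.0):
    """Double-plotted actogram (48-h rows), darkness shaded grey."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 8))
    bin_h = trace.bin_h
    bins_per_day = int(round(period_h / bin_h))
    n_days = int(math.floor(trace.n_bins / bins_per_day))
    counts = trace.counts[:n_days * bins_per_day].reshape(n_days, bins_per_day)
    peak = max(counts.max(), 1)
    tday = np.arange(bins_per_day) * bin_h
    for d in range(n_days):
        row = n_days - d  # top row = day 0
        for half, day in enumerate((d, d + 1)):
            if day >= n_days:
                continue
            y0 = row - 1
            x0 = half * period_h
            if schedule is not None:
                probes = trace.start_time_h + day * period_h + tday
                dark = ~schedule.is_light(
                    np.minimum(probes + bin_h / 2, schedule.end_h - 1e-9))
                in_rec = probes < trace.start_time_h + trace.duration_h
                for i in np.flatnonzero(dark & in_rec):
                    ax.axhspan(y0, y0 + 1, xmin=(x0 + tday[i]) / (2 * period_h),
                               xmax=(x0 + tday[i] + bin_h) / (2 * period_h),
                               color="0.85", lw=0, zorder=0)
            ax.bar(x0 + tday, counts[day] / peak * 0.9, width=bin_h,
                   bottom=y0, align="edge", color="black", zorder=1)
    ax.set_xlim(0, 2 * period_h)
    ax.set_ylim(0, n_days)
    ax.set_xlabel("time (h, double plotted)")
    ax.set_ylabel("day")
    ax.set_yticks([])
    return ax
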