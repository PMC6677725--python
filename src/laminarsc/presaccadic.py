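"""Bootstrap detection of pre-saccadic events E1/E2/E3/P and their
classification into Buildup and Burst activity.

Saccade-aligned multi-unit activity (trials with saccade latency in
[200, 400] ms) is searched for up to four events:

* ``E1`` — first 1-ms bin from -200 ms at which the detrended activity
  becomes and remains significantly different from the pre-go baseline for at
  least 100 ms (per-bin Welch t test, P < 0.01, against the pooled
  distribution of activity in the 100 ms preceding the go cue);
* ``E2`` — hinge point of a two-segment piecewise regression on
  [E1-100, E1] of the raw activity: the time accumulation begins;
* ``E3`` — hinge point between E2 and the peak time ``P``: the time the
  accumulation transitions into a burst;
* ``P``  — time of peak activity around saccade onset.

Each event is estimated on 100 bootstrap resamples of trials; an event is
kept only when the 95% quantile interval of its replicate distribution,
normalized by the event's search-window size, spans no more than 0.6 (and,
for E3, when the replicate slope distributions before and after the hinge do
not overlap).  Reliable events earlier than -50 ms re saccade are labeled
Buildup, later ones Burst.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from ._stats import welch_t_pvalues_columns
from .piecewise import two_piecewise_fit
from .spikes import RateWaveform

__all__ = [
    "EventEstimate",
    "PresaccadicClass",
    "detrend_presaccadic",
    "detect_e1_single",
    "detect_e2_single",
    "detect_e3_single",
    "bootstrap_events",
    "classify_channel",
    "BUILDUP_BURST_BOUNDARY",
]

BUILDUP_BURST_BOUNDARY = -50.0  # ms re saccade onset
E1_SCAN_START = -200.0
E1_PERSISTENCE_MS = 100
E2_WINDOW_MS = 100.0
DEFAULT_PEAK_WINDOW = (-50.0, 50.0)
RELIABILITY_THRESHOLD = 0.6
MIN_DETECTION_RATE = 0.5


@dataclass
class EventEstimate:
    """Bootstrap aggregate for one pre-saccadic event."""

    name: str
    replicates: np.ndarray            # per-bootstrap estimates, NaN = missed
    mean: float | None = None         # ms re saccade onset
    ci: tuple[float, float] | None = None
    normalized_ci_range: float | None = None
    detection_rate: float = 0.0
    reliable: bool = False
    extras: dict = field(default_factory=dict)

    @property
    def detected(self) -> bool:
        return self.mean is not None


@dataclass
class PresaccadicClass:
    buildup_present: bool = False
    buildup_onset: float | None = None
    buildup_rate: float | None = None
    burst_present: bool = False
    burst_onset: float | None = None
    burst_rate: float | None = None

    @property
    def category(self) -> str:
        if self.buildup_present and self.burst_present:
            return "Buildup-Burst"
        if self.buildup_present:
            return "Buildup-only"
        if self.burst_present:
            return "Burst-only"
        return "none"


def _fit_trend(time: np.ndarray, mean_trace: np.ndarray,
               window: tuple[float, float],
               gate_alpha: float = 0.05) -> tuple[float, float]:
    """Linear trend over ``window``, kept only when the slope is significant.

    Extrapolating an insignificant (noise-dominated) slope far beyond the
    fit window injects spurious offsets into the later bins it is subtracted
    from, so a slope whose OLS t test does not reject zero is replaced by a
    flat line at the window mean.
    """
    m = (time >= window[0]) & (time <= window[1])
    n = int(m.sum())
    if n < 3:
        raise ValueError("waveform does not cover the detrending window")
    x, y = time[m], mean_trace[m]
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx > 0 and resid.std() > 0:
        # 1-ms samples of a kernel-smoothed waveform are strongly
        # autocorrelated; inflate the OLS slope SE by the AR(1) effective
        # sample size so only genuine trends survive the gate
        rho = float(np.corrcoef(resid[:-1], resid[1:])[0, 1])
        rho = min(max(rho, 0.0), 0.98)
        n_eff = max(n * (1.0 - rho) / (1.0 + rho), 3.0)
        se = np.sqrt(resid.var(ddof=2) * n / (n - 2) / sxx)
        se *= np.sqrt((1.0 + rho) / (1.0 - rho))
        p = 2.0 * stats.t.sf(abs(slope) / se, n_eff - 2)
        if p >= gate_alpha:
            return 0.0, float(y.mean())
    return float(slope), float(intercept)


def detrend_presaccadic(
    waveform: RateWaveform,
    fit_window: tuple[float, float] = (-300.0, -200.0),
) -> tuple[RateWaveform, tuple[float, float]]:
    """Subtract the [-300, -200] ms linear trend (extrapolated everywhere).

    Removes slow delay-period drift before E1 detection; later events are
    estimated on the raw waveform.  Returns the detrended waveform and the
    ``(slope, intercept)`` of the removed line.
    """
    if waveform.time[0] > fit_window[0] or waveform.time[-1] < 50.0:
        raise ValueError("waveform must cover [-300, +50] ms re saccade onset")
    slope, intercept = _fit_trend(waveform.time, waveform.values, fit_window)
    line = slope * waveform.time + intercept
    return (
        replace(
            waveform,
            values=waveform.values - line,
            trial_matrix=waveform.trial_matrix - line[None, :],
        ),
        (slope, intercept),
    )


def detect_e1_single(
    activity: np.ndarray,
    time: np.ndarray,
    baseline: np.ndarray,
    *,
    scan_start: float = E1_SCAN_START,
    alpha: float = 0.01,
    persistence_ms: int = E1_PERSISTENCE_MS,
) -> float | None:
    """First bin from ``scan_start`` whose significance vs baseline persists
    for at least ``persistence_ms`` consecutive 1-ms bins.

    ``activity``: (n_trials, n_bins) detrended saccade-aligned traces;
    ``baseline``: pooled 1-D distribution (time points x trials).
    """
    if activity.shape[0] < 2:
        raise ValueError("need at least 2 trials")
    cols = time >= scan_start
    p = welch_t_pvalues_columns(activity[:, cols], baseline)
    sig = p < alpha
    n = sig.size
    if n < persistence_ms:
        return None
    run = 0
    # length of the significant run starting at each bin, scanned backwards
    runs = np.zeros(n, dtype=int)
    for i in range(n - 1, -1, -1):
        run = run + 1 if sig[i] else 0
        runs[i] = run
    hits = np.flatnonzero(runs >= persistence_ms)
    if hits.size == 0:
        return None
    return float(time[cols][hits[0]])


def detect_e2_single(
    mean_trace: np.ndarray,
    time: np.ndarray,
    e1b: float,
    *,
    window_ms: float = E2_WINDOW_MS,
) -> float:
    """Hinge point of the raw activity on [E1b - 100, E1b] (E2b <= E1b)."""
    m = (time >= e1b - window_ms) & (time <= e1b)
    fit = two_piecewise_fit(time[m], mean_trace[m])
    return float(fit.breakpoint)


def detect_e3_single(
    mean_trace: np.ndarray,
    time: np.ndarray,
    e2b: float,
    pb: float,
) -> tuple[float, float, float] | None:
    """Hinge point between E2b and Pb with the segment slopes, or ``None``
    when the interval is too short (< 6 samples)."""
    m = (time >= e2b) & (time <= pb)
    if m.sum() < 6:
        return None
    fit = two_piecewise_fit(time[m], mean_trace[m])
    return float(fit.breakpoint), float(fit.left_slope), float(fit.right_slope)


def _quantile_ci(vals: np.ndarray) -> tuple[float, float]:
    return (float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5)))


def bootstrap_events(
    trial_matrix: np.ndarray,
    time: np.ndarray,
    baseline_matrix: np.ndarray,
    *,
    n_boot: int = 100,
    seed: int = 0,
    peak_window: tuple[float, float] = DEFAULT_PEAK_WINDOW,
    alpha: float = 0.01,
    reliability_threshold: float = RELIABILITY_THRESHOLD,
    min_detection_rate: float = MIN_DETECTION_RATE,
) -> dict[str, EventEstimate]:
    """Bootstrap E1/E2/E3/P estimates for one channel.

    For E1, activity and baseline are both referenced to the resample's
    pre-go baseline mean and the extrapolated [-300, -200] ms linear trend
    is removed from the activity; E2/E3/P operate on the raw resample
    average.

    Parameters
    ----------
    trial_matrix
        (n_trials, n_bins) saccade-aligned spike densities covering at least
        [-300, +50] ms; include only trials with saccade latency in the
        standard 200-400 ms range.
    baseline_matrix
        (n_trials, n_base) go-cue-aligned densities over the 100 ms
        preceding the go cue, same trial order.
    seed
        Master seed; bootstrap replicate ``r`` uses ``seed + r``.
    """
    M = np.asarray(trial_matrix, float)
    B = np.asarray(baseline_matrix, float)
    n = M.shape[0]
    if n < 2:
        raise ValueError("need at least 2 trials for bootstrapping")
    if B.shape[0] != n:
        raise ValueError("trial and baseline counts must agree")
    time = np.asarray(time, float)

    peak_mask = (time >= peak_window[0]) & (time <= peak_window[1])
    peak_times = time[peak_mask]

    e1 = np.full(n_boot, np.nan)
    e2 = np.full(n_boot, np.nan)
    e3 = np.full(n_boot, np.nan)
    pk = np.full(n_boot, np.nan)
    slope_lo = np.full(n_boot, np.nan)
    slope_hi = np.full(n_boot, np.nan)

    for r in range(n_boot):
        rng = np.random.default_rng(seed + r)
        idx = rng.integers(0, n, size=n)
        sub = M[idx]
        mean_raw = sub.mean(axis=0)
        pb = float(peak_times[np.argmax(mean_raw[peak_mask])])
        pk[r] = pb

        # reference activity and baseline to the resample's pre-go mean,
        # then remove the extrapolated pre-saccadic linear trend from the
        # activity (E1 detection only)
        base_sub = B[idx]
        m0 = base_sub.mean()
        slope, intercept = _fit_trend(time, mean_raw - m0, (-300.0, -200.0))
        det = (sub - m0) - (slope * time + intercept)[None, :]
        det_base = (base_sub - m0).ravel()

        e1b = detect_e1_single(det, time, det_base, alpha=alpha)
        if e1b is None:
            continue
        e1[r] = e1b
        e2b = detect_e2_single(mean_raw, time, e1b)
        e2[r] = e2b
        res = detect_e3_single(mean_raw, time, e2b, pb)
        if res is not None:
            e3[r], slope_lo[r], slope_hi[r] = res

    def aggregate(name: str, vals: np.ndarray, normalizer: float,
                  extras: dict | None = None) -> EventEstimate:
        ok = vals[~np.isnan(vals)]
        est = EventEstimate(name=name, replicates=vals, extras=extras or {})
        est.detection_rate = ok.size / n_boot
        if ok.size == 0:
            return est
        est.mean = float(ok.mean())
        est.ci = _quantile_ci(ok)
        est.normalized_ci_range = (est.ci[1] - est.ci[0]) / normalizer
        est.reliable = (
            est.normalized_ci_range <= reliability_threshold
            and est.detection_rate >= min_detection_rate
        )
        return est

    both = ~np.isnan(e3) & ~np.isnan(e2)
    e3_norm = float(np.mean(pk[both] - e2[both])) if both.any() else np.nan
    peak_norm = peak_window[1] - peak_window[0]

    out = {
        "E1": aggregate("E1", e1, 200.0),
        "E2": aggregate("E2", e2, 100.0),
        "P": aggregate("P", pk, peak_norm),
    }
    sb, sa = slope_lo[~np.isnan(slope_lo)], slope_hi[~np.isnan(slope_hi)]
    extras: dict = {"slopes_before": sb, "slopes_after": sa}
    if sb.size and sa.size:
        ci_b, ci_a = _quantile_ci(sb), _quantile_ci(sa)
        extras["slope_ci_before"] = ci_b
        extras["slope_ci_after"] = ci_a
        extras["slopes_separated"] = ci_b[1] < ci_a[0] or ci_a[1] < ci_b[0]
    else:
        extras["slopes_separated"] = False
    est3 = aggregate("E3", e3, e3_norm if np.isfinite(e3_norm) else np.inf,
                     extras)
    # a hinge into a burst requires a significant slope change
    est3.reliable = est3.reliable and extras["slopes_separated"]
    out["E3"] = est3
    return out


def _ci_disjoint(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[1] < b[0] or b[1] < a[0]


def classify_channel(
    e2: EventEstimate,
    e3: EventEstimate,
    waveform: RateWaveform,
    *,
    boundary: float = BUILDUP_BURST_BOUNDARY,
) -> PresaccadicClass:
    """Label reliable hinge events as Buildup (< boundary) or Burst.

    When both hinges are reliable and their CIs are disjoint, each is
    labeled separately; when both are reliable but their CIs overlap they are
    treated as one hinge (the estimate with the tighter normalized CI wins,
    tie to E3); otherwise the single reliable hinge is labeled on its own.
    Onset rates are read from the supplied (movement-frame, baseline-
    corrected) trial-averaged waveform at the event means.
    """
    events: list[EventEstimate] = []
    if e2.reliable and e3.reliable:
        if _ci_disjoint(e2.ci, e3.ci):
            events = [e2, e3]
        else:
            tighter = e2 if (
                e2.normalized_ci_range < e3.normalized_ci_range
            ) else e3
            events = [tighter]
    elif e2.reliable:
        events = [e2]
    elif e3.reliable:
        events = [e3]

    out = PresaccadicClass()
    buildups = [ev for ev in events if ev.mean < boundary]
    bursts = [ev for ev in events if ev.mean >= boundary]

    def rate_at(t: float) -> float:
        i = int(np.argmin(np.abs(waveform.time - t)))
        return float(waveform.values[i])

    if buildups:
        onset = min(ev.mean for ev in buildups)
        out.buildup_present = True
        out.buildup_onset = onset
        out.buildup_rate = rate_at(onset)
    if bursts:
        # the burst begins at the later hinge when two fall past the boundary
        onset = max(ev.mean for ev in bursts)
        out.burst_present = True
        out.burst_onset = onset
        out.burst_rate = rate_at(onset)
    return out
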