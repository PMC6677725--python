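"""Visual-burst detection and visual-onset latency estimation.

Per-trial visual bursts are found with the Poisson-surprise statistic
S = -log P(>= n spikes in the burst interval | Poisson at the trial's mean
rate).  The session's alignment channel is the one with the most trials with
a detected burst; trials without a burst on it are discarded and every other
channel is realigned on its per-trial burst onsets.

Per-channel visual latency is then read from the realigned, baseline-
corrected trial-averaged spike density: the peak Pv is located in
[-50, 150] ms, two 20-ms windows W1 and W2 (W2 10 ms earlier) slide back in
1-ms steps from the peak, and the first window start where the two
distributions stop differing (Welch t test, P < 0.01) and stay
indistinguishable for 10 further steps defines Bv.  The visual latency Lv is
the hinge point of a two-segment piecewise regression on [Bv, Pv].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from ._stats import welch_t_pvalue
from .piecewise import two_piecewise_fit
from .spikes import RateWaveform

__all__ = [
    "BurstEvent",
    "VisualOnset",
    "DEFAULT_MIN_SPIKES",
    "DEFAULT_SURPRISE_THRESHOLD",
    "poisson_surprise",
    "poisson_surprise_bursts",
    "select_alignment_channel",
    "estimate_visual_onset",
]

DEFAULT_MIN_SPIKES = 3
DEFAULT_SURPRISE_THRESHOLD = -np.log(0.025)


@dataclass
class BurstEvent:
    onset: float
    offset: float
    n_spikes: int
    surprise: float


@dataclass
class VisualOnset:
    """Visual-onset estimate for one channel (times re burst alignment)."""

    peak_time: float | None = None       # Pv
    baseline_time: float | None = None   # Bv
    latency: float | None = None         # Lv
    detected: bool = False


def poisson_surprise(n_spikes: int, duration_ms: float, rate_hz: float) -> float:
    """S = -log P(>= n spikes | Poisson with mean rate over the interval)."""
    lam = rate_hz / 1000.0 * max(duration_ms, 1e-3)
    p = stats.poisson.sf(n_spikes - 1, lam)
    return float(-np.log(max(p, np.finfo(float).tiny)))


def poisson_surprise_bursts(
    spike_times: np.ndarray,
    epoch: tuple[float, float],
    *,
    min_spikes: int = DEFAULT_MIN_SPIKES,
    surprise_threshold: float = DEFAULT_SURPRISE_THRESHOLD,
    mean_rate: float | None = None,
    rate_interval: tuple[float, float] | None = None,
) -> list[BurstEvent]:
    """Detect bursts inside ``epoch`` by exhaustive surprise maximization.

    Every run of consecutive spikes within the epoch is scored against the
    trial's mean rate; the maximal-surprise run meeting both criteria is
    accepted and the search recurses on the remaining spikes, so returned
    bursts are disjoint and ordered by onset.

    ``mean_rate`` defaults to the count of all supplied spikes divided by
    ``rate_interval`` (or the span needed to cover spikes and epoch).
    """
    spikes = np.asarray(spike_times, dtype=float)
    lo, hi = epoch
    if hi <= lo:
        raise ValueError("epoch must have positive length")
    if mean_rate is None:
        if rate_interval is None:
            start = min(lo, spikes.min()) if spikes.size else lo
            stop = max(hi, spikes.max()) if spikes.size else hi
        else:
            start, stop = rate_interval
        mean_rate = spikes[(spikes >= start) & (spikes <= stop)].size / (
            (stop - start) / 1000.0
        )
    if mean_rate <= 0:
        return []

    inside = np.sort(spikes[(spikes >= lo) & (spikes <= hi)])
    out: list[BurstEvent] = []

    def search(seg: np.ndarray) -> None:
        m = seg.size
        if m < min_spikes:
            return
        i_idx, j_idx = np.triu_indices(m, k=min_spikes - 1)
        n = j_idx - i_idx + 1
        dur = np.maximum(seg[j_idx] - seg[i_idx], 1e-3)
        lam = mean_rate / 1000.0 * dur
        tail = stats.poisson.sf(n - 1, lam)
        S = -np.log(np.maximum(tail, np.finfo(float).tiny))
        best = int(np.argmax(S))
        if S[best] < surprise_threshold:
            return
        i, j = int(i_idx[best]), int(j_idx[best])
        out.append(
            BurstEvent(
                onset=float(seg[i]),
                offset=float(seg[j]),
                n_spikes=int(j - i + 1),
                surprise=float(S[best]),
            )
        )
        search(seg[:i])
        search(seg[j + 1 :])

    search(inside)
    out.sort(key=lambda b: b.onset)
    return out


def select_alignment_channel(
    detections: Mapping[int, Mapping[int, Sequence[BurstEvent]]],
) -> tuple[int, list[int], dict[int, float]]:
    """Pick the channel with the most trials with a detected burst.

    Parameters
    ----------
    detections
        ``{channel: {trial_id: [BurstEvent, ...]}}``; empty lists mean no
        burst on that trial.

    Returns
    -------
    (channel, retained_trial_ids, onsets)
        When several channels tie on the trial count (common when bursts are
        vigorous across many contacts), the tie goes to the channel with the
        largest summed surprise — the most reliably bursting contact.
        ``onsets`` maps each retained trial to the onset of its earliest
        burst on the alignment channel.
    """
    counts = {
        ch: sum(1 for bursts in trials.values() if len(bursts) > 0)
        for ch, trials in detections.items()
    }
    if not counts or max(counts.values()) == 0:
        raise ValueError("no visual bursts detected on any channel")
    best = max(counts.values())
    tied = [ch for ch, n in counts.items() if n == best]
    channel = max(
        tied,
        key=lambda ch: (
            sum(b.surprise for bursts in detections[ch].values() for b in bursts),
            ch,
        ),
    )
    onsets = {
        trial: min(b.onset for b in bursts)
        for trial, bursts in detections[channel].items()
        if len(bursts) > 0
    }
    return channel, sorted(onsets), onsets


def estimate_visual_onset(
    waveform: RateWaveform,
    *,
    peak_window: tuple[float, float] = (-50.0, 150.0),
    window_len: int = 20,
    window_shift: int = 10,
    alpha: float = 0.01,
    persistence: int = 10,
) -> VisualOnset:
    """W1/W2 sliding-window scan plus two-piecewise regression for Lv.

    The waveform must be trial-averaged and baseline-corrected on
    [-150, -50] ms relative to the visual-burst alignment.
    """
    t = waveform.time
    y = waveform.values
    sl = waveform.window_slice(peak_window)
    if np.ptp(y[sl]) == 0.0:
        return VisualOnset(detected=False)
    pv = float(t[sl][np.argmax(y[sl])])

    def window_vals(start: float) -> np.ndarray:
        s = waveform.window_slice((start, start + window_len))
        return y[s]

    scan_floor = peak_window[0]
    # iteration k: W1 = [pv-20-k, pv-k], W2 = [pv-30-k, pv-10-k]; the scan
    # ends when W2 reaches [scan_floor, scan_floor+20]
    k_max = int(pv - window_len - window_shift - scan_floor)
    if k_max < 0:
        return VisualOnset(peak_time=pv, detected=False)
    pvals = np.array([
        welch_t_pvalue(
            window_vals(pv - window_len - k),
            window_vals(pv - window_len - window_shift - k),
        )
        for k in range(k_max + 1)
    ])
    nonsig = pvals >= alpha
    # the distributions must first differ (they start around the peak) and
    # then *become* indistinguishable — leading non-significant iterations
    # before any significant one do not qualify
    sig_seen = np.logical_or.accumulate(~nonsig)
    bv = None
    for k in range(1, k_max + 1):
        # persist for 10 further iterations, or to the end of the scan
        if sig_seen[k - 1] and nonsig[k : min(k + persistence + 1, k_max + 1)].all():
            bv = float(pv - window_len - k)
            break
    if bv is None:
        return VisualOnset(peak_time=pv, detected=False)

    seg = waveform.window_slice((bv, pv))
    x = t[seg]
    if x.size < 5:
        return VisualOnset(peak_time=pv, baseline_time=bv, detected=False)
    fit = two_piecewise_fit(x, y[seg])
    return VisualOnset(
        peak_time=pv, baseline_time=bv, latency=float(fit.breakpoint),
        detected=True,
    )
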