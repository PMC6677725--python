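"""Spike-density waveforms, event alignment, baselines, and saccade detection.

Spike trains are converted to continuous rate estimates by convolving each
trial's spikes with a causal kernel shaped like an excitatory post-synaptic
potential, R(t) = (1 - exp(-t/tau_g)) * exp(-t/tau_d) with growth and decay
time constants of 1 and 20 ms.  The kernel is normalized to unit area so a
lone spike integrates to one and trial-averaged waveforms are in spikes/s.
All waveforms live on a 1-ms grid relative to an alignment event.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "RateWaveform",
    "epsp_kernel",
    "spike_density",
    "baseline_correct",
    "epoch_mean",
    "epoch_trial_means",
    "detect_saccade_onset",
]

#: default kernel time constants, ms
TAU_GROWTH = 1.0
TAU_DECAY = 20.0
#: kernel support, ms (5 decay constants; renormalized to unit mass)
KERNEL_LENGTH = 100


@dataclass
class RateWaveform:
    """A 1-ms-binned spike-density trace with alignment metadata.

    ``values`` is the trial average (spk/s); ``trial_matrix`` keeps the
    per-trial traces for distribution-based tests.
    """

    time: np.ndarray                     # ms relative to alignment event
    values: np.ndarray                   # spk/s, trial average
    trial_matrix: np.ndarray             # (n_trials, n_bins), spk/s
    alignment: str = "target_onset"
    baseline_window: tuple[float, float] | None = None

    @property
    def n_trials(self) -> int:
        return self.trial_matrix.shape[0]

    def window_slice(self, window: tuple[float, float]) -> slice:
        lo, hi = window
        if lo < self.time[0] or hi > self.time[-1]:
            raise ValueError(
                f"window {window} outside waveform support "
                f"[{self.time[0]}, {self.time[-1]}]"
            )
        i0 = int(np.searchsorted(self.time, lo, side="left"))
        i1 = int(np.searchsorted(self.time, hi, side="right"))
        return slice(i0, i1)


def epsp_kernel(
    tau_growth: float = TAU_GROWTH,
    tau_decay: float = TAU_DECAY,
    length: int = KERNEL_LENGTH,
) -> np.ndarray:
    """Unit-mass EPSP-shaped kernel sampled at 1 ms, causal (zero for t<0)."""
    t = np.arange(0, length + 1, dtype=float)
    k = (1.0 - np.exp(-t / tau_growth)) * np.exp(-t / tau_decay)
    return k / k.sum()


def spike_density(
    spike_trains: Sequence[np.ndarray],
    align_times: Sequence[float],
    window: tuple[float, float],
    *,
    alignment: str = "target_onset",
    tau_growth: float = TAU_GROWTH,
    tau_decay: float = TAU_DECAY,
) -> RateWaveform:
    """Convolve per-trial spike trains with the EPSP kernel in an aligned frame.

    Parameters
    ----------
    spike_trains
        One sorted array of spike times (ms) per trial; empty trials are
        allowed and contribute zero traces.
    align_times
        Alignment event time (ms, same clock as the spikes) for every trial.
    window
        ``(lo, hi)`` in ms relative to the alignment event, inclusive.
    """
    spike_trains = list(spike_trains)
    align_times = np.asarray(align_times, dtype=float)
    if len(spike_trains) == 0:
        raise ValueError("spike_density requires at least one trial")
    if len(spike_trains) != align_times.size:
        raise ValueError("one alignment time is required per trial")
    lo, hi = window
    if hi <= lo:
        raise ValueError("window must have positive length")

    kernel = epsp_kernel(tau_growth, tau_decay)
    pad = kernel.size - 1
    # spikes earlier than the window by up to one kernel length still
    # contribute mass inside the window
    edges = np.arange(lo - pad, hi + 2) - 0.5
    n_bins = int(hi - lo) + 1
    mat = np.zeros((len(spike_trains), n_bins))
    for i, (spikes, a) in enumerate(zip(spike_trains, align_times)):
        rel = np.asarray(spikes, dtype=float) - a
        rel = rel[(rel >= lo - pad) & (rel <= hi)]
        if rel.size == 0:
            continue
        counts, _ = np.histogram(rel, bins=edges)
        mat[i] = np.convolve(counts, kernel)[pad : pad + n_bins] * 1000.0

    time = np.arange(lo, hi + 1, dtype=float)
    return RateWaveform(
        time=time,
        values=mat.mean(axis=0),
        trial_matrix=mat,
        alignment=alignment,
    )


def baseline_correct(
    waveform: RateWaveform, baseline_window: tuple[float, float]
) -> RateWaveform:
    """Subtract the scalar trial-averaged mean over ``baseline_window``."""
    sl = waveform.window_slice(baseline_window)
    offset = float(waveform.values[sl].mean())
    return replace(
        waveform,
        values=waveform.values - offset,
        trial_matrix=waveform.trial_matrix - offset,
        baseline_window=tuple(baseline_window),
    )


def epoch_mean(waveform: RateWaveform, window: tuple[float, float]) -> float:
    """Arithmetic mean of the trial-averaged waveform over ``window`` (spk/s)."""
    sl = waveform.window_slice(window)
    return float(waveform.values[sl].mean())


def epoch_trial_means(
    waveform: RateWaveform, window: tuple[float, float]
) -> np.ndarray:
    """Per-trial epoch means, for rank-sum / t tests across trials."""
    sl = waveform.window_slice(window)
    return waveform.trial_matrix[:, sl].mean(axis=1)


def detect_saccade_onset(
    velocity: np.ndarray,
    go_cue_index: int,
    threshold: float = 30.0,
) -> int | None:
    """First sample at/after the go cue where eye velocity >= threshold (deg/s).

    ``velocity`` is sampled at 1 kHz; the returned value is a sample index on
    the same clock, or ``None`` if the threshold is never crossed.
    """
    velocity = np.asarray(velocity, dtype=float)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if go_cue_index >= velocity.size:
        raise ValueError("velocity trace shorter than the go cue")
    tail = velocity[go_cue_index:]
    hits = np.flatnonzero(tail >= threshold)
    if hits.size == 0:
        return None
    return int(go_cue_index + hits[0])
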