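"""Seeded synthetic laminar sessions: spikes, LFP, and trial events.

A session emulates a 16-contact linear-probe penetration through the superior
colliculus during visually guided (VG) and memory-guided (MG) delayed saccade
tasks.  Channel 1 is the most ventral contact.  Depth structure follows the
organization reported for SC populations:

* a visual transient whose amplitude is unimodal over channels (maximal a few
  contacts dorsal of the CSD reference) and whose latency increases linearly
  from dorsal to ventral contacts;
* low-rate delay activity proportional to the visual amplitude;
* a pre-saccadic buildup ramp starting earliest at a central channel and
  later with distance, feeding a motor burst that starts synchronously on all
  channels ~27 ms before saccade onset, peaks at saccade onset at a constant
  multiple of the rate at burst onset, and is maximal a couple of contacts
  ventral of the reference;
* an LFP with a post-target current sink dorsal of the reference contact, so
  the second-spatial-derivative (CSD) profile has a contiguous negative
  region whose ventral edge marks the true reference channel.

Spikes are drawn from an inhomogeneous Poisson process by thinning; every
random quantity derives from the single config seed, and the per-channel
ground truth needed for parameter-recovery tests is returned with the bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "TrialEvents",
    "SessionBundle",
    "LaminarRateTemplate",
    "laminar_rate_template",
    "sample_inhomogeneous_poisson",
    "synth_lfp",
    "synth_eye_velocity",
    "generate_session",
    "save_session",
    "load_session",
]


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic penetration.

    Channel indices prefixed ``aligned`` are relative to the CSD reference
    contact (positive = dorsal); plain channel numbers are 1-based probe
    contacts with 1 most ventral.  Rates are spk/s, times ms, depths µm.
    """

    n_channels: int = 16
    contact_spacing_um: float = 150.0
    n_trials: int = 200
    task_mix: dict = field(default_factory=lambda: {"VG": 0.5, "MG": 0.5})
    fixation_range: tuple[float, float] = (200.0, 350.0)
    delay_range: tuple[float, float] = (600.0, 900.0)
    saccade_latency_range: tuple[float, float] = (200.0, 400.0)
    mg_flash_ms: float = 300.0
    post_saccade_ms: float = 150.0

    reference_channel: int = 7            # true CSD reference contact
    visual_peak_channel: int = 4          # aligned index of max visual rate
    motor_peak_channel: int = -2          # aligned index of max motor rate
    visual_amp_max: float = 900.0
    visual_amp_floor: float = 30.0
    visual_sigma: float = 4.0             # channels
    visual_latency_base: float = 50.0     # ms after target, most dorsal contact
    visual_latency_span: float = 7.3      # dorsal-to-ventral latency gradient
    visual_rise_ms: float = 2.0
    visual_decay_ms: float = 15.0
    delay_fraction: float = 0.04          # delay plateau / visual amplitude

    buildup_origin_channel: int = 2       # aligned index of earliest buildup
    buildup_onset_earliest: float = -102.7  # ms re saccade onset
    buildup_delay_per_channel: float = 4.0  # ms per channel of distance
    burst_onset: float = -26.9            # ms re saccade, all channels
    burst_rate_max: float = 50.2          # rate at burst onset, peak channel
    burst_rate_floor: float = 3.0
    motor_sigma: float = 3.5              # channels
    burst_peak_factor_vg: float = 3.3     # peak rate / rate at burst onset
    burst_peak_factor_mg: float = 2.4
    burst_decay_ms: float = 30.0
    baseline_rate: float = 10.0

    lfp_sink_span: int = 4                # sink contacts dorsal of reference
    lfp_sink_amp_uv: float = 200.0
    lfp_noise_uv: float = 20.0
    lfp_window: tuple[float, float] = (-300.0, 500.0)  # ms re target onset

    anti_rf_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 4:
            raise ValueError("n_channels must be at least 4")
        for name in ("fixation_range", "delay_range", "saccade_latency_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"{name} must be an ordered non-negative pair")
        for name in (
            "visual_amp_max", "visual_amp_floor", "burst_rate_max",
            "burst_rate_floor", "baseline_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 1 <= self.reference_channel <= self.n_channels:
            raise ValueError("reference_channel outside the probe")
        if self.reference_channel + self.lfp_sink_span >= self.n_channels:
            raise ValueError("lfp sink extends past the dorsal-most contact")
        if self.burst_onset >= 0:
            raise ValueError("burst_onset must precede saccade onset")

    def aligned_index(self, channel: int) -> int:
        return channel - self.reference_channel

    def peak_factor(self, task: str) -> float:
        return self.burst_peak_factor_vg if task == "VG" else self.burst_peak_factor_mg


@dataclass
class TrialEvents:
    trial_id: int
    task: str                      # "VG" | "MG"
    target_onset: float            # ms from trial start
    go_cue: float
    saccade_onset: float
    delay_duration: float
    target_in_rf: bool = True

    @property
    def saccade_latency(self) -> float:
        return self.saccade_onset - self.go_cue


@dataclass
class SessionBundle:
    """All spikes, LFP, and events for one synthetic penetration."""

    config: GeneratorConfig
    events: list[TrialEvents]
    spikes: list[list[np.ndarray]]     # [channel-1][trial] sorted ms
    lfp: np.ndarray                    # (n_trials, n_channels, n_samples), µV
    lfp_time: np.ndarray               # ms relative to target onset
    ground_truth: dict
    session_id: str = "session-0"

    @property
    def n_channels(self) -> int:
        return self.config.n_channels

    def trials(self, task: str | None = None) -> list[int]:
        """Indices of target-in-RF trials, optionally restricted to one task."""
        return [
            i for i, ev in enumerate(self.events)
            if ev.target_in_rf and (task is None or ev.task == task)
        ]


class LaminarRateTemplate:
    """Closed-form firing-rate function (spk/s) for one channel and trial.

    Piecewise construction: baseline; linear-rise/exponential-decay visual
    transient with depth-dependent latency and amplitude; rectangular delay
    plateau; linear buildup ramp from a depth-dependent onset into a linear
    burst rise reaching ``peak_factor`` times the burst-onset rate at saccade
    onset; exponential post-saccadic decay.  Hinges are genuine slope breaks
    so changepoint estimators have well-defined targets.
    """

    def __init__(self, channel: int, task: str, config: GeneratorConfig,
                 events: TrialEvents):
        if not 1 <= channel <= config.n_channels:
            raise ValueError("channel outside the probe")
        c = config
        ai = c.aligned_index(channel)
        self.channel = channel
        self.task = task
        self.events = events
        self.config = c

        self.visual_amp = c.visual_amp_floor + (
            c.visual_amp_max - c.visual_amp_floor
        ) * np.exp(-((ai - c.visual_peak_channel) ** 2) / (2 * c.visual_sigma**2))
        frac = (c.n_channels - channel) / max(c.n_channels - 1, 1)
        self.visual_latency = c.visual_latency_base + c.visual_latency_span * frac
        self.delay_level = c.delay_fraction * self.visual_amp
        self.burst_rate = c.burst_rate_floor + (
            c.burst_rate_max - c.burst_rate_floor
        ) * np.exp(-((ai - c.motor_peak_channel) ** 2) / (2 * c.motor_sigma**2))
        self.buildup_onset = min(
            c.buildup_onset_earliest
            + c.buildup_delay_per_channel * abs(ai - c.buildup_origin_channel),
            c.burst_onset - 15.0,
        )
        self.peak_rate = c.peak_factor(task) * self.burst_rate
        if not events.target_in_rf:
            # flat response away from the response field
            self.visual_amp = 0.0
            self.delay_level = 0.0
            self.burst_rate = 0.0
            self.peak_rate = 0.0

    @property
    def max_rate(self) -> float:
        c = self.config
        return c.baseline_rate + self.delay_level + max(
            self.visual_amp, self.peak_rate
        )

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        c = self.config
        ev = self.events
        r = np.full(t.shape, float(c.baseline_rate))

        t_vis = ev.target_onset + self.visual_latency
        t_peak = t_vis + c.visual_rise_ms
        rising = (t >= t_vis) & (t < t_peak)
        r[rising] += self.visual_amp * (t[rising] - t_vis) / c.visual_rise_ms
        decaying = t >= t_peak
        r[decaying] += self.visual_amp * np.exp(
            -(t[decaying] - t_peak) / c.visual_decay_ms
        )

        sacc = ev.saccade_onset
        pre = t < sacc
        r[pre & (t >= t_peak)] += self.delay_level

        # accumulation: linear climb from the buildup onset to the rate
        # reached at burst onset (rate at the onset itself is ~0 above the
        # delay plateau, as reported for recorded prelude activity)
        t_build = sacc + self.buildup_onset
        t_burst = sacc + c.burst_onset
        ramp = pre & (t >= t_build) & (t < t_burst)
        r[ramp] += self.burst_rate * (t[ramp] - t_build) / (t_burst - t_build)
        burst = pre & (t >= t_burst)
        r[burst] += self.burst_rate + (self.peak_rate - self.burst_rate) * (
            t[burst] - t_burst
        ) / (sacc - t_burst)

        post = ~pre
        r[post] = c.baseline_rate + (self.delay_level + self.peak_rate) * np.exp(
            -(t[post] - sacc) / c.burst_decay_ms
        )
        return r


def laminar_rate_template(
    channel: int, task: str, config: GeneratorConfig, events: TrialEvents
) -> LaminarRateTemplate:
    """Rate function (spk/s over trial time) for one channel of one trial."""
    return LaminarRateTemplate(channel, task, config, events)


def sample_inhomogeneous_poisson(
    rate: Callable[[np.ndarray], np.ndarray],
    t_start: float,
    t_stop: float,
    rng: np.random.Generator,
    max_rate: float | None = None,
) -> np.ndarray:
    """Draw spike times (ms) by thinning against the rate's supremum.

    ``max_rate`` (spk/s) defaults to ``rate.max_rate`` when the callable
    exposes one; a finite bound is required.
    """
    if max_rate is None:
        max_rate = getattr(rate, "max_rate", None)
    if max_rate is None or not np.isfinite(max_rate):
        raise ValueError("thinning requires a finite rate bound")
    if max_rate < 0:
        raise ValueError("rate bound must be non-negative")
    if max_rate == 0 or t_stop <= t_start:
        return np.empty(0)
    lam = max_rate / 1000.0 * (t_stop - t_start)
    n = rng.poisson(lam)
    times = np.sort(rng.uniform(t_start, t_stop, size=n))
    keep = rng.uniform(0.0, max_rate, size=n) < rate(times)
    return times[keep]


def _sink_csd_profile(config: GeneratorConfig) -> np.ndarray:
    """Target mean CSD profile (arbitrary units) across the probe."""
    c = config
    prof = np.full(c.n_channels, 0.05)
    ref = c.reference_channel
    span = c.lfp_sink_span
    # unimodal negative sink with its ventral edge just dorsal of the reference
    depth = np.arange(1, span + 1)
    bump = np.exp(-((depth - (span + 1) / 2.0) ** 2) / (2 * (span / 2.5) ** 2))
    prof[ref : ref + span] = -(0.6 + 0.4 * bump / bump.max())
    prof[ref - 1] = 0.3
    if ref + span < c.n_channels:
        prof[ref + span] = 0.3
    return prof


def _sink_potential_weights(config: GeneratorConfig) -> np.ndarray:
    """Spatial LFP weights whose second difference reproduces the sink CSD."""
    c = config
    n = c.n_channels
    prof = _sink_csd_profile(config)
    h2 = (c.contact_spacing_um / 1000.0) ** 2
    # solve -(w[i-1]-2w[i]+w[i+1])/h^2 = prof[i] on interior contacts,
    # w = 0 at the probe ends
    A = np.zeros((n - 2, n - 2))
    for row, i in enumerate(range(1, n - 1)):
        A[row, row] = 2.0 / h2
        if row > 0:
            A[row, row - 1] = -1.0 / h2
        if row < n - 3:
            A[row, row + 1] = -1.0 / h2
    w = np.zeros(n)
    w[1:-1] = np.linalg.solve(A, prof[1:-1])
    return w / np.abs(w).max() * c.lfp_sink_amp_uv


def _sink_time_course(t_rel: np.ndarray) -> np.ndarray:
    """Normalized post-target transient (alpha shape, onset +20 ms, peak +70)."""
    s = (t_rel - 20.0) / 50.0
    out = np.where(s > 0, s * np.exp(1.0 - s), 0.0)
    return np.clip(out, 0.0, None)


def synth_lfp(
    config: GeneratorConfig,
    events: Sequence[TrialEvents],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial, per-channel LFP traces at 1 kHz around target onset.

    Returns ``(lfp, time)`` with ``lfp`` of shape
    ``(n_trials, n_channels, n_samples)`` in µV and ``time`` in ms relative
    to target onset.  The deterministic component is a spatial sink pattern
    (dorsal of the reference contact) times an alpha-shaped transient;
    seeded white noise is added per sample.
    """
    c = config
    lo, hi = c.lfp_window
    time = np.arange(lo, hi + 1, dtype=float)
    w = _sink_potential_weights(c)
    h = _sink_time_course(time)
    base = np.einsum("c,t->ct", w, h)
    lfp = np.empty((len(events), c.n_channels, time.size), dtype=np.float32)
    for i, ev in enumerate(events):
        # no evoked sink without stimulation in the response field
        evoked = base if ev.target_in_rf else np.zeros_like(base)
        if c.lfp_noise_uv > 0:
            lfp[i] = evoked + rng.normal(0.0, c.lfp_noise_uv, size=base.shape)
        else:
            lfp[i] = evoked
    return lfp, time


def synth_eye_velocity(
    events: TrialEvents, n_samples: int, *, peak: float = 300.0,
    slope_ms: float = 5.0, threshold: float = 30.0,
) -> np.ndarray:
    """Sigmoid eye-velocity trace (deg/s at 1 kHz) crossing ``threshold``
    exactly at the trial's saccade onset."""
    t = np.arange(n_samples, dtype=float)
    t0 = events.saccade_onset + slope_ms * np.log(peak / threshold - 1.0)
    return peak / (1.0 + np.exp(-(t - t0) / slope_ms))


def _draw_events(config: GeneratorConfig, rng: np.random.Generator) -> list[TrialEvents]:
    c = config
    tasks: list[str] = []
    names = sorted(c.task_mix)
    for name in names:
        tasks += [name] * int(round(c.task_mix[name] * c.n_trials))
    while len(tasks) < c.n_trials:
        tasks.append(names[-1])
    tasks = [tasks[i] for i in rng.permutation(len(tasks))[: c.n_trials]]

    n_anti = int(round(c.anti_rf_fraction * c.n_trials))
    in_rf = np.ones(c.n_trials, dtype=bool)
    if n_anti:
        in_rf[rng.choice(c.n_trials, size=n_anti, replace=False)] = False

    events = []
    for i, task in enumerate(tasks):
        fix = rng.uniform(*c.fixation_range)
        delay = rng.uniform(*c.delay_range)
        lat = rng.uniform(*c.saccade_latency_range)
        target = fix
        go = target + delay
        events.append(
            TrialEvents(
                trial_id=i,
                task=task,
                target_onset=float(target),
                go_cue=float(go),
                saccade_onset=float(go + lat),
                delay_duration=float(delay),
                target_in_rf=bool(in_rf[i]),
            )
        )
    return events


def _ground_truth(config: GeneratorConfig) -> dict:
    """Exact per-channel template parameters and template epoch statistics.

    Epoch rates are the infinite-trial expectations of what the analysis
    stages measure: the closed-form rate for a nominal trial is convolved
    with the EPSP spike-density kernel before taking the baseline-corrected
    visual ([0,100] ms after visual onset) and peri-saccadic ([-25,25] ms)
    means, so recovery tests compare like with like.
    """
    from .spikes import epsp_kernel

    c = config
    nominal = TrialEvents(
        trial_id=-1, task="VG", target_onset=300.0, go_cue=1050.0,
        saccade_onset=1350.0, delay_duration=750.0,
    )
    kernel = epsp_kernel()
    channels = list(range(1, c.n_channels + 1))
    gt: dict = {
        "reference_channel": c.reference_channel,
        "channels": channels,
        "aligned_index": [c.aligned_index(ch) for ch in channels],
    }
    per = {k: [] for k in (
        "visual_latency", "visual_amp", "delay_level", "buildup_onset",
        "burst_onset", "burst_rate", "peak_rate", "v_epoch_rate",
        "m_epoch_rate", "vmi",
    )}
    for ch in channels:
        tpl = LaminarRateTemplate(ch, "VG", c, nominal)
        per["visual_latency"].append(tpl.visual_latency)
        per["visual_amp"].append(tpl.visual_amp)
        per["delay_level"].append(tpl.delay_level)
        per["buildup_onset"].append(tpl.buildup_onset)
        per["burst_onset"].append(c.burst_onset)
        per["burst_rate"].append(tpl.burst_rate)
        per["peak_rate"].append(tpl.peak_rate)
        grid = np.arange(0.0, nominal.saccade_onset + 150.0)
        density = np.convolve(tpl(grid), kernel)[: grid.size]
        onset = nominal.target_onset + tpl.visual_latency
        in_v = (grid >= onset) & (grid <= onset + 100.0)
        v = float(density[in_v].mean() - c.baseline_rate)
        in_m = (np.abs(grid - nominal.saccade_onset) <= 25.0)
        m = float(density[in_m].mean() - (c.baseline_rate + tpl.delay_level))
        per["v_epoch_rate"].append(v)
        per["m_epoch_rate"].append(m)
        per["vmi"].append((m - v) / (m + v) if (m + v) != 0 else float("nan"))
    gt.update(per)
    return gt


def generate_session(
    config: GeneratorConfig, session_id: str | None = None
) -> SessionBundle:
    """Generate one seeded synthetic session (spikes + LFP + events)."""
    c = config
    rng = np.random.default_rng(c.seed)
    events = _draw_events(c, rng)
    spikes: list[list[np.ndarray]] = []
    for ch in range(1, c.n_channels + 1):
        per_trial = []
        for ev in events:
            tpl = LaminarRateTemplate(ch, ev.task, c, ev)
            t_end = ev.saccade_onset + c.post_saccade_ms
            per_trial.append(sample_inhomogeneous_poisson(tpl, 0.0, t_end, rng))
        spikes.append(per_trial)
    lfp, lfp_time = synth_lfp(c, events, rng)
    return SessionBundle(
        config=c,
        events=events,
        spikes=spikes,
        lfp=lfp,
        lfp_time=lfp_time,
        ground_truth=_ground_truth(c),
        session_id=session_id or f"session-{c.seed}",
    )


# ---------------------------------------------------------------------------
# on-disk format: one directory per session

def save_session(bundle: SessionBundle, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ev_rows = [
        {
            "trial_id": ev.trial_id,
            "task": ev.task,
            "target_onset_ms": ev.target_onset,
            "go_cue_ms": ev.go_cue,
            "saccade_onset_ms": ev.saccade_onset,
            "delay_duration_ms": ev.delay_duration,
            "target_in_rf": int(ev.target_in_rf),
        }
        for ev in bundle.events
    ]
    pd.DataFrame(ev_rows).to_csv(out / "events.csv", index=False)
    for ch in range(1, bundle.n_channels + 1):
        rows = []
        for trial, train in enumerate(bundle.spikes[ch - 1]):
            for t in train:
                rows.append((trial, t))
        pd.DataFrame(rows, columns=["trial_id", "spike_time_ms"]).to_csv(
            out / f"spikes_ch{ch}.csv", index=False
        )
    n_trials, n_ch, n_samp = bundle.lfp.shape
    lfp_cols = {"trial_id": np.repeat(np.arange(n_trials), n_samp)}
    time_rel = np.tile(bundle.lfp_time, n_trials)
    targets = np.repeat([ev.target_onset for ev in bundle.events], n_samp)
    lfp_cols["time_ms"] = time_rel + targets
    for ch in range(1, n_ch + 1):
        lfp_cols[f"ch{ch}"] = bundle.lfp[:, ch - 1, :].reshape(-1)
    pd.DataFrame(lfp_cols).to_csv(out / "lfp.csv", index=False)
    meta = {
        "session_id": bundle.session_id,
        "n_channels": bundle.n_channels,
        "contact_spacing_um": bundle.config.contact_spacing_um,
        "seed": bundle.config.seed,
        "lfp_window_ms": list(bundle.config.lfp_window),
        "config": asdict(bundle.config),
    }
    meta["config"]["task_mix"] = dict(bundle.config.task_mix)
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
    (out / "ground_truth.json").write_text(json.dumps(bundle.ground_truth, indent=2))
    return out


def load_session(session_dir: str | Path) -> SessionBundle:
    d = Path(session_dir)
    meta = json.loads((d / "meta.json").read_text())
    cfg_d = dict(meta["config"])
    for key in ("fixation_range", "delay_range", "saccade_latency_range", "lfp_window"):
        cfg_d[key] = tuple(cfg_d[key])
    config = GeneratorConfig(**cfg_d)
    ev_df = pd.read_csv(d / "events.csv")
    events = [
        TrialEvents(
            trial_id=int(r.trial_id),
            task=str(r.task),
            target_onset=float(r.target_onset_ms),
            go_cue=float(r.go_cue_ms),
            saccade_onset=float(r.saccade_onset_ms),
            delay_duration=float(r.delay_duration_ms),
            target_in_rf=bool(r.target_in_rf),
        )
        for r in ev_df.itertuples()
    ]
    n_trials = len(events)
    spikes = []
    for ch in range(1, config.n_channels + 1):
        df = pd.read_csv(d / f"spikes_ch{ch}.csv")
        per_trial = [np.empty(0) for _ in range(n_trials)]
        for trial, grp in df.groupby("trial_id"):
            per_trial[int(trial)] = np.sort(grp["spike_time_ms"].to_numpy(float))
        spikes.append(per_trial)
    lfp_df = pd.read_csv(d / "lfp.csv")
    lo, hi = config.lfp_window
    lfp_time = np.arange(lo, hi + 1, dtype=float)
    n_samp = lfp_time.size
    lfp = np.empty((n_trials, config.n_channels, n_samp), dtype=np.float32)
    for ch in range(1, config.n_channels + 1):
        lfp[:, ch - 1, :] = lfp_df[f"ch{ch}"].to_numpy(np.float32).reshape(n_trials, n_samp)
    gt_path = d / "ground_truth.json"
    gt = json.loads(gt_path.read_text()) if gt_path.exists() else {}
    return SessionBundle(
        config=config, events=events, spikes=spikes, lfp=lfp,
        lfp_time=lfp_time, ground_truth=gt,
        session_id=meta.get("session_id", d.name),
    )
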