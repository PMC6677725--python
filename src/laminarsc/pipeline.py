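"""End-to-end orchestration: per-session stages, depth alignment, and
population aggregation.

``run_session`` executes the full per-penetration analysis in order —
per-trial visual-burst detection and realignment, spike-density waveforms,
visual-onset latencies, epoch rates and VMI, unit categorization, delay-bin
profiles, bootstrap pre-saccadic events with Buildup/Burst classification,
and CSD reference-channel detection.  ``run_population`` re-indexes every
session onto the common CSD-aligned depth axis and produces
bootstrap-averaged depth profiles, cubic depth-trend fits with permutation
P values, and the Burst-to-peak scaling factor.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace as dc_replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bursts as _bursts
from . import csd as _csd
from . import metrics as _metrics
from . import presaccadic as _pre
from .spikes import (
    RateWaveform, spike_density, baseline_correct, epoch_mean, epoch_trial_means,
)
from .synthetic import SessionBundle

log = logging.getLogger("laminarsc")

__all__ = ["PipelineConfig", "SessionResult", "PopulationResult",
           "run_session", "run_population"]


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the published analysis settings."""

    burst_epoch: tuple[float, float] = (30.0, 150.0)       # ms re target onset
    min_spikes: int = 3
    surprise_threshold: float = float(_bursts.DEFAULT_SURPRISE_THRESHOLD)
    visual_window: tuple[float, float] = (-150.0, 150.0)   # ms re burst onset
    visual_baseline: tuple[float, float] = (-150.0, -50.0)
    visual_epoch: tuple[float, float] = (0.0, 100.0)
    movement_window: tuple[float, float] = (-300.0, 75.0)  # ms re saccade
    movement_baseline: tuple[float, float] = (-100.0, 0.0) # ms re go cue
    movement_epoch: tuple[float, float] = (-25.0, 25.0)
    latency_range: tuple[float, float] = (200.0, 400.0)
    n_boot: int = 100
    peak_window: tuple[float, float] = (-50.0, 50.0)
    buildup_burst_boundary: float = _pre.BUILDUP_BURST_BOUNDARY
    reliability_threshold: float = _pre.RELIABILITY_THRESHOLD
    csd_window: tuple[float, float] = (-50.0, 100.0)       # ms re burst onset
    ranksum_alpha: float = _metrics.RANKSUM_ALPHA
    rate_gate: float = _metrics.RATE_GATE_SPK_S
    n_boot_population: int = 1000
    n_perm: int = 1000
    aligned_clip: tuple[int, int] = (-8, 8)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {
            k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()
        }
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in asdict(self).items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class SessionResult:
    session_id: str
    task: str
    config: PipelineConfig
    alignment_channel: int | None
    reference_channel: int | None
    csd_flagged: bool
    n_trials: int
    n_trials_retained: int
    channels: pd.DataFrame
    delay: pd.DataFrame
    events: dict[int, dict[str, _pre.EventEstimate]] = field(default_factory=dict)
    alignable: bool = True


@dataclass
class PopulationResult:
    task: str
    profiles: dict[str, _metrics.PopulationProfile]
    fits: dict[str, _metrics.CubicFit]
    scaling_factor: float | None
    category_counts: pd.DataFrame
    presaccadic_counts: pd.DataFrame
    delay_profile: pd.DataFrame
    n_sessions: int


def _scalar_baseline_correct(waveform: RateWaveform, offset: float,
                             window: tuple[float, float]) -> RateWaveform:
    """Subtract a baseline measured in a different alignment frame."""
    return dc_replace(
        waveform,
        values=waveform.values - offset,
        trial_matrix=waveform.trial_matrix - offset,
        baseline_window=tuple(window),
    )


def _burst_aligned_lfp(bundle: SessionBundle, trial_ids: list[int],
                       onsets: dict[int, float],
                       window: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged LFP realigned on per-trial visual-burst onsets."""
    lo, hi = window
    time = np.arange(lo, hi + 1, dtype=float)
    lfp_lo = bundle.lfp_time[0]
    acc = np.zeros((bundle.n_channels, time.size))
    used = 0
    for i in trial_ids:
        rel = onsets[i] - bundle.events[i].target_onset  # burst re target
        start = int(round(rel + lo - lfp_lo))
        stop = start + time.size
        if start < 0 or stop > bundle.lfp.shape[2]:
            log.warning("trial %d: LFP window out of range, skipped", i)
            continue
        acc += bundle.lfp[i, :, start:stop]
        used += 1
    if used == 0:
        raise ValueError("no trials with LFP coverage for the CSD window")
    return acc / used, time


def run_session(
    bundle: SessionBundle,
    config: PipelineConfig | None = None,
    task: str = "VG",
) -> SessionResult:
    """Execute every per-session analysis stage for one task."""
    cfg = config or PipelineConfig()
    trials = bundle.trials(task)
    if not trials:
        raise ValueError(f"session has no target-in-RF {task} trials")
    events = bundle.events
    n_ch = bundle.n_channels

    # --- stage 1: per-trial visual-burst detection --------------------------
    detections: dict[int, dict[int, list]] = {}
    for ch in range(1, n_ch + 1):
        per_trial = {}
        for i in trials:
            ev = events[i]
            epoch = (ev.target_onset + cfg.burst_epoch[0],
                     ev.target_onset + cfg.burst_epoch[1])
            per_trial[i] = _bursts.poisson_surprise_bursts(
                bundle.spikes[ch - 1][i], epoch,
                min_spikes=cfg.min_spikes,
                surprise_threshold=cfg.surprise_threshold,
                rate_interval=(0.0, ev.saccade_onset + 100.0),
            )
        detections[ch] = per_trial

    base_cols = {
        "channel": list(range(1, n_ch + 1)),
        "aligned_index": [np.nan] * n_ch,
    }
    try:
        align_ch, retained, onsets = _bursts.select_alignment_channel(detections)
    except ValueError:
        log.warning("session %s: no visual bursts; unalignable", bundle.session_id)
        return SessionResult(
            session_id=bundle.session_id, task=task, config=cfg,
            alignment_channel=None, reference_channel=None, csd_flagged=False,
            n_trials=len(trials), n_trials_retained=0,
            channels=pd.DataFrame(base_cols), delay=pd.DataFrame(),
            alignable=False,
        )
    discarded = [i for i in trials if i not in onsets]
    if discarded:
        log.info("session %s: discarded %d/%d trials without a burst on the "
                 "alignment channel", bundle.session_id, len(discarded), len(trials))

    # --- movement-frame trial subset (standard saccade latencies) ----------
    mov_trials = [
        i for i in trials
        if cfg.latency_range[0] <= events[i].saccade_latency <= cfg.latency_range[1]
    ]
    if len(mov_trials) < len(trials):
        log.info("session %s: %d trials outside the %s ms latency range",
                 bundle.session_id, len(trials) - len(mov_trials), cfg.latency_range)

    onset_list = [onsets[i] for i in retained]
    go_list = [events[i].go_cue for i in mov_trials]
    sacc_list = [events[i].saccade_onset for i in mov_trials]
    delay_end = float(np.floor(min(events[i].go_cue - onsets[i] for i in retained)))

    rows = []
    delay_rows = []
    all_events: dict[int, dict[str, _pre.EventEstimate]] = {}
    for ch in range(1, n_ch + 1):
        trains_v = [bundle.spikes[ch - 1][i] for i in retained]
        trains_m = [bundle.spikes[ch - 1][i] for i in mov_trials]

        # visual frame: density over the delay too, for the bin analysis
        wf_v_raw = spike_density(
            trains_v, onset_list, (cfg.visual_baseline[0], max(delay_end, 151.0)),
            alignment="visual_burst",
        )
        wf_v = baseline_correct(wf_v_raw, cfg.visual_baseline)
        onset = _bursts.estimate_visual_onset(
            _crop(wf_v, cfg.visual_window)
        )
        V = epoch_mean(wf_v, cfg.visual_epoch)

        # movement frame
        wf_g = spike_density(trains_m, go_list, cfg.movement_baseline,
                             alignment="go_cue")
        m_base = float(wf_g.values.mean())
        wf_m_raw = spike_density(trains_m, sacc_list, cfg.movement_window,
                                 alignment="saccade_onset")
        wf_m = _scalar_baseline_correct(wf_m_raw, m_base, cfg.movement_baseline)
        M = epoch_mean(wf_m, cfg.movement_epoch)

        rec = _metrics.vmi(V, M)
        cat = _metrics.categorize_unit(
            epoch_trial_means(wf_v_raw, cfg.visual_epoch),
            epoch_trial_means(wf_v_raw, cfg.visual_baseline),
            epoch_trial_means(wf_m_raw, cfg.movement_epoch),
            epoch_trial_means(wf_g, cfg.movement_baseline),
            alpha=cfg.ranksum_alpha, rate_gate=cfg.rate_gate,
        )

        # delay-period bins from the last visual peak to the shortest delay end
        peak_t = _metrics.last_visual_peak(wf_v.time, wf_v.values)
        bins = _metrics.delay_bins(wf_v.time, wf_v.values, peak_t, delay_end)
        for b, val in enumerate(bins):
            delay_rows.append({"channel": ch, "bin": b + 1, "rate": float(val)})

        # pre-saccadic events
        # event detection runs on raw (non-baseline-corrected) activity; the
        # go-aligned baseline distribution is raw as well
        ev_est = _pre.bootstrap_events(
            wf_m_raw.trial_matrix, wf_m_raw.time, wf_g.trial_matrix,
            n_boot=cfg.n_boot, seed=cfg.seed + 10007 * ch,
            peak_window=cfg.peak_window,
            reliability_threshold=cfg.reliability_threshold,
        )
        all_events[ch] = ev_est
        cls = _pre.classify_channel(ev_est["E2"], ev_est["E3"], wf_m,
                                    boundary=cfg.buildup_burst_boundary)
        p_est = ev_est["P"]
        peak_rate = np.nan
        if p_est.detected:
            i_pk = int(np.argmin(np.abs(wf_m.time - p_est.mean)))
            peak_rate = float(wf_m.values[i_pk])

        def _f(x):
            return np.nan if x is None else float(x)

        row = {
            "channel": ch,
            "n_bursts": sum(1 for b in detections[ch].values() if b),
            "Pv": _f(onset.peak_time), "Bv": _f(onset.baseline_time),
            "Lv": _f(onset.latency), "visual_detected": onset.detected,
            "V": V, "M": M, "vmi": _f(rec.vmi),
            "category": cat.category,
            "presaccadic_category": cls.category,
            "buildup_onset": _f(cls.buildup_onset),
            "buildup_rate": _f(cls.buildup_rate),
            "burst_onset": _f(cls.burst_onset),
            "burst_rate": _f(cls.burst_rate),
            "peak_time": _f(p_est.mean), "peak_rate": peak_rate,
        }
        for name in ("E1", "E2", "E3", "P"):
            est = ev_est[name]
            row[f"{name}_mean"] = _f(est.mean)
            row[f"{name}_ci_lo"] = est.ci[0] if est.ci else np.nan
            row[f"{name}_ci_hi"] = est.ci[1] if est.ci else np.nan
            row[f"{name}_norm_ci"] = _f(est.normalized_ci_range)
            row[f"{name}_reliable"] = est.reliable
        rows.append(row)

    # --- CSD reference detection -------------------------------------------
    reference = None
    flagged = False
    try:
        lfp_mat, lfp_t = _burst_aligned_lfp(bundle, retained, onsets,
                                            cfg.csd_window)
        profile = _csd.compute_csd(
            lfp_mat, bundle.config.contact_spacing_um, time=lfp_t,
            detection_window=cfg.csd_window,
        )
        reference = _csd.detect_reference_channel(profile)
        flagged = profile.flagged
    except ValueError as err:
        log.warning("session %s: CSD reference detection failed (%s)",
                    bundle.session_id, err)

    channels = pd.DataFrame(rows)
    if reference is not None:
        channels["aligned_index"] = channels["channel"] - reference
    else:
        channels["aligned_index"] = np.nan

    return SessionResult(
        session_id=bundle.session_id, task=task, config=cfg,
        alignment_channel=align_ch, reference_channel=reference,
        csd_flagged=flagged, n_trials=len(trials),
        n_trials_retained=len(retained), channels=channels,
        delay=pd.DataFrame(delay_rows), events=all_events,
        alignable=reference is not None,
    )


def _crop(waveform: RateWaveform, window: tuple[float, float]) -> RateWaveform:
    sl = waveform.window_slice(window)
    return dc_replace(
        waveform,
        time=waveform.time[sl],
        values=waveform.values[sl],
        trial_matrix=waveform.trial_matrix[:, sl],
    )


_PROFILE_QUANTITIES = {
    "visual_rate": "V",
    "movement_rate": "M",
    "vmi": "vmi",
    "visual_latency": "rel_latency",
    "buildup_onset": "buildup_onset",
    "burst_onset": "burst_onset",
    "buildup_rate": "buildup_rate",
    "burst_rate": "burst_rate",
    "peak_rate": "peak_rate",
}
_FIT_QUANTITIES = ("visual_latency", "buildup_onset", "burst_onset",
                   "burst_rate", "peak_rate")


def run_population(
    results: list[SessionResult],
    config: PipelineConfig | None = None,
) -> PopulationResult:
    """Depth-align session results and compute population depth profiles."""
    cfg = config or (results[0].config if results else PipelineConfig())
    usable = [r for r in results if r.alignable and r.reference_channel is not None]
    if not usable:
        raise ValueError("no alignable sessions (no CSD reference detected)")
    task = usable[0].task

    tables = {}
    refs = {}
    for r in usable:
        df = r.channels.copy()
        ref_row = df[df["channel"] == r.reference_channel]
        ref_lv = ref_row["Lv"].iloc[0] if len(ref_row) else np.nan
        df["rel_latency"] = df["Lv"] - ref_lv
        df.loc[~df["visual_detected"].astype(bool), "rel_latency"] = np.nan
        tables[r.session_id] = df
        refs[r.session_id] = r.reference_channel
    aligned = _csd.align_sessions(tables, refs, clip=cfg.aligned_clip)

    profiles = {}
    fits = {}
    for name, col in _PROFILE_QUANTITIES.items():
        profiles[name] = _metrics.population_aggregate(
            aligned, col, quantity=name,
            n_boot=cfg.n_boot_population, seed=cfg.seed,
        )
    for name in _FIT_QUANTITIES:
        tab = profiles[name].table.dropna(subset=["mean"])
        if len(tab) >= 5:
            fits[name] = _metrics.cubic_fit_permutation(
                tab["aligned_index"].to_numpy(float), tab["mean"].to_numpy(float),
                n_perm=cfg.n_perm, seed=cfg.seed,
            )

    scaling = None
    if "burst_rate" in fits and "peak_rate" in fits:
        try:
            scaling, _, _ = _metrics.burst_peak_scaling(
                fits["burst_rate"], fits["peak_rate"], cfg.aligned_clip
            )
        except ValueError:
            log.warning("burst fit maximum non-positive; no scaling factor")

    def _counts(col: str) -> pd.DataFrame:
        sub = aligned[aligned[col] != "none"]
        counts = (
            sub.groupby(["aligned_index", col]).size().unstack(fill_value=0)
        )
        per_channel = counts.div(counts.sum(axis=1), axis=0)
        per_channel.columns = [f"{c}_frac" for c in per_channel.columns]
        out = pd.concat([counts, per_channel], axis=1).reset_index()
        return out

    delay_tables = {
        r.session_id: r.delay for r in usable if len(r.delay)
    }
    if delay_tables:
        delay_aligned = _csd.align_sessions(
            delay_tables, refs, clip=cfg.aligned_clip
        )
        delay_profile = (
            delay_aligned.groupby(["aligned_index", "bin"])["rate"]
            .agg(["mean", "count"]).reset_index()
            .rename(columns={"count": "n_sessions"})
        )
    else:
        delay_profile = pd.DataFrame()

    return PopulationResult(
        task=task,
        profiles=profiles,
        fits=fits,
        scaling_factor=scaling,
        category_counts=_counts("category"),
        presaccadic_counts=_counts("presaccadic_category"),
        delay_profile=delay_profile,
        n_sessions=len(usable),
    )


# ---------------------------------------------------------------------------
# output writers

def write_session(result: SessionResult, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.channels.to_csv(out / f"channels_{result.task}.csv", index=False)
    result.delay.to_csv(out / f"delay_bins_{result.task}.csv", index=False)
    meta = {
        "session_id": result.session_id, "task": result.task,
        "alignment_channel": result.alignment_channel,
        "reference_channel": result.reference_channel,
        "csd_flagged": result.csd_flagged,
        "n_trials": result.n_trials,
        "n_trials_retained": result.n_trials_retained,
        "alignable": result.alignable,
        "seed": result.config.seed,
    }
    (out / f"session_{result.task}.json").write_text(json.dumps(meta, indent=2))
    return out


def write_population(pop: PopulationResult, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, profile in pop.profiles.items():
        profile.table.to_csv(out / f"profile_{name}_{pop.task}.csv", index=False)
    fit_dump = {
        name: {
            "coefficients": list(map(float, fit.coefficients)),
            "r_squared": fit.r_squared,
            "p_perm": fit.p_perm,
            "n_perm": fit.n_perm,
        }
        for name, fit in pop.fits.items()
    }
    summary = {
        "task": pop.task,
        "n_sessions": pop.n_sessions,
        "scaling_factor": pop.scaling_factor,
        "fits": fit_dump,
    }
    (out / f"population_{pop.task}.json").write_text(json.dumps(summary, indent=2))
    pop.category_counts.to_csv(out / f"categories_{pop.task}.csv", index=False)
    pop.presaccadic_counts.to_csv(
        out / f"presaccadic_categories_{pop.task}.csv", index=False
    )
    return out
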