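# laminarsc

Laminar analysis of superior-colliculus (SC) population activity recorded
with linear multi-contact probes during visually guided (VG) and
memory-guided (MG) delayed saccade tasks.

The SC transforms visual input into saccade motor commands across its
dorsoventral depth: dorsal layers respond to the stimulus first, ventral
layers carry the movement burst. Quantifying that organization from
16-contact recordings requires a chain of specialized steps, which this
package implements as a tested, reusable library:

- **Spike densities** — spikes convolved with a causal EPSP-shaped kernel
  `R(t) = (1 − e^(−t/τg)) · e^(−t/τd)` (τg = 1 ms, τd = 20 ms, unit area),
  on a 1-ms grid, aligned to target onset, visual-burst onset, go cue, or
  saccade onset.
- **Burst alignment** — per-trial visual bursts detected with the Poisson
  surprise statistic `S = −log P(≥ n spikes | Poisson at the trial's mean
  rate)` (≥ 3 spikes, S ≥ −log 0.025) in the [30, 150] ms epoch after
  target onset; the channel with the most detected bursts anchors a
  per-trial realignment of all channels.
- **Visual latency** — per channel, the peak `Pv` is found in [−50, 150] ms,
  two sliding 20-ms windows (W2 10 ms earlier than W1) walk back in 1-ms
  steps until their activity distributions stop differing (Welch t test,
  P < 0.01, persisting 10 iterations), defining `Bv`; the latency `Lv` is
  the hinge point of a two-segment piecewise regression on `[Bv, Pv]`.
- **Pre-saccadic events** — on saccade-aligned activity (latencies
  200–400 ms), 100 bootstrap resamples each yield `E1` (first 1-ms bin from
  −200 ms whose difference from the pre-go baseline persists ≥ 100 ms),
  `E2` (hinge on `[E1−100, E1]`, the accumulation onset), `E3` (hinge
  between `E2` and the peak `P`, the burst onset). Events whose 95%
  replicate-CI range, normalized by the search-window size, exceeds 0.6 are
  discarded; reliable hinges before −50 ms are **Buildup**, later ones
  **Burst**.
- **Depth alignment** — the current–source density (second spatial
  difference of the LFP across 150 µm contacts, sinks negative) shows a
  visual-evoked sink; the contact at its ventral edge becomes aligned index
  0 in every session, putting penetrations on a common depth axis with at
  most 75 µm of index error.
- **Population statistics** — the visuomotor index
  `VMI = (M − V)/(M + V)` (V: [0, 100] ms after visual onset; M: ±25 ms
  around saccade onset), rank-sum unit categorization (P < 0.001 plus a
  10 spk/s floor), 50-ms delay-period bins, session-averaged depth profiles
  with 1000-resample bootstrap CIs, cubic depth-trend fits
  `ax³ + bx² + cx + d` with 1000-permutation P values, and the
  burst-to-peak amplitude scaling factor.

Because laminar SC recordings are not publicly deposited, the package ships
a fully seeded **synthetic session generator** (`laminarsc.synthetic`) that
encodes the laminar structure of interest — depth-graded visual amplitudes
and latencies, delay activity, a depth-graded accumulation onset, a
synchronous motor burst, and an LFP sink — with exact ground truth, so
every stage is validated by parameter recovery.

## Worked example

`examples/03_presaccadic_events.py` detects pre-saccadic events on the
strongest motor channel of a 200-trial synthetic session:

```
E1:   -67.0 ms  CI [-69.5, -60.0]  reliable=True
E2:   -85.8 ms  CI [-150.0, -70.0]  reliable=False
E3:   -26.9 ms  CI [-42.0, -18.5]  reliable=True
P:    12.9 ms  CI [7.0, 16.0]  reliable=True
classification: Burst-only
true buildup onset -86.7 ms, true burst onset -26.9 ms re saccade
```

The burst hinge `E3` lands exactly on the generator's synchronous burst
onset (−26.9 ms re saccade). The accumulation hinge `E2` points at the true
buildup onset but its bootstrap CI is too wide for the 0.6 reliability
gate on this channel, so the channel classifies as Burst-only — the
reliability gating working as designed.

`examples/04_depth_alignment_population.py` aligns three penetrations and
prints the population depth profiles; the recovered burst-to-peak scaling
factor (3.46) matches the generator's amplification of 3.3 within 5%, and
the VMI profile runs from a movement-dominated ventral plateau to visual
dominance dorsally.

The other examples cover session generation (`01`) and visual-latency
gradients (`02`). A thin CLI wraps the same pipeline for batch use:

```bash
laminarsc synth --seed 1 --out data/ --n-sessions 10
laminarsc all data/session-* --out results/ --tasks VG
```

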