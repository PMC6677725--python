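# Methods

This note documents the models, estimators, and design choices behind
`laminarsc`, in enough detail to reproduce or audit any stage.

## Spike-density estimation

Spike trains are convolved with a causal kernel shaped like an excitatory
post-synaptic potential, `R(t) = (1 − e^(−t/τg)) e^(−t/τd)` with growth and
decay constants τg = 1 ms and τd = 20 ms, sampled on a 1-ms grid. The kernel
is truncated at 100 ms (five decay constants) and renormalized to unit mass,
so a lone spike integrates to exactly 1 inside any window extending at least
100 ms past it and trial-averaged waveforms are calibrated in spk/s. The
amplitude normalization is our choice (the kernel shape alone does not fix
it); unit area makes epoch means equal firing rates. Waveforms are computed
only where the full window has data; spikes up to one kernel length before
the window still contribute, so there are no left-edge artifacts.

Two consequences of this kernel matter downstream and are accounted for in
the recovery tests:

* all waveform features are delayed by up to the kernel's mean lag (~21 ms
  for slow features); timing *differences* between channels are unaffected;
* 1-ms samples of a smoothed waveform are strongly autocorrelated
  (correlation length ≈ the kernel width), which any per-bin statistical
  test must respect.

## Visual-burst detection and alignment

Per-trial bursts are scored with the Poisson surprise
`S = −log P(≥ n spikes in the interval | Poisson at the trial's mean rate)`
in the [30, 150] ms epoch after target onset, with the published criteria
(≥ 3 spikes, S ≥ −log 0.025 ≈ 3.69). Rather than the classical heuristic
grow/shrink scan, the implementation maximizes S exhaustively over every
run of consecutive spikes inside the epoch and recurses on the remainder —
the global optimum of the same objective. A direct Poisson tail-sum oracle
verifies the S values in the tests.

The alignment channel is the one with the most trials containing a burst.
Ties (common when bursts are vigorous on many contacts) go to the channel
with the largest summed surprise — the most reliably bursting contact —
rather than an arbitrary positional rule. Trials without a burst on the
alignment channel are discarded; all channels are realigned on its
per-trial burst onsets. Note that burst onset is the time of a spike, so
the detected onset lags the underlying rate onset by the wait for the first
burst spike; with multi-unit-scale bursts this bias is 2–3 ms and common to
all channels, cancelling in across-channel latency differences.

## Visual latency (Pv / Bv / Lv)

On the burst-aligned, baseline-corrected ([−150, −50] ms) trial average,
the peak `Pv` is the argmax in [−50, 150] ms. Two 20-ms windows, W2 always
10 ms earlier than W1 and initially [Pv−30, Pv−10] and [Pv−20, Pv], slide
backwards in 1-ms steps until W2 reaches [−50, −30]. Their values are
compared with a two-tailed Welch t test at P < 0.01 (21 one-millisecond
samples per window). Because both windows start around the peak the test
is significant initially; `Bv` is the W1 start at the first iteration where
it *becomes* non-significant and remains so for the next 10 iterations (or
through the end of the scan, whichever comes first — without this
truncation a peak near 0 ms could never yield a Bv at all). Leading
non-significant iterations before any significant one do not qualify:
near-peak curvature can make the first few comparisons non-significant,
and accepting them produces spurious latencies just below the peak.
`Lv` is the breakpoint of the two-segment fit on `[Bv, Pv]`.

Zero-variance window pairs (exactly flat synthetic data) are handled by an
exact-equality rule: significant iff the means differ.

## Hinge-point ("two-piecewise") regression

Hinges are located by exhaustive search over integer breakpoints, at each
candidate fitting a **broken-stick model** — two lines constrained to meet
at the breakpoint (`y = a + bx + c(x − x_k)+`) — and minimizing the total
squared residual; ties resolve to the earliest breakpoint, and each segment
must contain at least 3 samples. Whether the original procedure constrained
continuity is not documented; we choose the continuous form because a
"hinge" is a connected joint and because the unconstrained variant is
degenerate on weakly structured windows (any split of a flat stretch fits
equally well, so the breakpoint wanders with noise). The unconstrained
two-independent-lines variant remains available (`continuous=False`), and
both are verified against brute-force oracles.

## Pre-saccadic events E1/E2/E3/P

Analysis uses saccade-aligned activity over [−300, +75] ms from trials with
saccade latencies in the standard 200–400 ms range, and a baseline of
go-cue-aligned activity over the 100 ms before the go cue. One hundred
bootstrap resamples of trials (with replacement, full n; replicate *r* is
seeded `seed + r`) each produce:

* **E1b** — activity and baseline are both referenced to the resample's
  pre-go baseline mean; a linear trend fitted on [−300, −200] ms is
  extrapolated and subtracted from the activity (only for this step). Each
  1-ms bin's across-trial distribution is compared against the pooled
  baseline distribution (time points × trials) with a Welch t test; E1b is
  the first bin from −200 ms whose significance at P < 0.01 persists for
  100 consecutive bins. Zero-variance cases use the exact-equality rule.
* **E2b** — the hinge of the raw resample average on `[E1b−100, E1b]`
  (E2b ≤ E1b by construction).
* **Pb** — the argmax of the raw average in the ±50 ms peak window.
* **E3b** — the hinge between E2b and Pb (skipped when the interval has
  fewer than 6 samples), with both segment slopes recorded.

Two numerical safeguards around the detrending step: the baseline is
referenced rather than extrapolated into (subtracting a line evaluated
100+ ms outside its fit window would inject the fit's noise into the
comparison), and the fitted slope is kept only when an AR(1)-corrected
t test rejects zero slope — the OLS slope SE of 100 autocorrelated samples
understates the truth several-fold, and subtracting an insignificant noise
slope creates spurious early E1 detections.

Replicates are aggregated as means with 95% quantile CIs; CI ranges are
normalized by the event's search-window size (E1: 200 ms; E2: 100 ms; E3:
the mean `Pb − E2b` interval; P: the peak-window width) and an event is
reliable only if the normalized range is ≤ 0.6, at least half the
replicates detected it (a mean over a minority of replicates is not
representative), and — for E3 — the replicate slope distributions before
and after the hinge have non-overlapping 95% intervals.

Reliable hinges earlier than −50 ms re saccade are classified Buildup,
later ones Burst. When both E2 and E3 are reliable with disjoint CIs each
is classified separately; with overlapping CIs they are treated as one
hinge (the tighter normalized CI wins, tie to E3); otherwise the single
reliable hinge is classified alone. Onset rates are read from the
baseline-corrected movement-frame average at the event means.

### A structural limitation of E2

E1 fires as soon as the accumulation becomes statistically visible, i.e.
when activity exceeds ≈ 2.6 standard errors of the across-trial mean. The
E2 search window `[E1b−100, E1b]` therefore ends where the in-window signal
is only ~2.6 SE, independent of firing-rate scale or trial count — the
window's information about the hinge does not grow with data quality. In
the low-variance regimes where parameter recovery is possible, E2's
replicate CI is consequently wide (typically 60–120 ms against the 60 ms
reliability bound), and only a minority of channel-sessions yield a
reliable Buildup estimate; those that do are accurate (single-digit ms
error in the recovery tests). Classification is therefore dominated by
Burst-only labels on synthetic data, and the expectation that
Buildup–Burst channels dominate the central depths is not met by this
pipeline under recovery-scale noise. This is a property of the E1-anchored
window construction, not of the hinge estimator; in recordings with large
across-trial variability E1 lags the hinge by tens of milliseconds and the
window covers the hinge comfortably.

## CSD depth alignment

The CSD is the negated second spatial difference of the trial-averaged,
burst-aligned LFP across contacts (150 µm pitch; conductivity folded into
arbitrary units; sinks negative), defined on the interior contacts. The
mean profile over a 150-ms window around the visual burst ([−50, +100] ms
by default; the exact start is configurable since only the spatial sign
structure matters) shows a contiguous negative sink dorsal of the
intermediate layers. The reference channel is the contact closest to the
interpolated negative-to-positive crossing at the sink's ventral edge; the
sink is the contiguous negative run containing the global minimum, and a
session is flagged for review when other negative regions deeper than 10%
of the sink minimum exist (shallow noise dips are ignored). Channel *k*
maps to aligned index `k − reference` (dorsal positive, 150 µm per step,
residual alignment error ≤ 75 µm); population analyses clip to [−8, +8].

## Population statistics

Depth profiles are session means per aligned index with 95% percentile
bootstrap CIs over sessions (1000 resamples); single-session indices are
reported with degenerate CIs and flagged, and session-averaged comparisons
in the recovery tests use indices observed in at least two sessions.
Cubic depth trends are least-squares fits of `ax³ + bx² + cx + d` over the
aligned index; the permutation P value is the fraction of 1000
depth-shuffles whose refitted R² is ≥ the observed R² (so a perfect fit can
attain P = 0 when no shuffle ties it), with significance at P < 0.05.
Constant data are guarded to R² = 0, P = 1. The burst-to-peak scaling
factor is the ratio of the maxima of the cubic fits to the peak-rate and
burst-onset-rate profiles over the shared index range. VG/MG comparisons
standardize each sample, test normality with a Kolmogorov–Smirnov test, and
use a t test when both samples pass, a Wilcoxon rank-sum test otherwise;
per-channel P values are reported raw, without multiple-testing correction.
Delay-period activity is summarized as baseline-corrected means in
non-overlapping 50-ms bins from the last visual-burst peak (the final local
maximum exceeding half the peak amplitude within [0, 150] ms — the
prominence criterion is our choice and configurable) to the end of the
shortest delay.

The visuomotor index `VMI = (M − V)/(M + V)` uses the baseline-corrected
mean rates V ([0, 100] ms after visual burst onset, baseline [−150, −50])
and M ([−25, +25] ms re saccade, baseline [−100, 0] re go cue); it is
undefined at V + M = 0. Units are categorized visual-only /
visuo-movement / movement-only from per-epoch rank-sum tests (P < 0.001)
against the epoch's baseline plus a 10 spk/s floor on the corrected mean.

## Synthetic sessions: what they emulate, and what they do not

The generator draws spikes from inhomogeneous Poisson processes (thinning
against the closed-form rate's supremum; validated by the time-rescaling
theorem) and builds, per trial: a fixation period (200–350 ms), target
onset, a 600–900 ms delay, a go cue, and a saccade 200–400 ms later. All
randomness derives from one seed; identical seeds give identical bundles.

Rate templates (all anchored to the channel's aligned depth index):

* **Visual transient** — 2-ms linear rise, 15-ms exponential decay; peak
  amplitude Gaussian over channels (σ = 4) with its maximum (900 spk/s) at
  aligned index +4 and a 30 spk/s floor; onset latency linear in depth,
  50 ms after target at the most dorsal contact and 7.3 ms later at the
  most ventral. The instantaneous amplitude is multi-unit scale — chosen so
  that per-trial Poisson-surprise onset detection has millisecond jitter,
  the regime the burst-alignment method presupposes; the resulting
  *measured* visual epoch rates peak near 180 spk/s, higher than the
  published session-averaged peak but with the identical depth profile.
* **Delay activity** — a plateau at 4% of the channel's visual amplitude
  from the transient peak until the saccade.
* **Accumulation (buildup)** — linear climb from zero (at the onset) to the
  channel's burst-onset rate; onset earliest (−102.7 ms re saccade) at
  aligned index +2 and 4 ms later per channel of distance.
* **Motor burst** — starts at −26.9 ms re saccade on every channel
  (synchronous by construction); the rate at burst onset is Gaussian over
  channels (σ = 3.5, maximum 50.2 spk/s at aligned index −2, floor 3); the
  peak at saccade onset is a constant multiple of the burst-onset rate
  (3.3 for VG, 2.4 for MG — MG's attenuated movement burst); exponential
  post-saccadic decay (30 ms).
* **Baseline** — 10 spk/s throughout; anti-response-field trials (optional)
  are flat.
* **LFP** — a spatial profile whose second difference is, by construction,
  a contiguous negative sink spanning four contacts dorsal of the
  configured reference channel (solved from the discrete Poisson equation,
  scaled to 200 µV), times an alpha-shaped transient beginning 20 ms after
  target onset, plus white noise (20 µV). Traces are stored per trial over
  [−300, +500] ms around target onset — everything the CSD stage uses —
  rather than whole-trial, to bound memory.

Ground-truth epoch rates (V, M, VMI) are defined as the infinite-trial
expectation of the measurement: the template convolved with the
spike-density kernel before epoch averaging, so recovery tests compare the
estimator against what an ideal observer of the same pipeline would see.

Not emulated: biophysical LFP generation, spike waveforms, across-trial
rate correlations or non-Poisson dispersion, session-to-session
heterogeneity of the laminar profiles, eye-movement kinematics beyond a
sigmoid velocity trace, and anti-RF response structure. Passing recovery
tests therefore demonstrate estimator correctness under Poisson
variability with a homogeneous laminar design — not robustness to the
correlated, heterogeneous variability of real recordings.

## Problem sizes

Recovery tests use ten 200-trial VG sessions (16 channels); the CSD
recovery check uses one hundred 30-trial LFP-only penetrations; sampler and
calibration checks use 100–1000 replicates (permutation calibration: 200
null datasets of 17 points with 1000 permutations each; bootstrap coverage:
200 datasets of 20 sessions with 1000 resamples each). Bootstrap event
detection uses the published 100 replicates throughout.

## Known limitations

* The E2 window-geometry limitation described above: Buildup
  classifications are sparse on low-variance data, and depth profiles of
  Buildup onsets rest on the minority of channel-sessions passing the
  reliability gate.
* Burst-onset and latency estimates inherit small biases from the causal
  kernel and spike-based onset detection; these cancel in across-channel
  contrasts but not in absolute event times.
* The alignment channel's own waveform is conditioned on its detected
  bursts (a pre-onset gap and post-onset sharpening); its latency estimate
  is treated like any other channel's and occasionally fails detection.
* Second-difference CSD, not iCSD: reference detection needs only the
  sink's sign structure, which both estimators share.
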