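"""Estimate per-channel visual-onset latencies from burst-aligned activity.

Per-trial visual bursts are detected with the Poisson-surprise statistic,
the channel with the most detections anchors the alignment, and each
channel's latency Lv is the hinge point of a two-segment fit between the
point of return-to-baseline (Bv) and the visual peak (Pv).
"""

import numpy as np

from laminarsc import GeneratorConfig, PipelineConfig, generate_session, run_session

config = GeneratorConfig(seed=3, n_trials=200, task_mix={"VG": 1.0})
bundle = generate_session(config)
result = run_session(bundle, PipelineConfig(seed=1), task="VG")

print(f"alignment channel: {result.alignment_channel} "
      f"({result.n_trials_retained}/{result.n_trials} trials with a burst)")

truth = np.array(bundle.ground_truth["visual_latency"])
df = result.channels[result.channels.visual_detected]
# anchor on the detected channel closest to the CSD reference contact
anchor = df.iloc[(df.channel - result.reference_channel).abs().argmin()]
print(f"latency anchor: contact {int(anchor.channel)} "
      f"(CSD reference is contact {result.reference_channel})")
print("channel  Lv(rel, ms)  true latency diff (ms)")
for _, row in df.iterrows():
    rel = row.Lv - anchor.Lv
    true = truth[int(row.channel) - 1] - truth[int(anchor.channel) - 1]
    print(f"  {int(row.channel):2d}     {rel:+6.1f}        {true:+6.2f}")
# Dorsal contacts (high numbers) lead by a few milliseconds: the recovered
# relative latencies track the configured dorsoventral gradient.
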