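"""Detect pre-saccadic Buildup/Burst events on one channel.

100 bootstrap resamples of trials each yield an E1 (sustained significant
change vs the pre-go baseline), E2 (hinge where accumulation begins), E3
(hinge into the burst), and P (peak time). Events whose normalized CI range
exceeds 0.6 are discarded; reliable hinges earlier than -50 ms re saccade
are Buildup, later ones Burst.
"""

import numpy as np

from laminarsc import (
    GeneratorConfig, bootstrap_events, classify_channel, generate_session,
    spike_density,
)

config = GeneratorConfig(seed=8, n_trials=200, task_mix={"VG": 1.0})
bundle = generate_session(config)
channel = config.reference_channel + config.motor_peak_channel  # strongest burst

events = bundle.events
trials = [i for i in bundle.trials("VG")
          if 200 <= events[i].saccade_latency <= 400]
trains = [bundle.spikes[channel - 1][i] for i in trials]
wf_go = spike_density(trains, [events[i].go_cue for i in trials], (-100, 0))
wf_sac = spike_density(trains, [events[i].saccade_onset for i in trials],
                       (-300, 75), alignment="saccade_onset")

estimates = bootstrap_events(wf_sac.trial_matrix, wf_sac.time,
                             wf_go.trial_matrix, n_boot=100, seed=0)
for name in ("E1", "E2", "E3", "P"):
    e = estimates[name]
    if e.detected:
        print(f"{name}: {e.mean:7.1f} ms  CI [{e.ci[0]:.1f}, {e.ci[1]:.1f}]  "
              f"reliable={e.reliable}")
    else:
        print(f"{name}: not detected")

cls = classify_channel(estimates["E2"], estimates["E3"], wf_sac)
print(f"classification: {cls.category}")
print(f"true buildup onset {bundle.ground_truth['buildup_onset'][channel-1]:.1f} ms, "
      f"true burst onset {config.burst_onset} ms re saccade")
# E3 pins the synchronous motor-burst hinge near -27 ms; E2, when its
# bootstrap CI is tight enough, recovers the earlier accumulation onset.
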