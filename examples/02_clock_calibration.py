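"""Tap detection and clock-drift calibration.

Synthetic traces carry five-spike calibration tap bursts at both ends.
This script detects them, pairs them with (simulated) video tap times
from a drifting reference clock, fits the linear clock model and shows
that label intervals map correctly onto device time.
"""

import somtag as st

dataset = st.simulate_trace(st.default_behaviour_library(), total_s=600, seed=2)
events = st.detect_taps(dataset.trace, threshold_g=3.0)
print(f"spike-burst events at: {[round(t, 2) for t in events]} s")
# vigorous hunting bursts can exceed the threshold too; the calibration
# taps are the bursts at the known handling times (trace start and end)
device_taps = [events[0], events[-1]]

# pretend the device leads the video clock by 2.5 s and drifts +0.18 s/h
video_taps = [(t - 2.5) / (1 + 0.18 / 3600) for t in device_taps]

clock = st.fit_clock(device_taps, video_taps)
print(f"fitted offset {clock.offset_s:.3f} s, drift {clock.drift_s_per_hour:.3f} s/h")

labels = [st.LabelInterval(100.0, 130.0, "walking", "bib_off")]
aligned = st.align_labels(labels, clock)
print(f"video-clock label [100, 130) -> device clock "
      f"[{aligned[0].start_s:.3f}, {aligned[0].end_s:.3f})")
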