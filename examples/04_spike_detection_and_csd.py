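"""Preprocessing fixtures: threshold-based multi-unit event detection and
current-source-density laminar assignment."""

import numpy as np

from lamvar import (assign_layers, compute_csd, detect_mu_events,
                    estimate_noise_sd, simulate_laminar_lfp, simulate_voltage)
from lamvar.synth import default_waveform

fs = 30_000.0
rng = np.random.default_rng(0)
wf = default_waveform(fs, amp=8.0)                   # SNR 8 vs unit noise
true_times = np.sort(rng.uniform(0.05, 9.95, 250))
trace = simulate_voltage(10.0, fs, 1.0, true_times, wf, seed=1)

print(f"robust noise SD estimate: {estimate_noise_sd(trace):.3f} (true 1.0)")
events = detect_mu_events(trace, fs, band_hz=(300.0, 5000.0), k=4.0)
print(f"detected {events.size} events for {true_times.size} true spikes")

lfp, times_ms, depths_um = simulate_laminar_lfp(sink_channel=12,
                                                source_channel=16, seed=0)
csd = compute_csd(lfp, times_ms, depths_um, fs=1000.0)
layers = assign_layers(csd)
print(f"\nCSD sink at {layers.sink_depth_um:.0f} um (dipole placed at "
      f"{depths_um[12]:.0f} um)")
print(f"granular layer spans {layers.sg_g_boundary_um:.0f}-"
      f"{layers.g_ig_boundary_um:.0f} um; channels above are SG, below IG")
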