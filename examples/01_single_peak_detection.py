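"""Detect single-particle fluorescence bursts in a photon-count trace.

Simulates a 10-second trace of sparse bead-like bursts on a Poisson
background (10 µs bins), runs the cluster-CWT detector with a Ricker
wavelet, and compares the detections with the simulation's ground truth.
"""

import numpy as np

import pcwa

# ~50 bursts of median peak amplitude 8 counts/bin on a 1 count/bin background
cfg = pcwa.beads_preset(seed=42, duration=10.0)
trace, truth = pcwa.simulate_trace(cfg)
print(f"trace: {len(trace):,} bins of {cfg.dt*1e6:.0f} µs, {len(truth)} true events")

# scales bracket the burst widths (~0.1 ms); threshold in robust noise units
grid = pcwa.make_log_grid(4e-5, 1e-3, 30)
config = pcwa.DetectorConfig(threshold=8.0, threshold_mode="mad")
events = pcwa.detect(trace, pcwa.ricker_spec(), grid, config)

# temporal burst width of each event: spot size / particle velocity
widths = cfg.spot_sigma_um / truth.velocity_true * 1e-3  # seconds
result = pcwa.match_events(events, truth, tolerance=3 * widths)
print(f"detected {len(events)} events: {result.tp} matched, "
      f"{result.fp} false, {result.fn} missed (TPR {result.tpr:.3f})")

errors_bins = [abs(dt) / trace.dt for _, _, dt in result.pairs]
print(f"median timing error: {np.median(errors_bins):.2f} bins")
# The detected scale tracks the burst width: for a Gaussian burst of width
# sigma the Ricker response peaks at scale sqrt(5)*sigma.
w = np.array([widths[j] for _, j, _ in result.pairs])
scales = np.array([events[i].scale for i, _, _ in result.pairs])
print(f"median detected-scale / sqrt(5)·width ratio: "
      f"{np.median(scales / (np.sqrt(5) * w)):.2f} (≈1 expected)")
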