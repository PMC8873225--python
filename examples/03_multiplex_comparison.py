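"""Multiplexed peak-number detection: matched wavelets vs shift-multiply.

Simulates a multi-spot (7-peak) single-molecule trace near the detection
limit and compares three detectors over their threshold scans, mirroring
a multiplexed assay in which particles are identified by their peak count
(candidates 6, 7, 8):

* shift-multiply: the product of N time-shifted copies of the raw counts;
* cluster-CWT with Morlet wavelets (single-band, weakly N-selective);
* cluster-CWT with MSG wavelets (matched to the full peak pattern).

Each method reports the threshold that best trades classification
accuracy against detection rate, at a ≥95% precision operating floor.

Takes a few minutes (one 60-second trace at 10 µs binning, three
detectors, threshold scans).
"""

from pcwa.evaluate import kpc_method_comparison

table = kpc_method_comparison(seed=42, duration=60.0)
print(f"{table.attrs['n_truth']} true 7-peak events in "
      f"{table.attrs['duration']:.0f} s\n")
print(table.round(3))
msg = table.loc["pcwa-msg"]
sm = table.loc["shift-multiply"]
print(f"\nMSG detects {msg.detected_true / max(sm.detected_true, 1):.1f}x more true "
      f"events than shift-multiply;")
print(f"error-rate ratio (shift-multiply : MSG) = "
      f"{sm.error_rate / max(msg.error_rate, 1e-9):.1f}")
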