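# pcwa — parallel cluster wavelet analysis for single-molecule sensor traces

Single-particle sensors — optofluidic fluorescence chips, nanopores,
mass spectrometers — produce long 1D signals in which rare, short events
must be found and identified against shot noise, often in real time.
`pcwa` implements a fast, cluster-based continuous-wavelet-transform
(CWT) event detector for such signals, together with a custom matched
wavelet for multi-peak signals produced by multi-spot excitation
patterns, reference detectors to compare against, a ground-truthed
simulator, and an evaluation harness.

## The method

The trace f(t) is correlated with scaled copies of a zero-mean mother
wavelet ψ,

    C(t, Δt) = ∫ f(t') (1/√Δt) ψ*((t−t')/Δt) dt',

giving a 2D map of similarity coefficients over time and scale. Instead
of following ridges through the map (the conventional, serial approach),
`pcwa` thresholds per-scale local maxima, groups them into *macro
clusters* separated by time gaps, and resolves each cluster independently
into *micro clusters*: star graphs of maxima linked to the
largest-coefficient centroid by a scale-dependent ellipse-overlap rule

    OL(i,0) = sgn((r_i + r_0)² − d²(i,0)),
    r_i = w·h·N·Δt_i·√C'_i / √(w²N²sin²θ_i + h²cos²θ_i),

with C'_i the min–max-normalised coefficient. One micro cluster = one
event, located at its centroid (t, Δt). Macro clusters are independent,
so the work parallelises trivially and runs in O(N) for N trace samples;
events carry their scale Δt, which for multi-spot signals equals the
peak spacing and converts directly to particle velocity v = pitch/Δt.

For particles crossing an N-spot excitation pattern, the package provides
the Multi-Spot Gaussian (MSG) wavelet — N Gaussians spaced one scale unit
apart, flanked by two negative skew-Gaussian lobes that enforce the
zero-mean admissibility condition — and a multiplexed classifier that
decides the peak count N by competing MSG wavelets. Baselines included:
amplitude-threshold counting, the shift-multiply product detector for
periodic peak trains, and a classic top-down ridge-line follower.

See `docs/methods.md` for the full model, parameter defaults, and design
decisions.

## A worked example

```python
import numpy as np
import pcwa

# 10 s of sparse fluorescence bursts on a Poisson background, 10 µs bins
cfg = pcwa.beads_preset(seed=42, duration=10.0)
trace, truth = pcwa.simulate_trace(cfg)

grid = pcwa.make_log_grid(4e-5, 1e-3, 30)           # scales: 40 µs – 1 ms
config = pcwa.DetectorConfig(threshold=8.0, threshold_mode="mad")
events = pcwa.detect(trace, pcwa.ricker_spec(), grid, config)

widths = cfg.spot_sigma_um / truth.velocity_true * 1e-3
result = pcwa.match_events(events, truth, tolerance=3 * widths)
print(len(trace), len(truth), result.tp, result.fp, result.fn)
```

Running `examples/01_single_peak_detection.py` (this example plus a few
diagnostics) prints:

```
trace: 1,000,000 bins of 10 µs, 56 true events
detected 86 events: 56 matched, 30 false, 0 missed (TPR 1.000)
median timing error: 0.51 bins
median detected-scale / sqrt(5)·width ratio: 1.03 (≈1 expected)
```

All 56 simulated bursts are recovered with sub-bin median timing error;
the detected scale tracks the burst width through the Ricker matched
scale √5·σ (the remaining detections are threshold-level noise maxima —
raise the threshold to trade them against recall). The other scripts in
`examples/` demonstrate the MSG wavelet's structure and spectrum, the
multiplexed peak-number comparison against shift-multiply, and the ROC
benchmark against ridge-line picking.

A thin command line mirrors the library (`pcwa simulate|detect|classify|
baseline|evaluate|benchmark`); run `pcwa --help`.

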