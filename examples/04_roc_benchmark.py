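"""ROC comparison of cluster-CWT detection against ridge-line following.

Simulates 75 spectrum-like 1D signals (Gaussian peaks of varying width
and SNR on a drifting baseline), sweeps the detection threshold of each
method, and reports the standardised partial area under the ROC curve
(FPR ∈ [0, 0.1]). Runtime: a couple of minutes.
"""

import pcwa

dataset = [pcwa.simulate_spectrum(n_points=4000, n_peaks=12, seed=1000 + k)
           for k in range(75)]
grid = pcwa.make_log_grid(4.5, 60.0, 15)
spec = pcwa.ricker_spec()


def cluster_detect(trace, thr):
    cfg = pcwa.DetectorConfig(threshold=thr, threshold_mode="mad")
    return pcwa.detect(trace, spec, grid, cfg)


def ridge_detect(trace, thr):
    cmap = pcwa.compute_cwt(trace, spec, grid)
    return pcwa.ridge_line_detect(cmap, snr_threshold=thr, min_coeff=0.0)


thresholds = [1, 2, 3, 4, 6, 9, 14, 20]
tolerance = 15.0  # points; ~1 peak width
roc_cluster = pcwa.roc_curve(cluster_detect, dataset, thresholds, tolerance)
roc_ridge = pcwa.roc_curve(ridge_detect, dataset, thresholds, tolerance)

print("cluster-CWT curve:")
print(roc_cluster[["threshold", "tpr", "fpr"]].round(4).to_string(index=False))
print(f"\npartial AUC (FPR<=0.1): cluster {roc_cluster.attrs['auc']:.4f}  "
      f"ridge {roc_ridge.attrs['auc']:.4f}")
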