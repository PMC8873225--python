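"""Quantitative comparison surface: matching, ROC, method tables, scaling.

Detections are matched to ground truth greedily, nearest-in-time first,
one-to-one within a tolerance; false-positive rates are normalised per
decision window (trace length divided by the median event footprint),
since a continuous trace offers no natural trial count.

:func:`comparison_table` drives the multiplexed-method comparison: each
method detects events with candidate peak numbers (e.g. {6,7,8}), scanning
a series of thresholds, and reports the detection count / rate and the
peak-number accuracy at the threshold that maximises their product — the
"optimal compromise" pick, alongside the full scan so users can re-pick.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .baselines import ShiftMultiplyConfig, shift_multiply_product
from .cwt import ScaleGrid, Trace, iter_cwt_rows, make_log_grid
from .detector import DetectorConfig, Event, _maxima_arrays, _row_maxima_indices, detect_from_maxima
from .errors import InvalidParameterError
from .simulate import GroundTruth
from .wavelets import WaveletSpec

__all__ = [
    "MatchResult",
    "match_events",
    "roc_curve",
    "comparison_table",
    "scaling_benchmark",
    "MultiplexPCWA",
    "MultiplexShiftMultiply",
]


@dataclass(frozen=True)
class MatchResult:
    """Outcome of one-to-one detection↔truth matching."""

    tp: int
    fp: int
    fn: int
    pairs: tuple[tuple[int, int, float], ...]  # (detected idx, truth idx, time error)
    tolerance: float | np.ndarray

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")


def _event_times(detected) -> np.ndarray:
    if len(detected) and isinstance(detected[0], Event):
        return np.array([e.t for e in detected], dtype=float)
    return np.asarray(detected, dtype=float)


def match_events(detected, truth, tolerance) -> MatchResult:
    """Greedy nearest-first one-to-one matching of detections to truth.

    ``truth`` may be a :class:`~pcwa.simulate.GroundTruth` or an array of
    times; ``tolerance`` is a scalar or a per-truth-event array (seconds).
    All candidate pairs within tolerance are sorted by absolute time error
    and accepted while both sides are unmatched.
    """
    det_t = _event_times(detected)
    truth_t = truth.t_true if isinstance(truth, GroundTruth) else np.asarray(truth, dtype=float)
    tol = np.broadcast_to(np.asarray(tolerance, dtype=float), truth_t.shape)
    if np.any(tol <= 0):
        raise InvalidParameterError("tolerance must be > 0")
    pairs = []
    if len(det_t) and len(truth_t):
        err = np.abs(det_t[:, None] - truth_t[None, :])
        cand = np.argwhere(err <= tol[None, :])
        order = np.argsort(err[cand[:, 0], cand[:, 1]], kind="stable")
        used_d = np.zeros(len(det_t), dtype=bool)
        used_t = np.zeros(len(truth_t), dtype=bool)
        for d, tr in cand[order]:
            if not used_d[d] and not used_t[tr]:
                used_d[d] = used_t[tr] = True
                pairs.append((int(d), int(tr), float(det_t[d] - truth_t[tr])))
    tp = len(pairs)
    return MatchResult(
        tp=tp,
        fp=len(det_t) - tp,
        fn=len(truth_t) - tp,
        pairs=tuple(pairs),
        tolerance=tolerance,
    )


def roc_curve(
    detector,
    dataset: list[tuple[Trace, GroundTruth]],
    thresholds,
    tolerance,
    footprint: float | None = None,
    fpr_cap: float = 0.1,
) -> pd.DataFrame:
    """ROC sweep of a configured detector closure over a labelled dataset.

    ``detector(trace, threshold)`` must return a list of events. Per
    threshold, TP/FP/FN are aggregated over all traces; ``fpr`` is false
    positives per decision window, with the window count defined as total
    trace length over ``footprint`` (default: 6× the median true event
    width, the resolvable decision resolution). The returned frame carries
    ``threshold``, ``tp``, ``fp``, ``fn``, ``tpr``, ``fpr`` and an ``auc``
    attribute: the standardised partial area under the curve over
    FPR ∈ [0, ``fpr_cap``] (trapezoid, divided by the cap). Sparse-event
    detectors operate at small false-positive rates, so the capped area
    is the discriminating summary; the full-range area saturates for any
    sane detector.
    """
    if not dataset:
        raise InvalidParameterError("dataset must contain at least one trace")
    if sum(len(truth) for _, truth in dataset) == 0:
        raise InvalidParameterError("ROC needs at least one true event")
    if footprint is None:
        widths = np.concatenate([truth.dt_true * truth.n_true for _, truth in dataset])
        footprint = 6.0 * float(np.median(widths))
    n_windows = sum(len(tr) * tr.dt for tr, _ in dataset) / footprint
    rows = []
    for thr in thresholds:
        tp = fp = fn = 0
        for trace, truth in dataset:
            res = match_events(detector(trace, thr), truth, tolerance)
            tp, fp, fn = tp + res.tp, fp + res.fp, fn + res.fn
        rows.append({"threshold": thr, "tp": tp, "fp": fp, "fn": fn})
    df = pd.DataFrame(rows)
    df["tpr"] = df.tp / (df.tp + df.fn)
    df["fpr"] = np.minimum(df.fp / n_windows, 1.0)
    curve = df.sort_values(["fpr", "tpr"]).reset_index(drop=True)
    fpr = np.r_[0.0, curve.fpr.values]
    tpr = np.r_[0.0, np.maximum.accumulate(curve.tpr.values)]
    # clip the curve to the cap, interpolating the last segment
    grid_f = np.unique(np.clip(np.r_[fpr, fpr_cap], 0.0, fpr_cap))
    grid_t = np.interp(grid_f, fpr, tpr) if fpr[-1] >= fpr_cap else np.interp(
        grid_f, np.r_[fpr, fpr_cap], np.r_[tpr, tpr[-1]]
    )
    df.attrs["auc"] = float(np.trapezoid(grid_t, grid_f) / fpr_cap)
    return df


class MultiplexPCWA:
    """Cluster-CWT detection with competing per-N wavelets (multiplex mode).

    One detection pass per candidate peak number; events from all passes
    are merged greedily by descending coefficient, suppressing any event
    within half the winner's footprint of an already kept one, so each
    particle transit yields a single event labelled with the wavelet that
    matched it best.

    Per-scale maxima are extracted once (at ``threshold_floor``) when the
    object is bound to a trace, making repeated threshold scans cheap.
    """

    def __init__(
        self,
        wavelets: dict[int, WaveletSpec],
        grid: ScaleGrid,
        cfg: DetectorConfig,
        threshold_floor: float = 0.0,
        refine_counts: bool | None = None,
    ):
        self.wavelets = dict(sorted(wavelets.items()))
        self.grid = grid
        self.cfg = cfg
        self.threshold_floor = threshold_floor
        # outer-peak evidence refinement belongs to the matched multi-peak
        # (MSG) pipeline; a plain band-pass multiplexer classifies by
        # coefficient alone
        if refine_counts is None:
            refine_counts = all(w.family == "msg" for w in self.wavelets.values())
        self.refine_counts = refine_counts
        self._maxima: dict[int, dict[str, np.ndarray]] | None = None
        self._trace_id: int | None = None

    def bind(self, trace: Trace) -> "MultiplexPCWA":
        """Precompute per-N maxima arrays for a trace (caches CWT work)."""
        floor_cfg = replace(self.cfg, threshold=self.threshold_floor)
        self._maxima = {
            n: _maxima_arrays(
                iter_cwt_rows(trace, spec, self.grid), self.grid, trace.dt, trace.t0, floor_cfg
            )
            for n, spec in self.wavelets.items()
        }
        self._trace = trace
        self._trace_id = id(trace)
        return self

    def detect(self, trace: Trace, threshold: float) -> list[Event]:
        if self._maxima is None or self._trace_id != id(trace):
            self.bind(trace)
        cfg = replace(self.cfg, threshold=threshold)
        merged: list[Event] = []
        for n, arrays in self._maxima.items():
            merged.extend(detect_from_maxima(arrays, cfg, self.grid, n_peaks=n))
        merged.sort(key=lambda e: -e.coeff)
        kept: list[Event] = []
        for ev in merged:
            radius = 0.5 * ev.n_peaks * ev.scale
            if all(abs(ev.t - k.t) > max(radius, 0.5 * k.n_peaks * k.scale) for k in kept):
                kept.append(ev)
        kept = [self._classify(ev) for ev in kept]
        kept.sort(key=lambda e: e.t)
        return kept

    def _classify(self, ev: Event) -> Event:
        """Re-assign the peak count by comparing candidates at one point.

        Every candidate wavelet is evaluated at the detected event's own
        (t*, Δt*): the peak spacing is a property of the signal, shared by
        all candidates, and at a common cell the background noise of the
        competing coefficients is strongly correlated, so it largely
        cancels out of the comparison. Letting each candidate keep its
        free maximum over the event footprint instead hands the decision
        to whichever wavelet caught the largest noise excursion (a
        winner's-curse bias that dominates errors for dim events).
        """
        trace = self._trace
        t_idx = int(round((ev.t - trace.t0) / trace.dt))
        # ±0.75 spacings covers the half-spacing displacement degeneracy:
        # an (N±1)-candidate matched to N peaks sits Δt/2 off the true centre
        jitter = max(int(round(0.75 * ev.scale / trace.dt)), 1)
        # two degeneracy families confuse the raw detection: the same-spacing
        # family (N±1 peaks at the detected Δt, displaced half a spacing) and
        # the span-matched family (N' peaks at spacing span/(N'−1), covering
        # the same footprint). Each candidate is therefore scored at both its
        # same-spacing and its span-preserving scale.
        span = max(ev.n_peaks - 1, 1) * ev.scale
        best_n, best_c, best_t, best_s = ev.n_peaks, -np.inf, t_idx, ev.scale
        coeffs: dict[int, float] = {}
        for n in sorted(self.wavelets):
            c_n, t_n, s_n = -np.inf, t_idx, ev.scale
            for s in {ev.scale, span / max(n - 1, 1)}:
                try:
                    w = self.wavelets[n].sample(s, trace.dt)
                except Exception:
                    continue
                half = len(w.values) // 2
                lo, hi = t_idx - half - jitter, t_idx + half + jitter + 1
                if lo < 0 or hi > len(trace):
                    continue
                resp = np.correlate(trace.counts[lo:hi], w.values[::-1], mode="valid")
                k = int(np.argmax(resp))
                c = float(resp[k] * trace.dt)
                if c > c_n:
                    c_n, t_n, s_n = c, lo + k + half, s
            if not np.isfinite(c_n):
                continue
            coeffs[n] = c_n
            if c_n > best_c:
                best_n, best_c, best_t, best_s = n, c_n, t_n, s_n
        # the argmax rule is kept when it is decisive; within the structural
        # ambiguity band (the runner-up within `ambiguity_margin` of the
        # winner) the count is settled by direct outer-peak evidence
        runner_up = max((c for n, c in coeffs.items() if n != best_n), default=-np.inf)
        if self.refine_counts and runner_up > (1.0 - self.ambiguity_margin) * best_c:
            best_n = self._refine_peak_count(best_n, best_t, best_s, coeffs)
        return replace(ev, n_peaks=best_n)

    # per-peak evidence threshold of the count refinement, in units of the
    # local background noise of the single-peak matched filter
    peak_z_threshold: float = 2.2
    # annexing an extra peak asserts a new feature, so it demands stronger
    # evidence than keeping a known one (cf. the added-parameter penalty in
    # model selection); it also guards against the chirped outer-peak tail
    # leaking into the extension probe
    peak_z_extend_threshold: float = 3.2
    # relative amplitude-consistency: peaks of one train share a common
    # brightness, so an outer peak far below the train's median evidence is
    # a phantom (the displaced-match degeneracy leaves its extra peak on
    # background) regardless of how bright the event is; and an annexed
    # peak must carry a sensible fraction of the train's typical evidence
    peak_rel_drop: float = 0.25
    peak_rel_extend: float = 0.3
    # fractional coefficient margin below which the argmax over candidate
    # wavelets is considered ambiguous (the structural N vs N±1 penalty is
    # ~1−sqrt(N/(N+1)) ≈ 7%, and a displaced degenerate match can sit much
    # further below the winner) and outer-peak evidence decides instead
    ambiguity_margin: float = 0.3

    def _peak_z(
        self, center: float, scale: float, bg: float, wiggle_frac: float = 0.2
    ) -> float:
        """Significance of a single peak at a bin position (matched filter).

        ``wiggle_frac`` bounds the positional jitter (in spacings) the
        probe may search. Tests of *known* peak positions tolerate 0.2;
        tests of *hypothesised* extension positions must stay near 0.05,
        otherwise the probe slides toward the train and reads the
        adjacent real peak's tail as evidence.
        """
        trace = self._trace
        sp = next(iter(self.wavelets.values()))
        sigma_plus = sp.msg_params.sigma_plus if sp.msg_params is not None else 0.18
        s_bins = sigma_plus * scale / trace.dt
        half = max(int(round(3 * s_bins)), 2)
        x = np.arange(-half, half + 1)
        g = np.exp(-0.5 * (x / s_bins) ** 2)
        g -= g.mean()  # zero mean: local background cancels
        sigma = np.sqrt(max(bg, 1e-12) * np.sum(g * g))
        wiggle = max(int(round(wiggle_frac * scale / trace.dt)), 1)
        lo = int(round(center)) - half - wiggle
        hi = int(round(center)) + half + wiggle + 1
        if lo < 0 or hi > len(trace):
            return float("nan")  # cannot assess: neither drop nor annex
        resp = np.correlate(trace.counts[lo:hi], g, mode="valid")
        return float(resp.max() / sigma)

    def _refine_peak_count(
        self, n0: int, t_idx: int, scale: float, coeffs: dict[int, float] | None = None
    ) -> int:
        """Greedy peak-count adjustment by outer-peak evidence.

        The argmax-coefficient rule is ambiguous between N and N±1 near
        the detection limit (a half-spacing shift matches N peaks of an
        (N+1)-peak wavelet at only a ~1−sqrt(N/(N+1)) coefficient
        penalty), so the count is refined by direct evidence: drop an
        outermost peak that is not significant against the local
        background, annex an adjacent position that is, within the
        candidate set.
        """
        trace = self._trace
        candidates = sorted(self.wavelets)
        s_bins = scale / trace.dt
        # Poisson background rate: the sample mean over a wide neighbourhood
        # (the event itself occupies a few % of it); a median would floor to
        # zero at sub-1 rates. Lower-bounded away from zero for the z scale.
        span = int(round(10 * n0 * s_bins))
        seg = trace.counts[max(t_idx - span, 0): t_idx + span]
        bg = max(float(seg.mean()), 1.0 / max(len(seg), 1))
        kappa = self.peak_z_threshold

        def key(p: float) -> int:
            return int(round(p / s_bins))

        def coeff_consistent(n_from: int, n_to: int) -> bool:
            """Does moving from n_from to n_to peaks keep the coefficient?

            Removing a *real* peak from an N-train costs at least a factor
            sqrt((N−1)/N) of the matched coefficient; removing a *phantom*
            (or adding a real peak) costs nothing. A candidate move whose
            target coefficient falls below that structural bound would
            sacrifice genuine signal and is vetoed.
            """
            if coeffs is None or n_from not in coeffs or n_to not in coeffs:
                return True
            bound = np.sqrt(min(n_from, n_to) / max(n_from, n_to))
            return coeffs[n_to] >= bound * coeffs[n_from]

        dropped: set[int] = set()
        annexed: set[int] = set()
        n, center = n0, float(t_idx)
        for _ in range(2 * len(candidates)):
            positions = center + (np.arange(n) - (n - 1) / 2.0) * s_bins
            # the drop probe's jitter is kept below the half-spacing
            # displacement so a phantom position cannot read the adjacent
            # real peak's flank as evidence of a peak
            z_all = np.array(
                [self._peak_z(p, scale, bg, wiggle_frac=0.1) for p in positions]
            )
            z_left, z_right = z_all[0], z_all[-1]
            median_z = float(np.nanmedian(z_all))
            drop_floor = max(kappa, self.peak_rel_drop * median_z)
            # drop the weaker outer peak if insignificant, absolutely or
            # relative to its siblings — but never one annexed earlier in
            # this refinement (prevents oscillation), and never when the
            # (n−1)-candidate's own coefficient shows the peak was real
            sides = sorted(
                [(z_left, positions[0], +0.5), (z_right, positions[-1], -0.5)]
            )
            z_w, p_w, shift_w = sides[0]
            if (
                z_w < drop_floor
                and n - 1 in self.wavelets
                and key(p_w) not in annexed
                and coeff_consistent(n, n - 1)
            ):
                dropped.add(key(p_w))
                center += shift_w * s_bins
                n -= 1
                continue
            # annex an adjacent position with significant evidence; the
            # probe's jitter is kept tight so the neighbouring real peak's
            # tail cannot masquerade as an extra peak
            exts = sorted(
                [
                    (self._peak_z(positions[0] - s_bins, scale, bg, wiggle_frac=0.05),
                     positions[0] - s_bins, -0.5),
                    (self._peak_z(positions[-1] + s_bins, scale, bg, wiggle_frac=0.05),
                     positions[-1] + s_bins, +0.5),
                ],
                reverse=True,
            )
            z_e, p_e, shift_e = exts[0]
            extend_floor = max(
                self.peak_z_extend_threshold, self.peak_rel_extend * median_z
            )
            if (
                z_e >= extend_floor
                and n + 1 in self.wavelets
                and key(p_e) not in dropped
                and coeff_consistent(n, n + 1)
            ):
                annexed.add(key(p_e))
                center += shift_e * s_bins
                n += 1
                continue
            break
        return n

    __call__ = detect


class MultiplexShiftMultiply:
    """Shift-multiply detection over competing peak numbers.

    The per-N best-product curves are computed once per trace; per
    threshold, product maxima from all N are merged by descending product
    with the same footprint suppression as the wavelet multiplexer.
    """

    def __init__(self, candidate_ns, dt_min: float, dt_max: float, dt_steps: int = 30):
        self.candidate_ns = sorted(candidate_ns)
        self.dt_min, self.dt_max, self.dt_steps = dt_min, dt_max, dt_steps
        self._curves: dict[int, tuple[np.ndarray, np.ndarray]] | None = None
        self._trace_id: int | None = None

    def bind(self, trace: Trace) -> "MultiplexShiftMultiply":
        self._curves = {}
        for n in self.candidate_ns:
            cfg = ShiftMultiplyConfig(
                n_peaks=n, dt_min=self.dt_min, dt_max=self.dt_max, dt_steps=self.dt_steps
            )
            self._curves[n] = shift_multiply_product(trace, cfg)
        self._trace_id = id(trace)
        self._dt = trace.dt
        self._t0 = trace.t0
        return self

    def detect(self, trace: Trace, threshold: float) -> list[Event]:
        if self._curves is None or self._trace_id != id(trace):
            self.bind(trace)
        merged: list[Event] = []
        for n, (best, best_dt) in self._curves.items():
            idx = _row_maxima_indices(best)
            idx = idx[best[idx] > threshold]
            for i in idx:
                d = float(best_dt[i])
                t = self._t0 + i * self._dt + (n - 1) * d / 2.0
                merged.append(
                    Event(t=t, scale=d, coeff=float(best[i]), n_members=1,
                          t_adjusted=t, n_peaks=n)
                )
        merged.sort(key=lambda e: -e.coeff)
        kept: list[Event] = []
        for ev in merged:
            radius = 0.5 * ev.n_peaks * ev.scale
            if all(abs(ev.t - k.t) > max(radius, 0.5 * k.n_peaks * k.scale) for k in kept):
                kept.append(ev)
        kept.sort(key=lambda e: e.t)
        return kept

    __call__ = detect


@dataclass
class MethodComparison:
    """Per-method result of the threshold-scan comparison."""

    name: str
    threshold: float
    detected_true: int
    detection_rate: float  # matched true events per second
    accuracy: float  # % of matched true events with the correct peak number
    scan: pd.DataFrame = field(repr=False, default=None)

    @property
    def error_rate(self) -> float:
        """% of matched true events assigned a wrong peak number."""
        return 100.0 - self.accuracy


#: minimum precision (matched / all detections) for a threshold to qualify
#: as an operating point in the compromise pick — a counting assay runs
#: essentially false-positive-free, so thresholds that admit a substantial
#: noise-detection fraction are not usable operating points for any method
PRECISION_FLOOR = 0.95


def _evaluate_method(
    name: str,
    detector,
    trace: Trace,
    truth: GroundTruth,
    thresholds,
    precision_floor: float = PRECISION_FLOOR,
) -> MethodComparison:
    tol = 0.5 * truth.n_true * truth.dt_true
    rows = []
    for thr in thresholds:
        events = detector(trace, thr)
        res = match_events(events, truth, tol)
        if res.tp:
            correct = sum(
                1 for d, tr, _ in res.pairs if events[d].n_peaks == truth.n_true[tr]
            )
            acc = 100.0 * correct / res.tp
        else:
            acc = 0.0
        rows.append(
            {
                "threshold": thr,
                "detected_true": res.tp,
                "false_positives": res.fp,
                "precision": res.tp / max(res.tp + res.fp, 1),
                "detection_rate": res.tp / trace.duration,
                "accuracy": acc,
            }
        )
    scan = pd.DataFrame(rows)
    # optimal compromise: among thresholds whose precision clears the
    # operating floor, maximise accuracy × detection rate; if no threshold
    # qualifies, fall back to the most precise one
    ok = scan.precision >= precision_floor
    pool = scan[ok] if ok.any() else scan[scan.precision == scan.precision.max()]
    best = int((pool.accuracy * pool.detection_rate).idxmax())
    row = scan.loc[best]
    return MethodComparison(
        name=name,
        threshold=float(row.threshold),
        detected_true=int(row.detected_true),
        detection_rate=float(row.detection_rate),
        accuracy=float(row.accuracy),
        scan=scan,
    )


def comparison_table(
    trace: Trace,
    truth: GroundTruth,
    methods: dict[str, tuple],
) -> pd.DataFrame:
    """Threshold-scanned comparison of multiplexed detectors on one dataset.

    ``methods`` maps a name to ``(detector, thresholds)`` where
    ``detector(trace, threshold)`` returns events labelled with their
    assigned peak number. Returns a DataFrame (index = method) with the
    compromise threshold, matched-true-event count, detection rate
    (events/s), accuracy (%) and error rate (%); per-method full scans
    are attached under ``attrs["scans"]``.
    """
    results = [
        _evaluate_method(name, det, trace, truth, thresholds)
        for name, (det, thresholds) in methods.items()
    ]
    df = pd.DataFrame(
        {
            "threshold": [r.threshold for r in results],
            "detected_true": [r.detected_true for r in results],
            "detection_rate": [r.detection_rate for r in results],
            "accuracy": [r.accuracy for r in results],
            "error_rate": [r.error_rate for r in results],
        },
        index=[r.name for r in results],
    )
    df.attrs["scans"] = {r.name: r.scan for r in results}
    return df


#: threshold scans used by the packaged multi-spot comparison
KPC_WAVELET_THRESHOLDS = (0.004, 0.006, 0.009, 0.013, 0.018, 0.027, 0.04)
KPC_SHIFTMUL_THRESHOLDS = (12.0, 30.0, 80.0, 200.0, 500.0, 1200.0)


def kpc_method_comparison(
    seed: int = 1,
    duration: float = 60.0,
    candidate_ns=(6, 7, 8),
    n_scales: int = 25,
    **preset_overrides,
) -> pd.DataFrame:
    """Shift-multiply vs Morlet-CWT vs MSG-CWT on the multi-spot preset.

    Generates one KPC-emulation trace, runs the three multiplexed
    detectors over their threshold scans, and returns the
    :func:`comparison_table`. The scale / Δt scan range is derived from
    the preset's velocity band (pitch / v), padded by 10%.
    """
    from .simulate import kpc_preset, simulate_trace
    from .wavelets import morlet_spec, msg_spec

    cfg = kpc_preset(seed=seed, duration=duration, **preset_overrides)
    trace, truth = simulate_trace(cfg)
    v_hi = 2.0 * cfg.velocity_mean
    v_lo = cfg.velocity_min_frac * v_hi
    s_min = cfg.spot_pitch_um / v_hi * 1e-3 * 0.9
    s_max = cfg.spot_pitch_um / v_lo * 1e-3 * 1.1
    grid = make_log_grid(s_min, s_max, n_scales)
    floor = min(KPC_WAVELET_THRESHOLDS)
    det_cfg = DetectorConfig(threshold=floor)

    msg_wavelets = {n: msg_spec(n) for n in candidate_ns}
    morlet_wavelets = {n: morlet_spec(center_cycles=float(n)) for n in candidate_ns}
    methods = {
        "shift-multiply": (
            MultiplexShiftMultiply(candidate_ns, s_min, s_max, dt_steps=40),
            KPC_SHIFTMUL_THRESHOLDS,
        ),
        "pcwa-morlet": (
            MultiplexPCWA(morlet_wavelets, grid, det_cfg, threshold_floor=floor),
            KPC_WAVELET_THRESHOLDS,
        ),
        "pcwa-msg": (
            MultiplexPCWA(msg_wavelets, grid, det_cfg, threshold_floor=floor),
            KPC_WAVELET_THRESHOLDS,
        ),
    }
    table = comparison_table(trace, truth, methods)
    table.attrs["n_truth"] = len(truth)
    table.attrs["duration"] = trace.duration
    return table


def scaling_benchmark(
    detector,
    trace_factory,
    lengths,
    reps: int = 3,
) -> pd.DataFrame:
    """Median runtime of ``detector(trace)`` vs trace length, with log-log slope.

    ``trace_factory(n)`` builds the input of length ``n``. The returned
    frame has columns ``length`` and ``median_s``; the least-squares slope
    of log(time) against log(length) is in ``attrs["slope"]``.
    """
    lengths = list(lengths)
    if len(lengths) < 2:
        raise InvalidParameterError("need at least two trace lengths")
    rows = []
    for n in lengths:
        trace = trace_factory(int(n))
        times = []
        for _ in range(reps):
            start = time.perf_counter()
            detector(trace)
            times.append(time.perf_counter() - start)
        rows.append({"length": int(n), "median_s": float(np.median(times))})
    df = pd.DataFrame(rows)
    slope = np.polyfit(np.log(df.length), np.log(df.median_s), 1)[0]
    df.attrs["slope"] = float(slope)
    return df
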