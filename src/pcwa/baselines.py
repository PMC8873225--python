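"""Reference detectors the cluster method is compared against.

* amplitude-threshold counting: one event per contiguous above-threshold
  run of the raw trace;
* shift-multiply: multiply N−1 time-shifted copies of the trace so only
  correctly spaced N-peak trains survive — the classic matched detector
  for spatially modulated excitation signals;
* ridge-line following: the conventional CWT peak picker that links
  per-scale maxima into ridges from the largest scale downward.

The ridge follower is deliberately the direct, serial transcription of the
classic method (per-ridge linear scan over each row's maxima): it is the
runtime and accuracy baseline, not an optimised reimplementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cwt import CWTMap, Trace
from .detector import Event, _row_maxima_indices
from .errors import InvalidParameterError, ResolutionError

__all__ = [
    "ShiftMultiplyConfig",
    "amplitude_threshold_detect",
    "shift_multiply_detect",
    "ridge_line_detect",
]


def amplitude_threshold_detect(trace: Trace, threshold: float) -> list[Event]:
    """Count one event per contiguous above-threshold run of the raw trace.

    The event time is the run's maximum sample; the event scale is the run
    duration (a crude width proxy).
    """
    above = trace.counts > threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(above)]
    events = []
    for lo, hi in zip(starts, ends):
        k = lo + int(np.argmax(trace.counts[lo:hi]))
        t = trace.t0 + k * trace.dt
        events.append(
            Event(
                t=t,
                scale=(hi - lo) * trace.dt,
                coeff=float(trace.counts[k]),
                n_members=1,
                t_adjusted=t,
                n_peaks=1,
            )
        )
    return events


@dataclass(frozen=True)
class ShiftMultiplyConfig:
    """Scan configuration for the shift-multiply detector."""

    n_peaks: int
    dt_min: float
    dt_max: float
    dt_steps: int = 30
    threshold: float = 0.0

    def __post_init__(self):
        if self.n_peaks < 2:
            raise InvalidParameterError("shift-multiply needs n_peaks >= 2")
        if not (0 < self.dt_min < self.dt_max):
            raise InvalidParameterError("need 0 < dt_min < dt_max")
        if self.dt_steps < 1:
            raise InvalidParameterError("dt_steps must be >= 1")


def shift_multiply_product(
    trace: Trace, cfg: ShiftMultiplyConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Best product over the Δt scan and its argmax Δt, per trace bin.

    ``P_Δt(t) = Π_{n=0}^{N−1} f(t + n·Δt)`` with shifts rounded to whole
    bins; returns ``(best_product, best_dt)`` arrays aligned to the train
    start bin (zero beyond the valid region).
    """
    n = len(trace)
    shifts = np.unique(np.round(np.linspace(cfg.dt_min, cfg.dt_max, cfg.dt_steps) / trace.dt).astype(int))
    shifts = shifts[shifts >= 1]
    if len(shifts) == 0:
        raise ResolutionError("Δt scan range is below one bin at this sampling")
    if n <= (cfg.n_peaks - 1) * shifts.max():
        raise InvalidParameterError("trace shorter than (N−1)·dt_max")
    best = np.zeros(n)
    best_dt = np.zeros(n)
    f = trace.counts
    for k in shifts:
        valid = n - (cfg.n_peaks - 1) * k
        prod = f[:valid].copy()
        for m in range(1, cfg.n_peaks):
            prod *= f[m * k : m * k + valid]
        improved = prod > best[:valid]
        best[:valid][improved] = prod[improved]
        best_dt[:valid][improved] = k * trace.dt
    return best, best_dt


def shift_multiply_detect(trace: Trace, cfg: ShiftMultiplyConfig) -> list[Event]:
    """Detect N-peak trains as local maxima of the best shift-multiply product.

    Events carry the centre time of the train (start + (N−1)Δt/2), the
    argmax Δt as scale, and the product as coefficient.
    """
    best, best_dt = shift_multiply_product(trace, cfg)
    idx = _row_maxima_indices(best)
    idx = idx[best[idx] > cfg.threshold]
    events = []
    for i in idx:
        dt_i = best_dt[i]
        t = trace.t0 + i * trace.dt + (cfg.n_peaks - 1) * dt_i / 2.0
        events.append(
            Event(
                t=float(t),
                scale=float(dt_i),
                coeff=float(best[i]),
                n_members=1,
                t_adjusted=float(t),
                n_peaks=cfg.n_peaks,
            )
        )
    return events


def ridge_line_detect(
    cmap: CWTMap,
    ridge_gap: int = 3,
    min_ridge_length: int = 3,
    snr_threshold: float = 2.0,
    max_skip: int = 2,
    min_coeff: float | None = None,
) -> list[Event]:
    """Classic top-down ridge following over a CWT map.

    Starting from the largest scale, each row's maxima either extend an
    active ridge (nearest maximum within ``ridge_gap`` bins, found by a
    per-ridge linear scan) or seed a new one; ridges missing more than
    ``max_skip`` consecutive rows are closed. Closed ridges are kept if
    they span at least ``min_ridge_length`` scales and their peak
    coefficient exceeds ``snr_threshold`` robust noise units (1.4826×MAD
    of the peak's scale row); the event sits at the ridge's
    maximum-coefficient point.
    """
    n_scales, n_times = cmap.coeffs.shape
    row_sigma = np.empty(n_scales)
    for i in range(n_scales):
        row = cmap.coeffs[i]
        row_sigma[i] = 1.4826 * np.median(np.abs(row - np.median(row))) or 1e-300

    ridges: list[dict] = []  # active: {"last": t_idx, "skip": int, "pts": [(s,t,c)]}
    closed: list[list[tuple[int, int, float]]] = []
    for i in range(n_scales - 1, -1, -1):
        idx = _row_maxima_indices(cmap.coeffs[i])
        margin = int(cmap.margins[i])
        if margin > 0:
            idx = idx[(idx >= margin) & (idx < n_times - margin)]
        if min_coeff is not None:
            idx = idx[cmap.coeffs[i, idx] >= min_coeff]
        claimed = np.zeros(len(idx), dtype=bool)
        still_active: list[dict] = []
        for ridge in ridges:
            # deliberate linear scan per ridge (the serial classic method)
            best_j, best_d = -1, ridge_gap + 1
            for j in range(len(idx)):
                if claimed[j]:
                    continue
                d = abs(int(idx[j]) - ridge["last"])
                if d < best_d:
                    best_d, best_j = d, j
            if best_j >= 0 and best_d <= ridge_gap:
                claimed[best_j] = True
                tj = int(idx[best_j])
                ridge["last"] = tj
                ridge["skip"] = 0
                ridge["pts"].append((i, tj, float(cmap.coeffs[i, tj])))
                still_active.append(ridge)
            else:
                ridge["skip"] += 1
                if ridge["skip"] > max_skip:
                    closed.append(ridge["pts"])
                else:
                    still_active.append(ridge)
        for j in np.flatnonzero(~claimed):
            tj = int(idx[j])
            still_active.append(
                {"last": tj, "skip": 0, "pts": [(i, tj, float(cmap.coeffs[i, tj]))]}
            )
        ridges = still_active
    closed.extend(r["pts"] for r in ridges)

    events = []
    for pts in closed:
        if len(pts) < min_ridge_length:
            continue
        s_best, t_best, c_best = max(pts, key=lambda p: p[2])
        if c_best / row_sigma[s_best] < snr_threshold:
            continue
        events.append(
            Event(
                t=cmap.t0 + t_best * cmap.dt,
                scale=float(cmap.grid.scales[s_best]),
                coeff=c_best,
                n_members=len(pts),
                t_adjusted=cmap.t0 + t_best * cmap.dt,
                n_peaks=1,
            )
        )
    events.sort(key=lambda e: e.t)
    return events
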