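"""The PCWA core: cluster-based selection of CWT local maxima into events.

The detection pipeline is

1. per-scale local maxima of the CWT map above a threshold,
2. grouping of maxima into *macro clusters* separated by time gaps larger
   than a preset value,
3. per macro cluster, iterative extraction of *micro clusters*: the
   largest-coefficient maximum (centroid) collects every maximum whose
   scale-dependent ellipse overlaps it,

        OL(i,0) = sgn((r_i + r_0)^2 − d^2(i,0)),
        d^2(i,0) = (t_i − t_0)^2 + (Δt_i − Δt_0)^2,
        r_i = w h N Δt_i sqrt(C'_i) / sqrt(w^2 N^2 sin^2 θ_i + h^2 cos^2 θ_i),
        C'_i = (C_i − min C) / (max C − min C),

   with ``r_0`` analogous but without the coefficient weight. A micro
   cluster of at least ``min_cluster_size`` maxima is one detected event,
   located at its centroid; unlinked maxima form a new, smaller cluster
   and the step repeats.

Macro clusters are mutually independent, so the result is identical
whether clusters are resolved serially or concurrently; the implementation
is serial and vectorised within each cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from .cwt import CWTMap, ScaleGrid, Trace, iter_cwt_rows
from .errors import InvalidParameterError
from .wavelets import WaveletSpec

__all__ = [
    "LocalMaximum",
    "DetectorConfig",
    "Event",
    "MacroCluster",
    "find_local_maxima",
    "form_macro_clusters",
    "overlap_link",
    "resolve_micro_clusters",
    "detect",
]


@dataclass(frozen=True)
class LocalMaximum:
    """A per-scale local maximum of the CWT map."""

    t_index: int
    scale_index: int
    t: float
    scale: float
    coeff: float


@dataclass(frozen=True)
class Event:
    """A detected event: the centroid of one micro cluster."""

    t: float
    scale: float
    coeff: float
    n_members: int
    t_adjusted: float
    n_peaks: int = 1

    def __post_init__(self):
        if self.n_members < 1:
            raise InvalidParameterError("event must have at least one member")


@dataclass(frozen=True)
class MacroCluster:
    """Maxima grouped by time proximity; members sorted by t."""

    members: tuple[LocalMaximum, ...]

    @property
    def t_span(self) -> tuple[float, float]:
        return (self.members[0].t, self.members[-1].t)


@dataclass(frozen=True)
class DetectorConfig:
    """Tunable parameters of the cluster detector.

    Attributes
    ----------
    threshold : float
        Minimum coefficient for a local maximum. In ``"absolute"`` mode the
        raw coefficient is compared; in ``"mad"`` mode the effective per-row
        threshold is ``threshold × 1.4826 × MAD(row)`` (robust noise units).
    w, h : float
        Ellipse spreading parameters in time and scale. Along the time axis
        the linking radius is ``w·N·Δt`` (the event footprint times w);
        along the scale axis it is ``h·Δt``.
    gap : float or None
        Macro-cluster split gap in seconds; ``None`` → twice the largest
        scale of the grid (events farther apart than the widest wavelet
        cannot share maxima).
    min_cluster_size : int
        Minimum number of maxima for a micro cluster to count as an event.
    exclude_boundary : bool
        Drop maxima within one wavelet support of either trace end.
    symmetric_r0 : bool
        Use the centroid's own peak count in the ``r_0`` denominator
        instead of the candidate's (the printed form is asymmetric; with a
        single wavelet per pass the two coincide).
    """

    threshold: float
    w: float = 1.0
    h: float = 1.0
    gap: float | None = None
    min_cluster_size: int = 3
    exclude_boundary: bool = True
    threshold_mode: Literal["absolute", "mad"] = "absolute"
    symmetric_r0: bool = False

    def __post_init__(self):
        if not (self.w > 0 and self.h > 0):
            raise InvalidParameterError("w and h must be > 0")
        if self.gap is not None and not (self.gap > 0):
            raise InvalidParameterError("gap must be > 0")
        if self.min_cluster_size < 1:
            raise InvalidParameterError("min_cluster_size must be >= 1")
        if not np.isfinite(self.threshold):
            raise InvalidParameterError("threshold must be finite")


def _row_maxima_indices(values: np.ndarray) -> np.ndarray:
    """Indices of local maxima of a 1D array (plateaus: leftmost edge wins).

    A plateau counts as a maximum only if the signal rises into it and
    falls after it; runs touching the array ends are never maxima.
    """
    d = np.sign(np.diff(values))
    if len(d) == 0:
        return np.empty(0, dtype=int)
    # backward-fill zero slopes with the next nonzero slope to the right,
    # so a plateau adopts its outgoing direction
    rev = d[::-1]
    nz = np.where(rev != 0, np.arange(len(rev)), -1)
    np.maximum.accumulate(nz, out=nz)
    filled = np.where(nz >= 0, rev[np.clip(nz, 0, None)], 0.0)[::-1]
    up = filled[:-1] > 0
    down = filled[1:] < 0
    return np.where(up & down)[0] + 1


def _maxima_arrays(
    rows: Sequence[tuple[int, np.ndarray, int]],
    grid: ScaleGrid,
    dt: float,
    t0: float,
    cfg: DetectorConfig,
) -> dict[str, np.ndarray]:
    """Collect thresholded per-row maxima into flat arrays (internal)."""
    t_idx: list[np.ndarray] = []
    s_idx: list[np.ndarray] = []
    coeff: list[np.ndarray] = []
    for i, row, margin in rows:
        idx = _row_maxima_indices(row)
        if cfg.threshold_mode == "mad":
            mad = np.median(np.abs(row - np.median(row)))
            thr = cfg.threshold * 1.4826 * mad
        else:
            thr = cfg.threshold
        idx = idx[row[idx] >= thr]
        if cfg.exclude_boundary and margin > 0:
            idx = idx[(idx >= margin) & (idx < len(row) - margin)]
        t_idx.append(idx)
        s_idx.append(np.full(len(idx), i, dtype=int))
        coeff.append(row[idx])
    ti = np.concatenate(t_idx) if t_idx else np.empty(0, dtype=int)
    si = np.concatenate(s_idx) if s_idx else np.empty(0, dtype=int)
    ci = np.concatenate(coeff) if coeff else np.empty(0, dtype=float)
    return {
        "t_index": ti,
        "scale_index": si,
        "t": t0 + ti * dt,
        "scale": grid.scales[si] if len(si) else np.empty(0),
        "coeff": ci,
    }


def _to_local_maxima(arrays: dict[str, np.ndarray]) -> list[LocalMaximum]:
    return [
        LocalMaximum(int(ti), int(si), float(t), float(s), float(c))
        for ti, si, t, s, c in zip(
            arrays["t_index"], arrays["scale_index"], arrays["t"], arrays["scale"], arrays["coeff"]
        )
    ]


def find_local_maxima(
    cmap: CWTMap, threshold: float, cfg: DetectorConfig | None = None
) -> list[LocalMaximum]:
    """Per-scale local maxima of a CWT map above ``threshold``.

    Each maximum is strictly greater than its time neighbours in its scale
    row (the leftmost sample of a plateau wins, for determinism);
    boundary-margin bins are excluded when configured.
    """
    cfg = replace(cfg, threshold=threshold) if cfg else DetectorConfig(threshold=threshold)
    rows = ((i, cmap.coeffs[i], int(cmap.margins[i])) for i in range(len(cmap.grid)))
    return _to_local_maxima(_maxima_arrays(rows, cmap.grid, cmap.dt, cmap.t0, cfg))


def form_macro_clusters(
    maxima: Sequence[LocalMaximum], gap: float
) -> list[MacroCluster]:
    """Partition maxima by sorting on t and splitting at time gaps > ``gap``."""
    if not (gap > 0):
        raise InvalidParameterError("gap must be > 0")
    if not maxima:
        return []
    ordered = sorted(maxima, key=lambda m: (m.t, m.scale))
    clusters: list[MacroCluster] = []
    start = 0
    for j in range(1, len(ordered)):
        if ordered[j].t - ordered[j - 1].t > gap:
            clusters.append(MacroCluster(tuple(ordered[start:j])))
            start = j
    clusters.append(MacroCluster(tuple(ordered[start:])))
    return clusters


def _link_mask(
    t: np.ndarray,
    s: np.ndarray,
    c: np.ndarray,
    centroid: int,
    cfg: DetectorConfig,
    n_peaks: int,
) -> np.ndarray:
    """Boolean overlap-link mask of every maximum against the centroid."""
    cmin, cmax = float(c.min()), float(c.max())
    if cmax > cmin:
        c_norm = (c - cmin) / (cmax - cmin)
    else:  # degenerate single-valued cluster
        c_norm = np.ones_like(c)
    dt_ = t - t[centroid]
    ds_ = s - s[centroid]
    d2 = dt_ * dt_ + ds_ * ds_
    theta = np.arctan2(ds_, dt_)
    w, h, n = cfg.w, cfg.h, float(n_peaks)
    denom = np.sqrt((w * n * np.sin(theta)) ** 2 + (h * np.cos(theta)) ** 2)
    r_i = w * h * n * s * np.sqrt(c_norm) / denom
    # r_0 as printed shares the candidate's N and theta in its denominator;
    # with one wavelet per detection pass the symmetric_r0 variant coincides
    r_0 = w * h * n * s[centroid] / denom
    linked = (r_i + r_0) ** 2 >= d2
    linked[centroid] = True
    return linked


def overlap_link(
    i: LocalMaximum,
    centroid: LocalMaximum,
    cfg: DetectorConfig,
    c_minmax: tuple[float, float],
    n_peaks: int,
) -> bool:
    """Does maximum ``i``'s ellipse overlap the cluster centroid?

    ``c_minmax`` is the (min, max) coefficient over the current cluster,
    the normalisation context of the coefficient weight C'.
    """
    cmin, cmax = c_minmax
    if cmax > cmin:
        c_norm = (i.coeff - cmin) / (cmax - cmin)
    else:
        c_norm = 1.0
    dt_ = i.t - centroid.t
    ds_ = i.scale - centroid.scale
    d2 = dt_ * dt_ + ds_ * ds_
    theta = np.arctan2(ds_, dt_)
    w, h, n = cfg.w, cfg.h, float(n_peaks)
    denom = np.sqrt((w * n * np.sin(theta)) ** 2 + (h * np.cos(theta)) ** 2)
    r_i = w * h * n * i.scale * np.sqrt(c_norm) / denom
    r_0 = w * h * n * centroid.scale / denom
    return bool((r_i + r_0) ** 2 >= d2)


def _resolve_arrays(
    t: np.ndarray,
    s: np.ndarray,
    c: np.ndarray,
    cfg: DetectorConfig,
    n_peaks: int,
) -> list[Event]:
    """Iterative star-graph extraction on one macro cluster (vectorised)."""
    events: list[Event] = []
    while len(t) >= cfg.min_cluster_size:
        # centroid: largest coefficient, ties broken by smaller t
        best = np.flatnonzero(c == c.max())
        centroid = int(best[np.argmin(t[best])])
        linked = _link_mask(t, s, c, centroid, cfg, n_peaks)
        size = int(linked.sum())
        if size >= cfg.min_cluster_size:
            events.append(
                Event(
                    t=float(t[centroid]),
                    scale=float(s[centroid]),
                    coeff=float(c[centroid]),
                    n_members=size,
                    t_adjusted=float(t[centroid]),
                    n_peaks=n_peaks,
                )
            )
        keep = ~linked
        t, s, c = t[keep], s[keep], c[keep]
    events.sort(key=lambda e: e.t)
    return events


def resolve_micro_clusters(
    mc: MacroCluster, cfg: DetectorConfig, n_peaks: int = 1
) -> list[Event]:
    """Resolve one macro cluster into events via iterated centroid linking.

    Each iteration picks the largest-coefficient member as centroid, links
    members by ellipse overlap, emits an event when the star graph has at
    least ``min_cluster_size`` nodes, and recurses on the unlinked
    remainder; the loop terminates because every iteration removes at
    least the centroid.
    """
    if not mc.members:
        return []
    t = np.array([m.t for m in mc.members])
    s = np.array([m.scale for m in mc.members])
    c = np.array([m.coeff for m in mc.members])
    return _resolve_arrays(t, s, c, cfg, n_peaks)


def _adjust_event_times(events: list[Event], trace: Trace) -> list[Event]:
    """Refine each event time to the raw-trace maximum within ±scale/2."""
    out = []
    n = len(trace)
    for ev in events:
        half = max(int(round(0.5 * ev.scale / trace.dt)), 1)
        center = int(round((ev.t - trace.t0) / trace.dt))
        lo = max(center - half, 0)
        hi = min(center + half + 1, n)
        if hi > lo:
            k = lo + int(np.argmax(trace.counts[lo:hi]))
            out.append(replace(ev, t_adjusted=trace.t0 + k * trace.dt))
        else:
            out.append(ev)
    return out


def detect(
    trace: Trace, wavelet: WaveletSpec, grid: ScaleGrid, cfg: DetectorConfig
) -> list[Event]:
    """Full pipeline: CWT → per-scale maxima → macro clusters → events.

    CWT rows are streamed (the full map is never materialised), so memory
    stays O(trace length) regardless of the number of scales. The result
    is deterministic and independent of macro-cluster processing order.
    """
    arrays = _maxima_arrays(
        iter_cwt_rows(trace, wavelet, grid), grid, trace.dt, trace.t0, cfg
    )
    events = detect_from_maxima(arrays, cfg, grid, n_peaks=wavelet.n_peaks)
    return _adjust_event_times(events, trace)


def detect_from_maxima(
    arrays: dict[str, np.ndarray],
    cfg: DetectorConfig,
    grid: ScaleGrid,
    n_peaks: int = 1,
) -> list[Event]:
    """Cluster pre-extracted maxima arrays into events (internal fast path).

    Used by :func:`detect` and by threshold scans, which extract maxima
    once at the lowest threshold and re-cluster cheaply per threshold.
    """
    t, s, c = arrays["t"], arrays["scale"], arrays["coeff"]
    if cfg.threshold_mode == "absolute":
        keep = c >= cfg.threshold
        t, s, c = t[keep], s[keep], c[keep]
    gap = cfg.gap if cfg.gap is not None else 2.0 * float(grid.scales[-1])
    if len(t) == 0:
        return []
    order = np.lexsort((s, t))
    t, s, c = t[order], s[order], c[order]
    splits = np.flatnonzero(np.diff(t) > gap) + 1
    events: list[Event] = []
    for lo, hi in zip(np.r_[0, splits], np.r_[splits, len(t)]):
        events.extend(_resolve_arrays(t[lo:hi], s[lo:hi], c[lo:hi], cfg, n_peaks))
    events.sort(key=lambda e: e.t)
    return events
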