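"""Cluster-detector tests: maxima, macro/micro clustering, full pipeline."""

import math

import numpy as np
import pytest

from pcwa import (
    CWTMap,
    DetectorConfig,
    InvalidParameterError,
    LocalMaximum,
    MacroCluster,
    Trace,
    detect,
    find_local_maxima,
    form_macro_clusters,
    make_log_grid,
    overlap_link,
    resolve_micro_clusters,
    ricker_spec,
)
from tests.conftest import gaussian_trace


def brute_force_micro_clusters(members, cfg, n_peaks):
    """Literal, unoptimised transcription of the overlap rule + flowchart.

    Plain-python re-derivation used as the oracle for the vectorised
    implementation: repeatedly take the largest-coefficient point as
    centroid, link every other point whose ellipse overlaps it, emit the
    centroid when the star graph is large enough, recurse on the rest.
    """
    events = []
    pts = list(members)
    while len(pts) >= cfg.min_cluster_size:
        cmax = max(p.coeff for p in pts)
        centroid = min((p for p in pts if p.coeff == cmax), key=lambda p: p.t)
        cmin = min(p.coeff for p in pts)
        linked = [centroid]
        for p in pts:
            if p is centroid:
                continue
            c_norm = (p.coeff - cmin) / (cmax - cmin) if cmax > cmin else 1.0
            d2 = (p.t - centroid.t) ** 2 + (p.scale - centroid.scale) ** 2
            theta = math.atan2(p.scale - centroid.scale, p.t - centroid.t)
            denom = math.sqrt(
                (cfg.w * n_peaks * math.sin(theta)) ** 2 + (cfg.h * math.cos(theta)) ** 2
            )
            r_i = cfg.w * cfg.h * n_peaks * p.scale * math.sqrt(c_norm) / denom
            r_0 = cfg.w * cfg.h * n_peaks * centroid.scale / denom
            if (r_i + r_0) ** 2 >= d2:
                linked.append(p)
        if len(linked) >= cfg.min_cluster_size:
            events.append((centroid.t, centroid.scale, centroid.coeff, len(linked)))
        pts = [p for p in pts if p not in linked]
    events.sort(key=lambda e: e[0])
    return events


def random_cluster(rng, n, t_span=1.0, scale_span=(1e-3, 1e-1)):
    return [
        LocalMaximum(
            t_index=i,
            scale_index=0,
            t=float(rng.uniform(0, t_span)),
            scale=float(np.exp(rng.uniform(*np.log(scale_span)))),
            coeff=float(rng.uniform(0.1, 5.0)),
        )
        for i in range(n)
    ]


class TestLocalMaxima:
    def _map(self, rows):
        coeffs = np.asarray(rows, dtype=float)
        grid = make_log_grid(1.0, 10.0, coeffs.shape[0]) if coeffs.shape[0] > 1 else None
        from pcwa.cwt import ScaleGrid

        grid = grid or ScaleGrid(np.array([1.0]))
        return CWTMap(coeffs=coeffs, grid=grid, dt=1.0, t0=0.0)

    def test_simple_peak(self):
        maxima = find_local_maxima(self._map([[0, 1, 0]]), threshold=0.5)
        assert [(m.t_index, m.coeff) for m in maxima] == [(1, 1.0)]

    def test_plateau_leftmost_edge_wins(self):
        maxima = find_local_maxima(self._map([[0, 1, 1, 0]]), threshold=0.5)
        assert [m.t_index for m in maxima] == [1]

    def test_threshold_filters(self):
        maxima = find_local_maxima(self._map([[0, 1, 0, 3, 0]]), threshold=2.0)
        assert [m.t_index for m in maxima] == [3]

    def test_rising_plateau_is_not_a_maximum(self):
        maxima = find_local_maxima(self._map([[0, 1, 1, 2, 0]]), threshold=0.5)
        assert [m.t_index for m in maxima] == [3]

    def test_streak_across_scales_for_single_event(self):
        """One clean Gaussian produces a connected streak of per-scale maxima."""
        from pcwa import compute_cwt

        trace = gaussian_trace([0.5], 5e-3, 10.0, 10000, 1e-4)
        grid = make_log_grid(2e-3, 2e-2, 12)
        cmap = compute_cwt(trace, ricker_spec(), grid)
        maxima = find_local_maxima(cmap, threshold=1e-6)
        per_scale = {m.scale_index for m in maxima}
        assert per_scale == set(range(12))
        assert all(abs(m.t - 0.5) < 2e-2 for m in maxima)


class TestMacroClusters:
    @staticmethod
    def _cluster_of(times, gap):
        ms = [LocalMaximum(0, 0, float(t), 0.01, 1.0) for t in times]
        return form_macro_clusters(ms, gap)

    def test_gap_split(self):
        ms = [
            LocalMaximum(0, 0, 1.0, 1.0, 1.0),
            LocalMaximum(1, 0, 1.001, 1.0, 1.0),
            LocalMaximum(2, 0, 5.0, 1.0, 1.0),
        ]
        clusters = form_macro_clusters(ms, gap=0.1)
        assert [len(c.members) for c in clusters] == [2, 1]

    def test_empty_input(self):
        assert form_macro_clusters([], gap=1.0) == []

    def test_partition_matches_brute_force(self, rng):
        """Every maximum lands in exactly one cluster; splits at gaps only."""
        for _ in range(20):
            ms = random_cluster(rng, int(rng.integers(1, 40)), t_span=10.0)
            gap = float(rng.uniform(0.05, 1.0))
            clusters = form_macro_clusters(ms, gap)
            assert sum(len(c.members) for c in clusters) == len(ms)
            # brute force: sorted times split wherever the gap is exceeded
            ts = sorted(m.t for m in ms)
            n_expected = 1 + sum(1 for a, b in zip(ts, ts[1:]) if b - a > gap)
            assert len(clusters) == n_expected
            for c in clusters:
                diffs = np.diff([m.t for m in c.members])
                assert np.all(diffs <= gap)

    def test_partition_properties_hold_for_arbitrary_inputs(self):
        """Property: clusters tile the input; intra-gaps ≤ gap < inter-gaps."""
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=60, derandomize=True, deadline=None)
        @given(
            times=st.lists(
                st.floats(0.0, 100.0, allow_nan=False, width=32),
                min_size=1, max_size=50,
            ),
            gap=st.floats(1e-3, 10.0, allow_nan=False),
        )
        def check(times, gap):
            clusters = self._cluster_of(times, gap)
            flat = sorted(m.t for c in clusters for m in c.members)
            assert flat == sorted(np.float32(t) for t in times)
            for c in clusters:
                assert all(np.diff([m.t for m in c.members]) <= gap)
            for a, b in zip(clusters, clusters[1:]):
                assert b.members[0].t - a.members[-1].t > gap

        check()

    def test_well_separated_events_one_cluster_each(self, rng):
        centers = [1.0, 5.0, 9.0]
        ms = []
        for c in centers:
            for _ in range(10):
                ms.append(
                    LocalMaximum(0, 0, c + float(rng.uniform(-0.01, 0.01)), 0.01, 1.0)
                )
        assert len(form_macro_clusters(ms, gap=0.1)) == 3


class TestOverlapLink:
    def test_coincident_point_links(self):
        cfg = DetectorConfig(threshold=0.0)
        c = LocalMaximum(0, 0, 1.0, 0.01, 2.0)
        i = LocalMaximum(1, 1, 1.0, 0.01, 1.0)
        assert overlap_link(i, c, cfg, (1.0, 2.0), 1)

    def test_distant_point_does_not_link(self):
        cfg = DetectorConfig(threshold=0.0)
        c = LocalMaximum(0, 0, 1.0, 0.01, 2.0)
        i = LocalMaximum(1, 1, 500.0, 0.01, 1.0)
        assert not overlap_link(i, c, cfg, (1.0, 2.0), 1)


class TestMicroClusters:
    def test_single_maximum_is_an_event(self):
        cfg = DetectorConfig(threshold=0.0, min_cluster_size=1)
        mc = MacroCluster((LocalMaximum(5, 2, 1.0, 0.01, 3.0),))
        events = resolve_micro_clusters(mc, cfg)
        assert len(events) == 1 and events[0].t == 1.0 and events[0].n_members == 1

    @pytest.mark.parametrize("n_peaks", [1, 7])
    def test_matches_brute_force_oracle(self, rng, n_peaks):
        """Vectorised partition equals the plain transcription on random clusters."""
        cfg = DetectorConfig(threshold=0.0, w=0.7, h=1.3, min_cluster_size=2)
        for _ in range(60):
            members = random_cluster(rng, int(rng.integers(2, 31)))
            mc = MacroCluster(tuple(sorted(members, key=lambda m: m.t)))
            got = [(e.t, e.scale, e.coeff, e.n_members) for e in
                   resolve_micro_clusters(mc, cfg, n_peaks)]
            expected = brute_force_micro_clusters(mc.members, cfg, n_peaks)
            assert len(got) == len(expected)
            for g, e in zip(got, expected):
                np.testing.assert_allclose(g, e, rtol=1e-12)

    def test_two_separated_streaks_give_two_events(self):
        members = []
        for t0 in (0.0, 1.0):
            for k in range(5):
                members.append(LocalMaximum(k, k, t0 + 1e-4 * k, 0.01 + 1e-3 * k, 1.0 + 0.1 * k))
        mc = MacroCluster(tuple(sorted(members, key=lambda m: m.t)))
        events = resolve_micro_clusters(mc, DetectorConfig(threshold=0.0, min_cluster_size=3))
        assert len(events) == 2


class TestDetect:
    def test_recovers_clean_peaks(self):
        dt = 1e-4
        centers = np.linspace(0.2, 1.8, 10)
        trace = gaussian_trace(centers, 4e-3, 10.0, 20000, dt)
        grid = make_log_grid(1e-3, 4e-2, 30)
        events = detect(trace, ricker_spec(), grid, DetectorConfig(threshold=1e-3))
        assert len(events) == 10
        for ev, c in zip(events, centers):
            assert abs(ev.t - c) <= dt
            # detected scale tracks the injected width (response optimum)
            assert 0.5 < ev.scale / (np.sqrt(5) * 4e-3) < 2.0

    def test_all_zero_trace_has_no_events(self):
        trace = Trace(counts=np.zeros(5000), dt=1e-4)
        grid = make_log_grid(1e-3, 1e-2, 10)
        events = detect(trace, ricker_spec(), grid, DetectorConfig(threshold=1e-6))
        assert events == []

    def test_threshold_monotonicity(self, rng):
        trace = Trace(counts=rng.poisson(2.0, 40000).astype(float), dt=1e-4)
        grid = make_log_grid(1e-3, 1e-2, 10)
        counts = [
            len(detect(trace, ricker_spec(), grid,
                       DetectorConfig(threshold=thr, min_cluster_size=2)))
            for thr in (1e-4, 3e-4, 1e-3, 3e-3)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_deterministic_and_order_independent(self, rng):
        """Macro clusters are independent: processing order cannot matter."""
        trace = gaussian_trace([0.3, 0.9, 1.5], 4e-3, 8.0, 20000, 1e-4, bg=0.0)
        trace = Trace(counts=trace.counts + rng.normal(0, 0.3, len(trace)), dt=1e-4)
        grid = make_log_grid(1e-3, 2e-2, 15)
        cfg = DetectorConfig(threshold=5e-3)
        a = detect(trace, ricker_spec(), grid, cfg)
        b = detect(trace, ricker_spec(), grid, cfg)
        assert a == b
        # resolving the macro clusters in any order gives the same events
        from pcwa import compute_cwt

        cmap = compute_cwt(trace, ricker_spec(), grid)
        maxima = find_local_maxima(cmap, cfg.threshold)
        clusters = form_macro_clusters(maxima, gap=2 * grid.scales[-1])
        fwd = [e for mc in clusters for e in resolve_micro_clusters(mc, cfg)]
        rev = [e for mc in reversed(clusters) for e in resolve_micro_clusters(mc, cfg)]
        assert sorted(fwd, key=lambda e: e.t) == sorted(rev, key=lambda e: e.t)

    def test_weak_event_near_strong_is_retained(self):
        """The sqrt(C') weight keeps a weak event close to a strong one."""
        dt = 1e-4
        trace = gaussian_trace(
            [1.0, 1.06, 1.5], 4e-3, [10.0, 1.0, 8.0], 20000, dt
        )
        grid = make_log_grid(1e-3, 2e-2, 25)
        events = detect(trace, ricker_spec(), grid,
                        DetectorConfig(threshold=1e-4, w=0.5, min_cluster_size=3))
        near = [e for e in events if 0.95 < e.t < 1.12]
        assert len(near) == 2  # strong + weak neighbour resolved separately
        assert len(events) == 3

    def test_t_adjusted_tracks_raw_maximum(self):
        dt = 1e-4
        trace = gaussian_trace([1.0], 4e-3, 10.0, 20000, dt)
        # add an asymmetric spike just off the Gaussian centre
        trace.counts[int(1.002 / dt)] += 5.0
        grid = make_log_grid(1e-3, 2e-2, 15)
        ev = detect(trace, ricker_spec(), grid, DetectorConfig(threshold=1e-3))[0]
        assert abs(ev.t_adjusted - 1.002) <= dt

    def test_config_validation(self):
        with pytest.raises(InvalidParameterError):
            DetectorConfig(threshold=np.nan)
        with pytest.raises(InvalidParameterError):
            DetectorConfig(threshold=0.0, w=-1.0)
        with pytest.raises(InvalidParameterError):
            DetectorConfig(threshold=0.0, min_cluster_size=0)
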