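"""Intrinsic ignition / metastability core, checked against an independent
brute-force implementation."""

import numpy as np
import pytest

from neuroignite import (
    EventRaster,
    IgnitionParams,
    coactivation_adjacency,
    compute_profile,
    event_integration,
    integration,
    integration_closed_form,
    window_length,
)
from neuroignite.ignition import ContractError


def raster_of(events, tr_ms=2400.0):
    return EventRaster(events=np.asarray(events, dtype=int), tr_ms=tr_ms)


# -- independent brute-force oracle (no package internals) ------------------


def brute_phi(events, tau):
    """Largest connected component of the co-event graph via BFS on sets."""
    active = [i for i in range(events.shape[0]) if events[i, tau] == 1]
    adj = {i: set() for i in range(events.shape[0])}
    for i in active:
        for j in active:
            if i != j:
                adj[i].add(j)
    best = 1
    seen = set()
    for start in range(events.shape[0]):
        if start in seen:
            continue
        comp, queue = {start}, [start]
        while queue:
            node = queue.pop()
            for nxt in adj[node]:
                if nxt not in comp:
                    comp.add(nxt)
                    queue.append(nxt)
        seen |= comp
        best = max(best, len(comp))
    return best


def brute_profile(events, twin):
    """Enumerate every driving event and window explicitly."""
    n, T = events.shape
    ign = np.full(n, np.nan)
    meta = np.full(n, np.nan)
    counts = np.zeros(n, dtype=int)
    for node in range(n):
        vals = []
        for t in range(T):
            if events[node, t] == 1 and t + twin < T:
                vals.append(
                    max(brute_phi(events, tau) for tau in range(t, t + twin + 1))
                )
        counts[node] = len(vals)
        if vals:
            ign[node] = np.mean(vals)
            meta[node] = np.std(vals, ddof=1) if len(vals) >= 2 else np.nan
    return ign, meta, counts


# -- window length ----------------------------------------------------------


class TestWindowLength:
    @pytest.mark.parametrize("tr,expected", [(2400, 7), (2100, 8), (1680, 10)])
    def test_known_values(self, tr, expected):
        assert window_length(tr) == expected

    def test_physical_duration_preserved_within_half_tr(self):
        for tr in range(1500, 3001, 25):
            assert abs(window_length(tr) * tr - 16800) <= tr / 2


# -- adjacency and integration ----------------------------------------------


class TestAdjacency:
    def test_two_active_nodes_single_edge(self):
        r = raster_of([[0, 1], [0, 1], [0, 0]])
        adj = coactivation_adjacency(r, 1)
        expected = np.zeros((3, 3))
        expected[0, 1] = expected[1, 0] = 1
        np.testing.assert_array_equal(adj, expected)

    def test_no_active_nodes_empty_graph(self):
        adj = coactivation_adjacency(raster_of(np.zeros((4, 3))), 0)
        assert adj.sum() == 0

    def test_all_active_complete_graph(self):
        adj = coactivation_adjacency(raster_of(np.ones((5, 2))), 1)
        assert adj.sum() == 5 * 4  # 10 undirected edges
        assert np.diag(adj).sum() == 0

    def test_tau_out_of_range(self):
        with pytest.raises(IndexError):
            coactivation_adjacency(raster_of(np.zeros((2, 3))), 3)


class TestIntegration:
    def test_three_active_of_ten(self):
        r = np.zeros((10, 1), dtype=int)
        r[[2, 5, 7], 0] = 1
        assert integration(coactivation_adjacency(raster_of(r), 0)) == 3

    def test_empty_graph_is_one(self):
        assert integration(np.zeros((6, 6))) == 1

    def test_normalized(self):
        assert integration(np.zeros((4, 4)), normalized=True) == 0.25

    def test_generic_equals_closed_form_on_random_rasters(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 9))
            T = int(rng.integers(2, 21))
            ev = (rng.random((n, T)) < 0.3).astype(int)
            r = raster_of(ev)
            closed = integration_closed_form(ev.sum(axis=0), n)
            for tau in range(T):
                assert integration(coactivation_adjacency(r, tau)) == closed[tau]


# -- event integration ------------------------------------------------------


class TestEventIntegration:
    def test_solitary_event_scores_one(self):
        ev = np.zeros((4, 10), dtype=int)
        ev[0, 3] = 1
        assert event_integration(raster_of(ev), 0, 3, IgnitionParams(window_tr=2)) == 1

    def test_hand_enumerated_window(self):
        # n=0 fires at t=1; nodes 1,2 at t=2; node 3 at t=3; T_win=2
        ev = np.zeros((4, 6), dtype=int)
        ev[0, 1] = 1
        ev[1, 2] = ev[2, 2] = 1
        ev[3, 3] = 1
        # Phi over [1,3] = [1, 2, 1] -> max 2
        assert event_integration(raster_of(ev), 0, 1, IgnitionParams(window_tr=2)) == 2

    def test_saturated_window_scores_n(self):
        ev = np.ones((5, 12), dtype=int)
        assert event_integration(raster_of(ev), 2, 4, IgnitionParams(window_tr=3)) == 5

    def test_non_event_rejected(self):
        ev = np.zeros((3, 8), dtype=int)
        ev[0, 1] = 1
        with pytest.raises(ContractError):
            event_integration(raster_of(ev), 1, 1, IgnitionParams(window_tr=2))

    def test_overrunning_window_rejected_unless_truncating(self):
        ev = np.zeros((3, 8), dtype=int)
        ev[0, 7] = 1
        with pytest.raises(ContractError):
            event_integration(raster_of(ev), 0, 7, IgnitionParams(window_tr=3))
        assert (
            event_integration(
                raster_of(ev), 0, 7, IgnitionParams(window_tr=3, truncate_overrunning=True)
            )
            == 1
        )


# -- profiles ---------------------------------------------------------------


class TestComputeProfile:
    def test_constant_integrations_zero_metastability(self):
        # node 0 fires three times, always alone with node 1 co-firing
        ev = np.zeros((3, 20), dtype=int)
        for t in (2, 8, 14):
            ev[0, t] = 1
            ev[1, t] = 1
        prof = compute_profile(raster_of(ev), IgnitionParams(window_tr=2))
        assert prof.ignition[0] == pytest.approx(2.0)
        assert prof.metastability[0] == pytest.approx(0.0)

    def test_two_point_sample_sd(self):
        # node 0: one solitary event (Phi max 1) and one with two co-events
        ev = np.zeros((4, 20), dtype=int)
        ev[0, 2] = 1
        ev[0, 10] = 1
        ev[1, 10] = ev[2, 10] = 1
        prof = compute_profile(raster_of(ev), IgnitionParams(window_tr=2))
        assert prof.ignition[0] == pytest.approx(2.0)  # mean of [1, 3]
        assert prof.metastability[0] == pytest.approx(np.sqrt(2))  # sample SD

    def test_matches_bruteforce_on_hand_built_raster(self, rng):
        ev = (rng.random((5, 50)) < 0.15).astype(int)
        params = IgnitionParams(window_tr=4)
        prof = compute_profile(raster_of(ev), params)
        ign, meta, counts = brute_profile(ev, 4)
        np.testing.assert_allclose(prof.ignition, ign, atol=1e-12)
        np.testing.assert_allclose(prof.metastability, meta, atol=1e-12)
        np.testing.assert_array_equal(prof.n_events, counts)

    def test_graph_method_agrees_with_closed_form(self, rng):
        ev = (rng.random((6, 30)) < 0.2).astype(int)
        params = IgnitionParams(window_tr=3)
        a = compute_profile(raster_of(ev), params, method="closed_form")
        b = compute_profile(raster_of(ev), params, method="graph")
        np.testing.assert_allclose(a.ignition, b.ignition, atol=1e-12)
        np.testing.assert_allclose(a.metastability, b.metastability, atol=1e-12)

    def test_bounds(self, rng):
        ev = (rng.random((6, 40)) < 0.3).astype(int)
        prof = compute_profile(raster_of(ev), IgnitionParams(window_tr=3))
        defined = ~np.isnan(prof.ignition)
        assert ((prof.ignition[defined] >= 1) & (prof.ignition[defined] <= 6)).all()
        meta = prof.metastability[~np.isnan(prof.metastability)]
        assert ((meta >= 0) & (meta <= 3)).all()

    def test_superposition_monotonicity(self, rng):
        """Adding events to other nodes never decreases node 0's values."""
        ev = (rng.random((5, 40)) < 0.1).astype(int)
        extra = ev.copy()
        extra[1:] |= (rng.random((4, 40)) < 0.2).astype(int)
        params = IgnitionParams(window_tr=3)
        times = [t for t in np.flatnonzero(ev[0]) if t + 3 < 40]
        for t in times:
            v1 = event_integration(raster_of(ev), 0, t, params)
            v2 = event_integration(raster_of(extra), 0, t, params)
            assert v2 >= v1

    def test_subject_means_exclude_undefined(self):
        ev = np.zeros((3, 20), dtype=int)
        ev[0, 2] = 1  # node 0: one event; nodes 1,2: none
        prof = compute_profile(raster_of(ev), IgnitionParams(window_tr=2))
        assert prof.mean_ignition == pytest.approx(1.0)
        assert np.isnan(prof.metastability[0])
        assert prof.n_events.tolist() == [1, 0, 0]
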