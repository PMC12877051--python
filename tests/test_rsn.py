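"""Network-level parcellation, correlation graphs and pooling levels."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neuroignite import (
    NETWORK_NAMES,
    affected_network_counts,
    metric_correlation_graph,
    network_metrics,
    parcellate_to_networks,
    subject_vs_region_correlation,
)
from neuroignite.containers import ParcellatedBold
from neuroignite.tumor import TumorOverlap


def metrics_frame(values):
    """values: subject -> {network -> (ign, meta)}"""
    rows = []
    for sub, nets in values.items():
        for net, (ign, meta) in nets.items():
            rows.append(
                {"subject": sub, "network": net, "ignition": ign, "metastability": meta}
            )
    return pd.DataFrame(rows)


class TestParcellateToNetworks:
    def test_identical_members_reproduce_signal(self, rng):
        base = rng.normal(size=60)
        sig = np.stack([base] * 4 + [rng.normal(size=60) for _ in range(3)])
        assignment = np.array([0] * 4 + [1, 2, 3])
        out = parcellate_to_networks(ParcellatedBold(sig, 2400), assignment)
        np.testing.assert_allclose(out.signal[0], base, atol=1e-12)

    def test_opposite_signals_cancel(self, rng):
        x = rng.normal(size=60)
        sig = np.stack([x, -x, x, x])
        out = parcellate_to_networks(
            ParcellatedBold(sig, 2400), np.array([0, 0, 1, 2])
        )
        np.testing.assert_allclose(out.signal[0], 0, atol=1e-12)

    def test_random_toy_matches_hand_means(self, rng):
        sig = rng.normal(size=(20, 50))
        assignment = rng.integers(0, 7, size=20)
        while len(set(assignment)) < 7:
            assignment = rng.integers(0, 7, size=20)
        out = parcellate_to_networks(ParcellatedBold(sig, 2100), assignment)
        for k in range(7):
            np.testing.assert_allclose(
                out.signal[k], sig[assignment == k].mean(axis=0), atol=1e-12
            )

    def test_uncovered_region_rejected(self, rng):
        sig = rng.normal(size=(5, 50))
        with pytest.raises(ValueError, match="uncovered"):
            parcellate_to_networks(ParcellatedBold(sig, 2400), np.array([0, 1, 2, 3]))


class TestCorrelationGraph:
    def test_identical_metrics_complete_graph_r_one(self, rng):
        shared = rng.normal(size=6)
        values = {
            f"s{i}": {net: (shared[i], shared[i] * 2) for net in NETWORK_NAMES}
            for i in range(6)
        }
        edges, graph = metric_correlation_graph(metrics_frame(values), "ign-ign")
        np.testing.assert_allclose(edges["r"], 1.0)
        assert graph.number_of_edges() == 21  # complete on 7 nodes

    def test_threshold_is_pure_filter(self, rng):
        values = {
            f"s{i}": {net: tuple(rng.normal(size=2)) for net in NETWORK_NAMES}
            for i in range(8)
        }
        frame = metrics_frame(values)
        thresholded, _ = metric_correlation_graph(frame, "meta-meta", r_min=0.4)
        full, _ = metric_correlation_graph(frame, "meta-meta", r_min=-np.inf)
        merged = thresholded.merge(full, on=["node_a", "node_b"], suffixes=("", "_full"))
        np.testing.assert_allclose(merged["r"], merged["r_full"])
        assert (thresholded["retained"] == (thresholded["r"] >= 0.4)).all()
        assert not thresholded.loc[thresholded["r"] < 0, "retained"].any()

    def test_null_retained_fraction_matches_t_distribution(self):
        n_sub = 6
        # P(r >= 0.4) for independent normals: one-sided t tail with n-2 df
        t_stat = 0.4 * np.sqrt((n_sub - 2) / (1 - 0.4**2))
        expected = stats.t.sf(t_stat, n_sub - 2)
        fractions = []
        rng = np.random.default_rng(99)
        for _ in range(300):
            values = {
                f"s{i}": {net: tuple(rng.normal(size=2)) for net in NETWORK_NAMES}
                for i in range(n_sub)
            }
            edges, _ = metric_correlation_graph(metrics_frame(values), "ign-ign")
            fractions.append(edges["retained"].mean())
        mc_err = 3 * np.sqrt(expected * (1 - expected) / (300 * 21))
        assert np.mean(fractions) == pytest.approx(expected, abs=mc_err + 0.01)

    def test_ign_meta_mode_has_self_edges(self, rng):
        values = {
            f"s{i}": {net: tuple(rng.normal(size=2)) for net in NETWORK_NAMES}
            for i in range(6)
        }
        edges, _ = metric_correlation_graph(metrics_frame(values), "ign-meta")
        self_pairs = edges[edges["node_a"] == edges["node_b"]]
        assert len(self_pairs) == 7
        edges2, _ = metric_correlation_graph(metrics_frame(values), "ign-ign")
        assert (edges2["node_a"] != edges2["node_b"]).all()

    def test_too_few_subjects_refused(self, rng):
        values = {
            f"s{i}": {net: tuple(rng.normal(size=2)) for net in NETWORK_NAMES}
            for i in range(3)
        }
        with pytest.raises(ValueError, match="4 subjects"):
            metric_correlation_graph(metrics_frame(values), "ign-ign")

    def test_attenuated_cohorts_retain_fewer_meta_edges(self):
        """Glioma-like (attenuated, noisier) cohorts keep fewer strong
        metastability edges than control-like cohorts (pooled over
        replicate cohorts)."""
        from neuroignite import CohortSpec, generate_bold

        total_ctl = total_gli = 0
        for seed in range(6):
            spec = CohortSpec(n_meningioma=1, seed=700 + seed)
            cohort, _ = generate_bold(spec)
            metrics = network_metrics(cohort, spec.network_assignment)
            ctl = [s for s in cohort if s.startswith("ctl")]
            gli = [s for s in cohort if s.startswith("gli")]
            e_ctl, _ = metric_correlation_graph(metrics, "meta-meta", ctl)
            e_gli, _ = metric_correlation_graph(metrics, "meta-meta", gli)
            total_ctl += e_ctl["retained"].sum()
            total_gli += e_gli["retained"].sum()
        assert total_gli < total_ctl


class TestPooling:
    def test_exact_linear_relation(self):
        values = {f"s{i}": {"VIS": (float(i), 2.0 * i + 1.0)} for i in range(5)}
        r, p = subject_vs_region_correlation(metrics_frame(values), "subject")
        assert r == pytest.approx(1.0)

    def test_anticorrelated(self):
        values = {f"s{i}": {"VIS": (float(i), -float(i))} for i in range(5)}
        r, _ = subject_vs_region_correlation(metrics_frame(values), "subject")
        assert r == pytest.approx(-1.0)

    def test_hand_listed_pairs_match_closed_form(self):
        pairs = [(1.0, 2.0), (2.0, 2.5), (3.0, 2.0), (4.0, 4.0), (5.0, 3.5)]
        values = {f"s{i}": {"VIS": p} for i, p in enumerate(pairs)}
        a = np.array([p[0] for p in pairs])
        b = np.array([p[1] for p in pairs])
        expected = ((a - a.mean()) * (b - b.mean())).sum() / np.sqrt(
            ((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum()
        )
        r, _ = subject_vs_region_correlation(metrics_frame(values), "subject")
        assert r == pytest.approx(expected)

    def test_subject_level_exceeds_region_level_when_pooling_dilutes(self, rng):
        """Strong subject-level coupling + weak within-subject coupling:
        subject means correlate better than pooled network values."""
        values = {}
        for i in range(10):
            level = rng.normal()
            values[f"s{i}"] = {
                net: (level + rng.normal(0, 0.1), level + rng.normal(0, 2.0))
                for net in NETWORK_NAMES
            }
        frame = metrics_frame(values)
        r_sub, _ = subject_vs_region_correlation(frame, "subject")
        r_reg, _ = subject_vs_region_correlation(frame, "network-region")
        assert r_sub > r_reg

    def test_refusal_below_three(self):
        values = {f"s{i}": {"VIS": (1.0 * i, 2.0)} for i in range(2)}
        with pytest.raises(ValueError, match=">= 3"):
            subject_vs_region_correlation(metrics_frame(values), "subject")


def test_affected_network_counts():
    assignment = np.array([0, 0, 1, 1, 2, 2, 3, 4, 5, 6])
    fractions = np.zeros(10)
    fractions[0] = 0.5  # VIS
    fractions[4] = 0.1  # DAN
    overlaps = {
        "p1": TumorOverlap(region_ids=[str(i) for i in range(10)], fractions=fractions),
        "c1": TumorOverlap(region_ids=[str(i) for i in range(10)], fractions=np.zeros(10)),
    }
    out = affected_network_counts(overlaps, assignment).set_index("subject")
    assert out.loc["p1", "n_affected_networks"] == 2
    assert bool(out.loc["p1", "VIS"]) and bool(out.loc["p1", "DAN"])
    assert out.loc["c1", "n_affected_networks"] == 0
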