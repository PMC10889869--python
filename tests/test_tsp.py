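"""Significance-profile arithmetic, superfamily rules, exemplar search."""

import itertools

import networkx as nx
import numpy as np
import pytest

from triadflow import (
    RewireConfig,
    classify_superfamily,
    compute_tsp,
    exemplar_triads,
    normalize_profile,
    profile_table,
    z_scores,
)
from triadflow.null_ensemble import EnsembleCensus
from triadflow.triads import canonical_triad_class
from triadflow.tsp import TSProfile

from conftest import random_digraph


def fake_ensemble(mean, sd, size=200):
    """Synthetic EnsembleCensus with prescribed column mean/sd (two-point rows)."""
    mean = np.asarray(mean, float)
    sd = np.asarray(sd, float)
    half = size // 2
    rows = np.vstack([np.tile(mean + sd, (half, 1)), np.tile(mean - sd, (half, 1))])
    return EnsembleCensus(rows)


def make_profile(z):
    z = np.asarray(z, float)
    return TSProfile(None, np.zeros(13), z, z, np.zeros(13), np.zeros(13))


class TestZScores:
    def test_direct_formula(self):
        ens = fake_ensemble(np.full(13, 4.0), np.full(13, 2.0))
        Z, flags = z_scores(np.full(13, 10), ens)
        assert np.allclose(Z, 3.0)
        assert all(not f for f in flags)

    def test_zero_deviation(self):
        ens = fake_ensemble(np.full(13, 7.0), np.full(13, 1.0))
        Z, _ = z_scores(np.full(13, 7), ens)
        assert np.allclose(Z, 0.0)

    def test_sigma_zero_conventions(self):
        mean = np.full(13, 5.0)
        ens = fake_ensemble(mean, np.zeros(13))
        emp = mean.copy()
        emp[0] = 9.0  # above the constant ensemble
        emp[1] = 1.0  # below it
        Z, flags = z_scores(emp, ens)
        assert Z[0] == 10.0 and Z[1] == -10.0 and np.all(Z[2:] == 0)
        assert "capped" in flags[0] and "capped" in flags[1]
        assert all("sd_zero" in f for f in flags)


class TestNormalize:
    def test_three_four_five(self):
        Z = np.zeros(13)
        Z[0], Z[1] = 3, 4
        z, _ = normalize_profile(Z)
        assert z[0] == pytest.approx(0.6) and z[1] == pytest.approx(0.8)
        assert np.all(z[2:] == 0)

    def test_zero_vector_flagged(self):
        z, flags = normalize_profile(np.zeros(13))
        assert np.all(z == 0)
        assert all("zero_profile" in f for f in flags)

    def test_unit_norm_for_nonzero_profiles(self, rng):
        for _ in range(25):
            Z = rng.normal(size=13) * rng.uniform(0.1, 50)
            z, _ = normalize_profile(Z)
            assert abs((z**2).sum() - 1) < 1e-12

    def test_scale_equivariance(self, rng):
        Z = rng.normal(size=13)
        z1, _ = normalize_profile(Z)
        z2, _ = normalize_profile(Z * 173.5)
        assert np.allclose(z1, z2)

    def test_sign_preserved(self, rng):
        Z = rng.normal(size=13)
        z, _ = normalize_profile(Z)
        assert np.all(np.sign(z) == np.sign(Z))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            normalize_profile(np.r_[np.inf, np.zeros(12)])


class TestComputeTsp:
    def test_complete_graph_degenerates_to_zero_profile(self):
        g = nx.complete_graph(6, create_using=nx.DiGraph)
        p = compute_tsp(g, RewireConfig(ensemble_size=20, seed=0))
        assert np.all(p.Z == 0) and np.all(p.z == 0)
        assert p.flagged("sd_zero") == list(range(1, 14))

    def test_tiny_graph_flagged(self):
        g = nx.DiGraph([("A", "B")])
        p = compute_tsp(g, RewireConfig(ensemble_size=10, seed=0))
        assert np.all(p.z == 0)
        assert p.flagged("too_small") == list(range(1, 14))

    def test_profile_records_intermediates(self, rng):
        g = random_digraph(rng, n=30, p=0.1, bias=0.4)
        p = compute_tsp(g, RewireConfig(ensemble_size=30, seed=4), period=1995)
        assert p.period == 1995
        assert p.counts.sum() > 0
        assert abs((p.z**2).sum() - 1) < 1e-12


class TestClassifySuperfamily:
    def test_social_pattern(self):
        z = np.zeros(13)
        z[12], z[5] = 0.8, -0.5
        assert classify_superfamily(make_profile(z)).label == "social"

    def test_information_processing_pattern(self):
        z = np.full(13, 0.0)
        z[0:6] = -0.1
        z[6], z[9] = 0.6, 0.4
        assert classify_superfamily(make_profile(z)).label == "information-processing"

    def test_near_zero_is_indeterminate(self):
        z = np.full(13, 0.01)
        assert classify_superfamily(make_profile(z)).label == "indeterminate"

    def test_dead_band_suppresses_weak_signs(self):
        z = np.zeros(13)
        z[12], z[5] = 0.04, -0.04  # inside the dead-band
        assert classify_superfamily(make_profile(z)).label == "indeterminate"

    def test_comparable_conflicting_patterns_are_indeterminate(self):
        z = np.zeros(13)
        z[0:6] = -0.5
        z[6], z[9], z[12] = 0.5, 0.4, 0.5  # both patterns, similar strength
        assert classify_superfamily(make_profile(z)).label == "indeterminate"

    def test_dominant_pattern_wins_a_conflict(self):
        z = np.zeros(13)
        z[0:6] = -0.3
        z[5], z[12] = -0.6, 0.6  # strong clique signature
        z[6], z[9] = 0.08, 0.07  # weak feed-forward co-match
        call = classify_superfamily(make_profile(z))
        assert call.evidence["information_processing_pattern"]
        assert call.label == "social"
        z2 = np.zeros(13)
        z2[0:6] = -0.35
        z2[6], z2[9] = 0.5, 0.4
        z2[12], z2[5] = 0.06, -0.35  # weak clique co-match
        assert classify_superfamily(make_profile(z2)).label == "information-processing"

    def test_reference_profiles_report_best_correlation(self):
        z = np.zeros(13)
        z[3] = 1.0
        refs = {"mine": z.copy(), "anti": -z}
        call = classify_superfamily(make_profile(z), refs=refs)
        assert call.label == "user-reference:mine"
        assert call.correlation == pytest.approx(1.0)


class TestExemplars:
    def build_weighted(self, arcs):
        g = nx.DiGraph()
        g.add_weighted_edges_from(arcs)
        return g

    def test_highest_volume_triad_wins(self):
        g = self.build_weighted(
            [
                ("A", "B", 100), ("B", "C", 300), ("A", "C", 500),   # volume 900
                ("X", "Y", 500), ("Y", "Z", 500), ("X", "Z", 500),   # volume 1500
            ]
        )
        out = exemplar_triads(g, {7}, top_k=2)
        assert [t.volume for t in out[7]] == [1500.0, 900.0]
        assert out[7][0].nodes == ("X", "Y", "Z")
        assert out[7][0].roles == ("origin", "transit", "destination")

    def test_absent_class_gives_empty_list(self):
        g = self.build_weighted([("A", "B", 10), ("B", "C", 10), ("A", "C", 10)])
        assert exemplar_triads(g, {13})[13] == []

    def test_matches_bruteforce_maximum(self, rng):
        g = random_digraph(rng, n=15, p=0.25, bias=0.5)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.integers(1, 1000))
        out = exemplar_triads(g, set(range(1, 14)), top_k=1)
        best = {}
        for triple in itertools.combinations(sorted(g.nodes), 3):
            arcs = [
                (u, v) for u in triple for v in triple if u != v and g.has_edge(u, v)
            ]
            cls = canonical_triad_class(arcs, nodes=triple)
            if cls == "disconnected":
                continue
            vol = sum(g[u][v]["weight"] for u, v in arcs)
            best[cls] = max(best.get(cls, 0.0), vol)
        for cls in range(1, 14):
            if best.get(cls):
                assert out[cls][0].volume == pytest.approx(best[cls])
            else:
                assert out[cls] == []

    def test_induced_class_matches_request(self):
        g = self.build_weighted(
            [("A", "B", 5), ("B", "A", 5), ("B", "C", 5), ("C", "B", 5), ("A", "C", 5), ("C", "A", 5)]
        )
        out = exemplar_triads(g, {13})
        assert out[13][0].class_index == 13 and out[13][0].volume == 30


class TestProfileTable:
    def test_long_format_shape(self):
        profiles = [make_profile(np.full(13, 0.1)) for _ in range(6)]
        for i, p in enumerate(profiles):
            p.period = 1990 + 5 * i
        tab = profile_table(profiles)
        assert len(tab) == 78
        assert set(tab.columns) == {"period", "triad_type", "z"}

    def test_single_profile_quartiles_collapse(self):
        p = make_profile(np.linspace(-0.5, 0.5, 13))
        tab = profile_table([p])
        med = tab.groupby("triad_type")["z"].median()
        assert np.allclose(med.values, p.z)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            profile_table([])
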