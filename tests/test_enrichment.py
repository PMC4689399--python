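"""Enrichment statistics: folds, exact tests, calibration, profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from netdrugg.community import CommunityPartition, walktrap
from netdrugg.enrichment import (
    articulation_enrichment,
    community_enrichment,
    feature_compare,
    network_profile,
    orbit_enrichment,
)
from netdrugg.graphlets import build_atlas
from netdrugg.network_io import InteractionGraph
from netdrugg.node_features import articulation_points
from netdrugg.pu_model import LabelSet


def name_graph(n):
    """Cheap graph providing n node names (a star; topology irrelevant)."""
    return InteractionGraph.from_edges([("hub", f"v{i:04d}") for i in range(n - 1)])


class TestOrbitEnrichment:
    def test_whole_index_as_targets_zero_logfold(self):
        gdv = pd.DataFrame(
            np.random.default_rng(0).integers(0, 50, size=(40, 5)),
            index=[f"n{i}" for i in range(40)], columns=[f"o{k}" for k in range(5)],
        )
        rep = orbit_enrichment(gdv, set(gdv.index))
        assert np.allclose(rep["log2_enrichment"], 0.0)

    def test_random_subsets_centred_near_zero(self):
        rng = np.random.default_rng(1)
        gdv = pd.DataFrame(
            rng.poisson(8, size=(200, 6)).astype(float),
            index=[f"n{i}" for i in range(200)], columns=[f"o{k}" for k in range(6)],
        )
        folds = []
        for _ in range(20):
            targets = set(rng.choice(gdv.index, 20, replace=False))
            folds.append(orbit_enrichment(gdv, targets)["log2_enrichment"].abs().mean())
        assert np.mean(folds) < 0.1

    def test_planted_dense_neighbourhood_enriched(self, bench_small):
        feats = bench_small["features"]
        orbit_cols = [c for c in feats.columns if c.startswith("orbit.")]
        gdv = feats[orbit_cols].rename(columns=lambda c: c.split(".", 1)[1])
        rep = orbit_enrichment(gdv, bench_small["labels"])
        atlas = build_atlas()
        dense = [f"o{o}" for gi in (26, 27, 28, 29) for o in atlas.orbits_of_graphlet(gi)]
        assert rep.loc[dense, "log2_enrichment"].mean() > 1.0
        # the plain-edge orbit shows only the (much smaller) degree effect
        assert rep.loc["o0", "log2_enrichment"] < rep.loc[dense, "log2_enrichment"].mean()

    def test_empty_targets_error(self):
        gdv = pd.DataFrame({"o0": [1, 2]}, index=["a", "b"])
        with pytest.raises(ValueError):
            orbit_enrichment(gdv, set())


class TestCommunityEnrichment:
    def test_closed_form_fold(self):
        # community 0 holds 10% of nodes but 50% of targets -> fold 5
        assignment = {f"n{i}": (0 if i < 10 else 1 + i % 9) for i in range(100)}
        p = CommunityPartition("manual", assignment)
        targets = {f"n{i}" for i in range(5)} | {f"n{i}" for i in range(90, 95)}
        report, curve = community_enrichment(p, targets, min_size=1)
        assert report.loc[0, "fold"] == pytest.approx(5.0)
        assert curve["cumulative_fraction"].iloc[-1] == pytest.approx(1.0)

    def test_proportional_targets_fold_one(self):
        assignment = {f"n{i}": i % 4 for i in range(200)}
        p = CommunityPartition("manual", assignment)
        targets = {f"n{i}" for i in range(20)}  # 5 per community of 50
        report, _ = community_enrichment(p, targets, min_size=1)
        assert np.allclose(report["fold"], 1.0)

    def test_small_communities_excluded_from_report(self):
        assignment = {f"n{i}": 0 for i in range(20)}
        assignment.update({f"m{i}": 1 for i in range(3)})
        p = CommunityPartition("manual", assignment)
        report, curve = community_enrichment(p, {"n0", "m0"}, min_size=5)
        assert 1 not in report.index  # size-3 community filtered
        assert curve["cumulative_fraction"].iloc[-1] == pytest.approx(1.0)

    def test_planted_concentration_coverage(self, bench_small):
        """Positives concentrated by construction: top communities cover most."""
        g = bench_small["graph"]
        p = bench_small["partitions"][0]
        labels = bench_small["labels"]
        report, curve = community_enrichment(p, labels, n_nodes=g.n)
        assert curve["cumulative_fraction"].iloc[-1] == pytest.approx(1.0)
        assert (report["fold"] >= 0).all()
        assert (report.loc[report["targets"] > 0, "fold"] > 0).all()
        assert (report["q"] >= report["p"] - 1e-15).all()


class TestArticulationEnrichment:
    def test_fifteen_vs_nine_percent_table(self):
        """The canonical contrast: 15% of 1000 targets vs 9% of 1000
        background nodes are articulation points."""
        g = name_graph(2000)
        names = g.names
        targets = set(names[:1000])
        aps = set(names[:150]) | set(names[1000:1090])
        res = articulation_enrichment(g, aps, targets)
        assert res["target_proportion"] == pytest.approx(0.15)
        assert res["background_proportion"] == pytest.approx(0.09)
        assert res["p"] < 0.05
        oracle = stats.fisher_exact([[150, 850], [90, 910]], alternative="greater")[1]
        assert res["p"] == pytest.approx(oracle)

    def test_extreme_table_minimal_p(self):
        g = name_graph(60)
        targets = set(g.names[:20])
        res = articulation_enrichment(g, targets, targets)  # targets all APs
        assert res["p"] < 1e-12

    def test_random_targets_not_significant_on_average(self):
        g = name_graph(400)
        rng = np.random.default_rng(2)
        aps = set(rng.choice(g.names, 60, replace=False))
        ps = [
            articulation_enrichment(g, aps, set(rng.choice(g.names, 80, replace=False)))["p"]
            for _ in range(40)
        ]
        assert np.mean(np.array(ps) < 0.05) < 0.2


class TestFeatureCompare:
    def test_identical_groups_p_one(self):
        feats = pd.DataFrame({"a": np.ones(30)}, index=[f"n{i}" for i in range(30)])
        rep = feature_compare(feats, {f"n{i}" for i in range(10)})
        assert rep.loc["a", "p"] == 1.0

    def test_planted_degree_shift_detected(self, bench_small):
        rep = feature_compare(bench_small["features"], bench_small["labels"])
        assert rep.loc["topo.degree", "q"] < 0.05
        assert rep.loc["topo.degree", "target_mean"] > rep.loc["topo.degree", "background_mean"]

    def test_null_calibration_false_positive_rate(self):
        rng = np.random.default_rng(3)
        feats = pd.DataFrame(
            rng.normal(size=(200, 10)),
            index=[f"n{i}" for i in range(200)],
            columns=[f"f{j}" for j in range(10)],
        )
        hits = []
        for _ in range(30):
            targets = set(rng.choice(feats.index, 40, replace=False))
            rep = feature_compare(feats, targets)
            hits.append((rep["p"] < 0.05).mean())
        assert np.mean(hits) < 0.12

    def test_bh_adjustment_matches_hand_rolled_reference(self):
        rng = np.random.default_rng(4)
        feats = pd.DataFrame(
            rng.normal(size=(60, 12)), index=[f"n{i}" for i in range(60)],
            columns=[f"f{j}" for j in range(12)],
        )
        rep = feature_compare(feats, set(feats.index[:20]))
        p = rep["p"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        q_ref = np.empty(m)
        running = 1.0
        for rank_from_end, idx in enumerate(order[::-1]):
            i = m - rank_from_end  # 1-based rank of this p-value
            running = min(running, p[idx] * m / i)
            q_ref[idx] = running
        assert np.allclose(rep["q"].to_numpy(), q_ref, atol=1e-12)


class TestNetworkProfile:
    def test_self_similarity_and_identical_rows(self, bench_small):
        feats = bench_small["features"]
        nodes = list(feats.index[:3])
        z, sim = network_profile(feats, nodes)
        assert np.allclose(np.diag(sim), 1.0)
        dup = feats.copy()
        dup.loc[nodes[1]] = dup.loc[nodes[0]]
        z2, sim2 = network_profile(dup, nodes[:2])
        assert sim2.iloc[0, 1] == pytest.approx(1.0)
        assert np.allclose(z2.iloc[0], z2.iloc[1])

    def test_hub_vs_peripheral_dissimilar(self, bench_small):
        feats = bench_small["features"]
        deg = feats["topo.degree"]
        hub = deg.idxmax()
        peripheral = deg.idxmin()
        _, sim = network_profile(feats, [hub, peripheral])
        assert sim.iloc[0, 1] < 0.5

    def test_unknown_node_errors(self, bench_small):
        with pytest.raises(KeyError):
            network_profile(bench_small["features"], ["nope"])
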