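"""Stratification, the PU ensemble estimator, CV/null machinery and scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from netdrugg.network_io import InteractionGraph
from netdrugg.pu_model import (
    STRATA,
    LabelSet,
    PUEnsembleRegressor,
    StratumDataset,
    cross_validate,
    fit_pu_ensemble,
    percentile_scores,
    random_label_null,
    ranked_auc,
    score,
    stratify,
)

TINY = dict(n_trees=30, gbm_stages=30)


def star_graph(degrees):
    """A graph whose node v{i} has exactly degrees[i] first neighbours."""
    edges = []
    for i, d in enumerate(degrees):
        for j in range(d):
            edges.append((f"v{i}", f"v{i}_leaf{j}"))
    return InteractionGraph.from_edges(edges)


def synthetic_dataset(n=300, n_pos=40, signal=True, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 8))
    pos_idx = rng.choice(n, n_pos, replace=False)
    y = np.zeros(n)
    y[pos_idx] = 1.0
    if signal:
        X[pos_idx, :3] += 2.0
    nodes = [f"n{i:03d}" for i in range(n)]
    feats = pd.DataFrame(X, index=nodes, columns=[f"f{j}" for j in range(8)])
    labels = LabelSet("synthetic", frozenset(nodes[i] for i in pos_idx))
    ds = StratumDataset("synthetic", STRATA["all"], nodes, set(labels.positives), False)
    return feats, labels, ds


class TestStratify:
    def test_degree_boundaries(self):
        g = star_graph([5, 6, 30, 31])
        labels = LabelSet("t", frozenset(["v0"]))
        out = stratify(g, labels)
        in_stratum = {s: set(out[s].nodes) for s in out}
        assert "v0" in in_stratum["low"] and "v0" not in in_stratum["medium"]
        assert "v1" in in_stratum["medium"] and "v2" in in_stratum["medium"]
        assert "v3" in in_stratum["high"]

    def test_small_stratum_flagged(self):
        g = star_graph([2] * 16)
        labels = LabelSet("t", frozenset(f"v{i}" for i in range(16)))
        out = stratify(g, labels)
        assert out["low"].too_small
        with pytest.raises(ValueError, match="too small"):
            fit_pu_ensemble(pd.DataFrame(np.ones((1, 1))), labels, dataset=out["low"])

    def test_all_stratum_is_union(self):
        g = star_graph([3, 10, 40, 2, 33])
        labels = LabelSet("t", frozenset(["v0", "v1", "v2", "v3", "v4"]))
        out = stratify(g, labels)
        assert out["all"].n_positives == sum(
            out[s].n_positives for s in ("low", "medium", "high")
        )
        assert sorted(out["all"].nodes) == sorted(
            out["low"].nodes + out["medium"].nodes + out["high"].nodes
        )

    def test_empty_labels_error(self):
        with pytest.raises(ValueError):
            stratify(star_graph([3]), LabelSet("t", frozenset()))


class TestRankedAuc:
    def test_perfect_separation(self):
        assert ranked_auc([0.9, 0.8, 0.1, 0.2], [True, True, False, False]) == 1.0

    def test_reversed(self):
        assert ranked_auc([0.1, 0.9], [True, False]) == 0.0

    def test_all_tied_is_half(self):
        assert ranked_auc([1.0] * 6, [True, False, True, False, False, False]) == 0.5

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            ranked_auc([1.0, 2.0], [True, True])


class TestPercentileScores:
    def test_strictly_lower_convention(self):
        vals = np.arange(100, dtype=float)
        pct = percentile_scores(vals)
        assert pct[78] == pytest.approx(78.0)

    def test_all_tied(self):
        assert np.allclose(percentile_scores(np.ones(100)), 49.5)

    def test_top_of_thousand(self):
        vals = np.arange(1000, dtype=float)
        assert percentile_scores(vals)[-1] == pytest.approx(99.9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50))
    def test_bounds_and_monotonicity(self, vals):
        pct = percentile_scores(np.array(vals))
        assert (pct >= 0).all() and (pct < 100).all()
        order = np.argsort(vals, kind="stable")
        assert (np.diff(pct[order]) >= -1e-12).all()


class TestEnsembleEstimator:
    def test_sklearn_contract(self):
        est = PUEnsembleRegressor(**TINY, random_state=3)
        params = est.get_params()
        assert params["n_trees"] == 30 and params["random_state"] == 3
        cloned = clone(est)
        assert cloned.get_params() == params

    def test_separable_signal_learned(self):
        feats, labels, ds = synthetic_dataset(signal=True)
        X = feats.to_numpy()
        y = np.array([v in labels.positives for v in feats.index], dtype=float)
        est = PUEnsembleRegressor(**TINY, random_state=0).fit(X, y)
        assert ranked_auc(est.predict(X), y == 1) > 0.95

    def test_refit_same_seed_bit_identical(self):
        feats, labels, ds = synthetic_dataset()
        b1 = fit_pu_ensemble(feats, labels, dataset=ds, seed=11,
                             estimator=PUEnsembleRegressor(**TINY))
        b2 = fit_pu_ensemble(feats, labels, dataset=ds, seed=11,
                             estimator=PUEnsembleRegressor(**TINY))
        X = feats.to_numpy()
        assert np.array_equal(b1.estimator.predict(X), b2.estimator.predict(X))

    def test_rejects_non_binary_targets(self):
        est = PUEnsembleRegressor(**TINY)
        with pytest.raises(ValueError):
            est.fit(np.random.default_rng(0).normal(size=(10, 2)), np.arange(10))

    def test_constant_columns_dropped_with_warning(self, caplog):
        feats, labels, ds = synthetic_dataset(n=80, n_pos=25)
        feats["const"] = 1.0
        import logging
        with caplog.at_level(logging.WARNING, logger="netdrugg.pu_model"):
            fit_pu_ensemble(feats, labels, dataset=ds, seed=0,
                            estimator=PUEnsembleRegressor(**TINY))
        assert any("constant" in r.message for r in caplog.records)

    def test_ensemble_invariant_to_member_rescaling(self):
        """Min-max scaling before averaging: shifting/stretching one member's
        raw outputs leaves the ensemble score unchanged."""
        feats, labels, ds = synthetic_dataset(n=120, n_pos=30)
        bundle = fit_pu_ensemble(feats, labels, dataset=ds, seed=4,
                                 estimator=PUEnsembleRegressor(**TINY))
        est = bundle.estimator
        X = feats.to_numpy()
        base = est.predict(X)
        member = est.predict_members(X)
        scaled = []
        for i, (name, vals) in enumerate(member.items()):
            vals = vals * (10.0 if name == "gbm" else 1.0) + (5.0 if name == "gbm" else 0.0)
            lo, hi = vals.min(), vals.max()
            scaled.append((vals - lo) / (hi - lo) if hi > lo else np.full_like(vals, 0.5))
        assert np.allclose(np.mean(scaled, axis=0), base, atol=1e-12)


class TestCrossValidation:
    def test_perfectly_separable_feature_gives_auc_100(self):
        feats, labels, ds = synthetic_dataset(n=200, n_pos=40, signal=False, seed=1)
        feats["oracle"] = [1.0 if v in labels.positives else 0.0 for v in feats.index]
        rep = cross_validate(feats, labels, dataset=ds, seed=0,
                             estimator=PUEnsembleRegressor(**TINY))
        assert rep["mean_auc"] == pytest.approx(100.0)
        assert rep["k"] == 10 and len(rep["fold_auc"]) == 10

    def test_no_signal_near_chance(self):
        aucs = []
        for seed in range(4):
            feats, labels, ds = synthetic_dataset(n=200, n_pos=40, signal=False, seed=seed)
            rep = cross_validate(feats, labels, dataset=ds, seed=seed,
                                 estimator=PUEnsembleRegressor(**TINY))
            aucs.append(rep["mean_auc"])
        assert 40 < np.mean(aucs) < 60

    def test_high_stratum_defaults_to_five_folds(self):
        g = star_graph([35] * 60)
        labels = LabelSet("t", frozenset(f"v{i}" for i in range(25)))
        ds = stratify(g, labels)["high"]
        feats = pd.DataFrame(
            np.random.default_rng(0).normal(size=(len(ds.nodes), 3)),
            index=ds.nodes, columns=list("abc"),
        )
        rep = cross_validate(feats, labels, dataset=ds, seed=0,
                             estimator=PUEnsembleRegressor(**TINY))
        assert rep["k"] == 5

    def test_too_few_positives_for_folds(self):
        feats, labels, ds = synthetic_dataset(n=50, n_pos=5)
        with pytest.raises(ValueError):
            cross_validate(feats, labels, dataset=ds, k=10, seed=0)


class TestRandomLabelNull:
    def test_null_near_chance_and_sized(self):
        feats, labels, ds = synthetic_dataset(n=250, n_pos=40, signal=True, seed=2)
        rep = random_label_null(feats, labels, dataset=ds, repeats=3, seed=9,
                                estimator=PUEnsembleRegressor(**TINY))
        assert len(rep["auc"]) == 3
        assert 35 < rep["mean_auc"] < 65

    def test_single_repeat_reproducible(self):
        feats, labels, ds = synthetic_dataset(n=150, n_pos=30)
        r1 = random_label_null(feats, labels, dataset=ds, repeats=1, seed=5,
                               estimator=PUEnsembleRegressor(**TINY))
        r2 = random_label_null(feats, labels, dataset=ds, repeats=1, seed=5,
                               estimator=PUEnsembleRegressor(**TINY))
        assert r1["auc"] == r2["auc"]


class TestScore:
    def test_percentile_table(self):
        feats, labels, ds = synthetic_dataset(n=100, n_pos=25)
        bundle = fit_pu_ensemble(feats, labels, dataset=ds, seed=0,
                                 estimator=PUEnsembleRegressor(**TINY))
        table = score(bundle, feats)
        assert list(table.columns) == ["node", "avg_output", "rank", "percentile"]
        assert (table["avg_output"].diff().dropna() <= 1e-12).all()  # sorted desc
        assert table["percentile"].between(0, 100, inclusive="left").all()

    def test_registry_mismatch_errors(self):
        feats, labels, ds = synthetic_dataset(n=80, n_pos=25)
        bundle = fit_pu_ensemble(feats, labels, dataset=ds, seed=0,
                                 estimator=PUEnsembleRegressor(**TINY))
        with pytest.raises(ValueError, match="registry"):
            score(bundle, feats.rename(columns={"f0": "other"}))

    def test_invariant_to_row_permutation(self):
        feats, labels, ds = synthetic_dataset(n=90, n_pos=25)
        bundle = fit_pu_ensemble(feats, labels, dataset=ds, seed=0,
                                 estimator=PUEnsembleRegressor(**TINY))
        t1 = score(bundle, feats)
        t2 = score(bundle, feats.sample(frac=1.0, random_state=1))
        merged = t1.merge(t2, on="node", suffixes=("_a", "_b"))
        assert np.allclose(merged["percentile_a"], merged["percentile_b"])
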