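"""Degree-stratified positive-unlabeled druggability modelling.

Known drug targets are the only labels available; everything else is
*unlabeled background*, never a negative.  The minority fraction is tiny
(a few percent), so regression ensembles are trained on a 0/1 target
(1 = positive, 0 = unlabeled) and evaluated with a rank-based
(Mann-Whitney) AUC of held-out positives against held-out background.
Because node descriptors depend on every other node, a true holdout is
impossible; the null reference is instead a structure-preserving
random-label experiment: the same graph and features, positives reassigned
to random nodes.

Degree strata (low <= 5, medium 6-30, high >= 31, plus "all") de-bias the
strong degree correlation of most descriptors.

The ensemble itself is a scikit-learn estimator (`PUEnsembleRegressor`):
random forest + gradient boosting + binomial-link GLM (L2-penalised
logistic regression), each model's outputs min-max scaled to [0, 1] before
averaging.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted, validate_data

from .network_io import InteractionGraph

logger = logging.getLogger(__name__)

__all__ = [
    "LabelSet",
    "DegreeStratum",
    "STRATA",
    "PUEnsembleRegressor",
    "ModelBundle",
    "stratify",
    "fit_pu_ensemble",
    "cross_validate",
    "random_label_null",
    "ranked_auc",
    "score",
    "percentile_scores",
]

MIN_POSITIVES = 20


@dataclass(frozen=True)
class LabelSet:
    """A named positive set over graph nodes; the rest is unlabeled."""

    name: str
    positives: frozenset[str]

    @classmethod
    def from_file(cls, path, name: str | None = None) -> "LabelSet":
        with open(path) as fh:
            ids = {line.strip() for line in fh if line.strip() and not line.startswith("#")}
        return cls(name=name or str(path), positives=frozenset(ids))

    def restrict(self, nodes) -> "LabelSet":
        return LabelSet(self.name, self.positives & set(nodes))


@dataclass(frozen=True)
class DegreeStratum:
    """A first-neighbour-count class: all / low (<=5) / medium (6-30) / high (>=31)."""

    name: str
    lo: int
    hi: int  # inclusive; use a large sentinel for "no upper bound"

    def contains(self, degree: int) -> bool:
        return self.lo <= degree <= self.hi


STRATA: dict[str, DegreeStratum] = {
    "all": DegreeStratum("all", 0, 10**9),
    "low": DegreeStratum("low", 0, 5),
    "medium": DegreeStratum("medium", 6, 30),
    "high": DegreeStratum("high", 31, 10**9),
}


@dataclass
class StratumDataset:
    """Nodes and positives of one degree stratum of one label set."""

    label_name: str
    stratum: DegreeStratum
    nodes: list[str]
    positives: set[str]
    too_small: bool

    @property
    def n_positives(self) -> int:
        return len(self.positives)


def stratify(g: InteractionGraph, labels: LabelSet) -> dict[str, StratumDataset]:
    """Split nodes into the four degree strata and count positives in each.

    Strata with fewer than 20 positives are flagged as too small for
    effective model building (fitting refuses them).
    """
    if not labels.positives:
        raise ValueError("label set is empty")
    deg = g.degree()
    out: dict[str, StratumDataset] = {}
    for sname, stratum in STRATA.items():
        nodes = [v for v in g.names if stratum.contains(deg[v])]
        pos = set(nodes) & labels.positives
        too_small = len(pos) < MIN_POSITIVES
        if too_small:
            logger.warning(
                "stratify: %s/%s has %d positives: too small for effective model building",
                labels.name, sname, len(pos),
            )
        out[sname] = StratumDataset(labels.name, stratum, nodes, pos, too_small)
    return out


class PUEnsembleRegressor(BaseEstimator, RegressorMixin):
    """Three-algorithm regression ensemble for positive-unlabeled scoring.

    Fits a random forest, a gradient-boosted machine and a binomial-link
    GLM (L2-penalised logistic regression) on a 0/1 target; ``predict``
    min-max scales each model's outputs over the scored batch and averages
    them, so the ensemble score is invariant to any monotone rescaling of a
    single member's outputs.

    Parameters mirror the reference configuration: 500 trees with sqrt(p)
    features per split, 500 boosting stages of depth 3 at learning rate
    0.05, and ridge penalty 1e-3 on the GLM; all configurable.
    """

    def __init__(
        self,
        n_trees: int = 500,
        gbm_stages: int = 500,
        gbm_depth: int = 3,
        gbm_learning_rate: float = 0.05,
        glm_ridge: float = 1e-3,
        random_state: int | None = None,
    ):
        self.n_trees = n_trees
        self.gbm_stages = gbm_stages
        self.gbm_depth = gbm_depth
        self.gbm_learning_rate = gbm_learning_rate
        self.glm_ridge = glm_ridge
        self.random_state = random_state

    def _members(self):
        return {
            "random_forest": RandomForestRegressor(
                n_estimators=self.n_trees,
                max_features="sqrt",
                random_state=self.random_state,
                n_jobs=1,
            ),
            "gbm": GradientBoostingRegressor(
                n_estimators=self.gbm_stages,
                max_depth=self.gbm_depth,
                learning_rate=self.gbm_learning_rate,
                random_state=self.random_state,
            ),
            "glm": LogisticRegression(
                C=1.0 / self.glm_ridge,
                solver="lbfgs",
                max_iter=2000,
                random_state=self.random_state,
            ),
        }

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("PU target must be 0 (unlabeled) or 1 (positive)")
        if y.sum() == 0:
            raise ValueError("no positives in training data")
        # constant columns carry no signal and break the GLM scaling
        self.keep_mask_ = X.std(axis=0) > 0
        dropped = int((~self.keep_mask_).sum())
        if dropped:
            logger.warning("PUEnsembleRegressor: dropping %d constant feature columns", dropped)
        Xk = X[:, self.keep_mask_]
        self.models_ = {}
        for name, model in self._members().items():
            if name == "glm":
                mu, sd = Xk.mean(axis=0), Xk.std(axis=0)
                self.glm_loc_, self.glm_scale_ = mu, sd
                model.fit((Xk - mu) / sd, y.astype(int))
            else:
                model.fit(Xk, y)
            self.models_[name] = model
        return self

    def predict_members(self, X) -> dict[str, np.ndarray]:
        """Raw per-model regression outputs (no scaling)."""
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        Xk = X[:, self.keep_mask_]
        out = {}
        for name, model in self.models_.items():
            if name == "glm":
                out[name] = model.predict_proba((Xk - self.glm_loc_) / self.glm_scale_)[:, 1]
            else:
                out[name] = model.predict(Xk)
        return out

    def predict(self, X) -> np.ndarray:
        """Ensemble score: average of per-model outputs min-max scaled over the batch."""
        member = self.predict_members(X)
        scaled = []
        for vals in member.values():
            lo, hi = vals.min(), vals.max()
            scaled.append((vals - lo) / (hi - lo) if hi > lo else np.full_like(vals, 0.5))
        return np.mean(scaled, axis=0)

    def feature_importances(self, feature_names=None) -> pd.DataFrame:
        """Per-model importances: impurity decrease (RF/GBM), |coefficient| (GLM)."""
        check_is_fitted(self)
        cols = np.asarray(
            feature_names if feature_names is not None
            else [f"x{i}" for i in range(self.n_features_in_)]
        )[self.keep_mask_]
        return pd.DataFrame(
            {
                "random_forest": self.models_["random_forest"].feature_importances_,
                "gbm": self.models_["gbm"].feature_importances_,
                "glm": np.abs(self.models_["glm"].coef_.ravel()),
            },
            index=cols,
        )


def ranked_auc(scores: np.ndarray, is_positive: np.ndarray) -> float:
    """Rank (Mann-Whitney) AUC of positives vs unlabeled, midrank ties."""
    scores = np.asarray(scores, dtype=float)
    is_positive = np.asarray(is_positive, dtype=bool)
    n_pos = int(is_positive.sum())
    n_neg = int((~is_positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both positives and unlabeled in the evaluation set")
    ranks = rankdata(scores)
    r_pos = ranks[is_positive].sum()
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


@dataclass
class ModelBundle:
    """A fitted ensemble plus its evaluation reports for one label/stratum."""

    label_name: str
    stratum: str
    estimator: PUEnsembleRegressor
    feature_names: list[str]
    nodes: list[str]
    cv_report: dict = field(default_factory=dict)
    null_report: dict = field(default_factory=dict)
    seed: int | None = None

    def manifest(self) -> dict:
        return {
            "label_set": self.label_name,
            "stratum": self.stratum,
            "n_nodes": len(self.nodes),
            "feature_registry": self.feature_names,
            "seed": self.seed,
            "cv_report": self.cv_report,
            "null_report": self.null_report,
            "params": self.estimator.get_params(),
        }

    def save_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _design(features: pd.DataFrame, nodes: list[str], positives: set[str]):
    X = features.loc[nodes].to_numpy(dtype=float)
    y = np.array([1.0 if v in positives else 0.0 for v in nodes])
    return X, y


def fit_pu_ensemble(
    features: pd.DataFrame,
    labels: LabelSet,
    stratum: str = "all",
    seed: int = 0,
    dataset: StratumDataset | None = None,
    graph: InteractionGraph | None = None,
    estimator: PUEnsembleRegressor | None = None,
) -> ModelBundle:
    """Fit the three-model ensemble on one degree stratum.

    ``dataset`` may be passed directly (from :func:`stratify`); otherwise
    ``graph`` is stratified here.  Refuses strata with < 20 positives.
    """
    if dataset is None:
        if graph is None:
            raise ValueError("pass either a StratumDataset or the graph to stratify")
        dataset = stratify(graph, labels)[stratum]
    if dataset.too_small:
        raise ValueError(
            f"stratum {dataset.stratum.name!r} of {labels.name!r} has "
            f"{dataset.n_positives} positives: too small for effective model building"
        )
    if features.isna().to_numpy().any():
        raise ValueError("feature matrix contains missing values")
    est = clone(estimator) if estimator is not None else PUEnsembleRegressor()
    est.set_params(random_state=seed)
    X, y = _design(features, dataset.nodes, dataset.positives)
    est.fit(X, y)
    return ModelBundle(
        label_name=labels.name,
        stratum=dataset.stratum.name,
        estimator=est,
        feature_names=list(features.columns),
        nodes=list(dataset.nodes),
        seed=seed,
    )


def cross_validate(
    features: pd.DataFrame,
    labels: LabelSet,
    stratum: str = "all",
    k: int | None = None,
    seed: int = 0,
    dataset: StratumDataset | None = None,
    graph: InteractionGraph | None = None,
    estimator: PUEnsembleRegressor | None = None,
) -> dict:
    """k-fold cross-validated ranked AUC (x100) of the ensemble.

    Folds are stratified to preserve the positive fraction; k defaults to
    10, or 5 for the high-degree stratum (its minority class is small).
    Reports per-fold and mean AUC for the ensemble and each member model.
    """
    if dataset is None:
        if graph is None:
            raise ValueError("pass either a StratumDataset or the graph to stratify")
        dataset = stratify(graph, labels)[stratum]
    if k is None:
        k = 5 if dataset.stratum.name == "high" else 10
    if dataset.n_positives < k:
        raise ValueError(
            f"{dataset.n_positives} positives cannot populate {k} folds"
        )
    X, y = _design(features, dataset.nodes, dataset.positives)
    proto = estimator if estimator is not None else PUEnsembleRegressor()
    fold_auc: list[float] = []
    member_auc: dict[str, list[float]] = {"random_forest": [], "gbm": [], "glm": []}
    for attempt in range(10):
        try:
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + attempt)
            folds = list(splitter.split(X, y.astype(int)))
            if any(y[test].sum() == 0 for _, test in folds):
                raise ValueError("empty-positive fold")
            break
        except ValueError:
            if attempt == 9:
                raise
    for fold_i, (train, test) in enumerate(folds):
        est = clone(proto)
        est.set_params(random_state=seed + fold_i)
        est.fit(X[train], y[train])
        is_pos = y[test] == 1
        fold_auc.append(100.0 * ranked_auc(est.predict(X[test]), is_pos))
        for name, vals in est.predict_members(X[test]).items():
            member_auc[name].append(100.0 * ranked_auc(vals, is_pos))
    return {
        "label_set": labels.name,
        "stratum": dataset.stratum.name,
        "k": k,
        "seed": seed,
        "fold_auc": fold_auc,
        "mean_auc": float(np.mean(fold_auc)),
        "member_mean_auc": {m: float(np.mean(v)) for m, v in member_auc.items()},
    }


def random_label_null(
    features: pd.DataFrame,
    labels: LabelSet,
    stratum: str = "all",
    repeats: int = 10,
    seed: int = 0,
    k: int | None = None,
    dataset: StratumDataset | None = None,
    graph: InteractionGraph | None = None,
    estimator: PUEnsembleRegressor | None = None,
) -> dict:
    """Structure-preserving random-label null for the CV AUC.

    For each repeat, the same number of positives is drawn uniformly from
    the stratum's nodes and :func:`cross_validate` is rerun; graph and
    features are untouched.  An honest model should sit near AUC 50 here.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if dataset is None:
        if graph is None:
            raise ValueError("pass either a StratumDataset or the graph to stratify")
        dataset = stratify(graph, labels)[stratum]
    rng = np.random.default_rng(seed)
    per_repeat = []
    for r in range(repeats):
        fake_pos = set(rng.choice(dataset.nodes, size=dataset.n_positives, replace=False))
        fake_ds = StratumDataset(
            label_name=f"{labels.name}:null{r}",
            stratum=dataset.stratum,
            nodes=dataset.nodes,
            positives=fake_pos,
            too_small=dataset.too_small,
        )
        rep = cross_validate(
            features,
            LabelSet(fake_ds.label_name, frozenset(fake_pos)),
            k=k,
            seed=int(rng.integers(2**31 - 1)),
            dataset=fake_ds,
            estimator=estimator,
        )
        per_repeat.append(rep["mean_auc"])
    return {
        "label_set": labels.name,
        "stratum": dataset.stratum.name,
        "repeats": repeats,
        "seed": seed,
        "auc": per_repeat,
        "mean_auc": float(np.mean(per_repeat)),
    }


def percentile_scores(avg_output: np.ndarray) -> np.ndarray:
    """Percentile score: percent of nodes ranked strictly below (ties averaged).

    ``percentile = 100 * (midrank - 1) / N`` -- a score of 78 means 78% of
    proteins rank below the protein.
    """
    avg_output = np.asarray(avg_output, dtype=float)
    n = len(avg_output)
    return 100.0 * (rankdata(avg_output) - 1.0) / n


def score(bundle: ModelBundle, features: pd.DataFrame) -> pd.DataFrame:
    """Score every node of the feature matrix with a fitted bundle.

    Returns a table sorted by descending ensemble output with columns
    ``node, avg_output, rank, percentile``.
    """
    missing = [c for c in bundle.feature_names if c not in features.columns]
    extra = [c for c in features.columns if c not in bundle.feature_names]
    if missing or extra:
        raise ValueError(
            f"feature registry mismatch: missing={missing[:5]}, extra={extra[:5]}"
        )
    X = features[bundle.feature_names].to_numpy(dtype=float)
    avg = bundle.estimator.predict(X)
    pct = percentile_scores(avg)
    out = pd.DataFrame(
        {
            "node": list(features.index),
            "avg_output": avg,
            "rank": rankdata(avg).astype(int) if len(set(avg)) == len(avg)
            else rankdata(avg, method="ordinal").astype(int),
            "percentile": pct,
        }
    )
    return out.sort_values(["avg_output", "node"], ascending=[False, True]).reset_index(drop=True)
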