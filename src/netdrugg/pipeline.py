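"""End-to-end orchestration: config, seed spawning, feature assembly, runs.

A single master seed deterministically spawns independent per-stage seeds
(spin glass, CV folds, label nulls, benchmark generation), so one integer
reproduces an entire run bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import community as community_mod
from . import enrichment as enrichment_mod
from .graphlets import count_orbits, graphlet_features
from .network_io import InteractionGraph, build_graph, read_edge_list, write_graph
from .node_features import articulation_points, topology_features
from .pu_model import (
    LabelSet,
    PUEnsembleRegressor,
    cross_validate,
    fit_pu_ensemble,
    random_label_null,
    score,
    stratify,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "spawn_seed", "compute_features", "run_features", "run_full"]


def spawn_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31 - 1)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (YAML-serializable)."""

    graph: str = ""
    positives: dict = field(default_factory=dict)  # label-set name -> path
    out_dir: str = "netdrugg_run"
    with_topology: bool = True
    with_community: bool = True
    with_graphlets: bool = True
    strata: list = field(default_factory=lambda: ["all"])
    k_folds: int | None = None     # None: 10, or 5 for the high stratum
    null_repeats: int = 10
    walktrap_t: int = 4
    spinglass_spins: int = 50
    n_trees: int = 500
    gbm_stages: int = 500
    gbm_depth: int = 3
    gbm_learning_rate: float = 0.05
    glm_ridge: float = 1e-3
    seed: int = 42

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def estimator(self) -> PUEnsembleRegressor:
        return PUEnsembleRegressor(
            n_trees=self.n_trees,
            gbm_stages=self.gbm_stages,
            gbm_depth=self.gbm_depth,
            gbm_learning_rate=self.gbm_learning_rate,
            glm_ridge=self.glm_ridge,
        )


def _write_tsv(df: pd.DataFrame, path, index_label: str | None = "node") -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", index_label=index_label)


def compute_features(g: InteractionGraph, config: RunConfig | None = None):
    """Assemble the full feature matrix (topo.* + comm.* + orbit.* + graphlet.*).

    Returns ``(features, partitions)`` -- the community partitions are reused
    by the enrichment stage.
    """
    config = config or RunConfig()
    blocks = []
    partitions = []
    t0 = time.time()
    if config.with_topology:
        blocks.append(topology_features(g))
        logger.info("features: topology block done (%.1fs)", time.time() - t0)
    if config.with_community:
        wt = community_mod.walktrap(g, t=config.walktrap_t)
        sg = community_mod.spinglass(
            g, spins=min(config.spinglass_spins, g.n),
            seed=spawn_seed(config.seed, "spinglass"),
        )
        partitions = [wt, sg]
        blocks.append(community_mod.community_features(g, partitions))
        logger.info("features: community block done (%.1fs)", time.time() - t0)
    if config.with_graphlets:
        gdv = count_orbits(g)
        blocks.append(graphlet_features(g, gdv))
        logger.info("features: graphlet block done (%.1fs)", time.time() - t0)
    if not blocks:
        raise ValueError("all feature blocks disabled")
    features = pd.concat(blocks, axis=1)
    if features.isna().to_numpy().any():
        raise FloatingPointError("feature assembly produced missing values")
    return features, partitions


def run_features(config: RunConfig, g: InteractionGraph | None = None) -> pd.DataFrame:
    """Compute and write features.tsv (+ registry manifest) for a run config."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if g is None:
        g = build_graph(read_edge_list(config.graph), drop_ambiguous=True)
    features, _ = compute_features(g, config)
    _write_tsv(features, out / "features.tsv")
    with open(out / "feature_registry.json", "w") as fh:
        json.dump({"columns": list(features.columns), "n_nodes": g.n}, fh, indent=2)
        fh.write("\n")
    return features


def run_full(config: RunConfig, g: InteractionGraph | None = None,
             label_sets: dict[str, LabelSet] | None = None) -> dict:
    """The whole pipeline: graph -> features -> models -> scores -> enrichment.

    Writes everything under ``config.out_dir`` and returns a result dict
    with the fitted bundles and reports.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if label_sets is None:
        if not config.positives:
            raise ValueError("no positive label lists configured")
        label_sets = {
            name: LabelSet.from_file(path, name=name)
            for name, path in config.positives.items()
        }
    if g is None:
        g = build_graph(read_edge_list(config.graph), drop_ambiguous=True)
    for name, ls in label_sets.items():
        label_sets[name] = ls.restrict(g.names)
        if not label_sets[name].positives:
            raise ValueError(f"label set {name!r} has no positives on the graph")

    write_graph(g, out / "graph.tsv", out / "graph_provenance.json")
    features, partitions = compute_features(g, config)
    _write_tsv(features, out / "features.tsv")
    if partitions:
        pdump = pd.DataFrame(
            {f"{p.algorithm}_id": [p.assignment[v] for v in g.names] for p in partitions},
            index=g.names,
        )
        _write_tsv(pdump, out / "partitions.tsv")

    manifest: dict = {"config": asdict(config), "seeds": {}, "models": {}}
    results: dict = {"graph": g, "features": features, "partitions": partitions,
                     "models": {}, "predictions": {}, "enrichment": {}}
    aps = articulation_points(g)
    estimator = config.estimator()
    for name, labels in label_sets.items():
        strata = stratify(g, labels)
        for sname in config.strata:
            ds = strata[sname]
            if ds.too_small:
                logger.warning("run_full: skipping %s/%s (%d positives)", name, sname, ds.n_positives)
                continue
            tag = f"{name}.{sname}"
            fit_seed = spawn_seed(config.seed, f"fit:{tag}")
            cv_seed = spawn_seed(config.seed, f"cv:{tag}")
            null_seed = spawn_seed(config.seed, f"null:{tag}")
            manifest["seeds"][tag] = {"fit": fit_seed, "cv": cv_seed, "null": null_seed}
            bundle = fit_pu_ensemble(features, labels, dataset=ds, seed=fit_seed,
                                     estimator=estimator)
            bundle.cv_report = cross_validate(features, labels, dataset=ds,
                                              k=config.k_folds, seed=cv_seed,
                                              estimator=estimator)
            if config.null_repeats > 0:
                bundle.null_report = random_label_null(
                    features, labels, dataset=ds, repeats=config.null_repeats,
                    seed=null_seed, k=config.k_folds, estimator=estimator,
                )
            bundle.save_manifest(out / f"model_{tag}.json")
            _write_tsv(
                bundle.estimator.feature_importances(bundle.feature_names),
                out / f"importances_{tag}.tsv", index_label="feature",
            )
            manifest["models"][tag] = {
                "cv_mean_auc": bundle.cv_report["mean_auc"],
                "null_mean_auc": bundle.null_report.get("mean_auc") if bundle.null_report else None,
            }
            results["models"][tag] = bundle
            if sname == "all":
                preds = score(bundle, features)
                preds.to_csv(out / f"predictions_{name}.tsv", sep="\t",
                             float_format="%.10g", index=False)
                if name == next(iter(label_sets)):
                    preds.to_csv(out / "predictions.tsv", sep="\t",
                                 float_format="%.10g", index=False)
                results["predictions"][name] = preds

        # enrichment reports on the full network
        enr: dict = {}
        enr["feature_compare"] = enrichment_mod.feature_compare(features, labels)
        _write_tsv(enr["feature_compare"], out / f"enrichment_features_{name}.tsv", index_label="item")
        if config.with_graphlets:
            orbit_cols = [c for c in features.columns if c.startswith("orbit.")]
            gdv = features[orbit_cols].rename(columns=lambda c: c.split(".", 1)[1])
            enr["orbits"] = enrichment_mod.orbit_enrichment(gdv, labels)
            _write_tsv(enr["orbits"], out / f"enrichment_orbits_{name}.tsv", index_label="item")
        if partitions:
            report, curve = enrichment_mod.community_enrichment(partitions[0], labels, n_nodes=g.n)
            enr["communities"], enr["coverage"] = report, curve
            _write_tsv(report, out / f"enrichment_communities_{name}.tsv", index_label="community")
            curve.to_csv(out / f"coverage_{name}.tsv", sep="\t", float_format="%.10g", index=False)
        enr["articulation"] = enrichment_mod.articulation_enrichment(g, aps, labels)
        results["enrichment"][name] = enr

    config.to_yaml(out / "config.yaml")
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    results["manifest"] = manifest
    return results
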