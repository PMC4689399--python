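"""Target-set versus background comparisons.

Everything here contrasts a node set of interest (e.g. cancer-drug targets)
with the rest of the interactome: per-orbit graphlet enrichment, per-community
fold enrichment with a target coverage curve, articulation-point enrichment
(Fisher), per-feature distribution shifts (Mann-Whitney), and z-score
"network profiles" for radar-style comparison of individual proteins.
P-values within a report are Benjamini-Hochberg adjusted; raw p is retained.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .community import CommunityPartition
from .network_io import InteractionGraph
from .pu_model import LabelSet

__all__ = [
    "orbit_enrichment",
    "community_enrichment",
    "articulation_enrichment",
    "feature_compare",
    "network_profile",
]


def _split(values: pd.DataFrame, targets: set[str]):
    in_t = values.index.isin(targets)
    if not in_t.any():
        raise ValueError("empty target set")
    return values.loc[in_t], values.loc[~in_t]


def _mannwhitney_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def orbit_enrichment(gdv: pd.DataFrame, targets: LabelSet | set) -> pd.DataFrame:
    """Per-orbit enrichment of targets over background.

    ``log2((mean count in targets + 1) / (mean count in background + 1))``
    (the pseudocount bounds the log-fold on sparse orbits), with a
    two-sided Mann-Whitney p-value on the per-node counts.  If the target
    set is the whole index, background defaults to the same set and the
    log-fold is exactly 0.
    """
    tset = targets.positives if isinstance(targets, LabelSet) else set(targets)
    in_t = gdv.index.isin(tset)
    if not in_t.any():
        raise ValueError("empty target set")
    tgt = gdv.loc[in_t]
    bg = gdv.loc[~in_t] if (~in_t).any() else tgt
    rows = []
    for col in gdv.columns:
        a = tgt[col].to_numpy(dtype=float)
        b = bg[col].to_numpy(dtype=float)
        rows.append(
            {
                "item": col,
                "target_mean": a.mean(),
                "background_mean": b.mean(),
                "log2_enrichment": np.log2((a.mean() + 1.0) / (b.mean() + 1.0)),
                "p": _mannwhitney_p(a, b),
            }
        )
    out = pd.DataFrame(rows).set_index("item")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def community_enrichment(
    p: CommunityPartition,
    targets: LabelSet | set,
    n_nodes: int | None = None,
    min_size: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-community target fold enrichment plus the coverage curve.

    fold = (targets in c / |c|) / (|targets| / N) with a hypergeometric
    (over-representation) p-value.  Communities of size < ``min_size`` are
    excluded from the ranked report.  The coverage curve is the cumulative
    fraction of all targets as communities are taken in order of
    decreasing target count (all communities, so it ends at 1).
    """
    tset = targets.positives if isinstance(targets, LabelSet) else set(targets)
    nodes = list(p.assignment)
    tset = tset & set(nodes)
    if not tset:
        raise ValueError("empty target set")
    n = n_nodes or len(nodes)
    t = len(tset)
    sizes = p.community_sizes()
    rows = []
    for c, size in sizes.items():
        members = p.members(c)
        k = sum(1 for v in members if v in tset)
        fold = (k / size) / (t / n)
        pval = float(stats.hypergeom.sf(k - 1, n, t, size))
        rows.append({"community": c, "size": size, "targets": k, "fold": fold, "p": pval})
    report = pd.DataFrame(rows).set_index("community")
    coverage_all = report.sort_values(["targets", "size"], ascending=[False, True])
    curve = pd.DataFrame(
        {
            "community": coverage_all.index,
            "targets": coverage_all["targets"].to_numpy(),
            "cumulative_fraction": coverage_all["targets"].cumsum().to_numpy() / t,
        }
    ).reset_index(drop=True)
    report = report[report["size"] >= min_size].sort_values("fold", ascending=False)
    if len(report):
        report["q"] = multipletests(report["p"], method="fdr_bh")[1]
    return report, curve


def articulation_enrichment(
    g: InteractionGraph, aps: set[str], targets: LabelSet | set
) -> dict:
    """One-sided Fisher's exact test for articulation-point over-representation.

    2x2 table: [targets that are/aren't articulation points; background
    that are/aren't].  Returns the two proportions and the p-value.
    """
    tset = targets.positives if isinstance(targets, LabelSet) else set(targets)
    tset = tset & set(g.names)
    bg = set(g.names) - tset
    a = len(tset & aps)
    b = len(tset - aps)
    c = len(bg & aps)
    d = len(bg - aps)
    _, pval = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return {
        "target_ap": a,
        "target_non_ap": b,
        "background_ap": c,
        "background_non_ap": d,
        "target_proportion": a / max(a + b, 1),
        "background_proportion": c / max(c + d, 1),
        "p": float(pval),
    }


def feature_compare(features: pd.DataFrame, targets: LabelSet | set) -> pd.DataFrame:
    """Per-feature target/background contrast: means, Mann-Whitney p, BH q,
    and box-plot quartile summaries for both groups."""
    tset = targets.positives if isinstance(targets, LabelSet) else set(targets)
    tgt, bg = _split(features, tset)
    if bg.empty:
        bg = tgt
    rows = []
    for col in features.columns:
        a = tgt[col].to_numpy(dtype=float)
        b = bg[col].to_numpy(dtype=float)
        qa = np.percentile(a, [25, 50, 75])
        qb = np.percentile(b, [25, 50, 75])
        rows.append(
            {
                "item": col,
                "target_mean": a.mean(),
                "background_mean": b.mean(),
                "target_q1": qa[0], "target_median": qa[1], "target_q3": qa[2],
                "background_q1": qb[0], "background_median": qb[1], "background_q3": qb[2],
                "p": _mannwhitney_p(a, b),
            }
        )
    out = pd.DataFrame(rows).set_index("item")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


DEFAULT_PROFILE_PANEL = (
    "topo.degree",
    "topo.pagerank",
    "topo.closeness",
    "topo.betweenness",
    "topo.burt_constraint",
    "topo.clustering_coefficient",
    "comm.walktrap.vertex_modularity",
    "comm.walktrap.community_size",
)


def network_profile(
    features: pd.DataFrame, nodes: list[str], panel: tuple[str, ...] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Radar-style z-score profiles and their pairwise Pearson similarity.

    Each requested node's panel features are standardized against the
    background (all-node) mean and standard deviation; profile similarity
    is the Pearson correlation of two z-vectors.
    """
    panel = tuple(panel or [c for c in DEFAULT_PROFILE_PANEL if c in features.columns])
    unknown = [v for v in nodes if v not in features.index]
    if unknown:
        raise KeyError(f"unknown node(s): {unknown[:5]}")
    sub = features[list(panel)]
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0).replace(0.0, 1.0)
    z = (sub.loc[nodes] - mu) / sd
    k = len(nodes)
    sim = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            zi, zj = z.iloc[i].to_numpy(), z.iloc[j].to_numpy()
            if np.allclose(zi, zj):
                r = 1.0
            elif zi.std() == 0 or zj.std() == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(zi, zj)[0, 1])
            sim[i, j] = sim[j, i] = r
    return z, pd.DataFrame(sim, index=nodes, columns=nodes)
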