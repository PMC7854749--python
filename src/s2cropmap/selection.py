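"""Two-step optimal-feature selection.

Step 1 ranks candidates by Mean Decrease Impurity (Gini importance) from a
random forest; step 2 clusters the top 50 on their Spearman rank-order
correlation structure (Ward linkage, flat cut at height 1) and keeps the
highest-MDI member of each cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.ensemble import RandomForestClassifier

log = logging.getLogger(__name__)

TOP_K = 50


@dataclass
class SelectionResult:
    ranked: list[str]                 # all candidates, MDI descending
    mdi: pd.Series                    # per-candidate importance (sums to 1)
    top: list[str]                    # first min(TOP_K, n) of ``ranked``
    clusters: dict[str, int]          # top feature -> cluster id
    selected: list[str]               # one max-MDI representative per cluster
    seed: int = 0
    config: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rank, name in enumerate(self.ranked, start=1):
            rows.append({
                "feature": name,
                "mdi": float(self.mdi[name]),
                "rank": rank,
                "cluster": self.clusters.get(name, -1),
                "selected": name in self.selected,
            })
        return pd.DataFrame(rows)


def _forest(seed: int, n_trees: int = 100, min_leaf: int = 10) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees, min_samples_leaf=min_leaf, max_features="sqrt",
        bootstrap=True, max_samples=0.5, oob_score=False,
        random_state=seed, n_jobs=1,
    )


def rank_mdi(fm: pd.DataFrame, labels, seed: int = 0, *,
             n_trees: int = 100, min_leaf: int = 10) -> pd.Series:
    """Impurity-based importances of all features, deterministic per seed."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("MDI ranking needs at least 2 classes")
    clf = _forest(seed, n_trees, min_leaf)
    clf.fit(fm.to_numpy(), y)
    return pd.Series(clf.feature_importances_, index=fm.columns)


def cluster_select(fm_top: pd.DataFrame, mdi: pd.Series, *,
                   threshold: float = 1.0, method: str = "ward",
                   criterion: str = "distance") -> tuple[dict[str, int], list[str]]:
    """Cluster features on Spearman correlations; keep one per cluster.

    Each feature's vector is its row of the feature-feature Spearman
    correlation matrix; clusters are flat-cut from a Ward dendrogram at the
    given height (``criterion='distance'``, default) or with scipy's
    inconsistency depth criterion (``criterion='inconsistent'``).
    """
    cols = list(fm_top.columns)
    if len(cols) < 2:
        return {cols[0]: 1} if cols else {}, list(cols)
    # Spearman = Pearson on ranks; the pandas route keeps constant columns
    # as NaN rows instead of collapsing the whole matrix
    corr = fm_top.rank(axis=0, method="average").corr(method="pearson").to_numpy()
    bad = ~np.isfinite(corr)
    if bad.any():
        log.warning("constant feature(s) produced undefined Spearman "
                    "correlations; treating them as uncorrelated")
        corr = np.where(bad, 0.0, corr)
        np.fill_diagonal(corr, 1.0)
    z = linkage(corr, method=method)
    flat = fcluster(z, t=threshold, criterion=criterion)
    clusters = dict(zip(cols, (int(c) for c in flat)))
    selected = []
    for cid in sorted(set(clusters.values())):
        members = [c for c in cols if clusters[c] == cid]
        # max MDI; ties resolved by rank (column) order
        selected.append(max(members, key=lambda c: (mdi[c], -cols.index(c))))
    selected.sort(key=cols.index)
    return clusters, selected


def select_features(fm: pd.DataFrame, labels, seed: int = 0, *,
                    top_k: int = TOP_K, threshold: float = 1.0,
                    method: str = "ward", criterion: str = "distance",
                    n_trees: int = 100, min_leaf: int = 10) -> SelectionResult:
    """Full two-step selection over a feature bank."""
    mdi = rank_mdi(fm, labels, seed, n_trees=n_trees, min_leaf=min_leaf)
    ranked = list(mdi.sort_values(ascending=False, kind="stable").index)
    top = ranked[: min(top_k, len(ranked))]
    clusters, selected = cluster_select(fm[top], mdi, threshold=threshold,
                                        method=method, criterion=criterion)
    return SelectionResult(ranked, mdi, top, clusters, selected, seed,
                           {"top_k": top_k, "threshold": threshold,
                            "method": method, "criterion": criterion})
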