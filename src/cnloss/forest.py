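"""Random-forest gene ranking: inactivated vs control as a binary
classification task over the filtered log2-CPM profile.

The ensemble is a seeded bagging of CART classification trees (Gini
splitting, sqrt(G) candidate features per split, no depth limit — the
classical random-forest recipe), with explicit per-tree bootstrap
bookkeeping so that out-of-bag (OOB) error, OOB permutation importance
(mean decrease in accuracy, MDA) and per-tree total Gini decreases (mean
decrease in Gini, MDG) are all available.  Because inactivated sets are
typically much smaller than control sets, trees use balanced class weights
by default.

MDG is reported as a percentage of the forest total (raw impurity sums are
implementation-scale-dependent; percentages are comparable across runs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .io import RF_COLUMNS


@dataclass
class ForestEnsemble:
    """A trained bagged-tree ensemble with out-of-bag bookkeeping."""

    trees: list = field(repr=False)
    bootstrap_indices: list = field(repr=False)   # per-tree in-bag sample idx
    classes_: np.ndarray = None                   # type: ignore[assignment]
    n_samples: int = 0
    n_features: int = 0
    oob_accuracy: float = float("nan")
    mdg_raw: np.ndarray = None                    # type: ignore[assignment]

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def train_forest(x: np.ndarray, labels: np.ndarray, n_trees: int = 500,
                 seed: int = 0, class_weight: str | None = "balanced"
                 ) -> ForestEnsemble:
    """Train the ensemble on a samples x genes matrix.

    Each tree sees a bootstrap resample of the samples and sqrt(G) candidate
    features per split.  Deterministic for a fixed seed.  Requires both
    classes to be present with >= 2 samples each.
    """
    x = np.ascontiguousarray(x, dtype=np.float32)  # sklearn's native dtype
    labels = np.asarray(labels)
    n, g = x.shape
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("forest training needs both classes present")
    if counts.min() < 2:
        raise ValueError("each class needs >= 2 samples")
    rng = np.random.default_rng(seed)
    trees, boots = [], []
    mdg = np.zeros(g)
    oob_votes = np.zeros((n, len(classes)))
    for _ in range(n_trees):
        idx = rng.integers(0, n, size=n)
        tree_seed = int(rng.integers(0, 2**31 - 1))
        tree = DecisionTreeClassifier(
            criterion="gini", max_features="sqrt",
            class_weight=class_weight, random_state=tree_seed)
        tree.fit(x[idx], labels[idx])
        trees.append(tree)
        boots.append(idx)
        mdg += tree.tree_.compute_feature_importances(normalize=False)
        oob = np.ones(n, dtype=bool)
        oob[idx] = False
        if oob.any():
            pred = tree.predict(x[oob], check_input=False)
            cls_idx = np.searchsorted(classes, pred)
            oob_votes[np.flatnonzero(oob), cls_idx] += 1
    mdg /= n_trees
    voted = oob_votes.sum(axis=1) > 0
    oob_pred = classes[np.argmax(oob_votes, axis=1)]
    oob_acc = float(np.mean(oob_pred[voted] == labels[voted])) if voted.any() \
        else float("nan")
    return ForestEnsemble(trees=trees, bootstrap_indices=boots,
                          classes_=classes, n_samples=n, n_features=g,
                          oob_accuracy=oob_acc, mdg_raw=mdg)


def gini_ranking(ensemble: ForestEnsemble, gene_ids: list[str],
                 mda: np.ndarray | None = None) -> pd.DataFrame:
    """Importance table ranked by mean decrease in Gini.

    ``mdg_percent`` is the per-gene mean impurity decrease normalized to sum
    to 100 over genes; rank 1 is the largest, ties broken lexicographically
    by gene id.
    """
    if len(gene_ids) != ensemble.n_features:
        raise ValueError("gene id list does not match the trained ensemble")
    mdg = ensemble.mdg_raw
    total = mdg.sum()
    mdg_percent = 100.0 * mdg / total if total > 0 else np.zeros_like(mdg)
    table = pd.DataFrame({
        "gene": gene_ids,
        "mdg_percent": mdg_percent,
        "mda": mda if mda is not None else np.nan,
    })
    table = (table.sort_values(["mdg_percent", "gene"],
                               ascending=[False, True], kind="mergesort")
             .reset_index(drop=True))
    table["rank"] = np.arange(1, len(table) + 1)
    return table.loc[:, RF_COLUMNS]


def mda_importance(ensemble: ForestEnsemble, x: np.ndarray,
                   labels: np.ndarray, seed: int = 0) -> np.ndarray:
    """Out-of-bag permutation importance (mean decrease in accuracy).

    For every tree and gene, the gene's values are permuted among that
    tree's OOB samples and the drop in the tree's OOB accuracy is recorded;
    the per-gene drops are averaged over trees.  Uninformative genes hover
    around zero (and may go slightly negative).
    """
    x = np.ascontiguousarray(x, dtype=np.float32)
    labels = np.asarray(labels)
    n, g = x.shape
    rng = np.random.default_rng(seed)
    drops = np.zeros(g)
    used = np.zeros(g)
    for tree, idx in zip(ensemble.trees, ensemble.bootstrap_indices):
        oob = np.ones(n, dtype=bool)
        oob[idx] = False
        m = int(oob.sum())
        if m < 2:
            continue
        x_oob = x[oob]
        y_oob = labels[oob]
        base = np.mean(tree.predict(x_oob, check_input=False) == y_oob)
        x_perm = x_oob.copy()
        for j in range(g):
            saved = x_perm[:, j].copy()
            x_perm[:, j] = saved[rng.permutation(m)]  # fresh draw per gene
            acc = np.mean(tree.predict(x_perm, check_input=False) == y_oob)
            drops[j] += base - acc
            used[j] += 1
            x_perm[:, j] = saved
    with np.errstate(invalid="ignore"):
        return np.where(used > 0, drops / np.maximum(used, 1), 0.0)


def de_rf_comparison(de: pd.DataFrame, rf: pd.DataFrame, top_k: int = 100,
                     alpha: float = 0.05) -> tuple[int, pd.DataFrame]:
    """How many of the top-k forest genes are significant in the DE analysis.

    Returns the overlap count and a paired series (forest rank, Gini share,
    DE q-value, significance flag) for the top-k genes, ready for the
    rank-vs-significance plot.
    """
    if set(de["gene"]) != set(rf["gene"]):
        raise ValueError("DE and RF tables cover different gene universes")
    if top_k > len(rf):
        import warnings
        warnings.warn(f"top_k={top_k} exceeds {len(rf)} genes; clipping")
        top_k = len(rf)
    top = rf.sort_values("rank", kind="mergesort").head(top_k)
    qmap = de.set_index("gene")["q"]
    series = pd.DataFrame({
        "rank": top["rank"].to_numpy(),
        "gene": top["gene"].to_numpy(),
        "mdg_percent": top["mdg_percent"].to_numpy(),
        "de_q": qmap.reindex(top["gene"]).to_numpy(),
    })
    series["significant"] = series["de_q"] < alpha
    return int(series["significant"].sum()), series
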