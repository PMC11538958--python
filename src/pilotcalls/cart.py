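"""Gini-split classification tree over the eight acoustic predictors.

The tree is grown greedily: every split considers all eight predictors
(``Dur``, ``BW``, ``Peak``, ``Range``, ``Trend``, ``Inflec``, ``Segm``,
``El``) and all midpoint thresholds between consecutive sorted unique
values, choosing the pair that maximizes the decrease in Gini impurity
``1 - sum(p_k^2)``.  Ties break deterministically by predictor order (as
listed above) and then by the lower threshold, so refitting identical
data yields an identical tree.  Auxiliary frequency statistics (min /
max / start / end frequency) are rejected by the schema: the tree
classifies calls by contour *shape*, not by position in frequency space.

The "global Gini index" reported with a fitted tree is the unweighted
arithmetic mean of the node impurities over all nodes; sample-weighted
and internal-/leaf-only variants are available since the convention is
not standardized.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: the eight admitted predictors, in tie-break order
PREDICTORS = ("Dur", "BW", "Peak", "Range", "Trend", "Inflec", "Segm", "El")

#: mapping from the canonical feature-table columns to predictor names
COLUMN_TO_PREDICTOR = {
    "dur_s": "Dur", "bw_hz": "BW", "peak_hz": "Peak", "range_ratio": "Range",
    "trend_ratio": "Trend", "n_inflections": "Inflec", "n_segments": "Segm",
    "n_elements": "El",
}


@dataclass
class TreeNode:
    """One node of the fitted tree (leaf iff no children)."""

    gini: float
    n: int
    counts: dict
    predicted_type: str
    split_feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None   # condition feature < threshold true
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def nodes(self):
        yield self
        if not self.is_leaf:
            yield from self.left.nodes()
            yield from self.right.nodes()


@dataclass
class TreeConfig:
    max_depth: int = 10
    min_leaf: int = 1
    min_impurity_decrease: float = 0.0


def gini_impurity(counts) -> float:
    """Gini impurity ``1 - sum((n_k / N)^2)`` of a class-count vector."""
    c = np.asarray(list(counts.values()) if isinstance(counts, dict) else counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("negative class count")
    total = c.sum()
    if total == 0:
        raise ValueError("gini impurity undefined for an empty node")
    p = c / total
    return float(1.0 - np.sum(p ** 2))


def _node_stats(y: np.ndarray):
    labels, counts = np.unique(y, return_counts=True)
    order = np.argsort(labels)
    counts_d = {str(labels[i]): int(counts[i]) for i in order}
    # majority prediction; ties toward the lexicographically smaller label
    best = max(counts_d.items(), key=lambda kv: (kv[1], ))
    top = max(counts_d.values())
    pred = min(k for k, v in counts_d.items() if v == top)
    return gini_impurity(counts_d), counts_d, pred


def _best_split(X: np.ndarray, y: np.ndarray, min_leaf: int):
    """Exhaustive (feature, threshold) search maximizing Gini decrease."""
    n = y.size
    parent_gini, _, _ = _node_stats(y)
    best = None  # (decrease, feat_idx, threshold)
    for fi in range(X.shape[1]):
        vals = X[:, fi]
        uniq = np.unique(vals)
        if uniq.size < 2:
            continue
        for thr in (uniq[:-1] + uniq[1:]) / 2.0:
            mask = vals < thr
            nl = int(mask.sum())
            if nl < min_leaf or n - nl < min_leaf:
                continue
            gl, _, _ = _node_stats(y[mask])
            gr, _, _ = _node_stats(y[~mask])
            decrease = parent_gini - (nl * gl + (n - nl) * gr) / n
            key = (decrease, -fi, -thr)
            if best is None or key > (best[0], -best[1], -best[2]):
                best = (decrease, fi, float(thr))
    return best


def _grow(X: np.ndarray, y: np.ndarray, cfg: TreeConfig, depth: int) -> TreeNode:
    gini, counts, pred = _node_stats(y)
    node = TreeNode(gini, int(y.size), counts, pred)
    if gini == 0.0 or depth >= cfg.max_depth or y.size < 2 * cfg.min_leaf:
        return node
    best = _best_split(X, y, cfg.min_leaf)
    if best is None or best[0] <= cfg.min_impurity_decrease or best[0] <= 0:
        return node
    _, fi, thr = best
    mask = X[:, fi] < thr
    node.split_feature = PREDICTORS[fi]
    node.threshold = thr
    node.left = _grow(X[mask], y[mask], cfg, depth + 1)
    node.right = _grow(X[~mask], y[~mask], cfg, depth + 1)
    return node


def _predictor_matrix(features: pd.DataFrame) -> np.ndarray:
    cols = dict(features.columns.to_series())
    renamed = features.rename(columns=COLUMN_TO_PREDICTOR)
    extra = [c for c in renamed.columns
             if c not in PREDICTORS and c not in ("call_id", "type", "label")]
    if extra:
        raise ValueError(
            f"only the eight predictors {list(PREDICTORS)} are admitted; "
            f"drop auxiliary columns {extra} (frequency position must not drive the tree)")
    missing = [c for c in PREDICTORS if c not in renamed.columns]
    if missing:
        raise ValueError(f"missing predictors: {missing}")
    X = renamed[list(PREDICTORS)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("predictors contain non-finite values")
    return X


def fit_tree(features: pd.DataFrame, labels, config: TreeConfig | None = None) -> TreeNode:
    """Fit the classification tree.

    ``features`` holds exactly the eight predictor columns (canonical
    feature-table names or the short predictor names), plus optionally
    ``call_id``; ``labels`` gives the call-type label per row.  A single
    class yields a trivial leaf with a warning.
    """
    cfg = config or TreeConfig()
    X = _predictor_matrix(features)
    y = np.asarray([str(l) for l in labels])
    if y.size != X.shape[0]:
        raise ValueError("labels length does not match features")
    if np.unique(y).size < 2:
        warnings.warn("single class: fitting a trivial leaf tree", stacklevel=2)
    return _grow(X, y, cfg, depth=0)


def global_gini(tree: TreeNode, nodes: str = "all", weighted: bool = False) -> float:
    """Average Gini impurity over the tree's nodes.

    ``nodes`` selects ``"all"`` (default), ``"internal"`` or
    ``"leaves"``; ``weighted=True`` weights each node by its sample
    count instead of the default unweighted mean.
    """
    sel = [nd for nd in tree.nodes()
           if nodes == "all"
           or (nodes == "internal" and not nd.is_leaf)
           or (nodes == "leaves" and nd.is_leaf)]
    if not sel:
        raise ValueError(f"tree has no {nodes} nodes")
    if weighted:
        w = np.array([nd.n for nd in sel], dtype=float)
        return float(np.average([nd.gini for nd in sel], weights=w))
    return float(np.mean([nd.gini for nd in sel]))


def classify(tree: TreeNode, features) -> tuple[str, list]:
    """Deterministic root-to-leaf descent for one call.

    ``features`` maps predictor names (short names or canonical column
    names) to values; missing predictors raise ``KeyError`` naming the
    predictor.  Returns ``(predicted_type, path)`` with the path as
    human-readable split conditions.
    """
    feat = {COLUMN_TO_PREDICTOR.get(k, k): v for k, v in dict(features).items()}
    node = tree
    path = []
    while not node.is_leaf:
        if node.split_feature not in feat:
            raise KeyError(f"missing predictor {node.split_feature!r}")
        v = float(feat[node.split_feature])
        if v < node.threshold:
            path.append(f"{node.split_feature} < {node.threshold:g}")
            node = node.left
        else:
            path.append(f"{node.split_feature} >= {node.threshold:g}")
            node = node.right
    return node.predicted_type, path


def classify_table(tree: TreeNode, features: pd.DataFrame) -> list:
    """Predictions for every row of a feature table."""
    renamed = features.rename(columns=COLUMN_TO_PREDICTOR)
    return [classify(tree, row[list(PREDICTORS)]) [0]
            for _, row in renamed.iterrows()]


def tree_to_dict(node: TreeNode) -> dict:
    d = {"gini": node.gini, "n": node.n, "counts": node.counts,
         "prediction": node.predicted_type}
    if not node.is_leaf:
        d.update({"feature": node.split_feature, "threshold": node.threshold,
                  "left": tree_to_dict(node.left), "right": tree_to_dict(node.right)})
    return d


def tree_to_json(tree: TreeNode, path=None) -> str:
    text = json.dumps(tree_to_dict(tree), indent=2, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def render_tree(node: TreeNode, indent: str = "") -> str:
    """Indented ASCII rendering with `<`/`>=` split annotations."""
    if node.is_leaf:
        return f"{indent}leaf: {node.predicted_type} (n={node.n}, gini={node.gini:.3f})\n"
    out = (f"{indent}{node.split_feature} < {node.threshold:g} "
           f"(n={node.n}, gini={node.gini:.3f})\n")
    out += render_tree(node.left, indent + "  ")
    out += f"{indent}{node.split_feature} >= {node.threshold:g}\n"
    out += render_tree(node.right, indent + "  ")
    return out
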