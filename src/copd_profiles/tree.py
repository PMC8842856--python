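"""Decision-tree allocation of COPD profiles.

Contains a from-scratch CART (greedy binary splits minimising Gini impurity,
thresholds at midpoints of sorted unique values, ``value < threshold`` goes
left), a bagged-tree permutation-importance ranker, the fixed published
3-variable allocation tree (CAT 18 / age 65 / FEV1 48 %pred) and Cohen's
kappa agreement with its interpretation bands.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class NotClassifiableError(ValueError):
    """A record lacks a variable the tree needs."""


@dataclass
class TreeNode:
    """Internal split or leaf. Splits send ``value < threshold`` left and
    ``value >= threshold`` right."""

    variable: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    label: int | None = None
    counts: dict[int, int] = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return self.variable is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"leaf": self.label, "counts": {str(k): v for k, v in self.counts.items()}}
        return {
            "variable": self.variable,
            "threshold": self.threshold,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "TreeNode":
        if "leaf" in data:
            return cls(label=data["leaf"], counts={int(k): v for k, v in data.get("counts", {}).items()})
        return cls(
            variable=data["variable"],
            threshold=data["threshold"],
            left=cls.from_dict(data["left"]),
            right=cls.from_dict(data["right"]),
        )


@dataclass
class TreeModel:
    """A fitted (or fixed) binary classification tree over named variables."""

    root: TreeNode
    variables: tuple[str, ...]
    depth: int
    training_accuracy: float | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "variables": list(self.variables),
                "depth": self.depth,
                "training_accuracy": self.training_accuracy,
                "root": self.root.to_dict(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "TreeModel":
        data = json.loads(text)
        return cls(
            root=TreeNode.from_dict(data["root"]),
            variables=tuple(data["variables"]),
            depth=data["depth"],
            training_accuracy=data.get("training_accuracy"),
        )

    def splits(self) -> list[tuple[int, str, float]]:
        """All internal splits as (depth-from-root, variable, threshold),
        in breadth-first order."""
        out, queue = [], [(0, self.root)]
        while queue:
            level, node = queue.pop(0)
            if not node.is_leaf:
                out.append((level, node.variable, float(node.threshold)))
                queue.append((level + 1, node.left))
                queue.append((level + 1, node.right))
        return out


def classify(model: TreeModel, record: Mapping) -> int:
    """Deterministic descent: value < threshold goes left, >= goes right."""
    node = model.root
    while not node.is_leaf:
        value = record.get(node.variable) if hasattr(record, "get") else record[node.variable]
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise NotClassifiableError(f"record lacks split variable '{node.variable}'")
        node = node.left if value < node.threshold else node.right
    return int(node.label)


def predict(model: TreeModel, data: pd.DataFrame) -> np.ndarray:
    """Vectorised classification of a table of records."""
    for _, var, _ in model.splits():
        if var not in data.columns:
            raise NotClassifiableError(f"input lacks split variable '{var}'")
        if data[var].isna().any():
            raise NotClassifiableError(f"missing values in split variable '{var}'")
    n = len(data)
    out = np.empty(n, dtype=int)
    index = np.arange(n)

    def descend(node: TreeNode, rows: np.ndarray) -> None:
        if rows.size == 0:
            return
        if node.is_leaf:
            out[rows] = node.label
            return
        values = data[node.variable].to_numpy()[rows]
        mask = values < node.threshold
        descend(node.left, rows[mask])
        descend(node.right, rows[~mask])

    descend(model.root, index)
    return out


# ---------------------------------------------------------------------------
# CART induction
# ---------------------------------------------------------------------------

def _gini(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts / total
    return float(1.0 - (p * p).sum())


def _best_split(column: np.ndarray, codes: np.ndarray, n_classes: int, min_leaf: int):
    """Best (impurity, threshold) for one feature, or None if unsplittable."""
    order = np.argsort(column, kind="stable")
    xs, ys = column[order], codes[order]
    n = xs.size
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), ys] = 1.0
    left_counts = np.cumsum(onehot, axis=0)            # counts for splits after row i
    total = left_counts[-1]
    boundaries = np.flatnonzero(xs[:-1] < xs[1:]) + 1  # split sizes (left-side n)
    if boundaries.size == 0:
        return None
    valid = boundaries[(boundaries >= min_leaf) & (n - boundaries >= min_leaf)]
    if valid.size == 0:
        return None
    lc = left_counts[valid - 1]
    rc = total - lc
    nl = valid.astype(float)
    nr = n - nl
    gini_l = 1.0 - ((lc / nl[:, None]) ** 2).sum(axis=1)
    gini_r = 1.0 - ((rc / nr[:, None]) ** 2).sum(axis=1)
    weighted = (nl * gini_l + nr * gini_r) / n
    best = int(np.argmin(weighted))  # ties: lowest threshold
    i = valid[best]
    threshold = 0.5 * (xs[i - 1] + xs[i])
    return float(weighted[best]), float(threshold)


def _grow(
    x: np.ndarray,
    codes: np.ndarray,
    classes: np.ndarray,
    variables: Sequence[str],
    depth: int,
    max_depth: int | None,
    min_leaf: int,
    rng: np.random.Generator | None,
    n_feature_sample: int | None,
) -> TreeNode:
    counts = np.bincount(codes, minlength=classes.size)
    label = int(classes[np.argmax(counts)])
    leaf = TreeNode(label=label, counts={int(c): int(k) for c, k in zip(classes, counts) if k})
    if (max_depth is not None and depth >= max_depth) or counts.max() == codes.size:
        return leaf
    if codes.size < 2 * min_leaf:
        return leaf
    candidates = range(len(variables))
    if n_feature_sample is not None and rng is not None:
        candidates = sorted(rng.choice(len(variables), size=n_feature_sample, replace=False))
    best = None
    for j in candidates:
        result = _best_split(x[:, j], codes, classes.size, min_leaf)
        if result is None:
            continue
        impurity, threshold = result
        if best is None or impurity < best[0] - 1e-12:
            best = (impurity, j, threshold)
    if best is None or best[0] >= _gini(counts) - 1e-12:
        return leaf
    _, j, threshold = best
    mask = x[:, j] < threshold
    node = TreeNode(variable=variables[j], threshold=threshold, counts=leaf.counts, label=label)
    node.left = _grow(x[mask], codes[mask], classes, variables, depth + 1,
                      max_depth, min_leaf, rng, n_feature_sample)
    node.right = _grow(x[~mask], codes[~mask], classes, variables, depth + 1,
                       max_depth, min_leaf, rng, n_feature_sample)
    return node


def _tree_depth(node: TreeNode) -> int:
    if node.is_leaf:
        return 0
    return 1 + max(_tree_depth(node.left), _tree_depth(node.right))


def induce_tree(
    train: pd.DataFrame,
    labels: Sequence[int],
    variables: Sequence[str],
    max_depth: int = 3,
    min_leaf: int = 5,
    validation: tuple[pd.DataFrame, Sequence[int]] | None = None,
) -> TreeModel:
    """Greedy Gini CART on the given candidate variables.

    Without a validation set, returns the depth-``max_depth`` tree. With one,
    trees of depth 2..max_depth are grown and the one with the highest
    validation accuracy is returned (ties favouring the shallower tree).
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    if len(variables) == 0:
        raise ValueError("at least one candidate variable required")
    y = np.asarray(labels)
    classes, codes = np.unique(y, return_inverse=True)
    x = train[list(variables)].to_numpy(dtype=float)

    def build(depth_limit: int) -> TreeModel:
        root = _grow(x, codes, classes, list(variables), 0, depth_limit, min_leaf, None, None)
        model = TreeModel(root=root, variables=tuple(variables), depth=_tree_depth(root))
        model.training_accuracy = float((predict(model, train[list(variables)]) == y).mean())
        return model

    if validation is None:
        return build(max_depth)
    vx, vy = validation
    vy = np.asarray(vy)
    best_model, best_acc = None, -1.0
    for depth_limit in range(2, max_depth + 1):
        model = build(depth_limit)
        acc = float((predict(model, vx[list(variables)]) == vy).mean())
        if acc > best_acc + 1e-12:
            best_model, best_acc = model, acc
    return best_model


# ---------------------------------------------------------------------------
# Data splitting and variable importance
# ---------------------------------------------------------------------------

def split_data(
    cohort: pd.DataFrame,
    labels: Sequence[int],
    train_fraction: float = 0.7,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/validation split (row indices into ``cohort``).

    Per stratum the training size is ``round(train_fraction * n)`` (banker's
    rounding), clipped so both partitions keep at least one member; a stratum
    with fewer than 2 members is an error.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        if members.size < 2:
            raise ValueError(f"stratum {cls} has fewer than 2 members")
        n_train = int(round(train_fraction * members.size))
        n_train = min(max(n_train, 1), members.size - 1)
        perm = rng.permutation(members)
        train_idx.append(perm[:n_train])
        val_idx.append(perm[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def rank_importance(
    features: pd.DataFrame,
    labels: Sequence[int],
    n_trees: int = 100,
    seed: int | None = None,
    max_depth: int | None = None,
    min_leaf: int = 3,
) -> pd.DataFrame:
    """Permutation variable importance from a bagged-tree ensemble.

    Each tree is grown on a bootstrap sample; importance of a variable is the
    mean drop in out-of-bag accuracy when that variable's out-of-bag values
    are permuted. Returns a table sorted by descending importance.
    """
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("labels must contain at least two classes")
    variables = list(features.columns)
    x = features.to_numpy(dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)
    drops = np.zeros((n_trees, len(variables)))
    weights = np.zeros(n_trees)
    classes, codes = np.unique(y, return_inverse=True)
    for t in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size == 0:
            continue
        root = _grow(x[boot], codes[boot], classes, variables, 0, max_depth, min_leaf, None, None)
        model = TreeModel(root=root, variables=tuple(variables), depth=_tree_depth(root))
        frame = pd.DataFrame(x[oob], columns=variables)
        baseline = (predict(model, frame) == y[oob]).mean()
        for j, var in enumerate(variables):
            permuted = frame.copy()
            permuted[var] = rng.permutation(permuted[var].to_numpy())
            drops[t, j] = baseline - (predict(model, permuted) == y[oob]).mean()
        weights[t] = 1.0
    importance = drops.sum(axis=0) / max(weights.sum(), 1.0)
    order = np.argsort(-importance, kind="stable")
    return pd.DataFrame(
        {"variable": [variables[j] for j in order], "importance": importance[order]}
    )


# ---------------------------------------------------------------------------
# Published allocation tree
# ---------------------------------------------------------------------------

#: Leaf-to-profile map for the fixed 3-variable tree. The published figure's
#: leaf assignment is not machine-readable; this default is a reconstruction
#: consistent with the per-profile medians (CAT 15/23/9/9, age 71/66/72/59,
#: FEV1 41/47/69/62) and is configuration, not ground truth.
DEFAULT_LEAF_MAP: dict[str, int] = {
    "cat_ge_18": 2,
    "cat_lt_18_age_ge_65_fev1_lt_48": 1,
    "cat_lt_18_age_ge_65_fev1_ge_48": 3,
    "cat_lt_18_age_lt_65": 4,
}

PUBLISHED_CUTOFFS = {"cat": 18.0, "age": 65.0, "fev1_pct": 48.0}


def published_tree_model(leaf_map: Mapping[str, int] | None = None) -> TreeModel:
    """The fixed allocation tree: CAT >= 18, else age >= 65, else FEV1 >= 48."""
    leaves = dict(DEFAULT_LEAF_MAP)
    if leaf_map:
        leaves.update(leaf_map)
    root = TreeNode(
        variable="cat",
        threshold=PUBLISHED_CUTOFFS["cat"],
        right=TreeNode(label=leaves["cat_ge_18"]),
        left=TreeNode(
            variable="age",
            threshold=PUBLISHED_CUTOFFS["age"],
            left=TreeNode(label=leaves["cat_lt_18_age_lt_65"]),
            right=TreeNode(
                variable="fev1_pct",
                threshold=PUBLISHED_CUTOFFS["fev1_pct"],
                left=TreeNode(label=leaves["cat_lt_18_age_ge_65_fev1_lt_48"]),
                right=TreeNode(label=leaves["cat_lt_18_age_ge_65_fev1_ge_48"]),
            ),
        ),
    )
    return TreeModel(root=root, variables=("cat", "age", "fev1_pct"), depth=3)


def published_tree(
    cat: float, age: float, fev1: float, leaf_map: Mapping[str, int] | None = None
) -> int:
    """Allocate one person with the fixed CAT-18 / age-65 / FEV1-48 tree."""
    for name, value in (("cat", cat), ("age", age), ("fev1", fev1)):
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise NotClassifiableError(f"missing input '{name}'")
    return classify(published_tree_model(leaf_map), {"cat": cat, "age": age, "fev1_pct": fev1})


# ---------------------------------------------------------------------------
# Agreement
# ---------------------------------------------------------------------------

KAPPA_BANDS = (
    (0.0, "poor"),          # k < 0
    (0.20, "slight"),       # 0.00 <= k <= 0.20
    (0.40, "fair"),         # 0.21 <= k <= 0.40
    (0.60, "moderate"),     # 0.41 <= k <= 0.60
    (0.80, "substantial"),  # 0.61 <= k <= 0.80
)


def kappa_band(kappa: float) -> str:
    """Interpretation band: poor < 0 <= slight <= 0.20 < fair <= 0.40 <
    moderate <= 0.60 < substantial <= 0.80 < almost perfect."""
    if kappa < 0.0:
        return "poor"
    for upper, name in KAPPA_BANDS[1:]:
        if kappa <= upper:
            return name
    return "almost perfect"


@dataclass
class AgreementResult:
    """Confusion matrix, accuracy, Cohen's kappa and its band."""

    confusion: pd.DataFrame
    accuracy: float
    kappa: float
    band: str

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "band": self.band,
            "confusion": {
                "labels": [int(v) for v in self.confusion.index],
                "matrix": self.confusion.to_numpy().tolist(),
            },
        }


def cohens_kappa(predicted: Sequence[int], actual: Sequence[int]) -> AgreementResult:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    p_o is the observed agreement and p_e the chance agreement from marginal
    products. Perfect observed agreement gives kappa 1 by convention.
    """
    pred = np.asarray(predicted)
    act = np.asarray(actual)
    if pred.size == 0 or act.size == 0:
        raise ValueError("empty label vectors")
    if pred.size != act.size:
        raise ValueError("label vectors differ in length")
    labels = np.unique(np.concatenate([pred, act]))
    index = {lab: i for i, lab in enumerate(labels)}
    matrix = np.zeros((labels.size, labels.size), dtype=int)
    for p, a in zip(pred, act):
        matrix[index[p], index[a]] += 1
    total = matrix.sum()
    p_o = np.trace(matrix) / total
    p_e = float((matrix.sum(axis=1) / total) @ (matrix.sum(axis=0) / total))
    kappa = 1.0 if p_o == 1.0 else (p_o - p_e) / (1.0 - p_e)
    confusion = pd.DataFrame(matrix, index=labels, columns=labels)
    confusion.index.name = "predicted"
    confusion.columns.name = "actual"
    return AgreementResult(
        confusion=confusion,
        accuracy=float(p_o),
        kappa=float(kappa),
        band=kappa_band(float(kappa)),
    )
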