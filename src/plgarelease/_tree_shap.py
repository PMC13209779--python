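"""Path-dependent TreeSHAP for scikit-learn decision trees.

Computes exact Shapley values for a regression tree under the
path-dependent value function: the expected tree output when the features
in a coalition are fixed to the explained row and the remaining splits are
traversed proportionally to training cover. Attributions plus the tree's
expected value reconstruct the tree's prediction exactly (local accuracy).

Used for DecisionTreeRegressor / RandomForestRegressor, whose attributions
are not available natively (XGBoost and LightGBM ship their own exact
implementations).
"""

from __future__ import annotations

import numpy as np


class _Path:
    """A maintained path of unique features with Shapley permutation weights."""

    __slots__ = ("d", "z", "o", "w")

    def __init__(self):
        self.d: list[int] = []    # feature index of each path entry
        self.z: list[float] = []  # fraction of "zero" (cover-weighted) paths
        self.o: list[float] = []  # fraction of "one" (x-following) paths
        self.w: list[float] = []  # permutation weights

    def copy(self) -> "_Path":
        p = _Path()
        p.d = self.d.copy()
        p.z = self.z.copy()
        p.o = self.o.copy()
        p.w = self.w.copy()
        return p

    def extend(self, pz: float, po: float, pi: int) -> None:
        l = len(self.d)
        self.d.append(pi)
        self.z.append(pz)
        self.o.append(po)
        self.w.append(1.0 if l == 0 else 0.0)
        for i in range(l - 1, -1, -1):
            self.w[i + 1] += po * self.w[i] * (i + 1) / (l + 1)
            self.w[i] = pz * self.w[i] * (l - i) / (l + 1)

    def unwind(self, i: int) -> None:
        l = len(self.d)
        o, z = self.o[i], self.z[i]
        n = self.w[l - 1]
        for j in range(l - 2, -1, -1):
            if o != 0:
                t = self.w[j]
                self.w[j] = n * l / ((j + 1) * o)
                n = t - self.w[j] * z * (l - 1 - j) / l
            else:
                self.w[j] = self.w[j] * l / (z * (l - 1 - j))
        for j in range(i, l - 1):
            self.d[j] = self.d[j + 1]
            self.z[j] = self.z[j + 1]
            self.o[j] = self.o[j + 1]
        del self.d[-1], self.z[-1], self.o[-1], self.w[-1]

    def unwound_sum(self, i: int) -> float:
        """Sum of weights after hypothetically unwinding entry ``i``."""
        l = len(self.d)
        o, z = self.o[i], self.z[i]
        total = 0.0
        n = self.w[l - 1]
        for j in range(l - 2, -1, -1):
            if o != 0:
                t = n * l / ((j + 1) * o)
                total += t
                n = self.w[j] - t * z * (l - 1 - j) / l
            else:
                total += self.w[j] * l / (z * (l - 1 - j))
        return total


def tree_expected_value(tree) -> float:
    """Cover-weighted mean leaf value (the tree's base value)."""
    t = tree.tree_
    leaves = t.children_left == -1
    covers = t.weighted_n_node_samples[leaves]
    values = t.value[leaves, 0, 0]
    return float(np.sum(covers * values) / np.sum(covers))


def tree_shap_values(tree, X: np.ndarray) -> np.ndarray:
    """Per-row, per-feature Shapley values for one fitted sklearn tree."""
    t = tree.tree_
    X = np.asarray(X, dtype=float)
    left, right = t.children_left, t.children_right
    feature, threshold = t.feature, t.threshold
    cover = t.weighted_n_node_samples
    value = t.value[:, 0, 0]
    n, m = X.shape
    phi = np.zeros((n, m))

    def recurse(row: int, node: int, path: _Path, pz: float, po: float,
                pi: int) -> None:
        path = path.copy()
        path.extend(pz, po, pi)
        if left[node] == -1:
            for i in range(1, len(path.d)):
                w = path.unwound_sum(i)
                phi[row, path.d[i]] += w * (path.o[i] - path.z[i]) * value[node]
            return
        d = feature[node]
        hot, cold = (
            (left[node], right[node])
            if X[row, d] <= threshold[node]
            else (right[node], left[node])
        )
        iz, io = 1.0, 1.0
        for k in range(1, len(path.d)):
            if path.d[k] == d:
                iz, io = path.z[k], path.o[k]
                path.unwind(k)
                break
        rj = cover[node]
        recurse(row, hot, path, iz * cover[hot] / rj, io, d)
        recurse(row, cold, path, iz * cover[cold] / rj, 0.0, d)

    for row in range(n):
        recurse(row, 0, _Path(), 1.0, 1.0, -1)
    return phi


def forest_shap_values(forest, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Mean per-tree attributions and base value for a RandomForestRegressor."""
    phis = [tree_shap_values(est, X) for est in forest.estimators_]
    bases = [tree_expected_value(est) for est in forest.estimators_]
    return np.mean(phis, axis=0), float(np.mean(bases))
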