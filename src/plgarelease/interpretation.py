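"""Feature attribution (SHAP) for both stages and Spearman screening.

Attributions satisfy local accuracy: per row, base value plus the feature
attributions equals the model output (the log-odds margin for the stage-1
classifier, the raw regression output for stage 2). Routes:

* stage-1 logistic model — closed-form linear SHAP,
  ``phi_j = w_j * (z_j - mean(z_j))`` on the standardized scale;
* XGBoost / LightGBM — the libraries' native exact TreeSHAP
  (``pred_contribs`` / ``pred_contrib``);
* sklearn decision tree / random forest — the package's path-dependent
  TreeSHAP (:mod:`plgarelease._tree_shap`);
* other model families (SVR) — seeded permutation-sampling Shapley against a
  background sample; allocation is approximate but local accuracy still
  holds exactly because each permutation's marginals telescope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._tree_shap import forest_shap_values, tree_expected_value, tree_shap_values
from .data import FEATURE_COLUMNS
from .stage1 import SlowReleaseClassifier
from .stage2 import REGRESSION_FEATURES, ReleaseRegressor


@dataclass
class AttributionSet:
    """Per-row, per-feature attributions on the model-output scale."""

    values: pd.DataFrame          # rows x features
    base_value: float
    predictions: np.ndarray       # model output per row (margin scale)
    method: str
    sample_size: int | None = None
    seed: int | None = None

    def ranking(self) -> list[str]:
        """Features ordered by decreasing mean |attribution|."""
        imp = self.values.abs().mean(axis=0)
        return list(imp.sort_values(ascending=False, kind="stable").index)

    def mean_signed(self) -> pd.Series:
        return self.values.mean(axis=0)

    def additivity_gap(self) -> np.ndarray:
        """Per-row |base + sum(attributions) - prediction|."""
        total = self.base_value + self.values.sum(axis=1).to_numpy()
        return np.abs(total - np.asarray(self.predictions))

    def effect_direction(self, feature: str, feature_values) -> float:
        """Signed effect of a feature: covariance between its value and its
        attribution across rows (attributions themselves center near zero
        over the background, so their plain mean carries no direction)."""
        v = np.asarray(feature_values, dtype=float)
        phi = self.values[feature].to_numpy()
        return float(np.cov(v, phi)[0, 1])


def shap_classification(classifier: SlowReleaseClassifier,
                        table: pd.DataFrame) -> AttributionSet:
    """Exact linear SHAP of the stage-1 model on the log-odds scale.

    Background distribution is the supplied table itself: the model is
    explained on the data it was fit on.
    """
    if not hasattr(classifier, "model_"):
        raise ValueError("classifier is not fitted")
    X = table[FEATURE_COLUMNS]
    Z = classifier._transform(X)
    w = classifier.coef_.ravel()
    mean_z = Z.mean(axis=0)
    phi = (Z - mean_z) * w
    base = float(classifier.intercept_[0] + w @ mean_z)
    return AttributionSet(
        values=pd.DataFrame(phi, columns=FEATURE_COLUMNS, index=X.index),
        base_value=base,
        predictions=classifier.decision_function(X),
        method="linear",
    )


def _sampling_shap(predict, X: np.ndarray, background: np.ndarray,
                   n_permutations: int, seed: int) -> tuple[np.ndarray, float]:
    """Permutation-sampling Shapley with an interventional background."""
    rng = np.random.default_rng(seed)
    n, m = X.shape
    phi = np.zeros((n, m))
    base = float(np.mean(predict(background)))
    for i in range(n):
        acc = np.zeros(m)
        for _ in range(n_permutations):
            order = rng.permutation(m)
            z = background.copy()
            prev = np.mean(predict(z))
            for j in order:
                z[:, j] = X[i, j]
                cur = np.mean(predict(z))
                acc[j] += cur - prev
                prev = cur
        phi[i] = acc / n_permutations
    return phi, base


def shap_regression(regressor: ReleaseRegressor, X: pd.DataFrame,
                    max_rows: int | None = None, seed: int = 0,
                    n_permutations: int = 16,
                    background_size: int = 64,
                    sampling_max_rows: int = 32) -> AttributionSet:
    """Attributions for a fitted stage-2 regressor on its raw output scale.

    Tree ensembles get exact attributions; kernel/linear families route to
    the closed form or the seeded sampling fallback. ``max_rows`` subsamples
    the explained rows (seeded) to bound cost on large matrices; the
    sampling fallback is additionally capped at ``sampling_max_rows``
    because each explained row costs many model evaluations.
    """
    if not hasattr(regressor, "model_"):
        raise ValueError("regressor is not fitted")
    X = X[REGRESSION_FEATURES] if set(REGRESSION_FEATURES) <= set(X.columns) else X
    cols = list(X.columns)
    if regressor.algorithm not in ("xgb", "lgbm", "dt", "rf", "lr", "mean"):
        max_rows = min(max_rows or sampling_max_rows, sampling_max_rows)
    if max_rows is not None and len(X) > max_rows:
        idx = np.random.default_rng(seed).choice(len(X), max_rows, replace=False)
        X = X.iloc[np.sort(idx)]
    Xv = X.to_numpy(dtype=float)
    algo = regressor.algorithm
    model = regressor.model_

    if algo == "xgb":
        import xgboost as xgb

        contrib = model.get_booster().predict(
            xgb.DMatrix(Xv, feature_names=cols), pred_contribs=True
        )
        phi, base = contrib[:, :-1], float(contrib[0, -1])
        pred = model.predict(Xv)
        method = "tree_exact"
    elif algo == "lgbm":
        contrib = model.predict(Xv, pred_contrib=True)
        phi, base = contrib[:, :-1], float(contrib[0, -1])
        pred = model.predict(Xv)
        method = "tree_exact"
    elif algo == "dt":
        phi = tree_shap_values(model, Xv)
        base = tree_expected_value(model)
        pred = model.predict(Xv)
        method = "tree_exact"
    elif algo == "rf":
        phi, base = forest_shap_values(model, Xv)
        pred = model.predict(Xv)
        method = "tree_exact"
    elif algo in ("lr", "mean"):
        pred = model.predict(Xv)
        if algo == "mean":
            phi = np.zeros_like(Xv)
            base = float(pred.mean())
        else:
            w = model.coef_.ravel()
            mean_x = Xv.mean(axis=0)
            phi = (Xv - mean_x) * w
            base = float(model.intercept_ + w @ mean_x)
        method = "linear"
    else:
        warnings.warn(
            f"no exact attribution for algorithm {algo!r}; using seeded "
            f"permutation sampling (permutations={n_permutations}, "
            f"background={background_size})", RuntimeWarning)
        rng = np.random.default_rng(seed)
        bg_idx = rng.choice(len(Xv), min(background_size, len(Xv)), replace=False)
        phi, base = _sampling_shap(model.predict, Xv, Xv[bg_idx],
                                   n_permutations, seed)
        pred = model.predict(Xv)
        method = "sampling"

    return AttributionSet(
        values=pd.DataFrame(phi, columns=cols, index=X.index),
        base_value=base,
        predictions=np.asarray(pred, dtype=float),
        method=method,
        sample_size=None if method != "sampling" else n_permutations,
        seed=seed,
    )


def spearman_matrix(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Pairwise absolute Spearman rank correlations of the predictors.

    Average ranks for ties. A constant column yields NaN against every other
    column (undefined correlation) and 1.0 on the diagonal.
    """
    cols = list(columns) if columns is not None else [
        c for c in table.columns if c in FEATURE_COLUMNS + ["predicted_slow_release"]
    ]
    X = table[cols].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("spearman_matrix needs at least 3 rows")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(X).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
    out = np.abs(rho)
    np.fill_diagonal(out, 1.0)
    return pd.DataFrame(out, index=cols, columns=cols)


def save_heatmap(matrix: pd.DataFrame, image_path=None, csv_path=None) -> None:
    """Export the |rho| matrix as a heatmap image and/or CSV."""
    if csv_path is not None:
        matrix.to_csv(csv_path)
    if image_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 7))
        im = ax.imshow(matrix.to_numpy(), vmin=0, vmax=1, cmap="viridis")
        ax.set_xticks(range(len(matrix.columns)),
                      labels=matrix.columns, rotation=90)
        ax.set_yticks(range(len(matrix.index)), labels=matrix.index)
        fig.colorbar(im, ax=ax, label=r"|Spearman $\rho$|")
        fig.tight_layout()
        fig.savefig(image_path, dpi=150)
        plt.close(fig)
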