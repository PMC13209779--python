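"""Robustness analyses of the selected stage-2 model.

Two schemes, both preserving group integrity:

* repeated group-based resampling — 30 independent GroupShuffleSplit draws of
  formulation-level train/test partitions (uncertainty analysis);
* leave-one-drug-out (LODO) — every formulation of one drug is held out in
  turn, probing generalization to chemically unseen drugs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupShuffleSplit

from .data import FEATURE_COLUMNS, RELEASE_COLUMN
from .metrics import mae, pearson_r
from .stage2 import REGRESSION_FEATURES, ReleaseRegressor

logger = logging.getLogger(__name__)


@dataclass
class ResamplingReport:
    """Per-repeat MAE / Pearson r and their mean (SD)."""

    per_repeat: pd.DataFrame  # columns: repeat, mae, pearson_r, n_test_rows
    test_fraction: float
    seed: int

    @property
    def n_repeats(self) -> int:
        return len(self.per_repeat)

    def summary(self) -> dict:
        m = self.per_repeat["mae"]
        r = self.per_repeat["pearson_r"]
        return {
            "n_repeats": self.n_repeats,
            "mae_mean": float(m.mean()), "mae_sd": float(m.std(ddof=1)),
            "r_mean": float(np.nanmean(r)), "r_sd": float(np.nanstd(r, ddof=1)),
        }


@dataclass
class LodoReport:
    """Per-drug MAE / Pearson r and their mean (SD)."""

    per_drug: pd.DataFrame  # columns: drug_id, mae, pearson_r, n_test_rows

    def summary(self) -> dict:
        m = self.per_drug["mae"]
        r = self.per_drug["pearson_r"]
        return {
            "n_drugs": len(self.per_drug),
            "mae_mean": float(m.mean()), "mae_sd": float(m.std(ddof=1)),
            "r_mean": float(np.nanmean(r)), "r_sd": float(np.nanstd(r, ddof=1)),
        }


def _fit_score(matrix: pd.DataFrame, train_mask, test_mask, algorithm: str,
               hyperparams, seed: int) -> tuple[float, float, int]:
    reg = ReleaseRegressor(algorithm, hyperparams, random_state=seed).fit(
        matrix.loc[train_mask, REGRESSION_FEATURES],
        matrix.loc[train_mask, RELEASE_COLUMN].to_numpy(),
    )
    y = matrix.loc[test_mask, RELEASE_COLUMN].to_numpy()
    pred = reg.predict(matrix.loc[test_mask, REGRESSION_FEATURES])
    if np.ptp(y) == 0:
        logger.info("constant observed release in test split; r undefined")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            r = pearson_r(pred, y) if len(y) >= 2 else float("nan")
    else:
        r = pearson_r(pred, y)
    return mae(pred, y), r, int(test_mask.sum())


def repeated_group_resampling(matrix: pd.DataFrame, algorithm: str = "xgb",
                              n_repeats: int = 30, test_fraction: float = 0.2,
                              seed: int = 0,
                              hyperparams: dict | None = None) -> ResamplingReport:
    """Uncertainty analysis: ``n_repeats`` fresh formulation-level splits.

    Each repeat draws a GroupShuffleSplit partition (group = formulation), so
    no formulation ever straddles its train/test boundary.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    groups = matrix["formulation_id"].to_numpy()
    if pd.unique(groups).size < 2:
        raise ValueError("need at least 2 formulation groups to resample")
    splitter = GroupShuffleSplit(n_splits=n_repeats, test_size=test_fraction,
                                 random_state=seed)
    rows = []
    for rep, (train, test) in enumerate(splitter.split(matrix, groups=groups)):
        train_mask = matrix.index.isin(matrix.index[train])
        test_mask = matrix.index.isin(matrix.index[test])
        if not train_mask.any() or not test_mask.any():
            raise ValueError("degenerate split: one side is empty")
        m, r, n = _fit_score(matrix, train_mask, test_mask, algorithm,
                             hyperparams, seed + rep)
        rows.append({"repeat": rep, "mae": m, "pearson_r": r, "n_test_rows": n})
    return ResamplingReport(pd.DataFrame(rows), test_fraction, seed)


def lodo_evaluate(matrix: pd.DataFrame, algorithm: str = "xgb", seed: int = 0,
                  hyperparams: dict | None = None) -> LodoReport:
    """Leave-one-drug-out: one iteration per drug, test sets partitioning the
    matrix by ``drug_id``. Deterministic apart from model seeds."""
    if "drug_id" not in matrix.columns:
        raise ValueError("matrix must carry a drug_id column for LODO")
    drugs = sorted(pd.unique(matrix["drug_id"]))
    if len(drugs) < 2:
        raise ValueError("LODO needs at least 2 distinct drugs")
    rows = []
    for drug in drugs:
        test_mask = (matrix["drug_id"] == drug).to_numpy()
        m, r, n = _fit_score(matrix, ~test_mask, test_mask, algorithm,
                             hyperparams, seed)
        rows.append({"drug_id": drug, "mae": m, "pearson_r": r, "n_test_rows": n})
    return LodoReport(pd.DataFrame(rows))
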