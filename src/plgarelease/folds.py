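"""Seeded, group-respecting fold assignment.

Groups (formulation or drug identifiers) are ordered, shuffled with a seeded
generator and dealt round-robin to folds, so every row of a group lands in
exactly one fold and fold membership is reproducible from the seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def grouped_fold_assignments(groups, k: int, seed: int = 0) -> dict:
    """Map each distinct group to a fold index in [0, k).

    Requires ``k`` no larger than the number of distinct groups.
    """
    unique = np.array(sorted(pd.unique(np.asarray(groups).astype(str))))
    if k > unique.size:
        raise ValueError(f"k={k} exceeds the {unique.size} distinct groups")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    rng.shuffle(unique)
    return {g: i % k for i, g in enumerate(unique)}


def grouped_kfold_indices(groups, k: int, seed: int = 0):
    """Yield (fold_id, train_idx, test_idx) positional index arrays."""
    groups = np.asarray(groups).astype(str)
    assignment = grouped_fold_assignments(groups, k, seed)
    fold_of_row = np.array([assignment[g] for g in groups])
    for fold in range(k):
        test = np.flatnonzero(fold_of_row == fold)
        train = np.flatnonzero(fold_of_row != fold)
        yield fold, train, test
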