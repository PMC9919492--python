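"""Class balancing and train/tune/test fold construction.

Non-walking hours vastly outnumber walking hours (sleep and sedentary time),
so the majority class is randomly undersampled down to the minority count
*before* splitting.  A single seeded shuffle then yields K parts; fold i
tests on part i, tunes on part i+1 (cyclically), and trains on the remaining
K-2 parts, so every instance is tested exactly once across the K folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .featurize import InstanceSet

__all__ = ["FoldSplit", "undersample_balance", "shuffle_and_fold", "save_folds", "load_folds"]


@dataclass(frozen=True)
class FoldSplit:
    """Disjoint train/tune/test instance indices for one fold."""

    fold_index: int
    train_ids: np.ndarray
    tune_ids: np.ndarray
    test_ids: np.ndarray

    def __post_init__(self) -> None:
        a, b, c = set(self.train_ids), set(self.tune_ids), set(self.test_ids)
        if a & b or a & c or b & c:
            raise ValueError("train/tune/test sets must be pairwise disjoint")

    @property
    def n_total(self) -> int:
        return len(self.train_ids) + len(self.tune_ids) + len(self.test_ids)


def undersample_balance(instances: InstanceSet, seed: int) -> InstanceSet:
    """Downsample the majority class to the minority count, without replacement.

    All minority instances are kept; the retained subset preserves the
    original instance order.  Deterministic given ``seed``.
    """
    y = instances.y
    neg_idx = np.nonzero(y == 0)[0]
    pos_idx = np.nonzero(y == 1)[0]
    if len(neg_idx) == 0 or len(pos_idx) == 0:
        raise ValueError("both classes must be non-empty to balance")
    minority, majority = (
        (pos_idx, neg_idx) if len(pos_idx) <= len(neg_idx) else (neg_idx, pos_idx)
    )
    rng = np.random.default_rng(seed)
    kept_majority = rng.choice(majority, size=len(minority), replace=False)
    keep = np.sort(np.concatenate([minority, kept_majority]))
    return instances.subset(
        keep, note=f"undersample_balance(seed={seed}, kept={len(keep)})"
    )


def shuffle_and_fold(
    balanced: InstanceSet | int, K: int = 10, seed: int = 0
) -> list[FoldSplit]:
    """One seeded shuffle into K parts; rotate test/tune/train across folds.

    Accepts an :class:`InstanceSet` or a plain instance count.  Requires
    K >= 3 (with fewer parts the tune part would collide with the test part
    or leave no training data) and N >= K.
    """
    N = balanced if isinstance(balanced, int) else len(balanced)
    if K < 3:
        raise ValueError("K must be >= 3 so train, tune and test parts are disjoint")
    if N < K:
        raise ValueError(f"need at least K={K} instances, got {N}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(N)
    parts = np.array_split(perm, K)
    folds = []
    for i in range(K):
        tune_part = (i + 1) % K
        train = np.concatenate(
            [parts[j] for j in range(K) if j != i and j != tune_part]
        )
        folds.append(
            FoldSplit(
                fold_index=i,
                train_ids=np.sort(train),
                tune_ids=np.sort(parts[tune_part]),
                test_ids=np.sort(parts[i]),
            )
        )
    return folds


def save_folds(folds: list[FoldSplit], path: str | Path, seed: int | None = None) -> None:
    """Write a split manifest (JSON) for exact replay."""
    manifest = {
        "K": len(folds),
        "seed": seed,
        "folds": [
            {
                "fold_index": f.fold_index,
                "train_ids": f.train_ids.tolist(),
                "tune_ids": f.tune_ids.tolist(),
                "test_ids": f.test_ids.tolist(),
            }
            for f in folds
        ],
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh)


def load_folds(path: str | Path) -> list[FoldSplit]:
    with open(path) as fh:
        manifest = json.load(fh)
    return [
        FoldSplit(
            fold_index=f["fold_index"],
            train_ids=np.asarray(f["train_ids"], dtype=np.int64),
            tune_ids=np.asarray(f["tune_ids"], dtype=np.int64),
            test_ids=np.asarray(f["test_ids"], dtype=np.int64),
        )
        for f in manifest["folds"]
    ]
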