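"""Random search over MLP hidden-layer architectures.

Each trial samples an architecture uniformly (layer count uniform on
1..max_layers, each width uniform over the width choices), evaluates it with
the *same* precomputed K-fold splits as every other trial, and records the
per-fold metrics.  Trials are ranked by mean cross-validated accuracy (the
optimization metric; MCC is recorded but never optimized), ties broken by
higher mean MCC and then by earlier trial, and the top-k architectures are
returned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataset import FoldSplit
from .evaluate import KFoldResult, run_kfold
from .featurize import InstanceSet
from .models import ArchitectureSpec, ClassifierSpec

__all__ = ["SearchSpace", "TrialResult", "SearchResult", "sample_architecture", "random_search"]


@dataclass(frozen=True)
class SearchSpace:
    """Sampling space for hidden-layer architectures."""

    max_layers: int = 5
    width_choices: tuple[int, ...] = (4, 8, 16, 32, 64, 128, 256)
    n_trials: int = 90
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_layers < 1:
            raise ValueError("max_layers must be >= 1")
        if not self.width_choices:
            raise ValueError("width_choices must be non-empty")
        if any(w < 1 for w in self.width_choices):
            raise ValueError("widths must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass(frozen=True)
class TrialResult:
    trial_index: int
    architecture: ArchitectureSpec
    kfold: KFoldResult
    wall_clock_s: float

    @property
    def mean_accuracy(self) -> float:
        return self.kfold.mean_metrics["accuracy"]

    @property
    def mean_mcc(self) -> float:
        return self.kfold.mean_metrics["mcc"]


@dataclass
class SearchResult:
    """All trials in sampling order, the accuracy-ranked view, and the trace."""

    space: SearchSpace
    trials: list[TrialResult]
    top: list[TrialResult]
    best_so_far: list[float] = field(default_factory=list)

    def write_log(self, path: str | Path) -> None:
        """One JSON record per trial, in sampling order."""
        records = []
        for t in self.trials:
            records.append(
                {
                    "trial_index": t.trial_index,
                    "architecture": t.architecture.as_dict(),
                    "mean_metrics": t.kfold.mean_metrics,
                    "sd_metrics": t.kfold.sd_metrics,
                    "wall_clock_s": t.wall_clock_s,
                }
            )
        with open(path, "w") as fh:
            json.dump(
                {
                    "space": {
                        "max_layers": self.space.max_layers,
                        "width_choices": list(self.space.width_choices),
                        "n_trials": self.space.n_trials,
                        "seed": self.space.seed,
                    },
                    "best_so_far": self.best_so_far,
                    "trials": records,
                },
                fh,
                indent=2,
            )


def sample_architecture(space: SearchSpace, rng: np.random.Generator) -> ArchitectureSpec:
    """Draw one architecture: uniform layer count, uniform widths."""
    n_layers = int(rng.integers(1, space.max_layers + 1))
    widths = rng.choice(np.asarray(space.width_choices), size=n_layers, replace=True)
    return ArchitectureSpec(hidden_layers=tuple(int(w) for w in widths))


def random_search(
    balanced: InstanceSet,
    folds: list[FoldSplit],
    space: SearchSpace,
    top_k: int = 3,
    mlp_hyperparams: dict | None = None,
) -> SearchResult:
    """Evaluate ``space.n_trials`` random architectures on shared folds.

    Fully reproducible from ``space.seed`` (architecture sampling and the
    per-trial classifier seeds both derive from it).
    """
    if not folds:
        raise ValueError("folds must be precomputed and shared across trials")
    rng = np.random.default_rng(space.seed)
    trials: list[TrialResult] = []
    best_so_far: list[float] = []
    best = -np.inf
    for i in range(space.n_trials):
        arch = sample_architecture(space, rng)
        spec = ClassifierSpec(
            kind="mlp",
            hyperparams=dict(mlp_hyperparams or {}),
            architecture=arch,
            seed=space.seed + i,
        )
        kfold = run_kfold(balanced, folds, spec)
        trial = TrialResult(
            trial_index=i,
            architecture=arch,
            kfold=kfold,
            wall_clock_s=float(np.sum(kfold.fit_seconds)),
        )
        trials.append(trial)
        best = max(best, trial.mean_accuracy)
        best_so_far.append(best)
    ranked = sorted(
        trials, key=lambda t: (-t.mean_accuracy, -t.mean_mcc, t.trial_index)
    )
    return SearchResult(
        space=space,
        trials=trials,
        top=ranked[: min(top_k, len(ranked))],
        best_so_far=best_so_far,
    )
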