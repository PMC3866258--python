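"""ROC/AUC scoring and leave-one-pair-out cross-validation.

Each protein-RNA complex in turn is held out: the CRF is trained on the
remaining complexes and every residue-base cell of the held-out grid is
scored with its conditional contact probability.  Performance is the
unweighted mean of per-fold AUCs.  AUC uses rank-based (Mann-Whitney) tie
handling: ties between a positive and a negative score receive half credit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .crf import FeatureConfig, ProteinRNAInstance
from .errors import UndefinedAUCError
from .inference import score_grid
from .training import TrainingConfig, fit


@dataclass
class ROCResult:
    auc: float
    roc_points: np.ndarray  # (k, 2) columns (fpr, tpr)

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC outside [0, 1]")


@dataclass
class CVResult:
    fold_aucs: list[float | None]
    mean_auc: float
    skipped: list[int] = field(default_factory=list)
    fold_scores: list[np.ndarray] = field(default_factory=list)
    fold_labels: list[np.ndarray] = field(default_factory=list)


def roc_auc(scores, labels) -> ROCResult:
    """Ranking AUC (Mann-Whitney statistic) plus the ROC polyline."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    classes = set(labels.tolist())
    if classes - {0, 1}:
        raise ValueError("labels must be 0/1")
    if len(classes) < 2:
        raise UndefinedAUCError("AUC undefined with a single class")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, _ = roc_curve(labels, scores)
    return ROCResult(auc=auc, roc_points=np.column_stack([fpr, tpr]))


def leave_one_out_cv(
    instances: list[ProteinRNAInstance],
    feature_config: FeatureConfig,
    training_config: TrainingConfig | None = None,
    conditioning: str = "map",
    trws_max_iterations: int = 50,
) -> CVResult:
    """Leave-one-pair-out CV: per-fold AUCs and their unweighted mean.

    ``conditioning`` selects the neighbor states used for test-time
    probabilities: ``"map"`` (TRW-S MAP grid, default), ``"zeros"`` or
    ``"ones"``.  Folds whose held-out grid contains a single class are
    skipped with a warning and excluded from the mean.
    """
    if len(instances) < 2:
        raise ValueError("leave-one-out CV needs at least 2 instances")
    if conditioning not in ("map", "zeros", "ones"):
        raise ValueError(f"unknown conditioning {conditioning!r}")
    fold_aucs: list[float | None] = []
    skipped: list[int] = []
    fold_scores: list[np.ndarray] = []
    fold_labels: list[np.ndarray] = []
    for held in range(len(instances)):
        train = instances[:held] + instances[held + 1 :]
        test = instances[held]
        if test.r is None:
            raise ValueError(f"instance {held} has no contact grid to evaluate")
        params = fit(train, feature_config, training_config)
        if conditioning == "map":
            cond = None
        else:
            from .crf import ContactGrid

            fill = 0 if conditioning == "zeros" else 1
            cond = ContactGrid(r=np.full(test.shape, fill, dtype=np.int8))
        scores = score_grid(
            params, feature_config, test,
            conditioning=cond, max_iterations=trws_max_iterations,
        )
        fold_scores.append(scores.ravel())
        fold_labels.append(test.r.r.ravel())
        try:
            result = roc_auc(scores.ravel(), test.r.r.ravel())
            fold_aucs.append(result.auc)
        except UndefinedAUCError:
            warnings.warn(
                f"fold {held}: held-out grid has a single class; skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            fold_aucs.append(None)
            skipped.append(held)
    valid = [a for a in fold_aucs if a is not None]
    mean = float(np.mean(valid)) if valid else float("nan")
    return CVResult(
        fold_aucs=fold_aucs,
        mean_auc=mean,
        skipped=skipped,
        fold_scores=fold_scores,
        fold_labels=fold_labels,
    )


def permutation_null(
    scores_by_fold: list[np.ndarray],
    labels_by_fold: list[np.ndarray],
    n_permutations: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of the mean fold AUC under label permutation.

    Labels are shuffled independently within each fold; the returned array
    holds one mean-over-folds AUC per permutation and centers on 0.5.
    """
    rng = np.random.default_rng(seed)
    out = np.empty(n_permutations)
    for t in range(n_permutations):
        aucs = []
        for scores, labels in zip(scores_by_fold, labels_by_fold):
            perm = rng.permutation(np.asarray(labels).ravel())
            aucs.append(roc_auc_score(perm, np.asarray(scores).ravel()))
        out[t] = float(np.mean(aucs))
    return out
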