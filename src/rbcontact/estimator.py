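"""Scikit-learn style estimator wrapping training and inference.

`ContactCRF` behaves like an sklearn classifier over grid-structured
instances: hyperparameters in ``__init__`` (so it composes with ``clone``
and model-selection utilities), ``fit`` on a list of labeled
`ProteinRNAInstance` objects, ``predict`` returning MAP contact grids,
``predict_proba`` returning per-cell contact probabilities, and fitted
attributes with a trailing underscore.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .coevolution import GroupingScheme
from .crf import ContactGrid, CRFParams, FeatureConfig, ProteinRNAInstance
from .evaluation import roc_auc
from .inference import build_energy, score_grid, trws_map
from .training import TrainingConfig, fit as _fit


def _as_list(X):
    if isinstance(X, ProteinRNAInstance):
        return [X], True
    return list(X), False


class ContactCRF(BaseEstimator):
    """Grid CRF contact predictor with coevolution and label features.

    Parameters
    ----------
    family : {1, 2, 3}
        Feature family: 1 = coevolution score only, 2 = coevolution plus
        residue/base label indicators, 3 = labels only.
    grouping : int
        Amino-acid grouping (2, 4, 8, 10, 15 Murphy groups, or 20 for the
        full alphabet); controls the label indicator size G*4.
    lasso_C : float
        L1 penalty strength; 0 disables the lasso.
    max_iter : int
        Optimizer iteration cap.
    tol : float
        Gradient tolerance for convergence.
    conditioning : {"map", "zeros", "ones"}
        Neighbor states used when scoring cells at test time.
    trws_max_iter : int
        TRW-S sweep cap for MAP inference.
    seed : int
        Retained for API completeness; fitting is deterministic.

    Attributes
    ----------
    params_ : CRFParams
        Fitted weight vectors (w_f_, w_g_ expose the arrays directly).
    n_iter_ : int
        Optimizer iterations used.
    converged_ : bool
        Whether the optimizer reported convergence.
    """

    def __init__(
        self,
        family: int = 1,
        grouping: int = 20,
        lasso_C: float = 0.0,
        max_iter: int = 500,
        tol: float = 1e-5,
        conditioning: str = "map",
        trws_max_iter: int = 50,
        seed: int = 0,
    ):
        self.family = family
        self.grouping = grouping
        self.lasso_C = lasso_C
        self.max_iter = max_iter
        self.tol = tol
        self.conditioning = conditioning
        self.trws_max_iter = trws_max_iter
        self.seed = seed

    @property
    def feature_config_(self) -> FeatureConfig:
        return FeatureConfig(
            family=self.family, grouping=GroupingScheme.from_name(self.grouping)
        )

    def fit(self, X, y=None):
        """Fit on labeled instances (y is ignored; labels ride on X)."""
        instances, _ = _as_list(X)
        config = TrainingConfig(
            lasso_C=self.lasso_C,
            max_iterations=self.max_iter,
            gradient_tolerance=self.tol,
            seed=self.seed,
        )
        params, info = _fit(instances, self.feature_config_, config, return_info=True)
        self.params_: CRFParams = params
        self.w_f_ = params.w_f
        self.w_g_ = params.w_g
        self.n_iter_ = info.n_iter
        self.converged_ = info.converged
        return self

    def _conditioning_grid(self, instance: ProteinRNAInstance):
        if self.conditioning == "map":
            return None
        fill = 0 if self.conditioning == "zeros" else 1
        return ContactGrid(r=np.full(instance.shape, fill, dtype=np.int8))

    def predict(self, X):
        """TRW-S MAP contact grid(s)."""
        check_is_fitted(self, "params_")
        instances, single = _as_list(X)
        grids = [
            trws_map(
                build_energy(self.params_, self.feature_config_, inst),
                max_iterations=self.trws_max_iter,
            )
            for inst in instances
        ]
        return grids[0] if single else grids

    def predict_proba(self, X):
        """Per-cell contact probability matrix (matrices)."""
        check_is_fitted(self, "params_")
        instances, single = _as_list(X)
        probs = [
            score_grid(
                self.params_,
                self.feature_config_,
                inst,
                conditioning=self._conditioning_grid(inst),
                max_iterations=self.trws_max_iter,
            )
            for inst in instances
        ]
        return probs[0] if single else probs

    def score(self, X, y=None) -> float:
        """Mean ranking AUC of predicted probabilities over labeled instances."""
        check_is_fitted(self, "params_")
        instances, _ = _as_list(X)
        aucs = []
        for inst in instances:
            if inst.r is None:
                raise ValueError("score needs labeled instances")
            probs = self.predict_proba(inst)
            aucs.append(roc_auc(probs.ravel(), inst.r.r.ravel()).auc)
        return float(np.mean(aucs))
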