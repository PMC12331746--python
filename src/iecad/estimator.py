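"""Scikit-learn-style estimators over the video network.

`EchoCADModel` is the fit/predict surface: ``fit`` runs the three-phase
schedule on a list of subject records, ``predict`` returns the aggregated
significant-CAD call per study, ``decision_function`` the continuous
significant-class score, and ``predict_gensini`` the max-over-views score.
`CycleResampler` wraps the 20-frame preprocessing as a transformer.  Both
compose with sklearn model selection via ``get_params``/``set_params``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .inference import StudyPrediction, assignment_scores, predict_study
from .network import IECadNetwork, ModelConfig
from .preprocess import FRAME_SIZE, RawCycle, resample_cycle
from .synthetic import SubjectRecord
from .training import TrainConfig, train_model

__all__ = ["EchoCADModel", "CycleResampler"]


class EchoCADModel(BaseEstimator):
    """Multi-task echo-video model with the three-phase training schedule.

    Parameters mirror the reference training recipe; reduced-scale studies
    lower ``frame_size``/``width`` and the phase epochs together.
    """

    def __init__(self, frame_size: int = FRAME_SIZE, width: float = 1.0,
                 rank: int = 4, n_heads: int = 8,
                 phase_epochs: tuple[int, int, int] = (30, 30, 90),
                 lr: float = 2e-4, weight_decay: float = 1e-5,
                 batch_size: int = 16, grad_accum: int = 3,
                 random_state: int = 0):
        self.frame_size = frame_size
        self.width = width
        self.rank = rank
        self.n_heads = n_heads
        self.phase_epochs = phase_epochs
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.grad_accum = grad_accum
        self.random_state = random_state

    # -- sklearn plumbing ----------------------------------------------------

    def _build(self) -> IECadNetwork:
        return IECadNetwork(ModelConfig(
            frame_size=self.frame_size, width=self.width, rank=self.rank,
            n_heads=self.n_heads, seed=self.random_state))

    def fit(self, X: list[SubjectRecord], y=None) -> "EchoCADModel":
        """Train on a cohort of subject records (labels live on the records)."""
        if not X:
            raise ValueError("empty cohort")
        size = X[0].clips["A4C"].data.shape[-1]
        if size != self.frame_size:
            raise ValueError(
                f"records are rendered at {size} px but frame_size="
                f"{self.frame_size}")
        self.network_ = self._build()
        self.history_ = train_model(self.network_, X, TrainConfig(
            phase_epochs=tuple(self.phase_epochs), lr=self.lr,
            weight_decay=self.weight_decay, batch_size=self.batch_size,
            grad_accum=self.grad_accum, seed=self.random_state))
        self.n_subjects_ = len(X)
        self.classes_ = np.array([0, 1])
        return self

    def _check_fitted(self):
        if not hasattr(self, "network_"):
            raise RuntimeError("fit the model before predicting")

    def predict_study(self, record: SubjectRecord) -> StudyPrediction:
        self._check_fitted()
        return predict_study(self.network_, record.clips)

    def predict(self, X: list[SubjectRecord]) -> np.ndarray:
        """Aggregated significant-CAD call (0/1) per study."""
        self._check_fitted()
        return np.array([int(self.predict_study(r).significant) for r in X])

    def predict_proba(self, X: list[SubjectRecord]) -> np.ndarray:
        self._check_fitted()
        p = np.array([assignment_scores(self.predict_study(r))[1] for r in X])
        return np.column_stack([1.0 - p, p]) if len(X) else np.empty((0, 2))

    def decision_function(self, X: list[SubjectRecord]) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict_gensini(self, X: list[SubjectRecord]) -> np.ndarray:
        """Max-over-views Gensini score per study."""
        return np.array([self.predict_study(r).gensini for r in X])

    def score(self, X: list[SubjectRecord], y=None) -> float:
        """Accuracy of the significant-CAD call against the record labels."""
        truth = np.array([int(r.significant) for r in X])
        return float(np.mean(self.predict(X) == truth))


class CycleResampler(BaseEstimator, TransformerMixin):
    """Transformer: RawCycle -> 20-frame VideoBlock."""

    def __init__(self, size: int = FRAME_SIZE, view: str = "A4C"):
        self.size = size
        self.view = view

    def fit(self, X, y=None):
        return self

    def transform(self, X: list[RawCycle]):
        return [resample_cycle(raw, view=self.view, size=self.size)
                for raw in X]
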