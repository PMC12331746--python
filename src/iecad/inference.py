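"""Per-study prediction: three views tested separately, then aggregated.

The final Gensini score is the maximum prediction over the A4C/A3C/A2C
views, a case is significant if any view calls it significant, and severity
follows the 15-point cutoff applied to the final score.  This max/any
aggregation maximises sensitivity: a lesion's wall-motion signature may be
visible in only one imaging plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clinical import CadLabel, SEVERE_CUTOFF, is_severe
from .network import IECadNetwork, NetworkOutput
from .preprocess import VIEWS, VideoBlock

__all__ = ["StudyPrediction", "predict_study", "assignments",
           "assignment_scores"]


@dataclass
class StudyPrediction:
    """Aggregated three-view network output for one study."""

    per_view: dict[str, NetworkOutput]
    gensini: float             # max over views
    significant: bool          # any view
    severe: bool               # final Gensini >= 15

    @property
    def label(self) -> CadLabel:
        return CadLabel(significant=self.significant, severe=self.severe)


def predict_study(model: IECadNetwork,
                  views: dict[str, VideoBlock | np.ndarray]) -> StudyPrediction:
    """Run each view independently in evaluation mode and aggregate."""
    missing = [v for v in VIEWS if v not in views]
    if missing or len(views) != len(VIEWS):
        raise ValueError(f"need exactly the views {VIEWS}; missing {missing}")
    per_view: dict[str, NetworkOutput] = {}
    for view in VIEWS:
        block = views[view]
        data = block.data if isinstance(block, VideoBlock) else np.asarray(block)
        per_view[view] = model.predict(data)
    gensini = max(out.gensini for out in per_view.values())
    significant = any(out.significant for out in per_view.values())
    return StudyPrediction(per_view=per_view, gensini=gensini,
                           significant=significant,
                           severe=is_severe(gensini))


def assignments(pred: StudyPrediction) -> CadLabel:
    """The four detection assignments from the final flags."""
    return pred.label


def assignment_scores(pred: StudyPrediction) -> dict[int, float]:
    """Continuous scores behind the four assignment ROC curves.

    1: max per-view significant-class probability; 2: final (max) Gensini;
    3/4: max/min of the two constituent scores, with the severity score
    mapped through a logistic centred on the 15-point cutoff so both lie
    in [0, 1].
    """
    p_sig = max(out.cad_probs[1] for out in pred.per_view.values())
    p_sev = float(1.0 / (1.0 + np.exp(-(pred.gensini - SEVERE_CUTOFF)
                                      / SEVERE_CUTOFF)))
    return {1: float(p_sig), 2: float(pred.gensini),
            3: max(float(p_sig), p_sev), 4: min(float(p_sig), p_sev)}
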