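"""Per-signal importance by full-length occlusion.

Each input signal is occluded over its whole duration and the discrepancy
between the model's occluded and reference outputs, measured as MAE,
quantifies how much the model relies on that signal.

Two reference modes exist for regression.  ``prediction-vs-prediction``
(the default) compares the occluded prediction to the unoccluded one and
needs no targets; a model provably independent of a signal scores exactly 0
for it.  ``prediction-vs-target`` compares both predictions to the ground
truth series, and additionally reports the unoccluded baseline error, the
framing used when benchmarking trained predictors against their test sets.

For classifiers the outputs carry no temporal structure, so importance is
the MAE between the per-sample *loss* vectors with and without occlusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import BlackBoxModel, SignalTensor, TargetData, mae
from .occlusion import DATASET_MEAN, FULL, OcclusionSpec, occlude_dataset, resolve_occlusion_values

__all__ = [
    "ImportanceReport",
    "signal_importance",
    "signal_importance_classification",
]

PRED_VS_PRED = "prediction-vs-prediction"
PRED_VS_TARGET = "prediction-vs-target"


@dataclass(frozen=True)
class ImportanceReport:
    """Per-signal occlusion importance scores.

    ``per_signal_score[j]`` is the mean over samples of the per-sample MAE
    discrepancy induced by fully occluding signal ``j``.  The per-sample
    vectors are retained in ``per_sample_scores`` for inspection.
    ``occlusion_values_used`` records the scalar substituted into each
    signal (relevant when the dataset-mean policy is used).
    """

    per_signal_score: Dict[int, float]
    per_sample_scores: Dict[int, np.ndarray]
    signal_names: tuple
    occlusion_value: Union[float, str]
    occlusion_values_used: Dict[int, float]
    reference_mode: str
    baseline_score: Optional[float] = None

    def ranking(self) -> list:
        """Signal indices ordered by score descending (ties: lower index first)."""
        return sorted(self.per_signal_score, key=lambda j: (-self.per_signal_score[j], j))

    def most_important(self) -> int:
        return self.ranking()[0]

    def to_frame(self) -> pd.DataFrame:
        """One row per occluded signal: score, occlusion value, mode."""
        rows = []
        for j, score in sorted(self.per_signal_score.items()):
            rows.append(
                {
                    "signal": self.signal_names[j],
                    "signal_index": j,
                    "score": score,
                    "occlusion_value": self.occlusion_values_used[j],
                    "occlusion_policy": self.occlusion_value,
                    "mode": self.reference_mode,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def _per_sample_mae(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """MAE per sample between two (s, h) batches: average per sample row."""
    return np.mean(np.abs(a - b), axis=1)


def signal_importance(
    X: SignalTensor,
    model: BlackBoxModel,
    occlusion_value: Union[float, str] = 0.0,
    mode: str = PRED_VS_PRED,
    Y: Optional[TargetData] = None,
    signals: Optional[Sequence[int]] = None,
) -> ImportanceReport:
    """Full-length occlusion importance for a regression model.

    Parameters
    ----------
    X
        The dataset tensor.
    model
        A regression black box.
    occlusion_value
        Scalar or :data:`~tsocclude.occlusion.DATASET_MEAN`.
    mode
        ``"prediction-vs-prediction"`` scores MAE(b(X_occ), b(X));
        ``"prediction-vs-target"`` scores MAE(b(X_occ), Y) and records
        MAE(b(X), Y) as the baseline.
    Y
        Ground-truth regression targets; required in target mode.
    signals
        Subset of signal indices to occlude; defaults to all.
    """
    if model.task != "regression":
        raise ValueError("signal_importance requires a regression model; "
                         "use signal_importance_classification for classifiers")
    if mode not in (PRED_VS_PRED, PRED_VS_TARGET):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == PRED_VS_TARGET:
        if Y is None or Y.kind != "regression":
            raise ValueError("prediction-vs-target mode requires regression TargetData Y")
        if Y.series.shape != (X.n_samples, X.n_timesteps):
            raise ValueError(
                f"target series shape {Y.series.shape} does not match X ({X.n_samples}, {X.n_timesteps})"
            )

    if signals is None:
        signals = range(X.n_signals)
    y_ref = model(X)
    ov_used = resolve_occlusion_values(X, occlusion_value)

    per_signal: Dict[int, float] = {}
    per_sample: Dict[int, np.ndarray] = {}
    baseline = None
    if mode == PRED_VS_TARGET:
        baseline = float(np.mean(_per_sample_mae(y_ref, Y.series)))
    for j in signals:
        j = X.signal_index(j)
        spec = OcclusionSpec(occlusion_value=occlusion_value, duration=FULL, signal_subset=(j,))
        y_occ = model(occlude_dataset(X, spec))
        ref = y_ref if mode == PRED_VS_PRED else Y.series
        scores = _per_sample_mae(y_occ, ref)
        per_sample[j] = scores
        per_signal[j] = float(scores.mean())
    return ImportanceReport(
        per_signal_score=per_signal,
        per_sample_scores=per_sample,
        signal_names=X.signal_names,
        occlusion_value=occlusion_value,
        occlusion_values_used={j: float(ov_used[j]) for j in per_signal},
        reference_mode=mode,
        baseline_score=baseline,
    )


def signal_importance_classification(
    X: SignalTensor,
    model: BlackBoxModel,
    Y: TargetData,
    occlusion_value: Union[float, str] = 0.0,
    signals: Optional[Sequence[int]] = None,
) -> ImportanceReport:
    """Loss-discrepancy importance for a classification model.

    The per-signal score is the MAE between the length-``s`` vector of
    per-sample losses under full occlusion of that signal and the losses on
    the unoccluded input.
    """
    if model.task != "classification":
        raise ValueError("requires a classification model")
    if model.per_sample_loss is None:
        raise ValueError("model must provide per_sample_loss for loss-based importance")
    if Y.kind != "classification":
        raise ValueError("Y must carry classification labels")

    if signals is None:
        signals = range(X.n_signals)
    loss_ref = np.asarray(model.per_sample_loss(model(X), Y), dtype=float)
    ov_used = resolve_occlusion_values(X, occlusion_value)

    per_signal: Dict[int, float] = {}
    per_sample: Dict[int, np.ndarray] = {}
    for j in signals:
        j = X.signal_index(j)
        spec = OcclusionSpec(occlusion_value=occlusion_value, duration=FULL, signal_subset=(j,))
        loss_occ = np.asarray(model.per_sample_loss(model(occlude_dataset(X, spec)), Y), dtype=float)
        per_sample[j] = np.abs(loss_occ - loss_ref)
        per_signal[j] = mae(loss_occ, loss_ref)
    return ImportanceReport(
        per_signal_score=per_signal,
        per_sample_scores=per_sample,
        signal_names=X.signal_names,
        occlusion_value=occlusion_value,
        occlusion_values_used={j: float(ov_used[j]) for j in per_signal},
        reference_mode="loss-discrepancy",
        baseline_score=float(loss_ref.mean()),
    )
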