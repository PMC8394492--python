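"""Top-k influential sub-signal extraction.

Each window of one signal of one sample is occluded in turn (all other
signals untouched) and scored by the MAE between the model's occluded and
unoccluded outputs.  Sorting the windows by score descending and keeping
the first ``k`` yields that sample's top-k influential sub-signals; the
union over all samples, re-sorted, is the dataset-level influential set
from which a global working subset of the highest-scoring entries is drawn
(the SOM consumer typically trains on the top few thousand).

For classifiers, scores are discrepancies between per-sample losses, and
only windows whose occlusion flips the predicted label are candidates.

Ties are broken by ascending window index, then ascending series index:
deterministic and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .core import BlackBoxModel, SignalTensor, SubSignal, TargetData, mae, n_windows, segment
from .occlusion import resolve_occlusion_values

__all__ = [
    "InfluentialSet",
    "topk_subsignals",
    "topk_subsignals_classification",
    "window_scores",
    "build_influential_set",
    "predicted_labels",
    "bce_loss",
]


@dataclass(frozen=True)
class WindowScore:
    """Score of one single-window, single-signal occlusion experiment."""

    series_index: int
    signal_index: int
    window_index: int
    start: int
    end: int
    score: float
    prediction_changed: Optional[bool] = None


@dataclass(frozen=True)
class InfluentialSet:
    """The global working subset G of influential sub-signals.

    Entries are ordered by score descending (ties: ascending window index,
    then ascending series index).  All share the same signal and window
    duration, recorded in the provenance fields.
    """

    sub_signals: Tuple[SubSignal, ...]
    k_per_series: int
    signal_index: int
    occlusion_value: Union[float, str]
    window_duration: int

    def __len__(self) -> int:
        return len(self.sub_signals)

    def scores(self) -> np.ndarray:
        return np.array([s.score for s in self.sub_signals])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "series": s.series_index,
                "signal": s.signal_index,
                "window": s.window_index,
                "start": s.start,
                "end": s.end,
                "score": s.score,
                "truncated": s.truncated,
                "prediction_changed": s.prediction_changed,
            }
            for s in self.sub_signals
        ]
        return pd.DataFrame(
            rows,
            columns=["series", "signal", "window", "start", "end", "score",
                     "truncated", "prediction_changed"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def _as_sample(x) -> np.ndarray:
    """Accept an (h, n) array or a single-sample SignalTensor."""
    if isinstance(x, SignalTensor):
        if x.n_samples != 1:
            raise ValueError("expected a single-sample tensor; index the batch first")
        return x.values[0]
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"sample must be 2-D (timesteps, signals), got shape {arr.shape}")
    return arr


def _occluded_batch(
    sample: np.ndarray, signal_index: int, d: int, ov: float
) -> Tuple[SignalTensor, List[Tuple[int, int]]]:
    """All q single-window occlusions of one signal, batched as q samples."""
    h, n = sample.shape
    windows = segment(h, d)
    batch = np.repeat(sample[None, :, :], len(windows), axis=0)
    for i, (a, b) in enumerate(windows):
        batch[i, a:b, signal_index] = ov
    names = tuple(f"s{j}" for j in range(n))
    return SignalTensor(batch, names), windows


def _resolve_ov(sample: np.ndarray, signal_index: int, ov: Union[float, str]) -> float:
    names = tuple(f"s{j}" for j in range(sample.shape[1]))
    tensor = SignalTensor(sample[None], names)
    return float(resolve_occlusion_values(tensor, ov)[signal_index])


def window_scores(
    sample,
    signal_index: int,
    model: BlackBoxModel,
    d: int,
    occlusion_value: Union[float, str] = 0.0,
    series_index: int = 0,
) -> List[WindowScore]:
    """Occlusion score of every window of one signal of one sample.

    The complete windowed influence profile: element ``i`` is the MAE
    between the model's output on the original sample and on the sample
    with window ``i`` of the chosen signal occluded.  Scores are returned
    in window order (unsorted); this is the quantity rendered as a heatmap
    over the signal trace.
    """
    if model.task != "regression":
        raise ValueError("window_scores requires a regression model")
    x = _as_sample(sample)
    ov = _resolve_ov(x, signal_index, occlusion_value)
    batch, windows = _occluded_batch(x, signal_index, d, ov)
    names = batch.signal_names
    y_ref = model(SignalTensor(x[None], names))[0]
    y_occ = model(batch)
    return [
        WindowScore(
            series_index=series_index,
            signal_index=signal_index,
            window_index=i,
            start=a,
            end=b,
            score=mae(y_ref, y_occ[i]),
        )
        for i, (a, b) in enumerate(windows)
    ]


def _sort_key(ws: WindowScore):
    return (-ws.score, ws.window_index, ws.series_index)


def _to_subsignals(x: np.ndarray, scored: List[WindowScore], d: int) -> List[SubSignal]:
    return [
        SubSignal(
            values=x[ws.start : ws.end, ws.signal_index],
            series_index=ws.series_index,
            signal_index=ws.signal_index,
            window_index=ws.window_index,
            start=ws.start,
            end=ws.end,
            score=ws.score,
            truncated=(ws.end - ws.start) < d,
            prediction_changed=ws.prediction_changed,
        )
        for ws in scored
    ]


def topk_subsignals(
    sample,
    signal_index: int,
    model: BlackBoxModel,
    d: int,
    k: int,
    occlusion_value: Union[float, str] = 0.0,
    series_index: int = 0,
) -> List[SubSignal]:
    """The k windows of one signal whose occlusion perturbs the output most.

    Returned sub-signals carry the ORIGINAL (unoccluded) slice values and
    are ordered by score descending with the package tie-break.
    """
    x = _as_sample(sample)
    q = n_windows(x.shape[0], d)
    if not 1 <= k <= q:
        raise ValueError(f"k must satisfy 1 <= k <= q={q}, got {k}")
    scored = sorted(
        window_scores(sample, signal_index, model, d, occlusion_value, series_index),
        key=_sort_key,
    )
    return _to_subsignals(x, scored[:k], d)


def predicted_labels(scores: np.ndarray) -> np.ndarray:
    """Label decision: argmax over class scores; 0.5 threshold for a single column."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("class scores must be 2-D (samples, classes)")
    if scores.shape[1] == 1:
        return (scores[:, 0] > 0.5).astype(int)
    return np.argmax(scores, axis=1)


def bce_loss(scores: np.ndarray, Y: TargetData, eps: float = 1e-12) -> np.ndarray:
    """Binary cross-entropy per sample for single-probability outputs."""
    p = np.clip(np.asarray(scores, dtype=float)[:, 0], eps, 1 - eps)
    y = Y.labels.astype(float)
    return -(y * np.log(p) + (1 - y) * np.log(1 - p))


def topk_subsignals_classification(
    sample,
    signal_index: int,
    model: BlackBoxModel,
    Y_sample: TargetData,
    d: int,
    k: int,
    occlusion_value: Union[float, str] = 0.0,
    series_index: int = 0,
) -> List[SubSignal]:
    """Classification variant: loss discrepancies, label-flip candidates only.

    A window enters the candidate list iff occluding it changes the
    predicted label; candidates are scored by the absolute difference of
    the per-sample loss with and without occlusion.  Fewer than ``k``
    entries (possibly none) are returned when fewer windows flip.
    """
    if model.task != "classification":
        raise ValueError("requires a classification model")
    if Y_sample.kind != "classification" or Y_sample.n_samples != 1:
        raise ValueError("Y_sample must carry exactly one classification label")
    x = _as_sample(sample)
    q = n_windows(x.shape[0], d)
    if not 1 <= k <= q:
        raise ValueError(f"k must satisfy 1 <= k <= q={q}, got {k}")

    loss_fn = model.per_sample_loss
    if loss_fn is None:
        loss_fn = bce_loss  # default for probability outputs

    ov = _resolve_ov(x, signal_index, occlusion_value)
    batch, windows = _occluded_batch(x, signal_index, d, ov)
    names = batch.signal_names
    ref_scores = model(SignalTensor(x[None], names))
    occ_scores = model(batch)
    label_ref = predicted_labels(ref_scores)[0]
    labels_occ = predicted_labels(occ_scores)
    Y_batch = TargetData(kind="classification", labels=np.repeat(Y_sample.labels, len(windows)))
    loss_ref = float(np.asarray(loss_fn(ref_scores, Y_sample), dtype=float)[0])
    loss_occ = np.asarray(loss_fn(occ_scores, Y_batch), dtype=float)

    candidates = [
        WindowScore(
            series_index=series_index,
            signal_index=signal_index,
            window_index=i,
            start=a,
            end=b,
            score=abs(loss_occ[i] - loss_ref),
            prediction_changed=True,
        )
        for i, (a, b) in enumerate(windows)
        if labels_occ[i] != label_ref
    ]
    candidates.sort(key=_sort_key)
    return _to_subsignals(x, candidates[:k], d)


def build_influential_set(
    X: SignalTensor,
    signal_index: int,
    model: BlackBoxModel,
    d: int,
    k: int,
    n_global: int,
    occlusion_value: Union[float, str] = 0.0,
    Y: Optional[TargetData] = None,
) -> InfluentialSet:
    """Union of per-sample top-k sub-signals, globally re-ranked.

    Computes each sample's top-k, unions them, sorts by score descending
    and keeps the ``n_global`` best as the working subset G.  Duplicate
    morphologies from different samples are kept — they carry distinct
    provenance.  For classification tasks the union may be empty (no
    label-flipping window anywhere); an empty set is returned with a
    warning rather than an error.
    """
    if n_global < 1:
        raise ValueError("n_global must be >= 1")
    signal_index = X.signal_index(signal_index)
    pooled: List[SubSignal] = []
    for i in range(X.n_samples):
        if model.task == "regression":
            pooled.extend(
                topk_subsignals(X.values[i], signal_index, model, d, k,
                                occlusion_value, series_index=i)
            )
        else:
            if Y is None:
                raise ValueError("classification requires labels Y")
            y_i = TargetData(kind="classification", labels=Y.labels[i : i + 1])
            pooled.extend(
                topk_subsignals_classification(X.values[i], signal_index, model, y_i,
                                               d, k, occlusion_value, series_index=i)
            )
    if not pooled:
        import warnings

        warnings.warn("influential set is empty (no occlusion flipped any prediction)")
    pooled.sort(key=lambda s: (-s.score, s.window_index, s.series_index))
    return InfluentialSet(
        sub_signals=tuple(pooled[:n_global]),
        k_per_series=k,
        signal_index=signal_index,
        occlusion_value=occlusion_value,
        window_duration=d,
    )
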