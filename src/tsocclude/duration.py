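"""Duration of occlusion-induced output perturbations.

An occlusion of an input window perturbs a sequence model's output for some
time after (and sometimes before) the occluded span.  The duration of that
perturbation is quantified by segmenting the occluded and unoccluded output
series into aligned windows of ``d`` timesteps, computing the MAE of each
aligned pair, and counting the windows whose MAE strictly exceeds a
threshold ``T``.  Duration in timesteps is ``count * d``.

A zero count does not mean zero perturbation — only that every windowed
discrepancy is at or below the chosen tolerance.  Results therefore always
carry the threshold used.

``T`` has no default: its scale is application-dependent.
:func:`suggest_threshold` derives one as a quantile of the per-window MAEs
of unoccluded predictions against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd

from .core import BlackBoxModel, SignalTensor, TargetData, ShapeError, mae, n_windows, segment
from .occlusion import OcclusionSpec, occlude_dataset

__all__ = [
    "DurationResult",
    "DurationSummary",
    "perturbation_duration",
    "mean_duration",
    "suggest_threshold",
]


@dataclass(frozen=True)
class DurationResult:
    """Windowed-MAE perturbation count for one (y, y_occ) pair."""

    window_count: int
    duration_timesteps: int
    threshold: float
    window_duration: int
    per_window_mae: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_window_mae", np.asarray(self.per_window_mae, dtype=float))


def perturbation_duration(
    y: np.ndarray, y_occ: np.ndarray, d: int, threshold: float
) -> DurationResult:
    """Count output windows where MAE(y_window, y_occ_window) > threshold.

    Both series are segmented into the same ``q`` windows of ``d``
    timesteps (last window clipped).  The comparison is strict; the count
    times ``d`` is the reported duration even when the trailing window is
    shorter.
    """
    y = np.asarray(y, dtype=float)
    y_occ = np.asarray(y_occ, dtype=float)
    if y.shape != y_occ.shape or y.ndim != 1:
        raise ShapeError(f"series must be 1-D and equal length, got {y.shape} vs {y_occ.shape}")
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    windows = segment(y.size, d)
    per_window = np.array([mae(y[a:b], y_occ[a:b]) for a, b in windows])
    wc = int(np.sum(per_window > threshold))
    return DurationResult(
        window_count=wc,
        duration_timesteps=wc * d,
        threshold=float(threshold),
        window_duration=d,
        per_window_mae=per_window,
    )


def suggest_threshold(
    X: SignalTensor,
    model: BlackBoxModel,
    Y: TargetData,
    d: int,
    quantile: float = 0.9,
) -> float:
    """A data-driven T: a quantile of baseline per-window prediction errors.

    Pools the per-window MAEs of the unoccluded predictions against the
    target series over all samples and returns the requested quantile
    (default 0.9).  Purely a convenience; the chosen value should be logged
    with any result that uses it.
    """
    if model.task != "regression" or Y.kind != "regression":
        raise ValueError("threshold suggestion needs a regression model and targets")
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    y_hat = model(X)
    windows = segment(X.n_timesteps, d)
    errs = [
        mae(y_hat[i, a:b], Y.series[i, a:b])
        for i in range(X.n_samples)
        for a, b in windows
    ]
    return float(np.quantile(errs, quantile))


@dataclass(frozen=True)
class DurationSummary:
    """Mean perturbation duration over samples and occlusion window positions."""

    mean: float
    std: float
    stderr: float
    n: int
    threshold: float
    window_duration: int
    output_window_duration: int
    signal_subset: Tuple[int, ...]
    durations: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "window_size": self.window_duration,
                    "signal_subset": "+".join(str(j) for j in self.signal_subset),
                    "mean_duration_ts": self.mean,
                    "std": self.std,
                    "stderr": self.stderr,
                    "n": self.n,
                    "threshold": self.threshold,
                }
            ]
        )


def mean_duration(
    X: SignalTensor,
    model: BlackBoxModel,
    d: int,
    threshold: float,
    occlusion_value: Union[float, str] = 0.0,
    signal_subset: Tuple[int, ...] = (0,),
    d_out: Optional[int] = None,
) -> DurationSummary:
    """Mean +/- spread of perturbation duration over all samples and windows.

    For every occlusion window position ``i`` of the input (duration ``d``)
    and every sample, occludes the subset signals in that window, predicts,
    and measures :func:`perturbation_duration` between the unoccluded and
    occluded output of that sample.  The output segmentation duration
    ``d_out`` defaults to ``d``.

    Both the standard deviation and the standard error of the pooled
    durations are reported.
    """
    if model.task != "regression":
        raise ValueError("perturbation duration is undefined for classification "
                         "(the target carries no temporal information)")
    d_out = d if d_out is None else d_out
    q = n_windows(X.n_timesteps, d)
    y_ref = model(X)
    durations = []
    for widx in range(q):
        spec = OcclusionSpec(
            occlusion_value=occlusion_value,
            duration=d,
            window_index=widx,
            signal_subset=signal_subset,
        )
        y_occ = model(occlude_dataset(X, spec))
        for i in range(X.n_samples):
            res = perturbation_duration(y_ref[i], y_occ[i], d_out, threshold)
            durations.append(res.duration_timesteps)
    arr = np.asarray(durations, dtype=float)
    return DurationSummary(
        mean=float(arr.mean()),
        std=float(arr.std(ddof=0)),
        stderr=float(arr.std(ddof=0) / np.sqrt(arr.size)),
        n=int(arr.size),
        threshold=float(threshold),
        window_duration=d,
        output_window_duration=d_out,
        signal_subset=tuple(signal_subset),
        durations=arr,
    )
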