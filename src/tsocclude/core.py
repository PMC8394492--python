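"""Core data types shared by every analysis stage.

The central container is :class:`SignalTensor`, a dense array of ``s``
multivariate time series, each with ``h`` timesteps and ``n`` named signals
(e.g. ECG, PPG).  Predictors are wrapped in the opaque
:class:`BlackBoxModel` contract: the explainer only ever *queries* the model,
it never inspects weights or gradients.

Timesteps are 0-based and windows are half-open ``[start, end)`` throughout
the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "SignalTensor",
    "TargetData",
    "BlackBoxModel",
    "SubSignal",
    "segment",
    "n_windows",
    "mae",
]


class ShapeError(ValueError):
    """Raised when array dimensions are inconsistent."""


class InvalidDurationError(ValueError):
    """Raised for a window duration outside [1, h]."""


@dataclass(frozen=True)
class SignalTensor:
    """A batch of multivariate time series, shape ``(s, h, n)``.

    Parameters
    ----------
    values
        Real array of shape ``(samples, timesteps, signals)``. All samples
        share the same length; ragged sets are not supported.
    signal_names
        One unique identifier per signal (e.g. ``("ecg", "ppg")``).
    sampling_freq
        Optional sampling frequency in Hz, carried as metadata only.
    """

    values: np.ndarray
    signal_names: Tuple[str, ...]
    sampling_freq: Optional[float] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 3:
            raise ShapeError(
                f"values must be 3-D (samples, timesteps, signals), got shape {arr.shape}"
            )
        s, h, n = arr.shape
        if s < 1 or h < 1 or n < 1:
            raise ShapeError(f"all dimensions must be >= 1, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("values must be finite reals")
        names = tuple(str(x) for x in self.signal_names)
        if len(names) != n:
            raise ValueError(f"expected {n} signal names, got {len(names)}")
        if len(set(names)) != n:
            raise ValueError("signal names must be unique")
        if self.sampling_freq is not None and not self.sampling_freq > 0:
            raise ValueError("sampling_freq must be positive")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "signal_names", names)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_timesteps(self) -> int:
        return self.values.shape[1]

    @property
    def n_signals(self) -> int:
        return self.values.shape[2]

    def signal_index(self, signal: "int | str") -> int:
        """Resolve a signal name or integer index to an integer index."""
        if isinstance(signal, str):
            try:
                return self.signal_names.index(signal)
            except ValueError:
                raise KeyError(
                    f"unknown signal {signal!r}; available: {self.signal_names}"
                ) from None
        idx = int(signal)
        if not 0 <= idx < self.n_signals:
            raise IndexError(f"signal index {idx} out of range [0, {self.n_signals})")
        return idx

    def with_values(self, values: np.ndarray) -> "SignalTensor":
        """A copy of this tensor carrying ``values`` and the same metadata."""
        return SignalTensor(values, self.signal_names, self.sampling_freq)

    def sample(self, i: int) -> np.ndarray:
        """The ``(h, n)`` array of sample ``i``."""
        return self.values[i]


@dataclass(frozen=True)
class TargetData:
    """Prediction targets: a per-sample output series or a class label.

    Exactly one of ``series`` (regression, shape ``(s, h)``) or ``labels``
    (classification, shape ``(s,)``) is populated, matching ``kind``.
    """

    kind: str
    series: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.kind not in ("regression", "classification"):
            raise ValueError(f"kind must be 'regression' or 'classification', got {self.kind!r}")
        if self.kind == "regression":
            if self.series is None or self.labels is not None:
                raise ValueError("regression targets require series and no labels")
            arr = np.asarray(self.series, dtype=float)
            if arr.ndim != 2:
                raise ShapeError(f"series must be 2-D (samples, timesteps), got {arr.shape}")
            object.__setattr__(self, "series", arr)
        else:
            if self.labels is None or self.series is not None:
                raise ValueError("classification targets require labels and no series")
            arr = np.asarray(self.labels)
            if arr.ndim != 1:
                raise ShapeError(f"labels must be 1-D, got shape {arr.shape}")
            object.__setattr__(self, "labels", arr.astype(int))

    @property
    def n_samples(self) -> int:
        arr = self.series if self.kind == "regression" else self.labels
        return arr.shape[0]


@dataclass(frozen=True)
class BlackBoxModel:
    """Opaque prediction contract.

    ``predict`` maps a :class:`SignalTensor` to a prediction batch: a real
    matrix ``(s, h)`` of output series for regression, or ``(s, c)`` of class
    scores for classification.  ``per_sample_loss`` optionally maps a
    prediction batch and a :class:`TargetData` to a length-``s`` loss vector;
    it is required by the loss-discrepancy analyses of classification tasks.

    The contract assumes ``predict`` is deterministic within a session:
    repeated calls on identical input return identical output.  Stochastic
    predictors (e.g. dropout left on at inference) are out of contract.
    """

    task: str
    predict: Callable[[SignalTensor], np.ndarray]
    per_sample_loss: Optional[Callable[[np.ndarray, TargetData], np.ndarray]] = None
    name: str = "black-box"

    def __post_init__(self) -> None:
        if self.task not in ("regression", "classification"):
            raise ValueError(f"task must be 'regression' or 'classification', got {self.task!r}")

    def __call__(self, X: SignalTensor) -> np.ndarray:
        out = np.asarray(self.predict(X), dtype=float)
        if out.ndim == 1:
            out = out[:, None] if self.task == "classification" else out[None, :]
        if out.shape[0] != X.n_samples:
            raise ShapeError(
                f"predict returned {out.shape[0]} rows for {X.n_samples} samples"
            )
        if self.task == "regression" and out.shape[1] != X.n_timesteps:
            raise ShapeError(
                f"regression output length {out.shape[1]} != h={X.n_timesteps}"
            )
        return out


@dataclass(frozen=True)
class SubSignal:
    """A contiguous slice of one signal, with provenance and influence score.

    ``values`` always holds the ORIGINAL (unoccluded) slice — downstream
    morphology clustering operates on real signal shapes.  ``truncated``
    flags the trailing window of a series whose length is not divisible by
    the window duration.
    """

    values: np.ndarray
    series_index: int
    signal_index: int
    window_index: int
    start: int
    end: int
    score: float
    truncated: bool = False
    prediction_changed: Optional[bool] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            raise ShapeError("sub-signal values must be 1-D")
        if not (0 <= self.start < self.end):
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end})")
        if self.end - self.start != arr.size:
            raise ShapeError(
                f"window [{self.start}, {self.end}) does not match {arr.size} values"
            )
        if self.score < 0:
            raise ValueError("score must be nonnegative")
        object.__setattr__(self, "values", arr)

    @property
    def length(self) -> int:
        return self.end - self.start


def n_windows(h: int, d: int) -> int:
    """Number of occlusion windows q = h/d + c, with c = 1 unless d divides h."""
    if not 1 <= d <= h:
        raise InvalidDurationError(f"duration must satisfy 1 <= d <= h, got d={d}, h={h}")
    return -(-h // d)


def segment(h: int, d: int) -> List[Tuple[int, int]]:
    """Partition ``[0, h)`` into ``q`` contiguous half-open windows of length ``d``.

    The first ``q - 1`` windows have length ``d``; the last is clipped to the
    series end and may be shorter.

    >>> segment(10, 4)
    [(0, 4), (4, 8), (8, 10)]
    """
    q = n_windows(h, d)
    return [(i * d, min((i + 1) * d, h)) for i in range(q)]


def mae(a: Sequence[float], b: Sequence[float]) -> float:
    """Mean absolute error between two equal-length vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ShapeError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ShapeError("mae of empty vectors is undefined")
    return float(np.mean(np.abs(a - b)))
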