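"""Masking vectors and occluded dataset construction.

A localized occlusion of duration ``d`` starting at timestep ``p`` is
described by a pair of complementary binary masks: the keep mask is 1
outside ``[p, min(p + d, h))`` and 0 inside; the occlude mask is its
negation.  The occluded signal is ``x * keep + ov * occlude`` with ``ov``
the occlusion value.  Windows running past the end of the series are
clipped.

Occlusion never mutates the input tensor; every call materializes exactly
one occluded copy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np

from .core import SignalTensor, ShapeError, n_windows

__all__ = [
    "DATASET_MEAN",
    "FULL",
    "OcclusionSpec",
    "MaskPair",
    "build_masks",
    "apply_occlusion",
    "occlude_dataset",
    "resolve_occlusion_values",
]

#: Token: occlude with the per-signal mean of the dataset.
DATASET_MEAN = "dataset-mean"
#: Token: occlude the whole signal length.
FULL = "full"


class InvalidOffsetError(ValueError):
    """Raised when the occlusion start offset lies outside the series."""


class InvalidWindowError(ValueError):
    """Raised when a window index is out of range for (h, d)."""


@dataclass(frozen=True)
class MaskPair:
    """Complementary keep/occlude masks of length ``h``."""

    keep_mask: np.ndarray
    occlude_mask: np.ndarray

    def __post_init__(self) -> None:
        k = np.asarray(self.keep_mask)
        o = np.asarray(self.occlude_mask)
        if k.shape != o.shape or k.ndim != 1:
            raise ShapeError("masks must be 1-D and equal length")
        if not np.array_equal(o, 1 - k):
            raise ValueError("occlude_mask must be the negation of keep_mask")
        object.__setattr__(self, "keep_mask", k.astype(np.int8))
        object.__setattr__(self, "occlude_mask", o.astype(np.int8))


@dataclass(frozen=True)
class OcclusionSpec:
    """One occlusion experiment: value, window, and the signals it touches.

    ``occlusion_value`` is a real scalar or the token :data:`DATASET_MEAN`
    (per-signal mean over all samples and timesteps).  ``duration`` is a
    positive window length in timesteps or the token :data:`FULL`;
    ``window_index`` is ignored when full.
    """

    occlusion_value: Union[float, str] = 0.0
    duration: Union[int, str] = FULL
    window_index: int = 0
    signal_subset: Tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        if isinstance(self.occlusion_value, str) and self.occlusion_value != DATASET_MEAN:
            raise ValueError(
                f"occlusion_value must be a number or {DATASET_MEAN!r}, got {self.occlusion_value!r}"
            )
        if isinstance(self.duration, str):
            if self.duration != FULL:
                raise ValueError(f"duration must be a positive int or {FULL!r}")
        elif self.duration < 1:
            raise ValueError(f"duration must be >= 1, got {self.duration}")
        if self.window_index < 0:
            raise InvalidWindowError(f"window_index must be >= 0, got {self.window_index}")
        subset = tuple(sorted(set(int(j) for j in self.signal_subset)))
        if not subset:
            raise ValueError("signal_subset must be nonempty")
        object.__setattr__(self, "signal_subset", subset)

    def validate_for(self, X: SignalTensor) -> None:
        h = X.n_timesteps
        if any(not 0 <= j < X.n_signals for j in self.signal_subset):
            raise IndexError(f"signal_subset {self.signal_subset} out of range for n={X.n_signals}")
        if self.duration != FULL:
            q = n_windows(h, int(self.duration))
            if self.window_index >= q:
                raise InvalidWindowError(
                    f"window_index {self.window_index} out of range for q={q} "
                    f"(h={h}, d={self.duration})"
                )


def build_masks(h: int, p: int, d: int) -> MaskPair:
    """Masks for an occlusion of duration ``d`` starting after ``p`` timesteps.

    The occluded span is ``[p, min(p + d, h))``; spans running past the end
    of the series are clipped.
    """
    if not 0 <= p < h:
        raise InvalidOffsetError(f"offset must satisfy 0 <= p < h, got p={p}, h={h}")
    if d < 1:
        raise ValueError(f"duration must be >= 1, got {d}")
    keep = np.ones(h, dtype=np.int8)
    keep[p : min(p + d, h)] = 0
    return MaskPair(keep_mask=keep, occlude_mask=1 - keep)


def apply_occlusion(series: np.ndarray, masks: MaskPair, ov: float) -> np.ndarray:
    """``series * keep + ov * occlude``, elementwise."""
    x = np.asarray(series, dtype=float)
    if x.shape != masks.keep_mask.shape:
        raise ShapeError(f"series shape {x.shape} != mask shape {masks.keep_mask.shape}")
    return x * masks.keep_mask + float(ov) * masks.occlude_mask


def resolve_occlusion_values(X: SignalTensor, occlusion_value: Union[float, str]) -> np.ndarray:
    """The per-signal occlusion scalars actually substituted, shape ``(n,)``.

    A numeric value is broadcast to every signal; :data:`DATASET_MEAN`
    yields each signal's mean over all samples and timesteps.
    """
    if occlusion_value == DATASET_MEAN:
        return X.values.mean(axis=(0, 1))
    return np.full(X.n_signals, float(occlusion_value))


def occlude_dataset(X: SignalTensor, spec: OcclusionSpec) -> SignalTensor:
    """A copy of ``X`` with ``spec``'s window of each subset signal replaced.

    Every sample is occluded identically.  With ``duration=FULL`` the whole
    signal is replaced.  ``X`` itself is never modified.
    """
    spec.validate_for(X)
    h = X.n_timesteps
    ov = resolve_occlusion_values(X, spec.occlusion_value)
    if spec.duration == FULL:
        start, end = 0, h
    else:
        d = int(spec.duration)
        start = d * spec.window_index
        end = min(start + d, h)
    out = X.values.copy()
    for j in spec.signal_subset:
        out[:, start:end, j] = ov[j]
    return X.with_values(out)
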