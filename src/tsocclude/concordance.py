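"""Agreement between occlusion influence and external per-timestep attributions.

An external attribution method (e.g. Integrated Gradients) assigns a value
to every timestep of a signal.  To compare it with the windowed occlusion
profile, the attribution track is aggregated per window — the sum of the
per-timestep values inside each window — and the window holding the
attribution maximum is compared with the window holding the occlusion-MAE
maximum.  A sample is concordant when the two indices differ by at most
``tolerance`` windows (default 1); the concordance score is the concordant
fraction over samples.

Attributions are consumed as provided; this module never computes them
(doing so would need model gradients, breaking the model-agnostic
contract).  Raw values are summed by default; set ``absolute=True`` to sum
magnitudes instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .core import ShapeError, segment

__all__ = [
    "AttributionTrack",
    "ConcordanceResult",
    "window_attribution_scores",
    "top_window",
    "concordant",
    "concordance_score",
]


@dataclass(frozen=True)
class AttributionTrack:
    """Per-timestep attribution of one signal of one sample."""

    values: np.ndarray
    method_name: str = "external"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            raise ShapeError("attribution track must be 1-D")
        if not np.all(np.isfinite(arr)):
            raise ValueError("attributions must be finite")
        object.__setattr__(self, "values", arr)


@dataclass(frozen=True)
class ConcordanceResult:
    """Aggregate index agreement between two windowed rankings."""

    per_sample_pairs: Tuple[Tuple[int, int], ...]
    score: float
    tolerance: int

    @property
    def n_samples(self) -> int:
        return len(self.per_sample_pairs)


def window_attribution_scores(track: "AttributionTrack | np.ndarray", d: int) -> np.ndarray:
    """Per-window attribution: the sum of the track inside each window.

    The trailing window sums its (shorter) span, so the window scores sum
    to the whole track.
    """
    values = track.values if isinstance(track, AttributionTrack) else np.asarray(track, dtype=float)
    if values.ndim != 1:
        raise ShapeError("attribution track must be 1-D")
    windows = segment(values.size, d)
    return np.array([values[a:b].sum() for a, b in windows])


def top_window(scores: Sequence[float]) -> int:
    """Index of the maximal window score; ties go to the lowest index."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or scores.size == 0:
        raise ShapeError("scores must be a nonempty 1-D vector")
    return int(np.argmax(scores))


def concordant(
    occlusion_scores: Sequence[float],
    attr_scores: Sequence[float],
    tolerance: int = 1,
) -> bool:
    """Whether the two argmax window indices differ by at most ``tolerance``."""
    a = np.asarray(occlusion_scores, dtype=float)
    b = np.asarray(attr_scores, dtype=float)
    if a.shape != b.shape:
        raise ShapeError(f"score vectors differ in length: {a.shape} vs {b.shape}")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    return abs(top_window(a) - top_window(b)) <= tolerance


def concordance_score(
    occlusion_scores: Sequence[Sequence[float]],
    attr_scores: Sequence[Sequence[float]],
    tolerance: int = 1,
) -> ConcordanceResult:
    """Concordant fraction over per-sample window-score vector pairs."""
    if len(occlusion_scores) != len(attr_scores):
        raise ShapeError("need one attribution score vector per occlusion score vector")
    if len(occlusion_scores) == 0:
        raise ValueError("need at least one sample")
    pairs: List[Tuple[int, int]] = []
    hits = 0
    for occ, att in zip(occlusion_scores, attr_scores):
        i_occ = top_window(occ)
        i_att = top_window(np.asarray(att, dtype=float))
        if len(np.asarray(occ)) != len(np.asarray(att)):
            raise ShapeError("score vectors differ in length")
        pairs.append((i_occ, i_att))
        if abs(i_occ - i_att) <= tolerance:
            hits += 1
    return ConcordanceResult(
        per_sample_pairs=tuple(pairs),
        score=hits / len(pairs),
        tolerance=tolerance,
    )
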