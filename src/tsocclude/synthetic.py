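"""Synthetic biosignal fixtures and analytically transparent black boxes.

Real evaluation of an occlusion explainer needs a predictor whose input
dependence is *known*.  This module provides both halves: quasi-periodic
signal generators (sine mixtures, spike trains, an ECG-like bump train,
white noise) with controllable amplitude, period and noise, and toy black
boxes whose occlusion responses have closed forms:

``constant``
    ignores the input; every occlusion score is 0.
``echo(j)``
    output = signal ``j`` verbatim.  Full occlusion of ``j`` with value
    ``ov`` induces a per-sample importance of mean(|x_j - ov|); occluding
    window ``i`` (span ``[a, b)``) scores sum(|x_j[a:b] - ov|) / h.
``linear(weights)``
    output[t] = sum_j weights[j] * x_j[t]; scores scale by |weights[j]|
    relative to the echo forms.
``window_gated(j, w*, d)``
    output is the constant series mean(x_j[window w*]).  Dependence is
    localized by construction: only occlusions touching window ``w*`` of
    signal ``j`` can change the output.
``threshold_classifier(j, tau)``
    label = [mean(x_j) > tau], reported as a sigmoid probability with a
    sharpness parameter; per-sample loss defaults to binary cross-entropy.

The generators are deliberately simple morphology factories, not
physiological simulators: the ECG-like beat is three Gaussian bumps
(P/QRS/T), which gives the SOM separability tests distinct shapes without
claiming realism.

All randomness flows from the spec seed through a named generator; there is
no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .core import BlackBoxModel, SignalTensor, TargetData

__all__ = ["SyntheticSpec", "generate_dataset", "make_black_box"]

GENERATORS = ("sine-mixture", "spike-train", "ecg-like", "white-noise")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one reproducible synthetic dataset.

    ``amplitude``, ``period`` and ``noise_sd`` may be scalars (shared by
    all signals) or per-signal sequences of length ``n``.  ``period`` is in
    timesteps.  Defaults emulate a short biosignal strip: 16 samples of
    250 timesteps, 2 signals, period 50 (a heart-beat-like cycle at low
    sampling rate), unit amplitude, 5% noise.
    """

    s: int = 16
    h: int = 250
    n: int = 2
    generator: str = "sine-mixture"
    amplitude: Union[float, Sequence[float]] = 1.0
    period: Union[float, Sequence[float]] = 50.0
    noise_sd: Union[float, Sequence[float]] = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s < 1 or self.h < 1 or self.n < 1:
            raise ValueError("dimensions must be >= 1")
        if self.generator not in GENERATORS:
            raise ValueError(f"unknown generator {self.generator!r}; choose from {GENERATORS}")

    def _per_signal(self, value) -> np.ndarray:
        arr = np.atleast_1d(np.asarray(value, dtype=float))
        if arr.size == 1:
            arr = np.full(self.n, arr[0])
        if arr.size != self.n:
            raise ValueError(f"expected scalar or {self.n} per-signal values, got {arr.size}")
        return arr


def _ecg_beat(t: np.ndarray, period: float) -> np.ndarray:
    """One quasi-ECG cycle: P, QRS and T as Gaussian bumps within a period."""
    phase = (t % period) / period
    p_wave = 0.15 * np.exp(-((phase - 0.18) ** 2) / (2 * 0.025**2))
    qrs = 1.0 * np.exp(-((phase - 0.42) ** 2) / (2 * 0.012**2))
    t_wave = 0.3 * np.exp(-((phase - 0.68) ** 2) / (2 * 0.045**2))
    return p_wave + qrs + t_wave


def generate_dataset(
    spec: SyntheticSpec,
    targets: Optional[str] = None,
    target_signal: int = 0,
    label_threshold: float = 0.0,
) -> Tuple[SignalTensor, Optional[TargetData]]:
    """Generate a reproducible tensor, optionally with targets.

    ``targets="regression"`` attaches the per-sample series of signal
    ``target_signal`` (so an echo model is a perfect predictor);
    ``targets="classification"`` attaches the label
    [mean(x_target_signal) > label_threshold].
    """
    rng = np.random.default_rng(spec.seed)
    amp = spec._per_signal(spec.amplitude)
    per = spec._per_signal(spec.period)
    sd = spec._per_signal(spec.noise_sd)
    t = np.arange(spec.h, dtype=float)
    X = np.zeros((spec.s, spec.h, spec.n))
    for i in range(spec.s):
        for j in range(spec.n):
            if spec.generator == "sine-mixture":
                phase = rng.uniform(0, 2 * np.pi)
                base = amp[j] * (
                    np.sin(2 * np.pi * t / per[j] + phase)
                    + 0.3 * np.sin(4 * np.pi * t / per[j] + 2 * phase)
                )
            elif spec.generator == "spike-train":
                base = np.zeros(spec.h)
                offset = rng.integers(0, max(1, int(per[j])))
                idx = np.arange(offset, spec.h, max(1, int(per[j])))
                base[idx] = amp[j]
            elif spec.generator == "ecg-like":
                shift = rng.uniform(0, per[j])
                base = amp[j] * _ecg_beat(t + shift, per[j])
            else:  # white-noise
                base = amp[j] * rng.standard_normal(spec.h)
            noise = sd[j] * rng.standard_normal(spec.h) if sd[j] > 0 else 0.0
            X[i, :, j] = base + noise
    names = tuple(f"sig{j}" for j in range(spec.n))
    tensor = SignalTensor(X, names)

    Y: Optional[TargetData] = None
    if targets == "regression":
        Y = TargetData(kind="regression", series=X[:, :, target_signal].copy())
    elif targets == "classification":
        labels = (X[:, :, target_signal].mean(axis=1) > label_threshold).astype(int)
        Y = TargetData(kind="classification", labels=labels)
    elif targets is not None:
        raise ValueError(f"targets must be None, 'regression' or 'classification', got {targets!r}")
    return tensor, Y


# ---------------------------------------------------------------------------
# Toy black boxes


def _bce(scores: np.ndarray, Y: TargetData, eps: float = 1e-12) -> np.ndarray:
    p = np.clip(np.asarray(scores, dtype=float)[:, 0], eps, 1 - eps)
    y = Y.labels.astype(float)
    return -(y * np.log(p) + (1 - y) * np.log(1 - p))


def make_black_box(kind: str, **params) -> BlackBoxModel:
    """Build a toy predictor with a documented closed-form occlusion response.

    Kinds: ``constant`` (value=0.0), ``echo`` (j), ``linear`` (weights),
    ``window_gated`` (j, window_index, d), ``threshold_classifier``
    (j, tau, sharpness=50.0).
    """
    if kind == "constant":
        value = float(params.pop("value", 0.0))
        _no_extra(kind, params)

        def predict(X: SignalTensor) -> np.ndarray:
            return np.full((X.n_samples, X.n_timesteps), value)

        return BlackBoxModel(task="regression", predict=predict, name="constant")

    if kind == "echo":
        j = int(params.pop("j"))
        _no_extra(kind, params)

        def predict(X: SignalTensor) -> np.ndarray:
            return X.values[:, :, j].copy()

        return BlackBoxModel(task="regression", predict=predict, name=f"echo({j})")

    if kind == "linear":
        weights = np.asarray(params.pop("weights"), dtype=float)
        _no_extra(kind, params)

        def predict(X: SignalTensor) -> np.ndarray:
            if X.n_signals != weights.size:
                raise ValueError(f"model expects {weights.size} signals, got {X.n_signals}")
            return np.einsum("shn,n->sh", X.values, weights)

        return BlackBoxModel(task="regression", predict=predict, name="linear")

    if kind == "window_gated":
        j = int(params.pop("j"))
        widx = int(params.pop("window_index"))
        d = int(params.pop("d"))
        _no_extra(kind, params)

        def predict(X: SignalTensor) -> np.ndarray:
            a = widx * d
            b = min(a + d, X.n_timesteps)
            if a >= X.n_timesteps:
                raise ValueError(f"gate window {widx} out of range for h={X.n_timesteps}")
            gate = X.values[:, a:b, j].mean(axis=1)
            return np.repeat(gate[:, None], X.n_timesteps, axis=1)

        return BlackBoxModel(
            task="regression", predict=predict, name=f"window_gated({j},{widx})"
        )

    if kind == "threshold_classifier":
        j = int(params.pop("j"))
        tau = float(params.pop("tau"))
        sharpness = float(params.pop("sharpness", 50.0))
        _no_extra(kind, params)

        def predict(X: SignalTensor) -> np.ndarray:
            margin = X.values[:, :, j].mean(axis=1) - tau
            p = 1.0 / (1.0 + np.exp(-sharpness * margin))
            return p[:, None]

        return BlackBoxModel(
            task="classification",
            predict=predict,
            per_sample_loss=_bce,
            name=f"threshold_classifier({j},{tau})",
        )

    raise ValueError(f"unknown black-box kind {kind!r}")


def _no_extra(kind: str, params: dict) -> None:
    if params:
        raise ValueError(f"unexpected parameters for {kind!r}: {sorted(params)}")
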