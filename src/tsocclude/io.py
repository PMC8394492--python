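"""Reading and writing the dataset tensor and attribution tracks.

Two on-disk layouts are supported:

HDF5
    one dataset ``X`` of shape (s, h, n); optional ``Y_series`` (s, h) or
    ``Y_labels`` (s); attributes ``signal_names`` (string list) and
    ``sampling_freq`` (scalar).  Attribution arrays live in an
    ``attributions/<signal_name>`` group, each (s, h).

CSV (directory)
    one file per signal named ``<signal_name>.csv``, each row one sample of
    length h, no header; regression targets in ``Y.csv`` (s rows x h);
    classification targets in ``Y.csv`` (s rows x 1).
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import h5py
import numpy as np
import pandas as pd

from .core import SignalTensor, TargetData

__all__ = [
    "save_hdf5",
    "load_hdf5",
    "save_csv_dir",
    "load_csv_dir",
    "load_attribution_csv",
    "save_subsignals",
    "load_subsignals",
]


def save_hdf5(
    path,
    X: SignalTensor,
    Y: Optional[TargetData] = None,
    attributions: Optional[Dict[str, np.ndarray]] = None,
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=X.values)
        f.attrs["signal_names"] = list(X.signal_names)
        if X.sampling_freq is not None:
            f.attrs["sampling_freq"] = X.sampling_freq
        if Y is not None:
            if Y.kind == "regression":
                f.create_dataset("Y_series", data=Y.series)
            else:
                f.create_dataset("Y_labels", data=Y.labels)
        if attributions:
            grp = f.create_group("attributions")
            for name, arr in attributions.items():
                grp.create_dataset(name, data=np.asarray(arr, dtype=float))


def load_hdf5(path) -> Tuple[SignalTensor, Optional[TargetData]]:
    with h5py.File(path, "r") as f:
        values = f["X"][...]
        names = tuple(
            x.decode() if isinstance(x, bytes) else str(x) for x in f.attrs["signal_names"]
        )
        freq = float(f.attrs["sampling_freq"]) if "sampling_freq" in f.attrs else None
        Y = None
        if "Y_series" in f:
            Y = TargetData(kind="regression", series=f["Y_series"][...])
        elif "Y_labels" in f:
            Y = TargetData(kind="classification", labels=f["Y_labels"][...])
    return SignalTensor(values, names, freq), Y


def load_attributions_hdf5(path) -> Dict[str, np.ndarray]:
    with h5py.File(path, "r") as f:
        if "attributions" not in f:
            return {}
        return {name: ds[...] for name, ds in f["attributions"].items()}


def save_csv_dir(directory, X: SignalTensor, Y: Optional[TargetData] = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for j, name in enumerate(X.signal_names):
        pd.DataFrame(X.values[:, :, j]).to_csv(
            directory / f"{name}.csv", index=False, header=False, float_format="%.17g"
        )
    if Y is not None:
        arr = Y.series if Y.kind == "regression" else Y.labels[:, None]
        pd.DataFrame(arr).to_csv(
            directory / "Y.csv", index=False, header=False, float_format="%.17g"
        )


def load_csv_dir(
    directory,
    signal_names: Optional[Sequence[str]] = None,
    target_kind: Optional[str] = None,
    sampling_freq: Optional[float] = None,
) -> Tuple[SignalTensor, Optional[TargetData]]:
    """Load the per-signal CSV layout.

    ``signal_names`` fixes the signal order; by default all ``*.csv`` files
    except ``Y.csv`` are loaded in sorted name order.  ``target_kind``
    ("regression" or "classification") controls how ``Y.csv`` is read; it
    is required when that file exists.
    """
    directory = Path(directory)
    if signal_names is None:
        signal_names = sorted(
            p.stem for p in directory.glob("*.csv") if p.name != "Y.csv"
        )
    if not signal_names:
        raise FileNotFoundError(f"no signal CSV files found in {directory}")
    mats = []
    for name in signal_names:
        f = directory / f"{name}.csv"
        if not f.exists():
            raise FileNotFoundError(f"missing signal file {f}")
        mats.append(_read_matrix(f))
    shapes = {m.shape for m in mats}
    if len(shapes) != 1:
        raise ValueError(f"signal files disagree on (s, h): {sorted(shapes)}")
    X = SignalTensor(np.stack(mats, axis=-1), tuple(signal_names), sampling_freq)

    Y = None
    y_path = directory / "Y.csv"
    if y_path.exists():
        if target_kind is None:
            raise ValueError("Y.csv present: pass target_kind='regression' or 'classification'")
        arr = _read_matrix(y_path)
        if target_kind == "regression":
            Y = TargetData(kind="regression", series=arr)
        else:
            Y = TargetData(kind="classification", labels=arr[:, 0])
    return X, Y


def load_attribution_csv(path) -> np.ndarray:
    """One attribution array (s rows x h), aligned to the dataset tensor."""
    return _read_matrix(Path(path))


def save_subsignals(path, subsignals) -> None:
    """Persist a sequence of scored sub-signals (values + provenance) to HDF5.

    Shorter (truncated trailing-window) entries are zero-padded to the
    longest length; true lengths are recoverable from start/end.
    """
    subsignals = list(subsignals)
    with h5py.File(path, "w") as f:
        if not subsignals:
            f.attrs["empty"] = True
            return
        length = max(s.length for s in subsignals)
        values = np.zeros((len(subsignals), length))
        for i, s in enumerate(subsignals):
            values[i, : s.length] = s.values
        f.create_dataset("values", data=values)
        for field_name in ("series_index", "signal_index", "window_index", "start", "end"):
            f.create_dataset(
                field_name, data=np.array([getattr(s, field_name) for s in subsignals])
            )
        f.create_dataset("score", data=np.array([s.score for s in subsignals]))
        f.create_dataset(
            "truncated", data=np.array([s.truncated for s in subsignals], dtype=bool)
        )
        changed = np.array(
            [-1 if s.prediction_changed is None else int(s.prediction_changed)
             for s in subsignals]
        )
        f.create_dataset("prediction_changed", data=changed)


def load_subsignals(path):
    from .core import SubSignal

    with h5py.File(path, "r") as f:
        if f.attrs.get("empty", False):
            return []
        values = f["values"][...]
        fields = {
            name: f[name][...]
            for name in ("series_index", "signal_index", "window_index",
                         "start", "end", "score", "truncated", "prediction_changed")
        }
    out = []
    for i in range(values.shape[0]):
        length = int(fields["end"][i] - fields["start"][i])
        changed = int(fields["prediction_changed"][i])
        out.append(
            SubSignal(
                values=values[i, :length],
                series_index=int(fields["series_index"][i]),
                signal_index=int(fields["signal_index"][i]),
                window_index=int(fields["window_index"][i]),
                start=int(fields["start"][i]),
                end=int(fields["end"][i]),
                score=float(fields["score"][i]),
                truncated=bool(fields["truncated"][i]),
                prediction_changed=None if changed < 0 else bool(changed),
            )
        )
    return out


def _read_matrix(path: Path) -> np.ndarray:
    try:
        return pd.read_csv(path, header=None).to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"malformed numeric CSV {path}: {exc}") from exc
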