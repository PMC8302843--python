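"""Time-domain feature extraction and robust-scaler preprocessing.

Each analysis frame of the 10-channel signal yields a 20-dimensional
feature vector: the per-channel root mean square (RMS, average discharge
level) followed by the per-channel integrated EMG (IEMG, total rectified
activity):

    RMS  = sqrt( (1/N) * sum_i x_i^2 )
    IEMG = sum_i |x_i|

Both are homogeneous of degree 1 in the signal, which is what makes the
per-batch robust scaler

    f'_j = (f_j - median_j) / IQR_j

exactly invariant to per-batch multiplicative gain: scaling a batch's raw
signal by a > 0 scales median_j and IQR_j by the same a, which cancels.
Median/IQR (rather than mean/SD) keep the fit stable under the occasional
outlier frame.  Quantiles use the linear-interpolation convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping

import json
import numpy as np
import pandas as pd

from .signal_io import EmptyInputError, Frame, N_CHANNELS

__all__ = [
    "FEATURE_COLUMNS",
    "META_COLUMNS",
    "FeatureMatrix",
    "ScalerParams",
    "rms",
    "iemg",
    "extract_features",
    "fit_robust_scaler",
    "apply_robust_scaler",
]

#: Fixed column order: the RMS block then the IEMG block, CH1..CH10 each.
FEATURE_COLUMNS: tuple[str, ...] = tuple(
    [f"RMS_CH{c}" for c in range(1, N_CHANNELS + 1)]
    + [f"IEMG_CH{c}" for c in range(1, N_CHANNELS + 1)]
)

META_COLUMNS: tuple[str, ...] = (
    "frame_index", "expression", "intensity", "subject_id", "batch_id",
)


def rms(window: np.ndarray) -> float:
    """Root mean square of a 1-D signal window."""
    x = np.asarray(window, dtype=float).ravel()
    if x.size == 0:
        raise EmptyInputError("rms of an empty window is undefined")
    return float(np.sqrt(np.mean(x**2)))


def iemg(window: np.ndarray) -> float:
    """Integrated EMG: sum of absolute sample values of a 1-D window."""
    x = np.asarray(window, dtype=float).ravel()
    if x.size == 0:
        raise EmptyInputError("iemg of an empty window is undefined")
    return float(np.sum(np.abs(x)))


@dataclass
class FeatureMatrix:
    """Frame-by-feature table: 20 feature columns plus carried-through
    frame/label/subject/batch metadata, backed by a pandas DataFrame."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in FEATURE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"feature matrix missing columns {missing}")

    @property
    def values(self) -> np.ndarray:
        """(n_frames, 20) float array in the fixed column order."""
        return self.data[list(FEATURE_COLUMNS)].to_numpy(dtype=float)

    @property
    def n_frames(self) -> int:
        return len(self.data)

    def expressions(self) -> np.ndarray:
        return self.data["expression"].to_numpy()

    def intensities(self) -> np.ndarray:
        return self.data["intensity"].to_numpy(dtype=int)

    def batches(self) -> np.ndarray:
        return self.data["batch_id"].to_numpy()

    def with_values(self, values: np.ndarray) -> "FeatureMatrix":
        out = self.data.copy()
        out[list(FEATURE_COLUMNS)] = np.asarray(values, dtype=float)
        return FeatureMatrix(out)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.data.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        return cls(pd.read_csv(path))


def extract_features(frames: Iterable[Frame]) -> FeatureMatrix:
    """One 20-feature row per frame: RMS of CH1..CH10 then IEMG of CH1..CH10."""
    rows = []
    for idx, frame in enumerate(frames):
        w = np.asarray(frame.window, dtype=float)
        if w.ndim != 2 or w.shape[0] != N_CHANNELS:
            raise ValueError(f"frame {idx} window must be (10, N), got {w.shape}")
        if w.shape[1] == 0:
            raise EmptyInputError(f"frame {idx} has zero-length window")
        feats = np.concatenate(
            [np.sqrt(np.mean(w**2, axis=1)), np.sum(np.abs(w), axis=1)]
        )
        row: dict[str, object] = dict(zip(FEATURE_COLUMNS, feats))
        row["frame_index"] = idx
        row["start_index"] = frame.start_index
        if frame.label is not None:
            row["expression"] = frame.label.expression
            row["intensity"] = frame.label.intensity
        else:
            row["expression"] = None
            row["intensity"] = None
        row["subject_id"] = getattr(frame, "subject_id", None)
        row["batch_id"] = getattr(frame, "batch_id", None)
        rows.append(row)
    if not rows:
        raise EmptyInputError("no frames supplied")
    return FeatureMatrix(pd.DataFrame(rows))


def extract_features_from_recordings(recordings, window: int = 200, hop: int = 50) -> FeatureMatrix:
    """Segment each recording and extract features, tagging every frame row
    with the recording's subject and batch ids."""
    from .signal_io import segment_windows

    tables = []
    for rec in recordings:
        fm = extract_features(segment_windows(rec, window, hop))
        fm.data["subject_id"] = rec.subject_id
        fm.data["batch_id"] = rec.batch_id
        tables.append(fm.data)
    return FeatureMatrix(pd.concat(tables, ignore_index=True))


# ---------------------------------------------------------------------------
# Robust scaler


@dataclass
class ScalerParams:
    """Per-feature median and interquartile range for one fit scope.

    Features with zero IQR (degenerate, e.g. a constant column) are
    median-centred only: the divisor is substituted with 1.0.
    """

    medians: np.ndarray
    iqrs: np.ndarray
    fitted_on: str = "global"

    def __post_init__(self) -> None:
        self.medians = np.asarray(self.medians, dtype=float)
        self.iqrs = np.asarray(self.iqrs, dtype=float)
        if self.medians.shape != self.iqrs.shape or self.medians.ndim != 1:
            raise ValueError("medians and iqrs must be 1-D arrays of equal length")
        if (self.iqrs < 0).any():
            raise ValueError("IQRs must be nonnegative")

    @property
    def divisors(self) -> np.ndarray:
        return np.where(self.iqrs > 0, self.iqrs, 1.0)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "medians": self.medians.tolist(),
            "iqrs": self.iqrs.tolist(),
            "fitted_on": self.fitted_on,
        }, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalerParams":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["medians"]), np.array(d["iqrs"]), d["fitted_on"])


def _fit_params(values: np.ndarray, name: str) -> ScalerParams:
    if values.shape[0] < 4:
        raise ValueError(
            f"group {name!r} has {values.shape[0]} rows; >= 4 required for quartiles"
        )
    medians = np.median(values, axis=0)
    q1, q3 = np.percentile(values, [25, 75], axis=0, method="linear")
    return ScalerParams(medians, q3 - q1, fitted_on=name)


def fit_robust_scaler(
    features: FeatureMatrix | np.ndarray,
    scope: Literal["per_batch", "global"] = "per_batch",
) -> dict[str, ScalerParams]:
    """Fit median/IQR per feature, either globally or per acquisition batch.

    Returns a mapping group-id -> :class:`ScalerParams` (the global scope
    uses the single key ``"global"``).  Statistics need no labels, so at
    inference time a new batch's scaler is fitted on its own unlabeled frames.
    """
    if isinstance(features, np.ndarray):
        if scope != "global":
            raise ValueError("per_batch scope requires a FeatureMatrix with batch ids")
        return {"global": _fit_params(np.asarray(features, dtype=float), "global")}
    if scope == "global":
        return {"global": _fit_params(features.values, "global")}
    if scope != "per_batch":
        raise ValueError(f"unknown scope {scope!r}")
    params = {}
    for batch_id, group in features.data.groupby("batch_id", sort=False):
        values = group[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
        params[batch_id] = _fit_params(values, str(batch_id))
    return params


def apply_robust_scaler(
    features: FeatureMatrix | np.ndarray,
    params: ScalerParams | Mapping[str, ScalerParams],
) -> FeatureMatrix | np.ndarray:
    """Scale every row: ``(f - median) / IQR`` with its group's parameters.

    With a per-batch parameter mapping, each row is scaled with the params
    of its own batch.  Arrays in, arrays out; FeatureMatrix in,
    FeatureMatrix out.
    """
    if isinstance(params, ScalerParams):
        lookup: Mapping[str, ScalerParams] | None = None
        single = params
    elif set(params) == {"global"}:
        lookup, single = None, params["global"]
    else:
        lookup, single = dict(params), None

    if isinstance(features, np.ndarray):
        if single is None:
            raise ValueError("array input requires a single ScalerParams")
        values = np.asarray(features, dtype=float)
        _check_dim(values, single)
        return (values - single.medians) / single.divisors

    values = features.values
    if single is not None:
        _check_dim(values, single)
        scaled = (values - single.medians) / single.divisors
    else:
        scaled = np.empty_like(values)
        batches = features.batches()
        for batch_id in np.unique(batches):
            if batch_id not in lookup:
                raise KeyError(f"no scaler fitted for batch {batch_id!r}")
            p = lookup[batch_id]
            _check_dim(values, p)
            mask = batches == batch_id
            scaled[mask] = (values[mask] - p.medians) / p.divisors
    return features.with_values(scaled)


def _check_dim(values: np.ndarray, params: ScalerParams) -> None:
    if values.shape[1] != params.medians.shape[0]:
        raise ValueError(
            f"feature dimension {values.shape[1]} does not match scaler "
            f"dimension {params.medians.shape[0]}"
        )
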