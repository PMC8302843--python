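"""Wearability metric from facial landmarks.

A face is summarised by 38 landmark points (2-D pixel coordinates from a
photograph); the nasal tip serves as the base point.  The 37 distances from
the remaining landmarks to the base point capture the face's geometry, and
the mean relative error (MRE) of those distances between a natural-state
photo and one taken with electrodes attached quantifies how much the
wearable restricts spontaneous expression: a smaller MRE means less
restriction.  Normalising by the natural-state distance makes the metric
scale-free and invariant to rigid motion of either photo.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["N_LANDMARKS", "LandmarkSet", "landmark_distances", "mre", "mre_repeats"]

N_LANDMARKS = 38


class DegenerateGeometryError(ValueError):
    """A landmark coincides with the base point (zero reference distance)."""


@dataclass
class LandmarkSet:
    """38 planar landmark points with a designated nasal-tip base point."""

    points: np.ndarray
    base_index: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (N_LANDMARKS, 2):
            raise ValueError(
                f"points must have shape ({N_LANDMARKS}, 2), got {self.points.shape}"
            )
        if not 0 <= self.base_index < N_LANDMARKS:
            raise ValueError(f"base_index out of range: {self.base_index}")

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        lines = [f"#base_point={self.base_index}", "point_id,x,y"]
        lines += [
            f"{i},{float(x)!r},{float(y)!r}" for i, (x, y) in enumerate(self.points)
        ]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "LandmarkSet":
        path = Path(path)
        base = 0
        for line in path.read_text(encoding="utf-8").splitlines():
            if line.startswith("#base_point="):
                base = int(line.partition("=")[2])
                break
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        df = df.sort_values("point_id")
        return cls(df[["x", "y"]].to_numpy(dtype=float), base_index=base)


def landmark_distances(s: LandmarkSet) -> np.ndarray:
    """Euclidean distance of each of the 37 non-base landmarks to the base
    point, in point order with the base point omitted."""
    base = s.points[s.base_index]
    others = np.delete(s.points, s.base_index, axis=0)
    d = np.linalg.norm(others - base, axis=1)
    if (d <= 0).any():
        bad = np.flatnonzero(d <= 0)
        raise DegenerateGeometryError(
            f"landmarks {bad.tolist()} coincide with the base point"
        )
    return d


def mre(before: LandmarkSet, after: LandmarkSet) -> float:
    """Mean relative error of the base-point distances.

    ``mean_i |l_after,i - l_before,i| / l_before,i`` over the 37 non-base
    landmarks; the natural-state ('before') face is the reference.
    """
    if before.base_index != after.base_index:
        raise ValueError("before/after sets must share the same base point index")
    d_before = landmark_distances(before)
    d_after = landmark_distances(after)
    return float(np.mean(np.abs(d_after - d_before) / d_before))


def mre_repeats(
    before_sets: list[LandmarkSet],
    after_sets: list[LandmarkSet],
    average: str = "per_pair",
) -> float:
    """MRE over repeated photographs of the same expression.

    ``per_pair`` averages the MRE of each before/after pair (the per-photo
    reading); ``pooled`` averages the per-landmark relative errors of all
    pairs in one mean (the per-point reading).  Both aggregations are
    exposed because either order of averaging is defensible.
    """
    if len(before_sets) != len(after_sets) or not before_sets:
        raise ValueError("need equal, nonzero numbers of before/after sets")
    if average == "per_pair":
        return float(np.mean([mre(b, a) for b, a in zip(before_sets, after_sets)]))
    if average == "pooled":
        errs = []
        for b, a in zip(before_sets, after_sets):
            db, da = landmark_distances(b), landmark_distances(a)
            errs.append(np.abs(da - db) / db)
        return float(np.mean(np.concatenate(errs)))
    raise ValueError(f"unknown average {average!r}; use 'per_pair' or 'pooled'")
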