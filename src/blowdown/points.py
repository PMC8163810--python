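"""Discrete-return lidar-style point sets.

A :class:`PointSet` holds planar coordinates, elevation (or, after terrain
normalization, height above ground), return number, and scan angle for each
return.  CSV is the interchange format, header ``x,y,z,return_number,scan_angle``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CSV_COLUMNS = ["x", "y", "z", "return_number", "scan_angle"]


@dataclass
class PointSet:
    x_m: np.ndarray
    y_m: np.ndarray
    z_m: np.ndarray
    return_number: np.ndarray
    scan_angle_deg: np.ndarray

    def __post_init__(self) -> None:
        self.x_m = np.asarray(self.x_m, dtype=float)
        self.y_m = np.asarray(self.y_m, dtype=float)
        self.z_m = np.asarray(self.z_m, dtype=float)
        self.return_number = np.asarray(self.return_number, dtype=int)
        self.scan_angle_deg = np.asarray(self.scan_angle_deg, dtype=float)
        n = len(self.x_m)
        for arr in (self.y_m, self.z_m, self.return_number, self.scan_angle_deg):
            if len(arr) != n:
                raise ValueError("all point attribute arrays must share one length")
        if not (np.all(np.isfinite(self.x_m)) and np.all(np.isfinite(self.y_m))):
            raise ValueError("point coordinates must be finite")
        if n and self.return_number.min() < 1:
            raise ValueError("return_number must be >= 1")

    def __len__(self) -> int:
        return len(self.x_m)

    def select(self, index: np.ndarray) -> "PointSet":
        """New PointSet restricted to a boolean mask or integer index."""
        return PointSet(
            self.x_m[index],
            self.y_m[index],
            self.z_m[index],
            self.return_number[index],
            self.scan_angle_deg[index],
        )

    def with_z(self, z_m: np.ndarray) -> "PointSet":
        return PointSet(self.x_m, self.y_m, z_m, self.return_number, self.scan_angle_deg)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.x_m,
                "y": self.y_m,
                "z": self.z_m,
                "return_number": self.return_number,
                "scan_angle": self.scan_angle_deg,
            }
        )


def read_points_csv(path) -> PointSet:
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"point CSV {path} missing columns: {missing}")
    return PointSet(
        df["x"].to_numpy(),
        df["y"].to_numpy(),
        df["z"].to_numpy(),
        df["return_number"].to_numpy(),
        df["scan_angle"].to_numpy(),
    )


def write_points_csv(points: PointSet, path) -> None:
    points.to_frame().to_csv(path, index=False)
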