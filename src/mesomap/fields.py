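"""Centroid-field container: the substrate of all spatial maps.

A :class:`CentroidField` holds 2D nucleus centroids in μm (image convention:
origin top-left, y increasing downward), an optional per-cell label flag
(e.g. IddU positivity) and a per-cell serial-section id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CentroidField"]


@dataclass
class CentroidField:
    points: np.ndarray  # (n, 2) float, μm
    label_flags: np.ndarray | None = None  # (n,) bool
    section_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            self.points = self.points.reshape(0, 2)
        if self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of x, y in μm")
        n = len(self.points)
        if self.label_flags is not None:
            self.label_flags = np.asarray(self.label_flags, dtype=bool)
            if len(self.label_flags) != n:
                raise ValueError("label_flags must align one-to-one with points")
        if self.section_id is None:
            self.section_id = np.zeros(n, dtype=int)
        else:
            self.section_id = np.asarray(self.section_id, dtype=int)
            if len(self.section_id) != n:
                raise ValueError("section_id must align one-to-one with points")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def with_labels(self, flags: np.ndarray) -> "CentroidField":
        return CentroidField(self.points.copy(), np.asarray(flags, dtype=bool), self.section_id.copy())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"x_um": self.x, "y_um": self.y})
        df["label"] = self.label_flags.astype(int) if self.label_flags is not None else 0
        df["section_id"] = self.section_id
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CentroidField":
        df = pd.read_csv(path)
        labels = df["label"].to_numpy(dtype=bool) if "label" in df else None
        section = df["section_id"].to_numpy(dtype=int) if "section_id" in df else None
        return cls(df[["x_um", "y_um"]].to_numpy(dtype=float), labels, section)
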