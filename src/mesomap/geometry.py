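"""Rigid 2D transforms for serial-section registration.

Sections are aligned by translation and rotation only, so the group of
allowed motions is SE(2).  Angles are in degrees, translations in μm,
and rotation is applied before translation: ``p' = R p + t``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RigidTransform2D"]


@dataclass(frozen=True)
class RigidTransform2D:
    """Rotation (degrees, counter-clockwise in the coordinate frame) then translation (μm)."""

    rotation_deg: float = 0.0
    tx_um: float = 0.0
    ty_um: float = 0.0

    @property
    def matrix(self) -> np.ndarray:
        th = np.deg2rad(self.rotation_deg)
        c, s = np.cos(th), np.sin(th)
        return np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 2) array of points."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix.T + np.array([self.tx_um, self.ty_um])

    def inverse(self) -> "RigidTransform2D":
        t = -self.matrix.T @ np.array([self.tx_um, self.ty_um])
        return RigidTransform2D(-self.rotation_deg, t[0], t[1])

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """Return the transform equivalent to applying ``other`` first, then ``self``."""
        t = self.apply(np.array([[other.tx_um, other.ty_um]]))[0]
        return RigidTransform2D(self.rotation_deg + other.rotation_deg, t[0], t[1])

    @property
    def is_identity(self) -> bool:
        return (
            abs(self.rotation_deg) < 1e-12
            and abs(self.tx_um) < 1e-12
            and abs(self.ty_um) < 1e-12
        )
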