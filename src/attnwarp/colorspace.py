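"""Circular hue arithmetic and the fixed-luminance CIELab color wheel.

Every stimulus color lives on a circle of constant chroma in the a*b* plane
at fixed L*.  Hue is a real-valued angle in degrees on ``[0, 360)``; all
arithmetic is modulo 360, signed offsets are positive in the
counterclockwise direction, and unsigned separations are reported on
``[0, 180]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["angular_distance", "signed_offset", "rotate", "ColorWheel"]


def angular_distance(a, b):
    """Unsigned circular separation between two hue angles, in ``[0, 180]``.

    Accepts scalars or arrays (broadcast).
    """
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.minimum(d, 360.0 - d)[()]


def signed_offset(start, end):
    """Signed rotation taking ``start`` to ``end``, in ``(-180, 180]``.

    Positive offsets are counterclockwise.
    """
    d = (np.asarray(end, dtype=float) - np.asarray(start, dtype=float)) % 360.0
    return np.where(d > 180.0, d - 360.0, d)[()]


def rotate(h, offset):
    """Rotate a hue angle by a signed offset in degrees, modulo 360."""
    m = (np.asarray(h, dtype=float) + np.asarray(offset, dtype=float)) % 360.0
    # fmod of a tiny negative can round up to exactly 360.0
    return np.where(m >= 360.0, m - 360.0, m)[()]


@dataclass(frozen=True)
class ColorWheel:
    """Equally spaced hues on a fixed-luminance circle in CIELab.

    Entry ``i`` sits at hue ``i * 360 / n_colors`` and maps to the Lab triple
    ``(center_L, center_a + radius*cos(hue + phase),
    center_b + radius*sin(hue + phase))``.  The phase is a free convention:
    only relative hue distances matter downstream, so it defaults to 0
    (hue 0 points along +a*).
    """

    n_colors: int = 360
    center_L: float = 54.0
    center_a: float = 21.5
    center_b: float = 11.5
    radius: float = 49.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.n_colors < 1:
            raise ValueError("n_colors must be positive")
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    @property
    def hues(self) -> np.ndarray:
        """Hue angle of every wheel entry, degrees in ``[0, 360)``."""
        return np.arange(self.n_colors) * (360.0 / self.n_colors)

    def lab(self) -> np.ndarray:
        """All wheel entries as an ``(n_colors, 3)`` array of (L, a, b)."""
        ang = np.deg2rad(self.hues + self.phase)
        out = np.empty((self.n_colors, 3))
        out[:, 0] = self.center_L
        out[:, 1] = self.center_a + self.radius * np.cos(ang)
        out[:, 2] = self.center_b + self.radius * np.sin(ang)
        return out

    def lab_at(self, hue: float) -> np.ndarray:
        """Lab triple of the wheel entry nearest to ``hue`` (degrees)."""
        idx = int(np.round(float(hue) % 360.0 / (360.0 / self.n_colors))) % self.n_colors
        return self.lab()[idx]

    def to_frame(self) -> pd.DataFrame:
        lab = self.lab()
        return pd.DataFrame(
            {"hue": self.hues, "L": lab[:, 0], "a": lab[:, 1], "b": lab[:, 2]}
        )

    def to_csv(self, path) -> None:
        """Export the wheel as a CSV with columns hue, L, a, b."""
        self.to_frame().to_csv(path, index=False)
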