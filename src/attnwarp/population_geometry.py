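"""Color-tuned population code, attentional gain, distances, and MDS warping.

A homogeneous bank of tuning curves tiles the hue circle; feature-based
attention multiplies each neuron's output by a feature-similarity gain
centered on the attended hue.  Stimulus-evoked population patterns are
compared by Euclidean distance, embedded with classical (Torgerson) MDS,
and the local expansion of the embedding quantifies the warping: with the
gain centered 20 degrees to one side of a target hue, the embedded distance
from the target to a foil on the gain side (away from the distractor)
exceeds the distance to the mirror foil.

The code is deterministic (no response noise).  Tuning shape and width are
free choices — the defaults (von Mises, kappa 1.5; gain amplitude 1, gain
concentration 0.5) put the unattended code close to a planar circle while
leaving a clearly signed warp under gain; a wrapped-Gaussian family is
provided behind the same interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .colorspace import angular_distance, signed_offset

__all__ = [
    "PopulationSpec",
    "GainProfile",
    "MDSResult",
    "GeometryResult",
    "population_response",
    "distance_matrix",
    "classical_mds",
    "asymmetry_index",
    "response_space_asymmetry",
    "analyze_geometry",
]

TUNING_FAMILIES = ("von_mises", "wrapped_gaussian")


@dataclass(frozen=True)
class PopulationSpec:
    """Bank of identical tuning curves with equally spaced preferred hues."""

    n_neurons: int = 180
    kappa: float = 1.5  # concentration; wrapped-Gaussian SD is 1/sqrt(kappa) rad
    family: str = "von_mises"
    response_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_neurons < 8:
            raise ValueError("n_neurons must be >= 8")
        if not self.kappa > 0:
            raise ValueError("kappa must be > 0")
        if self.family not in TUNING_FAMILIES:
            raise ValueError(f"family must be one of {TUNING_FAMILIES}")

    @property
    def preferred_hues(self) -> np.ndarray:
        return np.arange(self.n_neurons) * (360.0 / self.n_neurons)

    def tuning(self, theta, mu):
        """Tuning value for stimulus ``theta`` at preferred hue ``mu``.

        Unit peak at ``theta == mu``; depends only on the unsigned hue
        separation, so the curve is exactly even.
        """
        d = np.deg2rad(angular_distance(theta, mu))
        if self.family == "von_mises":
            f = np.exp(self.kappa * (np.cos(d) - 1.0))
        else:
            sd = 1.0 / np.sqrt(self.kappa)
            # wrap enough terms for the widest widths used in practice
            f = sum(
                np.exp(-0.5 * ((d + 2.0 * np.pi * k) / sd) ** 2) for k in range(-3, 4)
            )
            f = f / sum(
                np.exp(-0.5 * ((2.0 * np.pi * k) / sd) ** 2) for k in range(-3, 4)
            )
        return self.response_scale * f


@dataclass(frozen=True)
class GainProfile:
    """Feature-similarity multiplicative gain centered on the attended hue.

    ``gain(mu) = 1 + amplitude * exp(width * (cos(mu - attended_hue) - 1))``
    which lies in ``[1, 1 + amplitude]`` and is the identity when
    ``amplitude == 0``.
    """

    attended_hue: float = 20.0
    amplitude: float = 1.0
    width: float = 0.5

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not self.width > 0:
            raise ValueError("width must be > 0")

    def gain(self, mu):
        d = np.deg2rad(angular_distance(mu, self.attended_hue))
        return 1.0 + self.amplitude * np.exp(self.width * (np.cos(d) - 1.0))


def population_response(
    theta: float, spec: PopulationSpec, gain: Optional[GainProfile] = None
) -> np.ndarray:
    """Gain-modulated response of every neuron to stimulus hue ``theta``."""
    mu = spec.preferred_hues
    r = spec.tuning(theta, mu)
    if gain is not None:
        r = gain.gain(mu) * r
    return r


def _response_matrix(grid, spec, gain):
    grid = np.asarray(grid, dtype=float)
    mu = spec.preferred_hues
    f = spec.tuning(grid[:, None], mu[None, :])
    if gain is not None:
        f = gain.gain(mu)[None, :] * f
    return f


def distance_matrix(
    grid, spec: PopulationSpec, gain: Optional[GainProfile] = None
) -> np.ndarray:
    """Pairwise Euclidean distances between stimulus-evoked patterns.

    Entry (j, k) is the norm of ``r(grid[j]) - r(grid[k])``; the matrix is
    symmetric with a zero diagonal.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid is empty")
    return squareform(pdist(_response_matrix(grid, spec, gain)))


@dataclass
class MDSResult:
    coords: np.ndarray  # (n, dims) canonicalized embedding
    eigenvalues: np.ndarray  # all eigenvalues, descending
    degenerate: bool


def classical_mds(distances: np.ndarray, dims: int = 2, anchor: int = 0) -> MDSResult:
    """Torgerson double-centering + eigendecomposition embedding.

    The top-``dims`` components are kept and the free isometry is
    canonicalized: centroid at the origin (automatic), the ``anchor`` point
    rotated onto the +x axis, and the reflection fixed so the point a
    quarter of the way around the list has positive y.  ``degenerate`` is
    set when fewer than ``dims`` eigenvalues are positive.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distances must be a square matrix")
    n = D.shape[0]
    d2 = D ** 2
    row = d2.mean(axis=1)
    B = -0.5 * (d2 - row[:, None] - row[None, :] + row.mean())
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    tol = max(n, 1) * np.finfo(float).eps * max(abs(w[0]), 1.0)
    degenerate = int(np.sum(w > tol)) < dims
    lam = np.clip(w[:dims], 0.0, None)
    X = V[:, :dims] * np.sqrt(lam)[None, :]
    if dims == 2 and not degenerate:
        X = _canonicalize(X, anchor, (anchor + n // 4) % n)
    return MDSResult(coords=X, eigenvalues=w, degenerate=degenerate)


def _canonicalize(X: np.ndarray, anchor: int, quarter: int) -> np.ndarray:
    ang = np.arctan2(X[anchor, 1], X[anchor, 0])
    c, s = np.cos(-ang), np.sin(-ang)
    R = np.array([[c, -s], [s, c]])
    X = X @ R.T
    if X[quarter, 1] < 0:
        X = X * np.array([1.0, -1.0])
    return X


def _grid_index(grid: np.ndarray, hue: float) -> int:
    idx = int(np.argmin(angular_distance(grid, hue)))
    if angular_distance(grid[idx], hue) > 1e-9:
        raise ValueError(f"hue {hue} not on the evaluation grid")
    return idx


def asymmetry_index(
    spec: PopulationSpec,
    gain: GainProfile,
    target: float = 0.0,
    foil_delta: float = 10.0,
    grid_step: float = 1.0,
) -> float:
    """Embedded-distance ratio of the away-side foil over the toward-side foil.

    The away side is the side of the target on which the gain is centered
    (the off-tuned direction, opposite the distractor).  Values above 1 mean
    the representation was stretched away from the distractor.  With
    ``amplitude == 0`` the gain is the identity and the two sides are
    exchangeable by construction, so the index is exactly 1.
    """
    if gain.amplitude == 0.0:
        return 1.0  # identity gain: both foils are exchangeable by symmetry
    away = float(np.sign(signed_offset(target, gain.attended_hue)))
    if away == 0.0:
        raise ValueError("attended hue must be offset from the target when amplitude > 0")
    grid = np.arange(0.0, 360.0, grid_step)
    dm = distance_matrix(grid, spec, gain)
    mds = classical_mds(dm, dims=2, anchor=_grid_index(grid, target))
    if mds.degenerate:
        raise ValueError("degenerate embedding: fewer than 2 positive eigenvalues")
    i0 = _grid_index(grid, target)
    i_away = _grid_index(grid, (target + away * foil_delta) % 360.0)
    i_toward = _grid_index(grid, (target - away * foil_delta) % 360.0)
    X = mds.coords
    return float(
        np.linalg.norm(X[i0] - X[i_away]) / np.linalg.norm(X[i0] - X[i_toward])
    )


def response_space_asymmetry(
    spec: PopulationSpec,
    gain: GainProfile,
    target: float = 0.0,
    foil_delta: float = 10.0,
) -> float:
    """Same ratio computed on full response-pattern distances (MDS-free check)."""
    away = float(np.sign(signed_offset(target, gain.attended_hue)))
    if away == 0.0:
        away = 1.0
    pts = np.array(
        [target, (target + away * foil_delta) % 360.0, (target - away * foil_delta) % 360.0]
    )
    dm = distance_matrix(pts, spec, gain)
    return float(dm[0, 1] / dm[0, 2])


@dataclass
class GeometryResult:
    """Distance matrix, embedding, subsampled rendering, and warp metrics."""

    grid: np.ndarray
    distances: np.ndarray
    embedding: np.ndarray
    eigenvalues: np.ndarray
    subsampled: pd.DataFrame  # every `subsample_step` degrees, for plotting
    radii_cv: float
    asymmetry: float
    expansion_hue: float  # midpoint hue of the widest nearest-neighbor gap

    def embedding_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"hue": self.grid, "x": self.embedding[:, 0], "y": self.embedding[:, 1]}
        )

    def metrics(self) -> dict:
        return {
            "radii_cv": self.radii_cv,
            "asymmetry_index": self.asymmetry,
            "expansion_hue": self.expansion_hue,
        }

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.distances).to_csv(out / "distance_matrix.csv", index=False)
        self.embedding_frame().to_csv(out / "embedding.csv", index=False)
        self.subsampled.to_csv(out / "embedding_subsampled.csv", index=False)
        (out / "metrics.json").write_text(json.dumps(self.metrics(), indent=2))


def analyze_geometry(
    spec: PopulationSpec,
    gain: Optional[GainProfile] = None,
    target: float = 0.0,
    foil_delta: float = 10.0,
    grid_step: float = 1.0,
    subsample_step: float = 10.0,
) -> GeometryResult:
    """Full geometry pipeline for one population/gain configuration."""
    grid = np.arange(0.0, 360.0, grid_step)
    dm = distance_matrix(grid, spec, gain)
    mds = classical_mds(dm, dims=2, anchor=_grid_index(grid, target))
    if mds.degenerate:
        raise ValueError("degenerate embedding: fewer than 2 positive eigenvalues")
    X = mds.coords
    radii = np.linalg.norm(X, axis=1)
    radii_cv = float(radii.std() / radii.mean())
    nn = np.linalg.norm(X - np.roll(X, -1, axis=0), axis=1)
    gap = int(np.argmax(nn))  # gap between grid[gap] and grid[gap+1]
    expansion_hue = float((grid[gap] + grid_step / 2.0) % 360.0)
    if gain is not None and gain.amplitude > 0:
        asym = asymmetry_index(spec, gain, target, foil_delta, grid_step)
    else:
        asym = 1.0
    keep = np.isclose(
        np.mod(grid, subsample_step), 0.0
    )
    sub = pd.DataFrame({"hue": grid[keep], "x": X[keep, 0], "y": X[keep, 1]})
    return GeometryResult(
        grid=grid,
        distances=dm,
        embedding=X,
        eigenvalues=mds.eigenvalues,
        subsampled=sub,
        radii_cv=radii_cv,
        asymmetry=asym,
        expansion_hue=expansion_hue,
    )
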