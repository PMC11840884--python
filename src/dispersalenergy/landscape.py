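"""Patch landscapes on a Cartesian plane (metres) and distance matrices.

Two seeded generators cover the canonical fixtures: patches scattered
uniformly at random, and patches clustered around random centres
(spatially autocorrelated habitat).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "Landscape",
    "generate_random_landscape",
    "generate_clustered_landscape",
    "pairwise_distances",
]

Extent = Union[float, Tuple[float, float]]


def _as_extent(extent: Extent) -> Tuple[float, float]:
    if np.isscalar(extent):
        extent = (float(extent), float(extent))  # type: ignore[arg-type]
    w, h = float(extent[0]), float(extent[1])  # type: ignore[index]
    if not (w > 0 and h > 0):
        raise ValueError(f"extent must be positive, got {extent!r}")
    return w, h


@dataclass(frozen=True)
class Landscape:
    """A set of habitat patches with unique ids and (x, y) positions in metres."""

    patch_ids: Tuple[str, ...]
    coords: np.ndarray  # (n, 2) float array
    extent: Tuple[float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        ids = tuple(str(p) for p in self.patch_ids)
        if len(ids) != len(coords):
            raise ValueError("patch_ids and coords length mismatch")
        if len(set(ids)) != len(ids):
            raise ValueError("patch ids must be unique")
        extent = self.extent
        if extent is None:
            span = coords.max(axis=0) - coords.min(axis=0) if len(coords) else np.zeros(2)
            extent = (float(max(span[0], 1.0)), float(max(span[1], 1.0)))
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "patch_ids", ids)
        object.__setattr__(self, "extent", tuple(float(e) for e in extent))

    def __len__(self) -> int:
        return len(self.patch_ids)

    @property
    def bounding_box(self) -> Tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the patch coordinates."""
        lo, hi = self.coords.min(axis=0), self.coords.max(axis=0)
        return float(lo[0]), float(lo[1]), float(hi[0]), float(hi[1])

    # --- CSV round trip ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"patch_id": self.patch_ids, "x": self.coords[:, 0], "y": self.coords[:, 1]}
        )

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Landscape":
        """Read a ``patch_id,x,y`` table (coordinates in metres)."""
        df = pd.read_csv(path)
        missing = {"patch_id", "x", "y"} - set(df.columns)
        if missing:
            raise ValueError(f"landscape CSV missing column(s): {sorted(missing)}")
        return cls(tuple(df["patch_id"].astype(str)), df[["x", "y"]].to_numpy(float))


def _make_ids(n: int) -> Tuple[str, ...]:
    return tuple(f"p{i}" for i in range(n))


def generate_random_landscape(
    n: int, extent: Extent = 1.0, seed: Union[int, None] = None
) -> Landscape:
    """``n`` patches i.i.d. uniform over a rectangle of size ``extent`` [m].

    Deterministic under a fixed ``seed``.
    """
    if n < 2:
        raise ValueError(f"need at least 2 patches, got {n}")
    w, h = _as_extent(extent)
    rng = np.random.default_rng(seed)
    coords = rng.uniform(low=(0.0, 0.0), high=(w, h), size=(n, 2))
    return Landscape(_make_ids(n), coords, (w, h))


def generate_clustered_landscape(
    n: int,
    n_clusters: int,
    spread: float,
    extent: Extent = 1.0,
    seed: Union[int, None] = None,
) -> Landscape:
    """``n`` patches clustered around ``n_clusters`` random centres.

    Centres are uniform over the extent; patches scatter isotropically
    (Gaussian, sd = ``spread`` metres) around centres assigned round-robin,
    and are reflected back into the extent so all coordinates stay inside.
    """
    if n_clusters < 1 or n < n_clusters:
        raise ValueError(f"need n >= n_clusters >= 1, got n={n}, n_clusters={n_clusters}")
    if not spread > 0:
        raise ValueError(f"spread must be > 0, got {spread!r}")
    w, h = _as_extent(extent)
    rng = np.random.default_rng(seed)
    centres = rng.uniform(low=(0.0, 0.0), high=(w, h), size=(n_clusters, 2))
    assignment = np.arange(n) % n_clusters
    coords = centres[assignment] + rng.normal(scale=spread, size=(n, 2))
    # reflect strays back into the rectangle (repeat for far outliers)
    for dim, size in enumerate((w, h)):
        col = coords[:, dim]
        col = np.abs(col)                     # reflect at 0
        col = size - np.abs(size - col % (2 * size))  # fold into [0, size]
        coords[:, dim] = col
    return Landscape(_make_ids(n), coords, (w, h))


def pairwise_distances(landscape: Landscape) -> np.ndarray:
    """Symmetric Euclidean distance matrix [m] between all patches."""
    if len(landscape) < 2:
        raise ValueError("need at least 2 patches for a distance matrix")
    return squareform(pdist(landscape.coords))
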