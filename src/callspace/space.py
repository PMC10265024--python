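"""Acoustic trait spaces: 2-D embedding, kernel-density areas, and
density-weighted overlap statistics.

All calls to be compared are embedded jointly (comparisons across birds or
blocks are meaningless in separately fitted embeddings).  Each subset of the
embedding (one bird in one block, or the pooled flockmates) gets a Gaussian
kernel density estimated on a shared regular grid.  Repertoire diversity is
the area of the highest-density region (HDR) containing a fixed probability
mass L (default 0.95): cells are sorted by density and accumulated until mass
L is reached, which measures irregular, multimodal repertoires without a
convexity assumption.

Directional overlap of space A onto B is the share of A's probability mass
inside A's own HDR that also lies inside B's HDR:

    overlap(A -> B) = P_A(hdr A and hdr B) / P_A(hdr A)

so self-overlap is exactly 1 and overlap in high-density regions of A counts
more than overlap in its tails.  The symmetric summary is the arithmetic mean
of the two directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.manifold import TSNE

DEFAULT_PERPLEXITY = 30.0
DEFAULT_ITERATIONS = 1000
DEFAULT_GRID = 200
DEFAULT_HDR_LEVEL = 0.95
MIN_KDE_POINTS = 5


@dataclass
class Embedding:
    """Joint 2-D embedding of a scaled feature table."""

    coords: np.ndarray  # (n, 2)
    perplexity: float
    iterations: int
    seed: int


def embed(
    features: np.ndarray | pd.DataFrame,
    perplexity: float = DEFAULT_PERPLEXITY,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
) -> Embedding:
    """t-SNE embedding to 2 dimensions; bit-reproducible given the seed.

    Requires at least ``3 * perplexity`` rows.
    """
    X = np.asarray(features, dtype=float)
    min_rows = int(np.ceil(3 * perplexity))
    if X.shape[0] < min_rows:
        raise ValueError(
            f"need >= {min_rows} rows for perplexity {perplexity}, "
            f"got {X.shape[0]}"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=iterations,
        init="pca",
        random_state=seed,
        method="barnes_hut",
    )
    coords = tsne.fit_transform(X)
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("embedding produced non-finite coordinates")
    return Embedding(coords=np.asarray(coords, dtype=float),
                     perplexity=perplexity, iterations=iterations, seed=seed)


@dataclass
class Grid:
    """Regular 2-D lattice shared by all spaces built from one embedding."""

    x_centers: np.ndarray
    y_centers: np.ndarray

    @property
    def cell_area(self) -> float:
        return float(
            (self.x_centers[1] - self.x_centers[0])
            * (self.y_centers[1] - self.y_centers[0])
        )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.y_centers.size, self.x_centers.size)

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x_centers, self.y_centers)

    def same_as(self, other: "Grid") -> bool:
        return (
            self.x_centers.size == other.x_centers.size
            and self.y_centers.size == other.y_centers.size
            and np.allclose(self.x_centers, other.x_centers)
            and np.allclose(self.y_centers, other.y_centers)
        )


def make_grid(
    points: np.ndarray,
    resolution: int = DEFAULT_GRID,
    pad_bandwidths: float = 3.0,
) -> Grid:
    """Build a grid spanning ``points`` padded by a multiple of the Silverman
    bandwidth in each dimension."""
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    factor = n ** (-1.0 / 6.0)  # Silverman/Scott rate for d = 2
    pads = [
        max(pad_bandwidths * factor * pts[:, d].std(), 1e-9) for d in (0, 1)
    ]
    x = np.linspace(pts[:, 0].min() - pads[0], pts[:, 0].max() + pads[0],
                    resolution)
    y = np.linspace(pts[:, 1].min() - pads[1], pts[:, 1].max() + pads[1],
                    resolution)
    return Grid(x_centers=x, y_centers=y)


@dataclass
class AcousticSpace:
    """Kernel density of one subset on a shared grid, with its HDR area."""

    key: tuple
    grid: Grid
    density: np.ndarray       # grid.shape, sums (x cell area) to 1
    hdr_mask: np.ndarray      # boolean, the level-L highest-density region
    hdr_level: float
    n_points: int

    @property
    def area(self) -> float:
        """HDR area in embedding units squared."""
        return float(self.hdr_mask.sum() * self.grid.cell_area)

    def mass_inside(self, mask: np.ndarray) -> float:
        """Probability mass of this space inside a boolean grid mask."""
        return float(self.density[mask].sum() * self.grid.cell_area)


def hdr_mask_from_density(
    density: np.ndarray, cell_area: float, level: float
) -> np.ndarray:
    """Smallest-area cell set holding probability mass >= level: cells sorted
    by density, accumulated until the level is reached."""
    flat = density.ravel()
    order = np.argsort(flat)[::-1]
    cum = np.cumsum(flat[order]) * cell_area
    k = int(np.searchsorted(cum, level)) + 1
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(density.shape)


def kde_space(
    points: np.ndarray,
    grid: Grid | None = None,
    bandwidth_rule: str = "silverman",
    grid_resolution: int = DEFAULT_GRID,
    hdr_level: float = DEFAULT_HDR_LEVEL,
    key: tuple = (),
) -> AcousticSpace:
    """Gaussian-kernel density of one subset's embedded points.

    Bandwidth follows the requested rule on the subset's own points.  With no
    shared grid given, a private grid padded 3 bandwidths beyond the point
    range is built.  The density is renormalized on the grid so cell masses
    sum to 1.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if pts.shape[0] < MIN_KDE_POINTS:
        raise ValueError(
            f"subset too small for a kernel density: need >= {MIN_KDE_POINTS} "
            f"points, got {pts.shape[0]}"
        )
    if grid is None:
        grid = make_grid(pts, resolution=grid_resolution)
    xx, yy = grid.mesh()
    dx = grid.x_centers[1] - grid.x_centers[0]
    dy = grid.y_centers[1] - grid.y_centers[0]
    factor = pts.shape[0] ** (-1.0 / 6.0)
    bw = factor * pts.std(axis=0, ddof=1)
    if np.all(bw >= (0.5 * dx, 0.5 * dy)):
        kde = gaussian_kde(pts.T, bw_method=bandwidth_rule)
        density = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(grid.shape)
    else:
        # subset narrower than the shared grid can resolve: diagonal kernel
        # with bandwidths floored at half a cell, so mass always lands on
        # the lattice
        bwf = np.maximum(bw, (0.5 * dx, 0.5 * dy))
        gx = (grid.x_centers[None, :] - pts[:, 0][:, None]) / bwf[0]
        gy = (grid.y_centers[None, :] - pts[:, 1][:, None]) / bwf[1]
        kx = np.exp(-0.5 * gx**2)
        ky = np.exp(-0.5 * gy**2)
        density = np.einsum("ny,nx->yx", ky, kx) / (
            2 * np.pi * bwf[0] * bwf[1] * pts.shape[0]
        )
    total = density.sum() * grid.cell_area
    if total <= 0:
        raise RuntimeError("kernel density integrated to zero on the grid")
    density = density / total
    mask = hdr_mask_from_density(density, grid.cell_area, hdr_level)
    return AcousticSpace(
        key=key,
        grid=grid,
        density=density,
        hdr_mask=mask,
        hdr_level=hdr_level,
        n_points=pts.shape[0],
    )


def directional_overlap(a: AcousticSpace, b: AcousticSpace) -> float:
    """Share of A's HDR-contained probability mass that lies inside B's HDR.

    Density-weighted by construction: overlap through A's high-density cells
    contributes more than overlap through its tails.  Requires both spaces on
    the same grid.
    """
    if not a.grid.same_as(b.grid):
        raise ValueError("spaces are on different grids; rebuild on a shared grid")
    denom = a.mass_inside(a.hdr_mask)
    if denom <= 0:
        return 0.0
    return a.mass_inside(a.hdr_mask & b.hdr_mask) / denom


@dataclass
class OverlapResult:
    """Both directional overlaps and their arithmetic mean."""

    directional_ab: float
    directional_ba: float

    @property
    def mean_overlap(self) -> float:
        return 0.5 * (self.directional_ab + self.directional_ba)


def mean_overlap(a: AcousticSpace, b: AcousticSpace) -> OverlapResult:
    """Single pairwise mean overlap: the two directional proportions averaged."""
    return OverlapResult(
        directional_ab=directional_overlap(a, b),
        directional_ba=directional_overlap(b, a),
    )
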