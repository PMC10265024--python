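"""Per-individual vocal response variables per recording block.

From the joint acoustic trait space, each bird in each block yields:

- ``vocal_output``: number of contact calls produced;
- ``diversity_change``: HDR area in the block minus the same bird's block-1
  (baseline) area — positive means a more diverse repertoire than baseline;
- ``plasticity``: mean density-weighted overlap with the bird's own block-1
  space, stored as similarity to the starting self (lower = more plastic);
- ``convergence``: mean density-weighted overlap with the pooled space of the
  bird's three flockmates in the same block (block 1 is pre-exposure and is
  flagged accordingly).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .space import (
    DEFAULT_GRID,
    DEFAULT_HDR_LEVEL,
    MIN_KDE_POINTS,
    AcousticSpace,
    Grid,
    kde_space,
    make_grid,
    mean_overlap,
)

BLOCKS = (1, 2, 3, 4, 5)


def vocal_output(meta: pd.DataFrame, blocks=BLOCKS) -> pd.DataFrame:
    """Exact call counts per individual x block; zero-call cells included."""
    individuals = sorted(meta["individual"].unique()) if len(meta) else []
    idx = pd.MultiIndex.from_product(
        [individuals, list(blocks)], names=["individual", "block"]
    )
    counts = (
        meta.groupby(["individual", "block"]).size().reindex(idx, fill_value=0)
        if len(meta)
        else pd.Series(0, index=idx, dtype=int)
    )
    return counts.rename("vocal_output").reset_index()


def build_spaces(
    coords: np.ndarray,
    meta: pd.DataFrame,
    grid: Grid | None = None,
    grid_resolution: int = DEFAULT_GRID,
    hdr_level: float = DEFAULT_HDR_LEVEL,
) -> tuple[dict, dict, Grid]:
    """Kernel-density spaces per (individual, block) and pooled-flockmates
    spaces per (individual, block), all on one shared grid.

    Subsets with fewer than the minimum point count are skipped with a
    warning.  ``meta`` must carry individual, flock, and block columns aligned
    row-wise with ``coords``.
    """
    coords = np.asarray(coords, dtype=float)
    if grid is None:
        grid = make_grid(coords, resolution=grid_resolution)
    individual_spaces: dict[tuple, AcousticSpace] = {}
    pooled_spaces: dict[tuple, AcousticSpace] = {}
    for (ind, block), sub in meta.groupby(["individual", "block"]):
        pts = coords[sub.index.to_numpy()]
        if pts.shape[0] < MIN_KDE_POINTS:
            warnings.warn(
                f"skipping {ind} block {block}: only {pts.shape[0]} calls"
            )
            continue
        individual_spaces[(ind, block)] = kde_space(
            pts, grid=grid, hdr_level=hdr_level, key=(ind, block)
        )
    for (ind, block) in list(individual_spaces):
        flock = meta.loc[meta["individual"] == ind, "flock"].iloc[0]
        mates = meta[
            (meta["flock"] == flock)
            & (meta["individual"] != ind)
            & (meta["block"] == block)
        ]
        pts = coords[mates.index.to_numpy()]
        if pts.shape[0] < MIN_KDE_POINTS:
            warnings.warn(
                f"skipping pooled flockmates of {ind} block {block}: "
                f"only {pts.shape[0]} calls"
            )
            continue
        pooled_spaces[(ind, block)] = kde_space(
            pts, grid=grid, hdr_level=hdr_level, key=(ind, block, "pooled")
        )
    return individual_spaces, pooled_spaces, grid


def diversity_change(
    spaces: dict[int, AcousticSpace], blocks=BLOCKS
) -> dict[int, float]:
    """Block-k HDR area minus the block-1 baseline area, k >= 2.

    Block 1 is reported as identically 0.
    """
    if 1 not in spaces:
        raise ValueError("block-1 baseline space is missing")
    base = spaces[1].area
    out = {1: 0.0}
    for b in blocks[1:]:
        if b in spaces:
            out[b] = spaces[b].area - base
    return out


def plasticity(
    spaces: dict[int, AcousticSpace], blocks=BLOCKS
) -> dict[int, float]:
    """Mean overlap of each block's space with the block-1 space, stored as
    similarity to the starting self (block 1 maps to exactly 1)."""
    if 1 not in spaces:
        raise ValueError("block-1 baseline space is missing")
    out = {1: 1.0}
    for b in blocks[1:]:
        if b in spaces:
            out[b] = mean_overlap(spaces[b], spaces[1]).mean_overlap
    return out


def convergence(
    individual_spaces: dict[int, AcousticSpace],
    pooled_spaces: dict[int, AcousticSpace],
    blocks=BLOCKS,
) -> dict[int, float]:
    """Mean overlap of the individual's space with the pooled space of its
    three flockmates, per block (block 1 = pre-exposure)."""
    out = {}
    for b in blocks:
        if b in individual_spaces and b in pooled_spaces:
            out[b] = mean_overlap(
                individual_spaces[b], pooled_spaces[b]
            ).mean_overlap
    return out


def compute_vocal_metrics(
    coords: np.ndarray,
    meta: pd.DataFrame,
    grid_resolution: int = DEFAULT_GRID,
    hdr_level: float = DEFAULT_HDR_LEVEL,
) -> pd.DataFrame:
    """Full VocalMetricsTable: one row per individual x block with the four
    response variables, plus the HDR area itself."""
    meta = meta.reset_index(drop=True)
    blocks = tuple(sorted(meta["block"].unique()))
    ind_spaces, pooled, _ = build_spaces(
        coords, meta, grid_resolution=grid_resolution, hdr_level=hdr_level
    )
    counts = vocal_output(meta, blocks=blocks).set_index(["individual", "block"])

    info = meta.drop_duplicates("individual").set_index("individual")
    rows = []
    for ind in sorted(meta["individual"].unique()):
        by_block = {
            b: s for (i, b), s in ind_spaces.items() if i == ind
        }
        pooled_by_block = {
            b: s for (i, b), s in pooled.items() if i == ind
        }
        try:
            div = diversity_change(by_block, blocks)
            plas = plasticity(by_block, blocks)
        except ValueError:
            warnings.warn(f"{ind}: no baseline space; diversity/plasticity skipped")
            div, plas = {}, {}
        conv = convergence(by_block, pooled_by_block, blocks)
        for b in blocks:
            rows.append(
                {
                    "individual": ind,
                    "flock": info.loc[ind, "flock"] if "flock" in info else "",
                    "age_class": info.loc[ind, "age_class"]
                    if "age_class" in info
                    else "",
                    "block": b,
                    "vocal_output": int(counts.loc[(ind, b), "vocal_output"])
                    if (ind, b) in counts.index
                    else 0,
                    "area": by_block[b].area if b in by_block else np.nan,
                    "diversity_change": div.get(b, np.nan),
                    "plasticity": plas.get(b, np.nan),
                    "convergence": conv.get(b, np.nan),
                }
            )
    return pd.DataFrame(rows)
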