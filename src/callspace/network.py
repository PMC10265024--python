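"""Weighted 4-node social networks per flock and their summary metrics.

Three dimensions per flock: proximity (edge = proportion of valid snapshots
with the dyad within 10 cm), affiliation and agonism (edge = undirected
interaction count).  Density is the share of the six possible dyads with a
nonzero edge; strength is the weighted degree of each bird.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

CLOSE_PROXIMITY_CM = 10.0  # one body length; inclusive threshold
DIMENSIONS = ("proximity", "affiliation", "agonism")
_EVENT_TYPE = {"affiliation": "affiliative", "agonism": "agonistic"}
PERIODS = {"all": None, "first_half": (1, 2), "second_half": (3, 4)}


@dataclass
class SocialNetwork:
    """Symmetric weighted adjacency for one flock and one social dimension."""

    flock: str
    dimension: str
    adjacency: pd.DataFrame  # birds x birds, zero diagonal

    def __post_init__(self):
        a = self.adjacency.to_numpy(dtype=float)
        if not np.allclose(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if np.any(a < 0):
            raise ValueError("edge weights must be non-negative")

    @property
    def birds(self) -> list[str]:
        return list(self.adjacency.index)

    def to_networkx(self) -> nx.Graph:
        return nx.from_pandas_adjacency(self.adjacency)


def _empty_adjacency(birds: list[str]) -> pd.DataFrame:
    return pd.DataFrame(0.0, index=list(birds), columns=list(birds))


def proximity_edges(
    snapshots: pd.DataFrame,
    birds: list[str],
    threshold_cm: float = CLOSE_PROXIMITY_CM,
    flock: str = "",
) -> SocialNetwork:
    """Proximity network: per dyad, the proportion of snapshots with a valid
    distance measurement in which the pair was within ``threshold_cm``
    (inclusive).  Dyads with no valid snapshot get weight 0 with a warning.
    """
    known = set(birds)
    seen = set(snapshots["bird_a"]) | set(snapshots["bird_b"])
    unknown = seen - known
    if unknown:
        raise ValueError(f"snapshot rows reference unknown birds: {sorted(unknown)}")
    adj = _empty_adjacency(birds)
    for i, a in enumerate(birds):
        for b in birds[i + 1:]:
            rows = snapshots[
                ((snapshots["bird_a"] == a) & (snapshots["bird_b"] == b))
                | ((snapshots["bird_a"] == b) & (snapshots["bird_b"] == a))
            ]
            valid = rows["distance_cm"].dropna()
            if len(valid) == 0:
                warnings.warn(f"dyad ({a}, {b}) has no valid snapshots; weight 0")
                weight = 0.0
            else:
                weight = float((valid <= threshold_cm).sum() / len(valid))
            adj.loc[a, b] = adj.loc[b, a] = weight
    return SocialNetwork(flock=flock, dimension="proximity", adjacency=adj)


def interaction_edges(
    events: pd.DataFrame,
    dimension: str,
    birds: list[str],
    period: str = "all",
    flock: str = "",
) -> SocialNetwork:
    """Affiliation or agonism network: undirected interaction counts per dyad
    (actor/receiver collapsed), optionally restricted to the first (blocks
    1-2) or second (blocks 3-4) half of the observation period."""
    if dimension not in _EVENT_TYPE:
        raise ValueError(f"unknown dimension {dimension!r}; expected one of "
                         f"{sorted(_EVENT_TYPE)}")
    if period not in PERIODS:
        raise ValueError(f"unknown period {period!r}; expected one of "
                         f"{sorted(PERIODS)}")
    bad_types = set(events["type"]) - set(_EVENT_TYPE.values())
    if bad_types:
        raise ValueError(f"unknown interaction types in event log: {sorted(bad_types)}")
    known = set(birds)
    seen = set(events["actor"]) | set(events["receiver"])
    unknown = seen - known
    if unknown:
        raise ValueError(f"event rows reference unknown birds: {sorted(unknown)}")

    sub = events[events["type"] == _EVENT_TYPE[dimension]]
    if PERIODS[period] is not None and len(sub):
        if "block" in sub.columns:
            blocks = sub["block"]
        else:
            # 2 video sessions per block
            blocks = (sub["session"] - 1) // 2 + 1
        sub = sub[blocks.isin(PERIODS[period])]

    adj = _empty_adjacency(birds)
    for _, row in sub.iterrows():
        a, b = row["actor"], row["receiver"]
        adj.loc[a, b] += 1
        adj.loc[b, a] += 1
    return SocialNetwork(flock=flock, dimension=dimension, adjacency=adj)


def network_density(net: SocialNetwork) -> float:
    """Share of possible dyads with a nonzero edge (6 for a 4-bird flock)."""
    a = net.adjacency.to_numpy(dtype=float)
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    possible = len(iu[0])
    return float((a[iu] > 0).sum() / possible)


def node_strength(net: SocialNetwork) -> pd.Series:
    """Weighted degree: sum of edge weights incident to each bird."""
    return net.adjacency.sum(axis=1).rename("strength")


def network_metrics(net: SocialNetwork) -> pd.DataFrame:
    """One row per bird: flock, dimension, density (flock-level) and strength."""
    strength = node_strength(net)
    return pd.DataFrame(
        {
            "flock": net.flock,
            "dimension": net.dimension,
            "individual": strength.index,
            "density": network_density(net),
            "strength": strength.to_numpy(),
        }
    )
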