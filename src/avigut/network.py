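"""Variable-level Bray-Curtis threshold network.

The eight design variables (four intestine segments and four ages) each get
a mean composition profile; pairs whose Bray-Curtis dissimilarity falls
strictly below a cutoff (default 0.6) are connected, and nodes are placed
at their first two PCoA coordinates of the 8x8 dissimilarity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .beta import pcoa
from .io import FormatError, RelAbundanceMatrix, SampleMetadata
from scipy.spatial.distance import pdist, squareform

DEFAULT_CUTOFF = 0.6


def variable_profiles(rel: RelAbundanceMatrix, meta: SampleMetadata,
                      per_cell: bool = False) -> pd.DataFrame:
    """Mean composition per design variable.

    Default: 8 profiles — one per segment (averaged over ages and pens) and
    one per age (averaged over segments and pens).  ``per_cell=True``
    instead returns the 16 segment x age cell profiles.
    Every profile column sums to 1 (means of compositions stay closed).
    """
    meta.require_samples(rel.sample_ids)
    sub = meta.df.loc[rel.sample_ids]
    profiles: dict[str, pd.Series] = {}
    if per_cell:
        for (seg, age), grp in sub.groupby(["segment", "age_days"], sort=True):
            profiles[f"{seg}_{age}"] = rel.df[list(grp.index)].mean(axis=1)
    else:
        for seg, grp in sub.groupby("segment", sort=True):
            profiles[str(seg)] = rel.df[list(grp.index)].mean(axis=1)
        for age, grp in sub.groupby("age_days", sort=True):
            profiles[f"age_{age}"] = rel.df[list(grp.index)].mean(axis=1)
    expected = 16 if per_cell else 8
    if len(profiles) != expected:
        raise FormatError(
            f"expected {expected} design variables, found {len(profiles)} "
            "(empty factor level?)"
        )
    return pd.DataFrame(profiles)


def node_type(name: str) -> str:
    return "age" if name.startswith("age_") else "segment"


@dataclass
class VariableNetwork:
    graph: nx.Graph
    dissimilarity: DistanceMatrix
    cutoff: float
    coordinates: pd.DataFrame  # nodes x (x, y)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["dissimilarity"])
                for u, v, d in self.graph.edges(data=True)]

    @property
    def node_table(self) -> dict[str, tuple[str, float, float]]:
        out = {}
        for node in self.graph.nodes:
            x, y = self.coordinates.loc[node, ["x", "y"]]
            out[node] = (node_type(node), float(x), float(y))
        return out


def build_network(profiles: pd.DataFrame,
                  cutoff: float = DEFAULT_CUTOFF) -> VariableNetwork:
    """Connect variable pairs with Bray-Curtis dissimilarity strictly < cutoff.

    Node coordinates are the first two PCoA axes of the variable
    dissimilarity matrix.
    """
    if not 0 < cutoff <= 1:
        raise FormatError(f"cutoff must be within (0, 1], got {cutoff}")
    if profiles.shape[1] < 2:
        raise FormatError("need at least 2 variable profiles")
    names = [str(c) for c in profiles.columns]
    dm = DistanceMatrix(
        squareform(pdist(profiles.to_numpy(dtype=float).T, metric="braycurtis")),
        ids=names,
    )
    ordination = pcoa(dm)
    coords = ordination.coordinates
    xy = pd.DataFrame(index=names, columns=["x", "y"], dtype=float)
    xy["x"] = coords.iloc[:, 0] if coords.shape[1] >= 1 else 0.0
    xy["y"] = coords.iloc[:, 1] if coords.shape[1] >= 2 else 0.0
    xy = xy.fillna(0.0)

    g = nx.Graph()
    g.add_nodes_from(names)
    arr = np.asarray(dm.data)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if arr[i, j] < cutoff:
                g.add_edge(names[i], names[j], dissimilarity=float(arr[i, j]))
    return VariableNetwork(graph=g, dissimilarity=dm, cutoff=cutoff,
                           coordinates=xy)
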