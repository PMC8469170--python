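"""Core-microbiota computation with the adaptive rare-taxon filter.

A group's core is the set of taxa present (non-zero relative abundance) in
every one of its samples, computed after an adaptive prevalence filter:
the abundance threshold is five times the smallest non-zero relative
abundance observed anywhere in the matrix, and a taxon is retained only if
it exceeds that threshold in at least 50% of the samples of at least one
group.  Cores for multiple groups are then partitioned into Venn regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import FormatError, RelAbundanceMatrix


@dataclass
class CoreResult:
    threshold: float
    retained: list[str]
    cores: dict[str, set[str]]
    regions: dict[tuple[str, ...], list[str]]


def rare_taxon_filter(rel: RelAbundanceMatrix, groups: pd.Series | Mapping[str, str],
                      multiplier: float = 5.0, strict_abundance: bool = True,
                      inclusive_quota: bool = True) -> tuple[list[str], float]:
    """Adaptive rare-taxon filter.

    threshold = `multiplier` x (global minimum non-zero entry).  A taxon is
    retained iff, in at least one group, it is above the threshold in at
    least 50% of that group's samples.  "Above" is strict by default; the
    50% quota is inclusive at exact halves by default.
    """
    values = rel.df.to_numpy(dtype=float)
    positive = values[values > 0]
    if positive.size == 0:
        raise FormatError("all-zero relative abundance matrix")
    threshold = multiplier * float(positive.min())

    if not isinstance(groups, pd.Series):
        groups = pd.Series(dict(groups))
    missing = [s for s in rel.sample_ids if s not in groups.index]
    if missing:
        raise FormatError(f"samples without a group: {', '.join(missing)}")

    retained: list[str] = []
    group_cols = {
        g: [s for s in rel.sample_ids if groups[s] == g]
        for g in pd.unique(groups[rel.sample_ids])
    }
    for taxon in rel.taxon_ids:
        row = rel.df.loc[taxon]
        for cols in group_cols.values():
            vals = row[cols].to_numpy(dtype=float)
            hits = (vals > threshold).sum() if strict_abundance else (vals >= threshold).sum()
            quota = len(cols) / 2.0
            ok = hits >= quota if inclusive_quota else hits > quota
            if ok:
                retained.append(taxon)
                break
    return retained, threshold


def core_taxa(rel: RelAbundanceMatrix, sample_set: Sequence[str],
              retained: Sequence[str]) -> set[str]:
    """Retained taxa with strictly positive abundance in every listed sample."""
    if len(sample_set) == 0:
        raise FormatError("empty sample set")
    unknown = [s for s in sample_set if s not in rel.df.columns]
    if unknown:
        raise FormatError(f"unknown sample id(s): {', '.join(unknown)}")
    sub = rel.df.loc[list(retained), list(sample_set)]
    present = (sub.to_numpy(dtype=float) > 0).all(axis=1)
    return set(np.array(list(retained))[present])


def venn_partition(cores: Mapping[str, set[str]]
                   ) -> dict[tuple[str, ...], list[str]]:
    """Assign every taxon in the union of cores to its exact Venn region.

    Returns all 2^k - 1 regions (k = number of groups), keyed by the sorted
    tuple of group names whose cores contain the region's taxa; regions are
    disjoint and cover the union.
    """
    names = sorted(cores)
    if not 2 <= len(names) <= 4:
        raise FormatError("Venn partition supports 2-4 groups")
    regions: dict[tuple[str, ...], list[str]] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            regions[combo] = []
    for taxon in sorted(set().union(*cores.values())):
        membership = tuple(g for g in names if taxon in cores[g])
        regions[membership].append(taxon)
    return regions


def compute_cores(rel: RelAbundanceMatrix, groups: pd.Series,
                  multiplier: float = 5.0, strict_abundance: bool = True,
                  inclusive_quota: bool = True) -> CoreResult:
    """Filter, per-group cores, and Venn regions in one call."""
    retained, threshold = rare_taxon_filter(
        rel, groups, multiplier=multiplier,
        strict_abundance=strict_abundance, inclusive_quota=inclusive_quota,
    )
    cores = {
        str(g): core_taxa(rel, [s for s in rel.sample_ids if groups[s] == g], retained)
        for g in pd.unique(groups[rel.sample_ids])
    }
    regions = venn_partition(cores) if 2 <= len(cores) <= 4 else {}
    return CoreResult(threshold=threshold, retained=retained,
                      cores=cores, regions=regions)
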