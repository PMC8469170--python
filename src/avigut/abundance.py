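"""Rank aggregation and relative-abundance transforms.

ASVs missing the requested rank are pooled into an explicit "Unclassified"
row rather than dropped, so column totals (and compositional closure) are
preserved exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import RANKS, CountMatrix, FormatError, RelAbundanceMatrix, TaxonomyTable

UNCLASSIFIED = "Unclassified"
OTHERS = "Others"


def aggregate_by_rank(counts: CountMatrix, taxonomy: TaxonomyTable,
                      rank: str) -> CountMatrix:
    """Sum ASV counts over all ASVs sharing a value at `rank`.

    Column totals are preserved exactly; ASVs without an assignment at the
    rank contribute to the "Unclassified" row.
    """
    if rank not in RANKS:
        raise FormatError(f"unknown rank {rank!r}; expected one of {list(RANKS)}")
    missing = [t for t in counts.taxon_ids if t not in taxonomy.df.index]
    if missing:
        raise FormatError(f"taxa absent from taxonomy: {', '.join(missing[:5])}")
    labels = taxonomy.df.loc[counts.taxon_ids, rank].fillna(UNCLASSIFIED)
    agg = counts.df.groupby(labels.to_numpy()).sum()
    agg.index = agg.index.astype(str)
    # keep Unclassified last for readability
    if UNCLASSIFIED in agg.index:
        order = [i for i in agg.index if i != UNCLASSIFIED] + [UNCLASSIFIED]
        agg = agg.loc[order]
    return CountMatrix(agg, allow_empty_samples=counts.allow_empty_samples)


def to_relative(counts: CountMatrix) -> RelAbundanceMatrix:
    """Divide each sample column by its total."""
    totals = counts.df.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise FormatError(
            f"cannot normalize sample(s) with zero total: {', '.join(map(str, zero))}"
        )
    return RelAbundanceMatrix(counts.df / totals)


def top_k_with_others(rel: RelAbundanceMatrix, k: int) -> RelAbundanceMatrix:
    """Keep the k taxa with highest overall mean abundance; pool the rest.

    The pooled remainder becomes an "Others" row so columns still sum to 1.
    """
    if k < 0:
        raise FormatError("k must be non-negative")
    if k >= len(rel.taxon_ids):
        return RelAbundanceMatrix(rel.df.copy())
    means = rel.df.mean(axis=1)
    keep = list(means.sort_values(ascending=False).index[:k])
    kept = rel.df.loc[keep]
    others = rel.df.drop(index=keep).sum(axis=0)
    out = pd.concat([kept, others.to_frame(OTHERS).T])
    return RelAbundanceMatrix(out)
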