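"""Beta diversity: Bray-Curtis dissimilarity, PCoA, and one-factor PERMANOVA.

PERMANOVA (the ADONIS test) partitions the squared dissimilarities into
between- and within-group sums of squares and assesses the pseudo-F
statistic by permuting sample labels; when the number of distinct
relabelings is no larger than the requested permutation count the test
enumerates them exhaustively instead of sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sympy.utilities.iterables import multiset_permutations

from .io import CountMatrix, FormatError, RelAbundanceMatrix


def bray_curtis(matrix: CountMatrix | RelAbundanceMatrix) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between sample columns.

    d(x, y) = sum|x_i - y_i| / sum(x_i + y_i); 0 for identical samples,
    1 for disjoint support.
    """
    df = matrix.df
    values = df.to_numpy(dtype=float).T  # samples x taxa
    if values.size == 0:
        raise FormatError("empty matrix")
    if values.min() < 0:
        raise FormatError("abundances must be non-negative")
    totals = values.sum(axis=1)
    if (totals == 0).any():
        bad = [s for s, t in zip(df.columns, totals) if t == 0]
        raise FormatError(f"zero-total sample(s): {', '.join(map(str, bad))}")
    condensed = pdist(values, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=[str(c) for c in df.columns])


@dataclass
class PcoaResult:
    """Classical (metric) multidimensional scaling of a dissimilarity matrix."""

    coordinates: pd.DataFrame     # samples x retained axes
    eigenvalues: np.ndarray       # all eigenvalues, descending (negatives kept)
    proportion_explained: np.ndarray  # per retained axis, over positive eigvals


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> PcoaResult:
    """Gower double-centering of -d^2/2 followed by eigendecomposition.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue).  Axes with
    non-positive eigenvalues are dropped from the coordinates but their
    eigenvalues are still reported (no Lingoes/Cailliez correction).
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    if n_axes is not None and n_axes < 1:
        raise FormatError("n_axes must be >= 1")
    a = -0.5 * d ** 2
    centerer = np.eye(n) - np.full((n, n), 1.0 / n)
    b = centerer @ a @ centerer
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    positive = eigvals > tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    props = eigvals[positive] / eigvals[positive].sum()
    if n_axes is not None:
        coords = coords[:, :n_axes]
        props = props[:n_axes]
    columns = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=columns),
        eigenvalues=eigvals,
        proportion_explained=props,
    )


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int | None
    exhaustive: bool = False


def _permanova_ss(d2: np.ndarray, codes: np.ndarray,
                  n_groups: int) -> tuple[float, float]:
    """(SS_between, SS_within) from squared dissimilarities and group codes."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        members = np.flatnonzero(codes == g)
        if len(members) > 1:
            sub = d2[np.ix_(members, members)]
            ss_within += sub[np.triu_indices(len(members), k=1)].sum() / len(members)
    return ss_total - ss_within, ss_within


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    ss_b, ss_w = _permanova_ss(d2, codes, n_groups)
    return (ss_b / (n_groups - 1)) / (ss_w / (n - n_groups))


def _n_distinct_relabelings(counts: list[int]) -> int:
    n = sum(counts)
    total = math.factorial(n)
    for c in counts:
        total //= math.factorial(c)
    return total


def permanova(dm: DistanceMatrix, grouping, n_permutations: int = 999,
              seed: int | None = None) -> PermanovaResult:
    """One-factor PERMANOVA on a dissimilarity matrix.

    `grouping` is a sequence of labels aligned with dm.ids (or a mapping /
    pandas Series keyed by id).  The permutation p-value uses the standard
    +1 convention counting the observed labeling itself; with few enough
    distinct relabelings the null distribution is enumerated exactly.
    """
    ids = list(dm.ids)
    if isinstance(grouping, pd.Series):
        labels = [grouping[i] for i in ids]
    elif isinstance(grouping, dict):
        labels = [grouping[i] for i in ids]
    else:
        labels = list(grouping)
        if len(labels) != len(ids):
            raise FormatError("grouping length does not match matrix size")
    levels = sorted(set(map(str, labels)))
    if len(levels) < 2:
        raise FormatError("PERMANOVA requires at least 2 groups")
    codes = np.array([levels.index(str(l)) for l in labels])
    n, a = len(ids), len(levels)
    if n - a < 1:
        raise FormatError("PERMANOVA requires residual degrees of freedom")
    d2 = np.asarray(dm.data, dtype=float) ** 2

    f_obs = _pseudo_f(d2, codes, a)
    ss_b, ss_w = _permanova_ss(d2, codes, a)
    r2 = ss_b / (ss_b + ss_w)

    group_sizes = [int((codes == g).sum()) for g in range(a)]
    n_distinct = _n_distinct_relabelings(group_sizes)
    if n_distinct <= n_permutations:
        f_null = np.array([
            _pseudo_f(d2, np.array(perm), a)
            for perm in multiset_permutations(list(codes))
        ])
        p = float((f_null >= f_obs - 1e-12).sum()) / n_distinct
        return PermanovaResult(f_obs, r2, p, n_distinct, seed, exhaustive=True)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm, a) >= f_obs - 1e-12:
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)
    return PermanovaResult(f_obs, r2, p, n_permutations, seed, exhaustive=False)
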