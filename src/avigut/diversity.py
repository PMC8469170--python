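"""Alpha diversity under rarefaction, and the paired group comparisons.

Shannon and Chao1 are computed after subsampling every sample, without
replacement, to a common depth (default 37,761 reads — the smallest library
in the study design) and averaging over iterations (default 1,000), which
removes sequencing-effort bias from both indices.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix, FormatError

DEFAULT_DEPTH = 37_761
DEFAULT_ITERATIONS = 1_000


def shannon(counts: np.ndarray, base: float | None = None) -> float:
    """Shannon entropy H = -sum p_i log p_i over non-zero proportions.

    Natural log by default; pass ``base=2`` for bits.
    """
    x = np.asarray(counts, dtype=float)
    if x.size == 0 or x.sum() <= 0:
        raise FormatError("Shannon index undefined for an all-zero vector")
    if x.min() < 0:
        raise FormatError("counts must be non-negative")
    p = x[x > 0] / x.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def chao1(counts: np.ndarray, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton (F1) and doubleton (F2) counts.

    Bias-corrected form (default): S_obs + F1(F1-1)/(2(F2+1)), defined even
    when F2 = 0.  Classic form: S_obs + F1^2/(2 F2), an error when F2 = 0.
    """
    x = np.asarray(counts)
    if x.size and not np.issubdtype(x.dtype, np.integer):
        if not np.all(np.equal(np.mod(x, 1), 0)):
            raise FormatError("Chao1 requires integer counts, not relative abundances")
        x = x.astype(np.int64)
    if x.size and x.min() < 0:
        raise FormatError("counts must be non-negative")
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        raise FormatError("classic Chao1 undefined when there are no doubletons")
    return s_obs + f1 * f1 / (2.0 * f2)


def rarefy(counts: np.ndarray, depth: int, rng: np.random.Generator,
           sample_id: str = "<sample>") -> np.ndarray:
    """Subsample a count vector without replacement to exactly `depth` reads.

    Multivariate hypergeometric draw; the output always sums to `depth`.
    """
    x = np.asarray(counts)
    if not np.issubdtype(x.dtype, np.integer):
        x = x.astype(np.int64)
    total = int(x.sum())
    if depth > total:
        raise FormatError(
            f"sample {sample_id}: depth {depth} exceeds library size {total}"
        )
    if depth == total:
        return x.copy()
    return rng.multivariate_hypergeometric(x, depth, method="marginals")


@dataclass
class AlphaResult:
    """Per-sample mean and sd of each index over rarefaction iterations."""

    table: pd.DataFrame  # index: sample ids; columns: <index>_mean, <index>_sd
    depth: int
    n_iterations: int
    seed: int


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # substream keyed by a stable hash of the id, so results do not depend
    # on sample order
    return np.random.default_rng([seed, zlib.crc32(sample_id.encode())])


def rarefied_alpha(counts: CountMatrix, depth: int = DEFAULT_DEPTH,
                   iterations: int = DEFAULT_ITERATIONS, seed: int = 0,
                   indices: tuple[str, ...] = ("shannon", "chao1"),
                   log_base: float | None = None,
                   bias_corrected: bool = True,
                   on_shallow: str = "error") -> AlphaResult:
    """Rarefaction-averaged alpha diversity for every sample.

    ``on_shallow`` controls samples whose library is below `depth`:
    "error" (default) aborts listing them, "drop" excludes them.
    """
    funcs = {}
    for name in indices:
        if name == "shannon":
            funcs[name] = lambda v: shannon(v, base=log_base)
        elif name == "chao1":
            funcs[name] = lambda v: chao1(v, bias_corrected=bias_corrected)
        else:
            raise FormatError(f"unknown alpha index {name!r}")
    totals = counts.sample_totals()
    shallow = [s for s in counts.sample_ids if totals[s] < depth]
    if shallow:
        if on_shallow == "drop":
            pass
        else:
            raise FormatError(
                f"sample(s) below rarefaction depth {depth}: {', '.join(shallow)}"
            )
    rows = {}
    for sample_id in counts.sample_ids:
        if sample_id in shallow:
            continue
        vec = counts.df[sample_id].to_numpy()
        rng = _sample_rng(seed, sample_id)
        draws = {name: np.empty(iterations) for name in funcs}
        for it in range(iterations):
            sub = rarefy(vec, depth, rng, sample_id=sample_id)
            for name, fn in funcs.items():
                draws[name][it] = fn(sub)
        row = {}
        for name in funcs:
            row[f"{name}_mean"] = draws[name].mean()
            row[f"{name}_sd"] = draws[name].std(ddof=1) if iterations > 1 else 0.0
        rows[sample_id] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    return AlphaResult(table=table, depth=depth, n_iterations=iterations, seed=seed)


def paired_test(group_a, group_b, kind: str = "t") -> tuple[float, float]:
    """Two-sided paired comparison: Student t or Wilcoxon signed-rank.

    Returns (statistic, p).  For the t-test, identical vectors give
    (0.0, 1.0); constant non-zero differences (sd = 0) raise an error.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise FormatError("paired test requires equal-length 1-D vectors")
    if a.size < 2:
        raise FormatError("paired test requires n >= 2")
    diff = a - b
    if kind == "t":
        if np.all(diff == 0):
            return 0.0, 1.0
        if np.std(diff, ddof=1) == 0:
            raise FormatError(
                "paired t-test undefined: differences are constant (sd = 0)"
            )
        res = stats.ttest_rel(a, b)
        return float(res.statistic), float(res.pvalue)
    if kind == "wilcoxon":
        if np.all(diff == 0):
            raise FormatError(
                "Wilcoxon signed-rank undefined: all paired differences are zero"
            )
        res = stats.wilcoxon(a, b)
        return float(res.statistic), float(res.pvalue)
    raise FormatError(f"unknown test kind {kind!r}; expected 't' or 'wilcoxon'")
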