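"""qPCR standard-curve fitting and absolute 16S copy-number estimation.

A dilution series of a synthesized 16S V4 amplicon gives Ct values that are
linear in log10 template copies.  Ordinary least squares of Ct on log10
copies yields the standard curve; unknowns are quantified by inverting it,
and amplification efficiency follows from the slope (10^(-1/slope) - 1,
1.0 meaning perfect doubling each cycle).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import FormatError


@dataclass
class StandardCurve:
    slope: float          # Ct per log10 copies; negative for a valid curve
    intercept: float      # Ct at 1 copy
    r_squared: float
    efficiency: float     # fraction; 1.0 = 100%
    dynamic_range: float  # log10 units spanned by the dilution points
    ct_min: float
    ct_max: float
    valid: bool


def amplification_efficiency(slope: float) -> float:
    """E = 10^(-1/slope) - 1; the canonical efficiency of a qPCR assay."""
    return 10.0 ** (-1.0 / slope) - 1.0


def fit_standard_curve(log10_copies, ct) -> StandardCurve:
    """OLS fit of Ct against log10 input copies over a dilution series."""
    x = np.asarray(log10_copies, dtype=float)
    y = np.asarray(ct, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FormatError("log10_copies and ct must be equal-length 1-D vectors")
    if len(np.unique(x)) < 3:
        raise FormatError("standard curve requires >= 3 distinct dilution levels")
    fit = stats.linregress(x, y)
    slope, intercept = float(fit.slope), float(fit.intercept)
    valid = slope < 0
    if not valid:
        warnings.warn(
            f"fitted slope {slope:.4f} is non-negative; curve flagged invalid",
            stacklevel=2,
        )
    return StandardCurve(
        slope=slope,
        intercept=intercept,
        r_squared=float(fit.rvalue) ** 2,
        efficiency=amplification_efficiency(slope) if valid else float("nan"),
        dynamic_range=float(x.max() - x.min()),
        ct_min=float(y.min()),
        ct_max=float(y.max()),
        valid=valid,
    )


def estimate_copies(curve: StandardCurve, ct_table: pd.DataFrame,
                    negative_control_ct: float | None = None,
                    dna_input_ng: float | None = None) -> pd.DataFrame:
    """Interpolate copy numbers from sample Ct values.

    `ct_table` needs columns ``sample_id`` and ``ct``; technical duplicates
    (repeated sample_id) are averaged on the Ct scale.  Output columns:
    mean_ct, copies, in_range (mean Ct inside the curve's Ct span), and —
    when provided — flagged_by_negative_control and copies_per_ng.
    """
    if not curve.valid:
        raise FormatError("cannot quantify against an invalid standard curve")
    for col in ("sample_id", "ct"):
        if col not in ct_table.columns:
            raise FormatError(f"ct table missing column {col!r}")
    mean_ct = ct_table.groupby("sample_id", sort=False)["ct"].mean()
    log10_copies = (mean_ct - curve.intercept) / curve.slope
    out = pd.DataFrame({
        "mean_ct": mean_ct,
        "copies": 10.0 ** log10_copies,
        "in_range": (mean_ct >= curve.ct_min) & (mean_ct <= curve.ct_max),
    })
    if negative_control_ct is not None:
        out["flagged_by_negative_control"] = mean_ct >= negative_control_ct
    if dna_input_ng is not None:
        if dna_input_ng <= 0:
            raise FormatError("dna_input_ng must be positive")
        out["copies_per_ng"] = out["copies"] / dna_input_ng
    return out
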