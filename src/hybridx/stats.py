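"""Shared statistical helpers.

Benjamini-Hochberg adjustment lives here so that every module (differential
expression, asymmetry panel, phenotype comparisons) corrects p-values through
one code path.
"""

from __future__ import annotations

import math

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "round_sig"]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries (tests that could not be computed) are passed through as NaN
    and do not count toward the family size.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum() == 0:
        return out
    out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def round_sig(x: float, digits: int) -> float:
    """Round to a number of significant digits (half away handled by decimal rounding)."""
    if x == 0 or not math.isfinite(x):
        return x
    exp = math.floor(math.log10(abs(x)))
    return round(x, digits - 1 - exp)
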