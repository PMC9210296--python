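"""Sperm phenotype summaries: weighted morphology index and nonparametric tests.

The morphology index weights the four scored sperm categories (normal with a
long apical hook -> severely abnormal/amorphous) as 3/2/1/0, so an all-normal
animal scores 3.0 and an all-amorphous one 0.0. Trait comparisons between
each hybrid and each parent use a two-sided Wilcoxon rank-sum test (normal
approximation with tie correction), with medians, bootstrap SEs of the
median, and BH adjustment across the whole trait x pair panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .stats import bh_adjust

MORPH_COLUMNS = ["morph_normal", "morph_slight", "morph_abnormal", "morph_severe"]
MORPH_WEIGHTS = np.array([3.0, 2.0, 1.0, 0.0])

DEFAULT_TRAITS = ["testes_mg_g", "sv_mg_g", "motility", "sperm_count", "morphology_index"]
DEFAULT_PAIRS = [
    ("domXmus", "dom"), ("domXmus", "mus"),
    ("musXdom", "dom"), ("musXdom", "mus"),
    ("musXdom", "domXmus"),
]


def morphology_index(counts) -> float:
    """Weighted index in [0, 3]: (3 n1 + 2 n2 + 1 n3 + 0 n4) / total scored."""
    c = np.asarray(counts, dtype=float)
    if c.shape[-1] != 4:
        raise ValueError("expected four morphology category counts")
    if (c < 0).any():
        raise ValueError("category counts must be non-negative")
    total = c.sum(axis=-1)
    if np.any(total == 0):
        raise ValueError("no scored sperm")
    return (c @ MORPH_WEIGHTS) / total


def add_morphology_index(phenotypes: pd.DataFrame) -> pd.DataFrame:
    out = phenotypes.copy()
    out["morphology_index"] = morphology_index(out[MORPH_COLUMNS].to_numpy())
    return out


def bootstrap_se_median(values: np.ndarray, n_boot: int = 1000, seed: int = 0) -> float:
    rng = np.random.default_rng(seed)
    values = np.asarray(values, dtype=float)
    medians = np.median(
        values[rng.integers(0, len(values), size=(n_boot, len(values)))], axis=1
    )
    return float(medians.std(ddof=1))


@dataclass
class TraitSummary:
    cross: str
    versus: str
    trait: str
    n: int
    median: float
    se_median: float
    p_raw: float
    p_adj: float | None = None
    lower_flag: bool = False  # set when hybrid median is lower and p_adj < alpha


def summarize_and_test(
    phenotypes: pd.DataFrame,
    traits: list[str] | None = None,
    pairs: list[tuple[str, str]] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Trait medians (± bootstrap SE) and Wilcoxon comparisons, BH-corrected.

    One row per (hybrid, parent, trait). Direction flags mark traits where
    the first cross's median is lower and the adjusted p is below ``alpha``.
    """
    df = phenotypes
    if "morphology_index" not in df.columns and set(MORPH_COLUMNS) <= set(df.columns):
        df = add_morphology_index(df)
    traits = traits or [t for t in DEFAULT_TRAITS if t in df.columns]
    pairs = pairs or [p for p in DEFAULT_PAIRS if {p[0], p[1]} <= set(df["cross"])]

    rows: list[TraitSummary] = []
    for cross_a, cross_b in pairs:
        a_all = df[df["cross"] == cross_a]
        b_all = df[df["cross"] == cross_b]
        for trait in traits:
            a = a_all[trait].dropna().to_numpy(dtype=float)
            b = b_all[trait].dropna().to_numpy(dtype=float)
            if len(a) < 3 or len(b) < 3:
                raise ValueError(f"need >= 3 animals per group for {cross_a} vs {cross_b}, {trait}")
            if np.ptp(np.concatenate([a, b])) == 0:
                warnings.warn(f"constant trait {trait!r} in {cross_a} vs {cross_b}; p set to 1")
                p = 1.0
            else:
                p = float(mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)
            rows.append(
                TraitSummary(
                    cross=cross_a,
                    versus=cross_b,
                    trait=trait,
                    n=len(a),
                    median=float(np.median(a)),
                    se_median=bootstrap_se_median(a, n_boot=n_boot, seed=seed),
                    p_raw=p,
                )
            )

    adj = bh_adjust(np.array([r.p_raw for r in rows]))
    out_rows = []
    for r, pa in zip(rows, adj):
        r.p_adj = float(pa)
        other = df[df["cross"] == r.versus][r.trait].dropna()
        r.lower_flag = bool(r.median < float(np.median(other)) and r.p_adj < alpha)
        out_rows.append(
            (r.cross, r.versus, r.trait, r.n, r.median, r.se_median, r.p_raw, r.p_adj, r.lower_flag)
        )
    return pd.DataFrame(
        out_rows,
        columns=["cross", "versus", "trait", "n", "median", "se_median", "p_raw", "p_adj", "lower_flag"],
    )
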