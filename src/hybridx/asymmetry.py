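"""X-vs-autosome misexpression asymmetry and DE-gene overlap between contrasts.

Disrupted MSCI shows up as a directional excess: among genes expressed in a
stage, the fraction with higher expression in the hybrid is larger on the X
than on the autosomes. Each contrast x stage is summarized by up/down counts
for the X and the autosomes and compared with a Pearson chi-squared test on
the 2x2 direction table (no continuity correction), with BH adjustment across
the whole panel emitted in one run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .stats import bh_adjust


@dataclass
class DirectionSummary:
    contrast: str
    cell_type: str
    chromosome_class: str  # "X" or "autosome"
    n_up: int
    n_down: int
    n_de_up: int
    n_de_down: int
    n_expressed: int


@dataclass
class AsymmetryTest:
    contrast: str
    cell_type: str
    scope: str  # "all_expressed" or "de_only"
    chi2: float
    df: int
    p_raw: float
    p_adj: float | None = None
    undefined: bool = False


def classify_direction(de: pd.DataFrame, genes: pd.DataFrame) -> tuple[DirectionSummary, DirectionSummary]:
    """Split expressed genes of one contrast into X / autosome up/down counts.

    Up means logfc > 0 (higher in the contrast's first group); genes with
    logfc exactly 0 are counted in neither direction. DE counts use the
    is_de flag.
    """
    known = set(genes["gene_id"])
    missing = [g for g in de["gene_id"] if g not in known]
    if missing:
        raise ValueError(f"DE genes absent from annotation: {missing[:5]}")
    is_x = genes.set_index("gene_id")["is_x"]
    sub = de[de["expressed_in_cell_type"]].copy()
    sub["is_x"] = is_x.loc[sub["gene_id"]].to_numpy()
    contrast = de["contrast"].iloc[0] if len(de) else ""
    cell_type = de["cell_type"].iloc[0] if len(de) else ""

    out = []
    for x_flag, label in ((True, "X"), (False, "autosome")):
        s = sub[sub["is_x"] == x_flag]
        up = s["logfc"] > 0
        down = s["logfc"] < 0
        out.append(
            DirectionSummary(
                contrast=contrast,
                cell_type=cell_type,
                chromosome_class=label,
                n_up=int(up.sum()),
                n_down=int(down.sum()),
                n_de_up=int((up & s["is_de"]).sum()),
                n_de_down=int((down & s["is_de"]).sum()),
                n_expressed=len(s),
            )
        )
    return out[0], out[1]


def xa_asymmetry_test(
    x: DirectionSummary,
    a: DirectionSummary,
    scope: str = "all_expressed",
    continuity: bool = False,
) -> AsymmetryTest:
    """Pearson chi2 on [[x_up, x_down], [auto_up, auto_down]].

    With any zero marginal the test is undefined and flagged rather than
    computed. ``p_adj`` is filled in later by :func:`adjust_panel`.
    """
    if (x.contrast, x.cell_type) != (a.contrast, a.cell_type):
        raise ValueError("summaries come from different contrasts")
    if scope == "all_expressed":
        table = np.array([[x.n_up, x.n_down], [a.n_up, a.n_down]], dtype=float)
    elif scope == "de_only":
        table = np.array([[x.n_de_up, x.n_de_down], [a.n_de_up, a.n_de_down]], dtype=float)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return AsymmetryTest(x.contrast, x.cell_type, scope, np.nan, 1, np.nan, undefined=True)
    stat, p, _, _ = chi2_contingency(table, correction=continuity)
    return AsymmetryTest(x.contrast, x.cell_type, scope, float(stat), 1, float(p))


def adjust_panel(tests: list[AsymmetryTest]) -> pd.DataFrame:
    """BH-adjust across every test emitted in one run; returns the panel table."""
    p = np.array([t.p_raw for t in tests], dtype=float)
    adj = bh_adjust(p)
    rows = []
    for t, pa in zip(tests, adj):
        t.p_adj = None if np.isnan(pa) else float(pa)
        rows.append(
            (t.contrast, t.cell_type, t.scope, t.chi2, t.df, t.p_raw, t.p_adj, t.undefined)
        )
    return pd.DataFrame(
        rows,
        columns=["contrast", "cell_type", "scope", "chi2", "df", "p_raw", "p_adj", "undefined"],
    )


def contrast_overlap(
    de_a: pd.DataFrame, de_b: pd.DataFrame, genes: pd.DataFrame, x_only: bool = False
) -> tuple[int, int, int]:
    """Counts of DE genes in each contrast and their intersection (optionally X-linked only)."""
    keep = set(genes.loc[genes["is_x"], "gene_id"]) if x_only else set(genes["gene_id"])
    set_a = set(de_a.loc[de_a["is_de"], "gene_id"]) & keep
    set_b = set(de_b.loc[de_b["is_de"], "gene_id"]) & keep
    return len(set_a), len(set_b), len(set_a & set_b)
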