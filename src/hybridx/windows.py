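"""Sliding gene-window scan for local clusters of directionally misexpressed genes.

Genes are ordered along each chromosome (annotation order), and windows of W
consecutive expressed genes advance by a fixed step. Within a window the
number of up- (logFC > 0) and down-regulated genes is compared to the 99th
quantile of a Poisson whose rate is the genome-wide direction rate times W;
windows strictly above the quantile are flagged. The scan is restricted to
autosomes by default (the X-wide signal would otherwise dominate).
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd
from scipy.stats import poisson

logger = logging.getLogger(__name__)


def poisson_threshold(lam: float, quantile: float = 0.99) -> int:
    """Smallest k with P(Poisson(lam) <= k) >= quantile."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if lam == 0:
        return 0
    return int(poisson.ppf(quantile, lam))


@dataclass
class WindowResult:
    chromosome: str
    window_index: int
    first_order_index: int
    last_order_index: int
    n_genes: int
    n_up: int
    n_down: int
    lambda_up: float
    lambda_down: float
    threshold_up: int
    threshold_down: int
    flagged_up: bool
    flagged_down: bool


def scan_gene_windows(
    de: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 250,
    step: int = 25,
    quantile: float = 0.99,
    autosomes_only: bool = True,
    per_chromosome_rate: bool = False,
) -> pd.DataFrame:
    """Scan windows of ``window`` expressed genes, advancing by ``step``.

    Direction comes from the logfc sign among expressed genes; the Poisson
    rate is estimated genome-wide over the scanned chromosomes (or per
    chromosome with ``per_chromosome_rate``). The final partial window on
    each chromosome is dropped; chromosomes with fewer than ``window``
    expressed genes yield no windows (logged).
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    merged = de.merge(
        genes[["gene_id", "chromosome", "order_index", "is_x"]], on="gene_id", how="inner"
    )
    merged = merged[merged["expressed_in_cell_type"]]
    if autosomes_only:
        merged = merged[~merged["is_x"]]
    merged = merged.sort_values("order_index", kind="stable")

    n_total = len(merged)
    rate_up_global = float((merged["logfc"] > 0).sum()) / n_total if n_total else 0.0
    rate_down_global = float((merged["logfc"] < 0).sum()) / n_total if n_total else 0.0

    rows = []
    for chrom, sub in merged.groupby("chromosome", sort=False):
        if len(sub) < window:
            logger.warning("chromosome %s has %d < %d expressed genes; skipped", chrom, len(sub), window)
            continue
        if per_chromosome_rate:
            rate_up = float((sub["logfc"] > 0).sum()) / len(sub)
            rate_down = float((sub["logfc"] < 0).sum()) / len(sub)
        else:
            rate_up, rate_down = rate_up_global, rate_down_global
        lam_up = rate_up * window
        lam_down = rate_down * window
        thr_up = poisson_threshold(lam_up, quantile)
        thr_down = poisson_threshold(lam_down, quantile)
        up = (sub["logfc"] > 0).to_numpy()
        down = (sub["logfc"] < 0).to_numpy()
        order = sub["order_index"].to_numpy()
        w_index = 0
        for start in range(0, len(sub) - window + 1, step):
            sl = slice(start, start + window)
            n_up = int(up[sl].sum())
            n_down = int(down[sl].sum())
            rows.append(
                WindowResult(
                    chromosome=chrom,
                    window_index=w_index,
                    first_order_index=int(order[start]),
                    last_order_index=int(order[start + window - 1]),
                    n_genes=window,
                    n_up=n_up,
                    n_down=n_down,
                    lambda_up=lam_up,
                    lambda_down=lam_down,
                    threshold_up=thr_up,
                    threshold_down=thr_down,
                    flagged_up=n_up > thr_up,
                    flagged_down=n_down > thr_down,
                )
            )
            w_index += 1
    return pd.DataFrame([r.__dict__ for r in rows])


def flagged_spans_bed(results: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """BED rows (chromosome, start, end, name) for flagged windows."""
    by_order = genes.set_index("order_index")
    rows = []
    for _, r in results.iterrows():
        if not (r["flagged_up"] or r["flagged_down"]):
            continue
        first = by_order.loc[r["first_order_index"]]
        last = by_order.loc[r["last_order_index"]]
        direction = "up" if r["flagged_up"] else "down"
        rows.append(
            (r["chromosome"], int(first["start"]), int(last["end"]),
             f"{r['chromosome']}_w{int(r['window_index'])}_{direction}")
        )
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "name"])
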