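"""Variance and quality diagnostics comparing replicate strategies."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metacells import MetacellSet
from .timecourse import baseline_contrast

__all__ = [
    "mean_sd_per_stratum",
    "pooled_mean_sd",
    "compare_method_msd",
    "genes_detected",
    "severity_expression_table",
]


def mean_sd_per_stratum(mcs: MetacellSet) -> pd.DataFrame:
    """mSD per (cell_type, day): per-gene sample SD (ddof=1) across the
    stratum's metareplicates, averaged over all genes.

    Strata with fewer than two metareplicates are excluded.
    """
    expr = mcs.expression_matrix()
    meta = mcs.meta_table()
    rows = []
    for (ctype, day), grp in meta.groupby(["cell_type", "day"], sort=True):
        if len(grp) < 2:
            continue
        sub = expr[grp.index.to_numpy()]
        msd = sub.std(axis=0, ddof=1).mean()
        rows.append(
            {
                "cell_type": ctype,
                "day": day,
                "method": grp["method"].iloc[0],
                "n_metareplicates": len(grp),
                "mSD": float(msd),
            }
        )
    if not rows:
        raise ValueError("no stratum has >= 2 metareplicates")
    return pd.DataFrame(rows)


def pooled_mean_sd(mcs: MetacellSet) -> pd.DataFrame:
    """mSD per cell type with units pooled across all days.

    Mirrors the pooled-time comparison used to benchmark metacell
    variance against pseudobulk variance.
    """
    expr = mcs.expression_matrix()
    meta = mcs.meta_table()
    rows = []
    for ctype, grp in meta.groupby("cell_type", sort=True):
        if len(grp) < 2:
            continue
        sub = expr[grp.index.to_numpy()]
        rows.append(
            {
                "cell_type": ctype,
                "method": grp["method"].iloc[0],
                "n_units": len(grp),
                "mSD": float(sub.std(axis=0, ddof=1).mean()),
            }
        )
    if not rows:
        raise ValueError("no cell type has >= 2 units")
    return pd.DataFrame(rows)


def compare_method_msd(report_a: pd.DataFrame, report_b: pd.DataFrame) -> dict:
    """Grand-mean mSD of two methods plus an equal-variance t-test on the
    per-stratum mSD values (two-sided)."""
    t, p = baseline_contrast(report_a["mSD"].to_numpy(), report_b["mSD"].to_numpy())
    return {
        "grand_mean_a": float(report_a["mSD"].mean()),
        "grand_mean_b": float(report_b["mSD"].mean()),
        "t": t,
        "p": p,
        "n_strata_a": len(report_a),
        "n_strata_b": len(report_b),
    }


def genes_detected(expression: np.ndarray, unit_ids: list[str] | None = None) -> pd.DataFrame:
    """Per-unit count of genes with expression strictly above zero."""
    expression = np.atleast_2d(np.asarray(expression))
    counts = np.count_nonzero(expression > 0, axis=1)
    ids = unit_ids if unit_ids is not None else [str(i) for i in range(len(counts))]
    return pd.DataFrame({"unit": ids, "n_genes_detected": counts})


def severity_expression_table(mcs: MetacellSet, gene_list: list[str]) -> pd.DataFrame:
    """Long-format (gene, day, metacell, expression, severity) export."""
    unknown = [g for g in gene_list if g not in mcs.gene_ids]
    if unknown:
        raise KeyError(f"unknown genes: {unknown}")
    gene_idx = {g: i for i, g in enumerate(mcs.gene_ids)}
    rows = [
        {
            "gene": g,
            "day": m.day,
            "metacell": m.id,
            "expression": float(m.expression[gene_idx[g]]),
            "severity": m.severity,
        }
        for g in gene_list
        for m in mcs
    ]
    return pd.DataFrame(rows, columns=["gene", "day", "metacell", "expression", "severity"])
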