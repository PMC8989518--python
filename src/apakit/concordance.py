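"""Fold-change concordance between two differential-expression tables.

Genes are matched by id across the two tables, restricted to those
significant (p below the threshold) in both tables or in at least one,
and the agreement of their log2 fold changes is summarised by the
Pearson correlation with an ordinary-least-squares regression line
(table b's log2FC on table a's).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

FC_COLUMNS = ("gene_id", "log2fc", "p_value")


@dataclass
class ConcordanceResult:
    n_genes: int
    pearson_r: float
    r_squared: float
    slope: float
    intercept: float
    p_correlation: float

    def summary(self) -> str:
        return (
            f"n = {self.n_genes}\n"
            f"Pearson r = {self.pearson_r:.4f} (R^2 = {self.r_squared:.4f}), "
            f"p = {self.p_correlation:.3g}\n"
            f"OLS: b = {self.slope:.4f} * a + {self.intercept:.4f}"
        )


def _check_fc_table(table: pd.DataFrame, label: str) -> None:
    missing = set(FC_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"table {label} missing columns: {sorted(missing)}")
    if table["gene_id"].duplicated().any():
        raise ValueError(f"table {label} has duplicate gene ids")


def fc_concordance(
    a: pd.DataFrame,
    b: pd.DataFrame,
    p_thresh: float = 0.05,
    mode: str = "both",
) -> ConcordanceResult:
    """Pearson correlation and OLS fit of b's log2FC on a's.

    mode='both' keeps genes with p < p_thresh in both tables (the
    conservative reading); mode='either' requires it in at least one.
    Fewer than three surviving genes is an error.
    """
    if mode not in ("both", "either"):
        raise ValueError(f"mode must be 'both' or 'either', got {mode!r}")
    _check_fc_table(a, "a")
    _check_fc_table(b, "b")
    merged = a.merge(b, on="gene_id", suffixes=("_a", "_b"))
    sig_a = merged["p_value_a"] < p_thresh
    sig_b = merged["p_value_b"] < p_thresh
    keep = (sig_a & sig_b) if mode == "both" else (sig_a | sig_b)
    merged = merged.loc[keep]
    if len(merged) < 3:
        raise ValueError(
            f"only {len(merged)} genes survive intersection and p < {p_thresh} "
            f"filtering (mode={mode}); need >= 3"
        )
    x = merged["log2fc_a"].to_numpy()
    y = merged["log2fc_b"].to_numpy()
    fit = stats.linregress(x, y)
    return ConcordanceResult(
        n_genes=len(merged),
        pearson_r=float(fit.rvalue),
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_correlation=float(fit.pvalue),
    )


def read_fc_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", comment="#")
    _check_fc_table(table, str(path))
    return table
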