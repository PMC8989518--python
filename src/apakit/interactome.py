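"""Proximity-labelling (BioID) interactor shortlisting.

Bait-fusion proximity labelling yields label-free quantification (LFQ)
intensities per protein in bait and free-ligase control replicates.
Candidate interactors are shortlisted with four conjunctive, strict
filters: >4 razor + unique peptides, >20% sequence coverage, p < 0.05
(two-sided pooled-variance Student's t-test on log2 intensities versus
the free-ligase control) and log2 fold change > 1.

LFQ intensity 0 encodes a missing value (MaxQuant convention); zeros
are dropped, never imputed, and a protein without at least two
non-missing values per group has an undefined p-value and fails the
p filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SHORTLIST_FILTERS = ("peptides", "coverage", "p_value", "log2fc")


@dataclass
class ShortlistThresholds:
    min_peptides: int = 4      # strict: must exceed
    min_coverage_pct: float = 20.0
    max_p: float = 0.05
    min_log2fc: float = 1.0


def log2fc_and_ttest(
    bait: np.ndarray, control: np.ndarray
) -> tuple[float, float]:
    """log2 fold change and Student's t p-value for one protein.

    Zeros are treated as missing.  log2FC = mean(log2 bait) -
    mean(log2 control); p is from a two-sided, two-sample,
    pooled-variance t-test on the log2 values.  With fewer than two
    non-missing values in either group p is NaN (undefined).  If the
    pooled variance is zero: p = 0 when the means differ, 1 otherwise.
    """
    bait = np.asarray(bait, dtype=float)
    control = np.asarray(control, dtype=float)
    if np.any(bait < 0) or np.any(control < 0):
        raise ValueError("intensities must be non-negative (0 = missing)")
    b = np.log2(bait[bait > 0])
    c = np.log2(control[control > 0])
    if len(b) == 0 or len(c) == 0:
        return math.nan, math.nan
    log2fc = float(b.mean() - c.mean())
    if len(b) < 2 or len(c) < 2:
        return log2fc, math.nan
    pooled_var = (
        ((len(b) - 1) * b.var(ddof=1) + (len(c) - 1) * c.var(ddof=1))
        / (len(b) + len(c) - 2)
    )
    if pooled_var == 0.0:
        return log2fc, 0.0 if log2fc != 0.0 else 1.0
    t = log2fc / math.sqrt(pooled_var * (1 / len(b) + 1 / len(c)))
    df = len(b) + len(c) - 2
    p = 2.0 * stats.t.sf(abs(t), df)
    return log2fc, float(p)


def shortlist(
    table: pd.DataFrame,
    bait_cols: list[str],
    control_cols: list[str],
    thresholds: ShortlistThresholds | None = None,
) -> pd.DataFrame:
    """Apply the four shortlist filters to every protein.

    ``table`` needs protein_id, razor_unique_peptides, coverage_pct and
    the replicate intensity columns.  Returns a frame with log2fc,
    p_value, passes and failed_filters (comma-joined names) per
    protein; passes is True iff all four strict filters pass.
    """
    th = thresholds or ShortlistThresholds()
    rows = []
    for _, r in table.iterrows():
        log2fc, p = log2fc_and_ttest(
            r[bait_cols].to_numpy(dtype=float), r[control_cols].to_numpy(dtype=float)
        )
        failed = []
        if not r["razor_unique_peptides"] > th.min_peptides:
            failed.append("peptides")
        if not r["coverage_pct"] > th.min_coverage_pct:
            failed.append("coverage")
        if not (p == p and p < th.max_p):  # NaN-safe: undefined p fails
            failed.append("p_value")
        if not (log2fc == log2fc and log2fc > th.min_log2fc):
            failed.append("log2fc")
        rows.append(
            {
                "protein_id": r["protein_id"],
                "razor_unique_peptides": r["razor_unique_peptides"],
                "coverage_pct": r["coverage_pct"],
                "log2fc": log2fc,
                "p_value": p,
                "passes": not failed,
                "failed_filters": ",".join(failed),
            }
        )
    return pd.DataFrame(rows)


def read_quant_table(path, groups_path) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Load a quant TSV plus a sample->{bait,control} group TSV."""
    table = pd.read_csv(path, sep="\t", comment="#")
    groups = pd.read_csv(groups_path, sep="\t", comment="#")
    gmap = dict(zip(groups.iloc[:, 0].astype(str), groups.iloc[:, 1].astype(str)))
    bait = [s for s, g in gmap.items() if g == "bait"]
    control = [s for s, g in gmap.items() if g == "control"]
    if len(bait) < 2 or len(control) < 2:
        raise ValueError("need >=2 replicates per condition")
    return table, bait, control
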