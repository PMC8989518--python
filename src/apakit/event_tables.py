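"""Splice-event post-filters/tallies and dPPAU computation/classification.

Two table-level procedures sit here.  First, the junction-count
post-filter applied to differential splice events (rMATS-style tables)
before any event is tallied or visualised: an event survives only if
it is significant (FDR < 0.05) and has enough supporting junction
reads for its event class.  Second, the alternative-polyadenylation
shift statistic dPPAU: the condition-minus-control difference in mean
proximal polyA-site usage (PPAU, percent), classified as a
proximal-usage gain (dPPAU > t) or loss (dPPAU < -t) at strict
thresholds t = 0 and t = 20.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EVENT_TYPES = ("SE", "MXE", "RI", "A3SS", "A5SS")

#: Event classes filtered on the summed junction reads (>= 10 over all
#: exon:exon junctions of the event).
SUM_RULE_TYPES = ("A3SS", "A5SS")
#: Event classes filtered on SJC >= 10 OR inclusion counts >= 10 in one
#: junction and >= 5 in the other.
SJC_RULE_TYPES = ("SE", "MXE", "RI")

SPLICE_COLUMNS = ("event_id", "type", "IJC_1", "IJC_2", "SJC", "FDR")


def _validate_splice_table(table: pd.DataFrame) -> None:
    missing = set(SPLICE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"splice table missing columns: {sorted(missing)}")
    unknown = set(table["type"]) - set(EVENT_TYPES)
    if unknown:
        raise ValueError(f"unknown splice event type(s): {sorted(unknown)}")
    for col in ("IJC_1", "IJC_2", "SJC"):
        if (table[col] < 0).any():
            raise ValueError(f"negative junction counts in column {col}")


def filter_splice_events(table: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Keep significant events with sufficient junction support.

    A row is kept iff FDR < ``fdr`` and its type-specific read rule
    holds: A3SS/A5SS need IJC_1 + IJC_2 + SJC >= 10; SE/MXE/RI need
    SJC >= 10, or one inclusion count >= 10 with the other >= 5.
    Deterministic and idempotent; row order preserved.
    """
    _validate_splice_table(table)
    sig = table["FDR"] < fdr
    ijc_hi = table[["IJC_1", "IJC_2"]].max(axis=1)
    ijc_lo = table[["IJC_1", "IJC_2"]].min(axis=1)
    sum_ok = (table["IJC_1"] + table["IJC_2"] + table["SJC"]) >= 10
    sjc_ok = (table["SJC"] >= 10) | ((ijc_hi >= 10) & (ijc_lo >= 5))
    reads_ok = np.where(table["type"].isin(SUM_RULE_TYPES), sum_ok, sjc_ok)
    return table.loc[sig & reads_ok].copy()


def tally_event_types(table: pd.DataFrame) -> dict[str, int]:
    """Exact event count per class; every class reported (zeros included)."""
    counts = table["type"].value_counts() if len(table) else pd.Series(dtype=int)
    return {t: int(counts.get(t, 0)) for t in EVENT_TYPES}


@dataclass
class PPAUTable:
    """Per-event proximal polyA usage (percent) per sample.

    ``data`` holds event_id, gene and one numeric column per sample;
    ``group_map`` assigns each sample column to 'control' or
    'condition'.
    """

    data: pd.DataFrame
    group_map: dict[str, str]

    def __post_init__(self) -> None:
        groups = set(self.group_map.values())
        if groups - {"control", "condition"}:
            raise ValueError(f"groups must be control/condition, got {sorted(groups)}")
        for needed in ("control", "condition"):
            if needed not in groups:
                raise ValueError(f"no samples assigned to group {needed!r}")
        missing = set(self.group_map) - set(self.data.columns)
        if missing:
            raise ValueError(f"group_map names absent sample columns: {sorted(missing)}")
        values = self.data[list(self.group_map)].to_numpy(dtype=float)
        if np.any(values < 0) or np.any(values > 100):
            raise ValueError("PPAU values must lie in [0, 100]")

    def samples(self, group: str) -> list[str]:
        return [s for s, g in self.group_map.items() if g == group]


@dataclass
class DPPAUResult:
    """Per-event dPPAU plus per-threshold proximal up/down counts."""

    table: pd.DataFrame  # event_id, gene, dppau
    counts: dict[float, dict[str, int]] = field(default_factory=dict)

    @property
    def dppau(self) -> pd.Series:
        return self.table.set_index("event_id")["dppau"]


def compute_dppau(ppau: PPAUTable) -> DPPAUResult:
    """dPPAU = mean PPAU over condition samples - mean over controls."""
    cond = ppau.data[ppau.samples("condition")].mean(axis=1)
    ctrl = ppau.data[ppau.samples("control")].mean(axis=1)
    out = pd.DataFrame(
        {
            "event_id": ppau.data["event_id"],
            "gene": ppau.data.get("gene", ppau.data["event_id"]),
            "dppau": cond - ctrl,
        }
    )
    return DPPAUResult(table=out)


def classify_dppau(
    result: DPPAUResult, thresholds: tuple[float, ...] = (0.0, 20.0)
) -> dict[float, dict[str, int]]:
    """Count proximal-usage shifts at each strict threshold.

    At threshold t: proximal_up = #{dPPAU > t}, proximal_down =
    #{dPPAU < -t}; events with |dPPAU| <= t are left uncounted.
    """
    d = result.table["dppau"].to_numpy()
    counts: dict[float, dict[str, int]] = {}
    for t in thresholds:
        if t < 0:
            raise ValueError("thresholds must be >= 0")
        counts[float(t)] = {
            "proximal_up": int(np.sum(d > t)),
            "proximal_down": int(np.sum(d < -t)),
        }
    result.counts = counts
    return counts


def read_splice_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", comment="#")
    _validate_splice_table(table)
    return table


def read_ppau_table(path, groups_path) -> PPAUTable:
    """Load a PPAU TSV plus a two-column sample->group TSV."""
    data = pd.read_csv(path, sep="\t", comment="#")
    groups = pd.read_csv(groups_path, sep="\t", comment="#")
    group_map = dict(zip(groups.iloc[:, 0].astype(str), groups.iloc[:, 1].astype(str)))
    return PPAUTable(data=data, group_map=group_map)
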