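"""Two-stage significance filtering of differential-expression results.

Stage one flags genes with adjusted p <= 0.05 and |log2 fold change| >= 1 as
initially significant (up or down by the sign of the fold change).  Stage
two restricts to the most significant genes: raw p <= 1e-4 after excluding
transcripts with fewer than 350 aligned reads.  The module consumes a
finished DE results table (gene, read count, log2FC, p, adjusted p); it
never recomputes p-values — upstream model fitting is out of scope.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

DE_COLUMNS = ("gene_id", "total_reads", "log2fc", "p_value", "p_adjusted")

ADJ_P_MAX = 0.05
LOG2FC_MIN = 1.0
STRICT_P_MAX = 1e-4
MIN_READS = 350


class SchemaError(ValueError):
    """Required DE-results column missing."""


def _check_columns(table: pd.DataFrame, cols=DE_COLUMNS) -> None:
    for col in cols:
        if col not in table.columns:
            raise SchemaError(f"missing required column: {col!r}")


def read_de_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a CSV/TSV DE results table (delimiter sniffed from the header)."""
    path = Path(path)
    if sep is None:
        sep = "\t" if "\t" in path.open().readline() else ","
    table = pd.read_csv(path, sep=sep)
    _check_columns(table)
    return table


def initial_significance(
    table: pd.DataFrame,
    adj_p_max: float = ADJ_P_MAX,
    log2fc_min: float = LOG2FC_MIN,
) -> pd.DataFrame:
    """Flag initially significant genes: adjusted p <= 0.05 and |log2FC| >= 1.

    Thresholds are inclusive.  Adds boolean ``initial_significant`` and a
    ``direction`` column ('up' for log2FC >= 1, 'down' for <= -1, else
    'none').
    """
    _check_columns(table, ("gene_id", "log2fc", "p_adjusted"))
    out = table.copy()
    big = out["log2fc"].abs() >= log2fc_min
    out["initial_significant"] = (out["p_adjusted"] <= adj_p_max) & big
    out["direction"] = np.select(
        [big & (out["log2fc"] > 0), big & (out["log2fc"] < 0)], ["up", "down"], "none"
    )
    return out


def strict_filter(
    table: pd.DataFrame,
    p_max: float = STRICT_P_MAX,
    min_reads: int = MIN_READS,
    use_adjusted_p: bool = False,
) -> pd.DataFrame:
    """Most-significant gene list: raw p <= 1e-4 and >= 350 aligned reads.

    Raw p is the default cut variable (``use_adjusted_p`` switches to the
    adjusted column).  Rows are ordered deterministically — ascending p,
    ties by descending |log2FC|, then gene_id — so the top-gene list is
    reproducible.
    """
    _check_columns(table, ("gene_id", "total_reads", "log2fc", "p_value"))
    p_col = "p_adjusted" if use_adjusted_p else "p_value"
    kept = table[(table[p_col] <= p_max) & (table["total_reads"] >= min_reads)].copy()
    kept["_absfc"] = kept["log2fc"].abs()
    kept = kept.sort_values(
        [p_col, "_absfc", "gene_id"], ascending=[True, False, True], kind="mergesort"
    ).drop(columns="_absfc")
    return kept.reset_index(drop=True)


def summarize_de(table: pd.DataFrame) -> dict:
    """Counts and percentages of up/down-regulated and strictly filtered genes.

    Percentages are 100 * count / n_total at full precision in the returned
    dict; rendered summaries round to one decimal.
    """
    if table.empty:
        return {
            "n_total": 0, "n_up": 0, "n_down": 0,
            "pct_up": 0.0, "pct_down": 0.0, "n_strict": 0,
        }
    flagged = (
        table
        if "initial_significant" in table.columns
        else initial_significance(table)
    )
    sig = flagged[flagged["initial_significant"]]
    n_total = int(len(flagged))
    n_up = int((sig["direction"] == "up").sum())
    n_down = int((sig["direction"] == "down").sum())
    n_strict = int(len(strict_filter(flagged)))
    return {
        "n_total": n_total,
        "n_up": n_up,
        "n_down": n_down,
        "pct_up": 100.0 * n_up / n_total,
        "pct_down": 100.0 * n_down / n_total,
        "n_strict": n_strict,
    }


def render_de_summary(summary: dict) -> str:
    """One-line human-readable DE summary with percentages to one decimal."""
    return (
        f"{summary['n_up']} genes (out of {summary['n_total']}, "
        f"{summary['pct_up']:.1f}%) overexpressed and {summary['n_down']} "
        f"({summary['pct_down']:.1f}%) underexpressed; "
        f"{summary['n_strict']} pass the strict filter"
    )
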