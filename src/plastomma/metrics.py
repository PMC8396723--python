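"""Genome-level metric tables and size-correlation analyses.

Builds the per-taxon overview table (total/LSC/SSC/IR lengths, %GC, ndh
gene counts, per-region indel events) and computes the size correlations
(Pearson r with a two-sided t-test p-value).  Additivity of the
quadripartite lengths (total = LSC + SSC + 2 IR) is validated per row
and violations are surfaced as data-quality flags, never silently
corrected; an explicit fix mode recomputes the offending LSC from
total - SSC - 2 IR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .records import GenomeRecord

log = logging.getLogger(__name__)


@dataclass
class MetricTable:
    """Per-taxon genome metrics with additivity flags."""

    table: pd.DataFrame

    @property
    def additivity_violations(self) -> list[str]:
        bad = self.table[~self.table["additive"]]
        return list(bad["taxon"])


def build_metric_table(
    records: list[GenomeRecord] | None = None,
    table: pd.DataFrame | None = None,
    ndh_counts: pd.DataFrame | None = None,
    region_indels: pd.DataFrame | None = None,
) -> MetricTable:
    """Assemble the overview table from records or a prebuilt frame.

    ``ndh_counts`` (taxon-indexed, columns ndh_present / ndh_complete)
    and ``region_indels`` (taxon-indexed, columns lsc_indels / ssc_indels
    / ir_indels) are merged when given.  Additivity violations are
    flagged in the ``additive`` column and logged.
    """
    if (records is None) == (table is None):
        raise ValueError("give either records or a prebuilt table")
    if records is not None:
        rows = []
        for rec in records:
            part = rec.partition
            if part is None:
                raise ValueError(f"{rec.taxon}: record not partitioned")
            rows.append(
                {
                    "taxon": rec.taxon,
                    "total_bp": len(rec),
                    "lsc_bp": part.lsc_len,
                    "ssc_bp": part.ssc_len,
                    "ir_bp": part.ir_len,
                    "gc_percent": round(100 * rec.gc, 1),
                }
            )
        table = pd.DataFrame(rows)
    else:
        table = table.copy()
    table["additive"] = (
        table["total_bp"]
        == table["lsc_bp"] + table["ssc_bp"] + 2 * table["ir_bp"]
    )
    for taxon in table.loc[~table["additive"], "taxon"]:
        log.warning("metric table: additivity violated for %s", taxon)
    for extra in (ndh_counts, region_indels):
        if extra is not None:
            table = table.merge(
                extra.reset_index().rename(columns={"index": "taxon"}),
                on="taxon",
                how="left",
            )
    return MetricTable(table=table)


def fix_additivity(metric_table: MetricTable) -> MetricTable:
    """Recompute LSC as total - SSC - 2 IR for flagged rows (explicit,
    never automatic)."""
    table = metric_table.table.copy()
    bad = ~table["additive"]
    table.loc[bad, "lsc_bp"] = (
        table.loc[bad, "total_bp"]
        - table.loc[bad, "ssc_bp"]
        - 2 * table.loc[bad, "ir_bp"]
    )
    table["additive"] = (
        table["total_bp"] == table["lsc_bp"] + table["ssc_bp"] + 2 * table["ir_bp"]
    )
    return MetricTable(table=table)


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r with two-sided p from t = r sqrt((n-2)/(1-r^2)), df n-2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


#: the size-correlation pairs reported by the study design
DEFAULT_PAIRS = [
    ("total_bp", "lsc_bp"),
    ("total_bp", "ssc_bp"),
    ("total_bp", "ndh_complete"),
    ("total_bp", "lsc_indels"),
    ("total_bp", "ir_indels"),
    ("ssc_bp", "ndh_present"),
    ("ssc_bp", "ndh_complete"),
]


def correlation_suite(
    metric_table: MetricTable,
    pairs: list[tuple[str, str]] | None = None,
    fix_additivity_first: bool = False,
) -> tuple[pd.DataFrame, pd.Series]:
    """Pearson r/p for the requested column pairs, plus per-column ranges.

    Pairs touching a missing column are skipped with a warning.  Returns
    (correlations frame, max-min range per numeric column).
    """
    mt = fix_additivity(metric_table) if fix_additivity_first else metric_table
    table = mt.table
    rows = []
    for xcol, ycol in pairs if pairs is not None else DEFAULT_PAIRS:
        if xcol not in table.columns or ycol not in table.columns:
            log.warning("correlation pair (%s, %s) skipped: column missing", xcol, ycol)
            continue
        sub = table[[xcol, ycol]].dropna()
        r, p = pearson_with_p(sub[xcol], sub[ycol])
        rows.append({"x": xcol, "y": ycol, "n": len(sub), "r": r, "p": p})
    numeric = table.select_dtypes("number")
    ranges = numeric.max() - numeric.min()
    return pd.DataFrame(rows), ranges
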