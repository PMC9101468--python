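"""Population summaries of credited time per ICATUS division.

Produces the per-method, per-division summary rows: median minutes with
quartiles over all participants, non-participation (participants with zero
credited minutes in the criterion method), the partaker-only median, and the
paired Wilcoxon signed-rank comparison against the criterion.  Percentiles
use linear interpolation between order statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .agreement import WilcoxonResult, wilcoxon_signed_rank
from .catalog import ActivityCatalog, DIVISIONS, MethodRecord, TimeslotGrid
from .crediting import CreditTable, aggregate_divisions

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DivisionSummary:
    """One summary row: a division under one method, compared to the criterion."""

    division: str
    method: str
    n: int
    non_participation_count: int
    non_participation_pct: float
    median: float
    p25: float
    p75: float
    partaker_median: float
    wilcoxon: WilcoxonResult

    @property
    def wilcoxon_p(self) -> float:
        return self.wilcoxon.p_value


def _aligned_division(
    credits: CreditTable, criterion_credits: CreditTable, division: str
) -> tuple[np.ndarray, np.ndarray]:
    if division not in DIVISIONS:
        raise ValueError(f"unknown division {division!r}")
    a = set(credits.participants)
    b = set(criterion_credits.participants)
    if a != b:
        raise ValueError(
            "participant sets differ between credit tables; "
            f"symmetric difference: {sorted(a ^ b)}"
        )
    order = sorted(a)
    return (
        credits.minutes.loc[order, division].to_numpy(dtype=float),
        criterion_credits.minutes.loc[order, division].to_numpy(dtype=float),
    )


def summarize_division(
    credits: CreditTable,
    division: str,
    criterion_credits: CreditTable,
    non_participation_on: str = "criterion",
) -> DivisionSummary:
    """Summary of one division's credited minutes under one method.

    Median and quartiles are over all participants of ``credits``.
    Non-participation counts participants with zero credited minutes — by
    default judged on the criterion table (one non-participation column per
    division, not one per method); pass ``non_participation_on="method"`` to
    judge on the method's own credits.  The partaker median is over
    participants with positive criterion minutes.  The Wilcoxon signed-rank
    compares the method's values with the criterion's; with no non-zero
    differences it is flagged not testable.
    """
    if non_participation_on not in ("criterion", "method"):
        raise ValueError("non_participation_on must be 'criterion' or 'method'")
    vals, crit = _aligned_division(credits, criterion_credits, division)
    n = vals.size
    np_basis = crit if non_participation_on == "criterion" else vals
    non_part = int((np_basis == 0).sum())
    partakers = vals[crit > 0]
    return DivisionSummary(
        division=division,
        method=credits.method,
        n=n,
        non_participation_count=non_part,
        non_participation_pct=100.0 * non_part / n if n else math.nan,
        median=float(np.percentile(vals, 50)),
        p25=float(np.percentile(vals, 25)),
        p75=float(np.percentile(vals, 75)),
        partaker_median=float(np.median(partakers)) if partakers.size else math.nan,
        wilcoxon=wilcoxon_signed_rank(vals, crit),
    )


def summary_table(
    method_tables: Mapping[str, CreditTable],
    criterion_credits: CreditTable,
    divisions: Sequence[str] = DIVISIONS,
) -> pd.DataFrame:
    """Tidy frame of DivisionSummary rows for several methods (criterion included)."""
    rows = []
    for method, table in method_tables.items():
        for division in divisions:
            s = summarize_division(table, division, criterion_credits)
            rows.append(
                {
                    "division": division,
                    "method": method,
                    "n": s.n,
                    "non_participation_count": s.non_participation_count,
                    "non_participation_pct": s.non_participation_pct,
                    "median": s.median,
                    "p25": s.p25,
                    "p75": s.p75,
                    "partaker_median": s.partaker_median,
                    "wilcoxon_p": s.wilcoxon_p,
                    "wilcoxon_testable": s.wilcoxon.testable,
                }
            )
    return pd.DataFrame(rows)


def compare_day_types(
    records: Iterable[MethodRecord],
    method: str,
    catalog: ActivityCatalog,
    grid: TimeslotGrid,
    mode: str = "simultaneous_aware",
) -> pd.DataFrame:
    """Observation-day versus non-observation-day medians for one method.

    Pairs each participant's two day types; unpaired participants are
    dropped with a logged count.  Returns one row per division with both
    medians, their difference, and the paired Wilcoxon p (reactivity check:
    e.g. caregiving inflated, own production deflated while observed).
    """
    by_day: dict[str, dict[str, pd.Series]] = {"observation": {}, "non_observation": {}}
    for rec in records:
        if rec.method != method or not rec.is_complete:
            continue
        by_day[rec.day_type][rec.participant_id] = aggregate_divisions(
            rec, catalog, grid, mode
        )
    paired = sorted(set(by_day["observation"]) & set(by_day["non_observation"]))
    n_dropped = len(set(by_day["observation"]) ^ set(by_day["non_observation"]))
    if n_dropped:
        logger.warning("dropped %d participants lacking both day types", n_dropped)
    if not paired:
        raise ValueError(f"no participants with both day types for method {method!r}")
    obs = pd.DataFrame({p: by_day["observation"][p] for p in paired}).T
    non = pd.DataFrame({p: by_day["non_observation"][p] for p in paired}).T
    rows = []
    for division in DIVISIONS:
        w = wilcoxon_signed_rank(obs[division].to_numpy(), non[division].to_numpy())
        rows.append(
            {
                "division": division,
                "method": method,
                "n_pairs": len(paired),
                "median_observation": float(obs[division].median()),
                "median_non_observation": float(non[division].median()),
                "median_difference": float(obs[division].median() - non[division].median()),
                "wilcoxon_p": w.p_value,
                "wilcoxon_testable": w.testable,
            }
        )
    return pd.DataFrame(rows)
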