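"""Group statistics and the reference-table reproduction report.

Group summaries use the population standard deviation (n denominator) and
round half-up to 4 decimals for display, matching the source table's
reporting convention.  Two-group comparisons use the exact Mann-Whitney U
test (full permutation null, mid-ranks for ties), valid at the small group
sizes involved here.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from math import comb
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import DomainError
from .molar_ratio import RatioRecord, load_table1, process_table

__all__ = [
    "GroupSummary",
    "group_summary",
    "mann_whitney_u_exact",
    "reproduce_table1",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 4) -> float:
    """Decimal round-half-up (0.00005 -> 0.0001), unlike banker's rounding."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GroupSummary:
    """Mean and population SD of one group, rounded for display."""

    label: str
    n: int
    mean: float
    sd_population: float
    values: tuple[float, ...]


def group_summary(values: Sequence[float], label: str = "") -> GroupSummary:
    """Arithmetic mean and population SD (n denominator), 4-decimal display.

    The raw vector is retained on the summary for downstream tests.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise DomainError("cannot summarize an empty group")
    return GroupSummary(
        label=label,
        n=int(vals.size),
        mean=round_half_up(float(vals.mean())),
        sd_population=round_half_up(float(vals.std(ddof=0))),
        values=tuple(float(v) for v in vals),
    )


def mann_whitney_u_exact(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Exact Mann-Whitney U test via full enumeration of the permutation null.

    Returns ``(U, p)`` where U is the statistic of ``x`` (mid-ranks for
    ties) and p is the exact two-sided probability, computed as
    2 * min(P(U <= u), P(U >= u)) over all C(nx+ny, nx) group labelings,
    capped at 1.  Restricted to nx, ny <= 12 (enumeration regime).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx == 0 or ny == 0:
        raise DomainError("both groups must be non-empty")
    if nx > 12 or ny > 12:
        raise DomainError("exact enumeration supported for group sizes <= 12")

    combined = np.concatenate([x, y])
    ranks = rankdata(combined)  # mid-ranks for ties
    u_obs = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)

    # Exact null distribution of the x rank sum over all C(n, nx) labelings,
    # counted by dynamic programming.  Doubled mid-ranks are exact integers,
    # so sums can be used as array indices.
    ranks2 = np.rint(2.0 * ranks).astype(np.int64)
    n = nx + ny
    max_sum = int(ranks2.sum())
    # dp[k, s]: number of k-subsets of the ranks seen so far with doubled sum s
    dp = np.zeros((nx + 1, max_sum + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for r in ranks2:
        for k in range(nx, 0, -1):  # descending so each rank is used at most once
            dp[k, r:] += dp[k - 1, : max_sum + 1 - r]
    counts = dp[nx]
    total = comb(n, nx)

    sum2_obs = int(np.rint(2.0 * ranks[:nx].sum()))
    p_le = counts[: sum2_obs + 1].sum() / total
    p_ge = counts[sum2_obs:].sum() / total
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return u_obs, p


#: Overlapping condition groups of the reference table.
_CONDITION_GROUPS = {
    "isoflurane": ("c", "d"),
    "midazolam_fentanyl": ("a", "b"),
    "fio2_0.3": ("a", "c"),
    "fio2_1.0": ("b", "d"),
}


def _collect(records: Sequence[RatioRecord], labels, attr: str) -> list[float]:
    return [getattr(r, attr) for r in records if r.group in labels]


def reproduce_table1(records: Optional[Sequence[RatioRecord]] = None) -> dict:
    """Summary report over the packaged reference table.

    For each overlapping condition group (anesthetic and FIO2 level) the
    report carries the summary of the table's printed dry-ratio column and,
    separately, of the dry ratios recomputed from each row's own humid
    ratio and bag conditions, plus their difference.  Test-lung QC counts
    and the per-block maximum |recomputed - printed| are included.
    """
    if records is None:
        records = load_table1()
    processed = process_table(records)

    report: dict = {"groups": {}, "qc": {}, "reproduction": {}, "mann_whitney": {}}
    for name, labels in _CONDITION_GROUPS.items():
        printed = group_summary(_collect(processed, labels, "r_dry"), f"{name}/printed")
        recomputed = group_summary(
            _collect(processed, labels, "r_dry_computed"), f"{name}/recomputed"
        )
        report["groups"][name] = {
            "printed": printed,
            "recomputed": recomputed,
            "mean_diff": round_half_up(recomputed.mean - printed.mean, 5),
        }

    report["qc"] = {
        "n": len(processed),
        "n_pass": sum(1 for r in processed if r.qc_pass),
        "all_pass": all(r.qc_pass for r in processed),
    }
    for block in ("a", "b", "c", "d"):
        diffs = [
            abs(r.r_dry_computed - r.r_dry) for r in processed if r.group == block
        ]
        report["reproduction"][block] = {"max_abs_diff": max(diffs), "n": len(diffs)}

    u_anesth, p_anesth = mann_whitney_u_exact(
        _collect(processed, ("c", "d"), "r_dry"),
        _collect(processed, ("a", "b"), "r_dry"),
    )
    u_fio2, p_fio2 = mann_whitney_u_exact(
        _collect(processed, ("a", "c"), "r_dry"),
        _collect(processed, ("b", "d"), "r_dry"),
    )
    report["mann_whitney"] = {
        "anesthetic": {"U": u_anesth, "p": p_anesth},
        "fio2": {"U": u_fio2, "p": p_fio2},
    }
    return report
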