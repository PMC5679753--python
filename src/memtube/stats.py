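"""Exact 2x2 statistics for fission-event counts.

Fisher's exact test on tables of (fission, no-fission) counts per condition.
The two-sided p-value follows the method of small p-values: the sum of
hypergeometric point probabilities, over all tables with the observed
margins, that do not exceed the observed table's point probability (with a
1e-12 relative tolerance absorbing floating-point ties).  All combinatorics
run in log-gamma space, exact well beyond the n ~ 200 of the packaged
fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, lgamma, log
from typing import Iterable, Sequence

import pandas as pd

_REL_TOL = 1e-12


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows are conditions, columns yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    @property
    def row_proportions(self) -> tuple[float, float]:
        r1 = self.a + self.b
        r2 = self.c + self.d
        return (self.a / r1 if r1 else float("nan"),
                self.c / r2 if r2 else float("nan"))


@dataclass(frozen=True)
class TestResult:
    p_two_sided: float
    point_prob: float
    proportions: tuple[float, float]


def _log_binom(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def hypergeom_point_prob(a: int, r1: int, r2: int, k: int) -> float:
    """P(first cell = a) given row margins (r1, r2) and column margin k."""
    lo, hi = max(0, k - r2), min(r1, k)
    if not lo <= a <= hi:
        raise ValueError(f"a={a} infeasible for margins ({r1},{r2};{k})")
    return exp(_log_binom(r1, a) + _log_binom(r2, k - a) - _log_binom(r1 + r2, k))


def fisher_two_sided(t: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher exact p-value (method of small p-values)."""
    r1, r2 = t.a + t.b, t.c + t.d
    k = t.a + t.c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or k == 0 or k == n:
        # a zero margin: only one table is possible
        return TestResult(1.0, 1.0, t.row_proportions)
    lo, hi = max(0, k - r2), min(r1, k)
    log_obs = (_log_binom(r1, t.a) + _log_binom(r2, k - t.a)
               - _log_binom(n, k))
    p = 0.0
    included = 0
    for x in range(lo, hi + 1):
        lp = _log_binom(r1, x) + _log_binom(r2, k - x) - _log_binom(n, k)
        if lp <= log_obs + log(1.0 + _REL_TOL):
            p += exp(lp)
            included += 1
    if included == hi - lo + 1:  # every feasible table: exactly 1
        p = 1.0
    return TestResult(min(p, 1.0), exp(log_obs), t.row_proportions)


def fission_percentage(table) -> float:
    """100 * n_positive / n_events at one decimal (the printed convention)."""
    if table.n_events < 1:
        raise ValueError("no scored events")
    return round(100.0 * table.n_positive / table.n_events, 1)


def compare_conditions(t1, t2) -> TestResult:
    """Fisher's exact test between two event tables (fission vs no fission)."""
    return fisher_two_sided(ContingencyTable2x2(
        t1.n_positive, t1.n_events - t1.n_positive,
        t2.n_positive, t2.n_events - t2.n_positive,
    ))


#: the printed pairwise comparisons: (condition 1, condition 2, printed
#: upper bound on p).  None means no bound was printed for that pair.
PAPER_COMPARISONS: tuple[tuple[str, str, float | None], ...] = (
    ("shigella_wt", "shigella_drp1_crispr", 1e-7),
    ("shigella_wt", "shigella_drp1_sirna", 1e-4),
    ("shigella_wt", "shigella_mff_sirna", 1e-4),
    ("afm_wt_maintext", "afm_drp1_maintext", 1e-8),
    ("vinyl_scrambled", "vinyl_drp1_sirna", 1e-16),
    ("vinyl_wt_crispr", "vinyl_drp1_crispr", 1e-9),
    ("vinyl_scrambled", "vinyl_mff_sirna", 1e-9),
    ("afm_wt_methods", "afm_drp1_methods", None),
)


def analyze_all(fixture: Iterable, comparisons=PAPER_COMPARISONS) -> pd.DataFrame:
    """Batch Fisher tests over an event-table fixture.

    One row per comparison whose two condition labels exist in the fixture:
    counts, percentages, two-sided p, the printed bound (if any) and whether
    the computed p satisfies it.  Deterministic: re-running yields an
    identical table.
    """
    by_label = {t.label: t for t in fixture}
    rows = []
    for lab1, lab2, bound in comparisons:
        if lab1 not in by_label or lab2 not in by_label:
            continue
        t1, t2 = by_label[lab1], by_label[lab2]
        res = compare_conditions(t1, t2)
        rows.append({
            "condition_1": lab1,
            "condition_2": lab2,
            "events_1": t1.n_events,
            "positive_1": t1.n_positive,
            "events_2": t2.n_events,
            "positive_2": t2.n_positive,
            "percent_1": fission_percentage(t1),
            "percent_2": fission_percentage(t2),
            "p_two_sided": res.p_two_sided,
            "printed_bound": bound if bound is not None else float("nan"),
            "bound_satisfied": (res.p_two_sided < bound) if bound else True,
        })
    return pd.DataFrame(rows)
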