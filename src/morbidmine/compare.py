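"""Cross-race comparison of multimorbidity patterns within an age/obesity cell.

For one (age band, obesity class) cell, the union of patterns frequent in
at least one race stratum is partitioned into three classes:

* ``shared_all``  — frequent in every configured race,
* ``shared_some`` — frequent in more than one but not all,
* ``distinct``    — frequent in exactly one race.

Every configured race gets full support/prevalence/CI figures for every
pattern, frequent there or not (the "gray sector" counts): downstream
prevalence tests need the complete contingency table, and a pattern being
below threshold in a race is information, not missing data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .cohort import TransactionSet
from .mining import FrequentPattern
from .stats import PrevalenceCI, clopper_pearson

__all__ = [
    "RacePatternStats",
    "PatternComparison",
    "PatternCountSummary",
    "classify_patterns",
    "count_summary",
    "report_filter",
    "SHARED_ALL",
    "SHARED_SOME",
    "DISTINCT",
]

SHARED_ALL = "shared_all"
SHARED_SOME = "shared_some"
DISTINCT = "distinct"


@dataclass(frozen=True)
class RacePatternStats:
    """One race's support for one pattern, with an exact binomial CI."""

    support_count: int
    n_patients: int
    prevalence: float
    ci: PrevalenceCI
    frequent: bool


@dataclass(frozen=True)
class PatternComparison:
    """One pattern's classification across races within one cell."""

    cell: tuple[str, str]  # (age_band, obesity_class)
    items: tuple[str, ...]
    races_frequent: frozenset[str]
    class_label: str
    per_race: Mapping[str, RacePatternStats]

    @property
    def max_prevalence(self) -> float:
        return max(s.prevalence for s in self.per_race.values())


@dataclass(frozen=True)
class PatternCountSummary:
    """Per-race pattern tallies for one cell (overall and distinct-only)."""

    cell: tuple[str, str]
    race: str
    overall_count: int
    distinct_count: int


def _support_in(transactions: TransactionSet, items: tuple[str, ...]) -> int:
    needed = frozenset(items)
    return sum(1 for t in transactions.transactions.values() if needed <= t)


def classify_patterns(
    patterns_by_race: Mapping[str, Sequence[FrequentPattern]],
    race_list: Sequence[str],
    transactions_by_race: Mapping[str, TransactionSet],
    *,
    min_size: int = 2,
    ci_level: float = 0.95,
) -> list[PatternComparison]:
    """Partition a cell's patterns into shared-all / shared-some / distinct.

    Parameters
    ----------
    patterns_by_race
        Mined frequent patterns per race stratum of one cell, all mined at
        the same support threshold and chapter filter.
    race_list
        The configured analysis races; classification is relative to this
        list (a race with no data simply never reaches ``shared_all``).
    transactions_by_race
        The same cell's transaction sets, used to compute exact support
        counts in races where the pattern fell below threshold.
    """
    race_list = list(race_list)
    if not race_list:
        raise ValueError("race_list must not be empty")

    frequent_in: dict[tuple[str, ...], set[str]] = {}
    mined_support: dict[tuple[tuple[str, ...], str], FrequentPattern] = {}
    cell = None
    for race, patterns in patterns_by_race.items():
        for p in patterns:
            if p.size < min_size:
                continue
            frequent_in.setdefault(p.items, set()).add(race)
            mined_support[(p.items, race)] = p
            if p.stratum is not None:
                cell = (p.stratum.age_band, p.stratum.obesity_class)
    if cell is None:
        any_ts = next(iter(transactions_by_race.values()), None)
        cell = (
            (any_ts.stratum.age_band, any_ts.stratum.obesity_class)
            if any_ts is not None
            else ("", "")
        )

    comparisons = []
    for items in sorted(frequent_in, key=lambda it: (len(it), it)):
        races_frequent = frozenset(frequent_in[items])
        if races_frequent == frozenset(race_list):
            label = SHARED_ALL
        elif len(races_frequent) == 1:
            label = DISTINCT
        else:
            label = SHARED_SOME
        per_race: dict[str, RacePatternStats] = {}
        for race in race_list:
            mined = mined_support.get((items, race))
            if mined is not None:
                x, n = mined.support_count, mined.n_patients
            elif race in transactions_by_race:
                ts = transactions_by_race[race]
                x, n = _support_in(ts, items), ts.n_patients
            else:
                x, n = 0, 0
            ci = clopper_pearson(x, n, ci_level) if n > 0 else clopper_pearson(0, 1, ci_level)
            per_race[race] = RacePatternStats(
                support_count=x,
                n_patients=n,
                prevalence=x / n if n else 0.0,
                ci=ci,
                frequent=race in races_frequent,
            )
        comparisons.append(
            PatternComparison(
                cell=cell,
                items=items,
                races_frequent=races_frequent,
                class_label=label,
                per_race=per_race,
            )
        )
    return comparisons


def count_summary(
    comparisons: Iterable[PatternComparison], race_list: Sequence[str]
) -> list[PatternCountSummary]:
    """Per-race overall and distinct pattern counts (Table-2-style tallies)."""
    comparisons = list(comparisons)
    cell = comparisons[0].cell if comparisons else ("", "")
    out = []
    for race in race_list:
        overall = sum(1 for c in comparisons if race in c.races_frequent)
        distinct = sum(
            1
            for c in comparisons
            if c.class_label == DISTINCT and race in c.races_frequent
        )
        out.append(
            PatternCountSummary(
                cell=cell, race=race, overall_count=overall, distinct_count=distinct
            )
        )
    return out


def report_filter(
    comparisons: Iterable[PatternComparison], min_display_prevalence: float
) -> list[PatternComparison]:
    """Reporting-only prevalence cut: keep patterns whose best per-race
    prevalence reaches the display threshold.  Never affects classification."""
    return [c for c in comparisons if c.max_prevalence >= min_display_prevalence]
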