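"""Frequent-itemset mining with FP-growth, plus a brute-force oracle.

A pattern A (a set of disease categories) is *frequent* in a stratum when
the number of patient transactions containing A is at least ceil(xi * n),
xi being the minimum support fraction (5% in the default analysis) and n
the stratum denominator.  The threshold comparison is inclusive: a pattern
at exactly xi qualifies.

``mine_frequent_itemsets`` implements FP-growth — transactions are
compressed into a prefix tree ordered by item frequency, then mined
recursively through conditional pattern bases, so no candidate generation
is needed.  ``brute_force_itemsets`` enumerates every subset of the item
universe and exists purely as an independent test oracle.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .cohort import StratumKey, TransactionSet

__all__ = [
    "MinerConfig",
    "FrequentPattern",
    "EmptyStratumError",
    "min_support_count",
    "mine_frequent_itemsets",
    "brute_force_itemsets",
    "filter_multimorbidity",
]


class EmptyStratumError(ValueError):
    """Mining was asked to run on a stratum with no patients."""


@dataclass(frozen=True)
class MinerConfig:
    """Mining parameters: support fraction, size bounds, optional universe."""

    min_support_fraction: float = 0.05
    min_itemset_size: int = 1
    max_itemset_size: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.min_support_fraction <= 1.0:
            raise ValueError("min_support_fraction must be in (0, 1]")
        if self.min_itemset_size < 1:
            raise ValueError("min_itemset_size must be >= 1")


@dataclass(frozen=True)
class FrequentPattern:
    """An itemset with its support count in one stratum."""

    items: tuple[str, ...]
    support_count: int
    n_patients: int
    stratum: StratumKey | None = None

    @property
    def prevalence(self) -> float:
        return self.support_count / self.n_patients

    @property
    def size(self) -> int:
        return len(self.items)


def min_support_count(min_support_fraction: float, n_patients: int) -> int:
    """ceil(xi * n) with a guard against float round-up artifacts.

    0.05 * 2000 evaluates to slightly above 100 in binary floating point;
    a naive ceil would wrongly exclude patterns at exactly the threshold.
    """
    return max(1, math.ceil(min_support_fraction * n_patients - 1e-9))


def _coerce_transactions(
    transactions: TransactionSet | Mapping[str, Iterable[str]] | Iterable[Iterable[str]],
    n_patients: int | None,
) -> tuple[list[frozenset[str]], int, StratumKey | None]:
    stratum = None
    if isinstance(transactions, TransactionSet):
        stratum = transactions.stratum
        sets = [frozenset(t) for _, t in sorted(transactions.transactions.items())]
        n = transactions.n_patients
    elif isinstance(transactions, Mapping):
        sets = [frozenset(t) for _, t in sorted(transactions.items())]
        n = len(sets)
    else:
        sets = [frozenset(t) for t in transactions]
        n = len(sets)
    if n_patients is not None:
        n = n_patients
    return sets, n, stratum


# ---------------------------------------------------------------------------
# FP-tree
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("item", "count", "parent", "children")

    def __init__(self, item: int, count: int, parent: "_Node | None"):
        self.item = item
        self.count = count
        self.parent = parent
        self.children: dict[int, _Node] = {}


def _build_tree(
    itemized: Iterable[tuple[tuple[int, ...], int]],
) -> tuple[_Node, dict[int, list[_Node]]]:
    """Build a prefix tree from (rank-sorted item tuple, multiplicity) pairs."""
    root = _Node(-1, 0, None)
    node_links: dict[int, list[_Node]] = defaultdict(list)
    for items, mult in itemized:
        node = root
        for item in items:
            child = node.children.get(item)
            if child is None:
                child = _Node(item, 0, node)
                node.children[item] = child
                node_links[item].append(child)
            child.count += mult
            node = child
    return root, node_links


def _mine_tree(
    node_links: dict[int, list[_Node]],
    item_counts: Counter,
    min_count: int,
    suffix: tuple[int, ...],
    out: dict[frozenset[int], int],
    max_size: int | None,
) -> None:
    # Least-frequent items first (highest rank), standard FP-growth order.
    for item in sorted(item_counts, reverse=True):
        support = item_counts[item]
        itemset = frozenset(suffix + (item,))
        out[itemset] = support
        if max_size is not None and len(itemset) >= max_size:
            continue
        # Conditional pattern base: prefix paths of every node holding `item`.
        cond: list[tuple[tuple[int, ...], int]] = []
        cond_counts: Counter = Counter()
        for node in node_links[item]:
            path = []
            parent = node.parent
            while parent is not None and parent.item != -1:
                path.append(parent.item)
                parent = parent.parent
            if path:
                path.reverse()
                cond.append((tuple(path), node.count))
                for p in path:
                    cond_counts[p] += node.count
        freq = {i: c for i, c in cond_counts.items() if c >= min_count}
        if not freq:
            continue
        filtered = [
            (tuple(i for i in path if i in freq), mult) for path, mult in cond
        ]
        filtered = [(p, m) for p, m in filtered if p]
        _, child_links = _build_tree(filtered)
        _mine_tree(
            child_links, Counter(freq), min_count, suffix + (item,), out, max_size
        )


def _finalize(
    counts: Mapping[frozenset[str], int],
    n: int,
    stratum: StratumKey | None,
    config: MinerConfig,
) -> list[FrequentPattern]:
    patterns = [
        FrequentPattern(tuple(sorted(items)), c, n, stratum)
        for items, c in counts.items()
        if len(items) >= config.min_itemset_size
        and (config.max_itemset_size is None or len(items) <= config.max_itemset_size)
    ]
    patterns.sort(key=lambda p: (p.size, p.items))
    return patterns


def mine_frequent_itemsets(
    transactions: TransactionSet | Mapping[str, Iterable[str]] | Iterable[Iterable[str]],
    config: MinerConfig | None = None,
    *,
    n_patients: int | None = None,
) -> list[FrequentPattern]:
    """All itemsets with support >= ceil(xi * n), mined by FP-growth.

    Output is deterministic: sorted by itemset size, then lexicographically
    by items.  Result is invariant to transaction order and to item order
    within transactions.
    """
    config = config or MinerConfig()
    sets, n, stratum = _coerce_transactions(transactions, n_patients)
    if n < 1:
        raise EmptyStratumError("stratum has no patients")
    min_count = min_support_count(config.min_support_fraction, n)

    item_counts = Counter(item for t in sets for item in t)
    frequent = {i: c for i, c in item_counts.items() if c >= min_count}
    if not frequent:
        return []
    # Rank: descending support, ties lexicographic; lower rank = more frequent.
    order = sorted(frequent, key=lambda i: (-frequent[i], i))
    rank = {item: r for r, item in enumerate(order)}

    # Deduplicate identical filtered transactions for tree compactness.
    filtered: Counter = Counter()
    for t in sets:
        key = tuple(sorted((rank[i] for i in t if i in rank)))
        if key:
            filtered[key] += 1

    _, node_links = _build_tree(filtered.items())
    raw: dict[frozenset[int], int] = {}
    _mine_tree(
        node_links,
        Counter({rank[i]: c for i, c in frequent.items()}),
        min_count,
        (),
        raw,
        config.max_itemset_size,
    )
    named = {
        frozenset(order[r] for r in itemset): count for itemset, count in raw.items()
    }
    return _finalize(named, n, stratum, config)


def brute_force_itemsets(
    transactions: TransactionSet | Mapping[str, Iterable[str]] | Iterable[Iterable[str]],
    config: MinerConfig | None = None,
    *,
    n_patients: int | None = None,
    max_universe: int = 20,
) -> list[FrequentPattern]:
    """Exhaustive-enumeration oracle: same contract as the FP-growth miner.

    Counts support of every non-empty subset of the observed item universe
    by direct containment.  Exponential in the universe size, hence the
    hard guard — this function exists for verification, not analysis.
    """
    config = config or MinerConfig()
    sets, n, stratum = _coerce_transactions(transactions, n_patients)
    if n < 1:
        raise EmptyStratumError("stratum has no patients")
    universe = sorted(set().union(*sets)) if sets else []
    if len(universe) > max_universe:
        raise ValueError(
            f"item universe of {len(universe)} exceeds {max_universe}; "
            "the brute-force oracle is for tests only"
        )
    min_count = min_support_count(config.min_support_fraction, n)
    counts: dict[frozenset[str], int] = {}
    for size in range(1, len(universe) + 1):
        for combo in itertools.combinations(universe, size):
            needed = frozenset(combo)
            support = sum(1 for t in sets if needed <= t)
            if support >= min_count:
                counts[needed] = support
    return _finalize(counts, n, stratum, config)


def filter_multimorbidity(
    patterns: Sequence[FrequentPattern], min_size: int = 2
) -> list[FrequentPattern]:
    """Keep only true multimorbidity patterns (two or more conditions)."""
    return [p for p in patterns if p.size >= min_size]
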