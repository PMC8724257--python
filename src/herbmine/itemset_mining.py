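"""Frequent-itemset mining and association rules over prescription sets.

A levelwise (Apriori-style) enumeration with downward-closure pruning: a
size-k candidate is generated only when all of its size-(k-1) subsets are
frequent. Support of an itemset is the number (or fraction) of transactions
containing all its items; a rule A -> B is kept when
confidence = count(A u B) / count(A) clears the confidence threshold.

Instance sizes in prescription surveys (tens of materials, around a hundred
transactions) never require FP-growth or bitmap tricks; the levelwise scan
is the transparent, oracle-checkable choice.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from .errors import ValidationError
from .io_model import TransactionSet


@dataclass(frozen=True)
class ItemsetSupport:
    items: tuple[str, ...]   # sorted lexicographically
    count: int
    fraction: float


@dataclass(frozen=True)
class AssociationRule:
    antecedent: tuple[str, ...]
    consequent: tuple[str, ...]
    support_count: int
    support_fraction: float
    confidence: float


@dataclass(frozen=True)
class MiningConfig:
    """Mining thresholds; defaults are the survey's settings.

    ``min_support`` is a fraction of N (0.50); the comparison is inclusive
    (>=) by default. ``min_confidence`` (0.95) is strict (>) by default.
    ``consequent_policy`` controls rule generation: "single_item" emits one
    rule per single-item consequent; "any_split" emits every nonempty
    antecedent/consequent bipartition.
    """

    min_support: float = 0.50
    support_inclusive: bool = True
    min_confidence: float = 0.95
    confidence_inclusive: bool = False
    max_size: int = 5
    consequent_policy: str = "single_item"

    def __post_init__(self) -> None:
        if not (0 < self.min_support <= 1):
            raise ValueError(f"min_support must be in (0, 1], got {self.min_support}")
        if not (0 <= self.min_confidence <= 1):
            raise ValueError(f"min_confidence must be in [0, 1], got {self.min_confidence}")
        if self.max_size < 2:
            raise ValueError(f"max_size must be >= 2, got {self.max_size}")
        if self.consequent_policy not in ("single_item", "any_split"):
            raise ValueError(f"unknown consequent_policy {self.consequent_policy!r}")


def brute_force_support(ts: TransactionSet, items: Iterable[str]) -> int:
    """Count transactions containing every item, by linear scan.

    The independent oracle used to verify both the miner and the exact
    constraint solver. The empty itemset is contained in every transaction.
    """
    itemset = frozenset(items)
    outside = itemset - set(ts.universe)
    if outside:
        raise ValidationError(f"items outside the universe: {sorted(outside)}")
    return sum(1 for t in ts.transactions if itemset <= t)


def _passes(count: int, threshold: float, inclusive: bool) -> bool:
    return count >= threshold if inclusive else count > threshold


def mine_frequent_itemsets(
    ts: TransactionSet, config: MiningConfig | None = None
) -> list[ItemsetSupport]:
    """Enumerate all frequent itemsets of sizes 1..max_size.

    Output is sorted by size, then count descending, then lexicographic
    items, so repeated runs are byte-stable. Itemsets of size >= 2 are the
    "combinations" of the survey's terminology.
    """
    config = config or MiningConfig()
    if ts.N == 0:
        raise ValidationError("cannot mine an empty transaction set (N = 0)")
    threshold = config.min_support * ts.N

    counts: dict[frozenset[str], int] = {}
    # L1
    single_counts = {item: 0 for item in ts.universe}
    for t in ts.transactions:
        for item in t:
            single_counts[item] += 1
    level = []
    for item in sorted(ts.universe):
        c = single_counts[item]
        if _passes(c, threshold, config.support_inclusive):
            fs = frozenset([item])
            counts[fs] = c
            level.append((item,))

    k = 1
    while level and k < config.max_size:
        k += 1
        frequent_prev = set(map(frozenset, level))
        candidates: list[tuple[str, ...]] = []
        # join: pairs of (k-1)-sets sharing the first k-2 items
        for a, b in combinations(level, 2):
            if a[:-1] == b[:-1]:
                cand = a + (b[-1],) if a[-1] < b[-1] else b + (a[-1],)
                # prune: every (k-1)-subset must be frequent
                if all(frozenset(cand[:i] + cand[i + 1:]) in frequent_prev
                       for i in range(k)):
                    candidates.append(cand)
        next_level = []
        for cand in candidates:
            fs = frozenset(cand)
            c = sum(1 for t in ts.transactions if fs <= t)
            if _passes(c, threshold, config.support_inclusive):
                counts[fs] = c
                next_level.append(cand)
        level = sorted(next_level)

    out = [
        ItemsetSupport(items=tuple(sorted(fs)), count=c, fraction=c / ts.N)
        for fs, c in counts.items()
    ]
    out.sort(key=lambda s: (len(s.items), -s.count, s.items))
    return out


def generate_rules(
    ts: TransactionSet,
    frequent: Sequence[ItemsetSupport],
    config: MiningConfig | None = None,
) -> list[AssociationRule]:
    """Association rules from mined frequent itemsets.

    Every antecedent of a frequent itemset is itself frequent (downward
    closure), so its count is read from the mined table; a missing
    antecedent indicates the itemsets were not mined from this transaction
    set and raises. Rules are sorted by confidence descending, then support,
    then lexicographic antecedent/consequent.
    """
    config = config or MiningConfig()
    by_set = {frozenset(s.items): s.count for s in frequent}

    rules: list[AssociationRule] = []
    for s in frequent:
        if len(s.items) < 2:
            continue
        full = frozenset(s.items)
        if config.consequent_policy == "single_item":
            splits = [(full - {c}, frozenset([c])) for c in s.items]
        else:
            splits = []
            for r in range(1, len(s.items)):
                for cons in combinations(s.items, r):
                    cfs = frozenset(cons)
                    splits.append((full - cfs, cfs))
        for ante, cons in splits:
            if not ante or not cons:
                continue
            if ante not in by_set:
                raise ValidationError(
                    f"antecedent {sorted(ante)} missing from the frequent table; "
                    "itemsets must be mined from the same transactions"
                )
            ante_count = by_set[ante]
            conf = s.count / ante_count
            if _passes(conf, config.min_confidence, config.confidence_inclusive):
                rules.append(AssociationRule(
                    antecedent=tuple(sorted(ante)),
                    consequent=tuple(sorted(cons)),
                    support_count=s.count,
                    support_fraction=s.fraction,
                    confidence=conf,
                ))
    rules.sort(key=lambda r: (-r.confidence, -r.support_count, r.antecedent, r.consequent))
    return rules
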