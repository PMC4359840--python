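"""Rough-set kernel: indiscernibility partitions, approximations, positive
region, dependency degree, core and an exhaustive reduct oracle.

Given a decision table, an attribute subset B induces the indiscernibility
relation IND(B) — two objects are indiscernible when they agree on every
attribute of B — and hence an equivalence partition of the universe.  The
positive region POS_B(D) is the union of B-blocks that are pure in the
decision, and the dependency degree is

    gamma_B = |POS_B(D)| / |O|.

A reduct is a minimal subset R with gamma_R equal to gamma of the full
condition set; the core is the intersection of all reducts, equivalently the
attributes whose single removal changes gamma.  Inconsistent tables (equal
condition rows, different decisions) are legal and simply have gamma_C < 1;
reducts then preserve gamma_C rather than reach 1.

The kernel works on an integer-coded matrix cached on the table; subsets are
grouped by mixed-radix keys (with a lexicographic fallback when the radix
product would overflow), which keeps the GA's inner loop fast.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .table import DecisionTable, TableError

__all__ = [
    "EquivalencePartition",
    "Approximation",
    "DependencyResult",
    "ReductSet",
    "partition",
    "approximate",
    "dependency",
    "compute_core",
    "enumerate_reducts",
]


# ---------------------------------------------------------------------------
# fast grouped views of the encoded table
# ---------------------------------------------------------------------------

def _group_inverse(codes: np.ndarray, cards: np.ndarray, cols: Sequence[int]) -> np.ndarray:
    """Group id per row under value-equality on ``cols`` (ids arbitrary)."""
    n = codes.shape[0]
    cols = list(cols)
    if not cols:
        return np.zeros(n, dtype=np.int64)
    prod = 1
    for c in cols:
        prod *= int(cards[c])
        if prod > 2**62:
            break
    if prod <= 2**62:
        strides = np.empty(len(cols), dtype=np.int64)
        s = 1
        for i, c in enumerate(cols):
            strides[i] = s
            s *= int(cards[c])
        key = codes[:, cols] @ strides
        _, inv = np.unique(key, return_inverse=True)
    else:  # pragma: no cover - needs >62 bits of joint cardinality
        _, inv = np.unique(codes[:, cols], axis=0, return_inverse=True)
    return inv.astype(np.int64)


def _pos_mask(
    codes: np.ndarray, cards: np.ndarray, ycodes: np.ndarray, n_classes: int,
    cols: Sequence[int],
) -> np.ndarray:
    """Boolean mask of objects in the positive region POS_cols(D)."""
    n = codes.shape[0]
    cols = list(cols)
    if not cols:
        # single block: pure iff the decision is constant
        return np.full(n, n_classes == 1)
    inv = _group_inverse(codes, cards, cols)
    n_groups = int(inv.max()) + 1
    counts = np.bincount(inv * n_classes + ycodes, minlength=n_groups * n_classes)
    pure = (counts.reshape(n_groups, n_classes) > 0).sum(axis=1) == 1
    return pure[inv]


def _pos_count(
    codes: np.ndarray, cards: np.ndarray, ycodes: np.ndarray, n_classes: int,
    cols: Sequence[int],
) -> int:
    return int(_pos_mask(codes, cards, ycodes, n_classes, cols).sum())


def _resolve_condition_indices(table: DecisionTable, subset: Iterable[str]) -> list[int]:
    conds = table.condition_attributes
    index = {a: j for j, a in enumerate(conds)}
    subset = list(subset)
    if not subset:
        raise TableError("attribute subset is empty")
    unknown = [a for a in subset if a not in index]
    if unknown:
        raise TableError(f"unknown attribute(s): {unknown}")
    # de-duplicate, keep table order
    return sorted({index[a] for a in subset})


# ---------------------------------------------------------------------------
# public types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EquivalencePartition:
    """Partition O/IND(B): blocks of mutually indiscernible objects."""

    blocks: tuple[tuple[int, ...], ...]
    attribute_subset: tuple[str, ...]

    def block_of(self, obj: int) -> tuple[int, ...]:
        for b in self.blocks:
            if obj in b:
                return b
        raise KeyError(obj)


@dataclass(frozen=True)
class Approximation:
    """Lower/upper approximation and boundary of a target object set."""

    lower: frozenset[int]
    upper: frozenset[int]
    boundary: frozenset[int]
    target: frozenset[int]


@dataclass(frozen=True)
class DependencyResult:
    """Positive region and dependency degree gamma for an attribute subset."""

    positive_region: frozenset[int]
    gamma: float
    subset: tuple[str, ...]


@dataclass(frozen=True)
class ReductSet:
    core: frozenset[str]
    reducts: tuple[frozenset[str], ...]
    reference_gamma: float


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def partition(table: DecisionTable, subset: Iterable[str]) -> EquivalencePartition:
    """Partition of the objects by value-equality on ``subset``.

    ``subset`` may include the decision attribute.  Blocks are ordered by
    their first object index (deterministic).
    """
    subset = list(subset)
    if not subset:
        raise TableError("attribute subset is empty")
    valid = set(table.condition_attributes) | {table.decision_attribute}
    unknown = [a for a in subset if a not in valid]
    if unknown:
        raise TableError(f"unknown attribute(s): {unknown}")
    cols = [a for a in list(table.data.columns) if a in set(subset)]
    groups: dict[tuple, list[int]] = {}
    for i, row in enumerate(table.data[cols].itertuples(index=False, name=None)):
        groups.setdefault(row, []).append(i)
    blocks = tuple(tuple(v) for v in groups.values())  # insertion order = first occurrence
    return EquivalencePartition(blocks=blocks, attribute_subset=tuple(cols))


def approximate(
    table: DecisionTable, subset: Iterable[str], target: Iterable[int]
) -> Approximation:
    """B-lower and B-upper approximation of a target object set."""
    target = frozenset(int(t) for t in target)
    bad = [t for t in target if not (0 <= t < table.n_objects)]
    if bad:
        raise TableError(f"unknown object(s): {sorted(bad)}")
    part = partition(table, subset)
    lower: set[int] = set()
    upper: set[int] = set()
    for block in part.blocks:
        bset = set(block)
        if bset & target:
            upper |= bset
            if bset <= target:
                lower |= bset
    return Approximation(
        lower=frozenset(lower),
        upper=frozenset(upper),
        boundary=frozenset(upper - lower),
        target=target,
    )


def dependency(table: DecisionTable, subset: Iterable[str]) -> DependencyResult:
    """Positive region and dependency degree gamma_B of the decision on B.

    POS_B(D) is the union over decision classes X of the B-lower
    approximation of X; gamma = |POS| / |O|.
    """
    cols = _resolve_condition_indices(table, subset)
    codes, cards, ycodes, k = table.encoded()
    mask = _pos_mask(codes, cards, ycodes, k, cols)
    conds = table.condition_attributes
    return DependencyResult(
        positive_region=frozenset(int(i) for i in np.flatnonzero(mask)),
        gamma=float(mask.sum()) / table.n_objects,
        subset=tuple(conds[j] for j in cols),
    )


def compute_core(table: DecisionTable) -> frozenset[str]:
    """Attributes whose single removal changes gamma of the full set.

    Equals the intersection of all reducts; computed by the one-by-one
    removal test.
    """
    conds = table.condition_attributes
    codes, cards, ycodes, k = table.encoded()
    all_cols = list(range(len(conds)))
    pos_full = _pos_count(codes, cards, ycodes, k, all_cols)
    core = []
    for j in all_cols:
        rest = [c for c in all_cols if c != j]
        if _pos_count(codes, cards, ycodes, k, rest) != pos_full:
            core.append(conds[j])
    return frozenset(core)


def enumerate_reducts(table: DecisionTable, max_attributes: int = 16) -> ReductSet:
    """All minimal gamma-preserving subsets, by exhaustive search.

    Subsets are visited in order of increasing size; supersets of already
    found reducts are pruned, so every reported subset is minimal by
    construction.  Intended as a testing oracle — attribute reduction is
    NP-hard, hence the ``max_attributes`` guard.
    """
    conds = table.condition_attributes
    m = len(conds)
    if m > max_attributes:
        raise TableError(
            f"|C| = {m} exceeds the exhaustive-search guard "
            f"max_attributes = {max_attributes}"
        )
    codes, cards, ycodes, k = table.encoded()
    pos_full = _pos_count(codes, cards, ycodes, k, list(range(m)))
    reduct_masks: list[int] = []
    reducts: list[frozenset[str]] = []
    for size in range(1, m + 1):
        for combo in combinations(range(m), size):
            mask = 0
            for j in combo:
                mask |= 1 << j
            if any(mask & r == r for r in reduct_masks):
                continue  # superset of a known reduct
            if _pos_count(codes, cards, ycodes, k, list(combo)) == pos_full:
                reduct_masks.append(mask)
                reducts.append(frozenset(conds[j] for j in combo))
    core: frozenset[str] = frozenset(conds)
    for r in reducts:
        core &= r
    if not reducts:  # only possible if pos_full unreachable by any subset: cannot happen
        core = frozenset()
    return ReductSet(
        core=core,
        reducts=tuple(reducts),
        reference_gamma=pos_full / table.n_objects,
    )
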