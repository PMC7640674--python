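"""Balanced incomplete block designs for best-worst scaling choice sets.

A BWS object-case questionnaire shows each respondent a series of
*choice sets* (blocks) of ``k`` items drawn from a master list of ``v``
items.  For the counting analysis to be fair every item must appear
equally often and every pair of items must co-occur equally often, i.e.
the blocks must form a (v, k, lambda) balanced incomplete block design
(BIBD): ``b`` blocks of size ``k``, each item replicated ``r`` times,
each unordered pair together in exactly ``lambda`` blocks.

The designs used here are *symmetric* cyclic designs (b = v) built by
developing a planar difference set modulo v: a k-subset D of Z_v whose
pairwise differences hit every nonzero residue exactly ``lambda`` times.
Shifting D by 0..v-1 yields the b = v blocks.  The statin-outcome
instrument uses (v, k, lambda) = (13, 4, 1): 13 choice sets of four
outcomes in which every pair of outcomes meets exactly once.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

from .study_data import ITEMS, ITEM_LABELS

__all__ = [
    "ItemCatalog",
    "BWSDesign",
    "DesignReport",
    "DifferenceSetNotFound",
    "KNOWN_BASE_BLOCKS",
    "bibd_params",
    "find_difference_set",
    "develop_design",
    "validate_design",
    "pairs_per_block",
    "statin_outcome_design",
]


class DifferenceSetNotFound(LookupError):
    """Exhaustive search finished without finding a difference set."""


@dataclass(frozen=True)
class ItemCatalog:
    """Ordered master list of items under evaluation.

    Parameters
    ----------
    items
        Unique, non-empty item identifiers; order fixes the 0-based
        internal index of each item.
    descriptions
        Optional lay-description text per item.
    """

    items: tuple[str, ...]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("item catalog must not be empty")
        if len(set(self.items)) != len(self.items):
            raise ValueError("item identifiers must be unique")
        object.__setattr__(self, "items", tuple(self.items))

    def __len__(self) -> int:
        return len(self.items)

    def index(self, item: str) -> int:
        return self.items.index(item)


def default_catalog() -> ItemCatalog:
    """The 13 statin benefit/harm outcomes of the motivating study."""
    return ItemCatalog(items=ITEMS, descriptions=dict(ITEM_LABELS))


@dataclass(frozen=True)
class BWSDesign:
    """A block design realised on an item catalog.

    ``blocks`` holds 0-based item indices, each block sorted ascending
    (presentation randomisation is out of analytic scope).
    """

    catalog: ItemCatalog
    v: int
    k: int
    lambda_: int
    blocks: tuple[tuple[int, ...], ...]

    @property
    def b(self) -> int:
        return len(self.blocks)

    @property
    def r(self) -> int:
        """Per-item replication, lambda * (v-1) / (k-1)."""
        return self.lambda_ * (self.v - 1) // (self.k - 1)

    @property
    def block_ids(self) -> list[str]:
        return [f"B{i:02d}" for i in range(self.b)]

    def block_items(self, block_index: int) -> tuple[str, ...]:
        return tuple(self.catalog.items[i] for i in self.blocks[block_index])

    def blocks_containing(self, item: str) -> list[int]:
        idx = self.catalog.index(item)
        return [bi for bi, blk in enumerate(self.blocks) if idx in blk]


@dataclass
class DesignReport:
    """validate_design output: coverage tallies plus human-readable findings."""

    valid: bool
    pair_coverage: dict[tuple[int, int], int]
    replication: dict[int, int]
    violations: list[str]


def bibd_params(v: int, k: int, lambda_: int = 1) -> tuple[int, int]:
    """Number of blocks ``b`` and replication ``r`` of a (v, k, lambda) BIBD.

    ``b = lambda v (v-1) / (k (k-1))`` and ``r = lambda (v-1) / (k-1)``;
    both must be integers (necessary existence conditions).

    Raises
    ------
    ValueError
        If ``v < 2``, ``k`` outside ``[2, v]``, ``lambda_ < 1``, or the
        divisibility conditions fail.
    """
    if v < 2:
        raise ValueError(f"need at least two items, got v={v}")
    if not 2 <= k <= v:
        raise ValueError(f"block size k={k} must satisfy 2 <= k <= v={v}")
    if lambda_ < 1:
        raise ValueError(f"pair coverage lambda={lambda_} must be positive")
    r_num = lambda_ * (v - 1)
    b_num = lambda_ * v * (v - 1)
    if r_num % (k - 1) or b_num % (k * (k - 1)):
        raise ValueError(
            f"no ({v}, {k}, {lambda_}) BIBD exists: "
            f"r = {r_num}/{k - 1} or b = {b_num}/{k * (k - 1)} is not an integer"
        )
    return b_num // (k * (k - 1)), r_num // (k - 1)


def _difference_counts(subset: tuple[int, ...], v: int) -> Counter:
    counts: Counter = Counter()
    for d1, d2 in itertools.permutations(subset, 2):
        counts[(d1 - d2) % v] += 1
    return counts


def is_difference_set(subset: tuple[int, ...], v: int, lambda_: int = 1) -> bool:
    """True iff every nonzero residue mod v occurs exactly lambda_ times
    among the ordered pairwise differences of ``subset``."""
    counts = _difference_counts(tuple(subset), v)
    return all(counts.get(d, 0) == lambda_ for d in range(1, v))


def find_difference_set(v: int, k: int, lambda_: int = 1) -> tuple[int, ...]:
    """Lexicographically first (v, k, lambda) planar difference set in Z_v.

    Exhaustive over all C(v, k) subsets, so intended for v up to ~30.
    A symmetric design (b = v) additionally requires
    ``k (k-1) = lambda (v-1)``.

    Raises
    ------
    ValueError
        If the divisibility / symmetry conditions already rule one out.
    DifferenceSetNotFound
        If the exhaustive search completes empty.
    """
    bibd_params(v, k, lambda_)  # divisibility; raises ValueError
    if k * (k - 1) != lambda_ * (v - 1):
        raise ValueError(
            f"({v}, {k}, {lambda_}) admits no cyclic difference set: "
            f"k(k-1)={k * (k - 1)} != lambda(v-1)={lambda_ * (v - 1)}"
        )
    for subset in itertools.combinations(range(v), k):
        if is_difference_set(subset, v, lambda_):
            return subset
    raise DifferenceSetNotFound(f"no ({v}, {k}, {lambda_}) difference set in Z_{v}")


#: Known base blocks for cyclic development; each entry is verified by
#: validate_design in the test suite.
KNOWN_BASE_BLOCKS: dict[tuple[int, int, int], tuple[int, ...]] = {
    (7, 3, 1): (0, 1, 3),
    (13, 4, 1): (0, 1, 3, 9),
    (21, 5, 1): (0, 1, 6, 8, 18),
    (11, 5, 2): (1, 3, 4, 5, 9),
}


def develop_design(
    catalog: ItemCatalog, base_block: tuple[int, ...], v: int
) -> BWSDesign:
    """Cyclically develop a difference set into a symmetric BIBD.

    Block i is ``{(d + i) mod v for d in base_block}``, i = 0..v-1,
    items sorted ascending within each block.  The result is validated;
    a base block that is not a difference set raises.
    """
    if len(catalog) != v:
        raise ValueError(f"catalog has {len(catalog)} items, design modulus is {v}")
    k = len(set(base_block))
    if k != len(base_block):
        raise ValueError("base block has repeated residues")
    lambda_, rem = divmod(k * (k - 1), v - 1)
    if rem:
        raise ValueError(f"k(k-1)={k * (k - 1)} not divisible by v-1={v - 1}")
    blocks = tuple(
        tuple(sorted((d + shift) % v for d in base_block)) for shift in range(v)
    )
    design = BWSDesign(catalog=catalog, v=v, k=k, lambda_=lambda_, blocks=blocks)
    report = validate_design(design)
    if not report.valid:
        raise ValueError(
            "base block is not a difference set; development is unbalanced: "
            + "; ".join(report.violations[:5])
        )
    return design


def validate_design(design: BWSDesign) -> DesignReport:
    """Audit a design against the BIBD balance conditions.

    Counts every unordered pair's co-occurrence and every item's
    replication; the design is valid iff all pairs are covered exactly
    ``lambda_`` times, all items replicated exactly ``r`` times, and all
    blocks have exactly ``k`` distinct members.  Invalid designs yield
    ``valid=False`` with findings, never an exception.
    """
    v, k, lam = design.v, design.k, design.lambda_
    violations: list[str] = []
    pair_coverage: dict[tuple[int, int], int] = {
        pair: 0 for pair in itertools.combinations(range(v), 2)
    }
    replication: dict[int, int] = {i: 0 for i in range(v)}

    for bi, block in enumerate(design.blocks):
        if len(set(block)) != len(block):
            violations.append(f"block {bi} has repeated items")
        if len(set(block)) != k:
            violations.append(f"block {bi} has {len(set(block))} distinct items, expected k={k}")
        for i in block:
            replication[i] += 1
        for i, j in itertools.combinations(sorted(set(block)), 2):
            pair_coverage[(i, j)] += 1

    try:
        _, r = bibd_params(v, k, lam)
    except ValueError as exc:
        violations.append(str(exc))
        r = None

    for pair, count in pair_coverage.items():
        if count != lam:
            names = tuple(design.catalog.items[x] for x in pair)
            violations.append(f"pair {names} covered {count} times, expected {lam}")
    if r is not None:
        for i, count in replication.items():
            if count != r:
                violations.append(
                    f"item {design.catalog.items[i]!r} replicated {count} times, expected {r}"
                )
    return DesignReport(
        valid=not violations,
        pair_coverage=pair_coverage,
        replication=replication,
        violations=violations,
    )


def pairs_per_block(k: int) -> int:
    """Count of ordered (best, worst) pairs in a block of size k: k(k-1).

    With k = 4 this is the 12 maxdiff alternatives per choice set.
    """
    if k < 2:
        raise ValueError(f"a choice set needs at least 2 items, got k={k}")
    return k * (k - 1)


def statin_outcome_design() -> BWSDesign:
    """The (13, 4, 1) design on the 13 statin outcomes.

    Built from the catalogued base block {0, 1, 3, 9} mod 13; 13 choice
    sets of four in which every pair of outcomes co-occurs exactly once
    and every outcome appears exactly four times.
    """
    return develop_design(default_catalog(), KNOWN_BASE_BLOCKS[(13, 4, 1)], 13)
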