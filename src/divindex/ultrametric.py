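"""Ultrametric reversals: necessary conditions and the reversible family U.

The family ``U`` consists of clock-like trees built from nested cherries: for
an even number of leaves ``n`` with ``m = n/2`` cherries, the ``i``-th cherry
from the root has stem length ``n - 2i`` and pendant length ``i`` (the deepest
cherry repeats stem and pendant of its sibling), spine edges all have length
one, and every root-to-leaf distance is ``n - 1``.  Removing the even-indexed
leaf of every cherry reverses both the Fair Proportion and Equal-Splits
rankings in the relaxed (tie-tolerant) sense.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Tuple

from .extinction import RankingComparison, compare_rankings
from .indices import AllocationRule, scores
from .tree import ExtinctionEvent, RootedTree, TreeError, natural_key

__all__ = [
    "UltrametricFamilySpec",
    "generate_U",
    "even_index_event",
    "check_prop10",
    "check_cor11",
    "Prop10Result",
    "ultrametric_reversal_report",
]


@dataclass(frozen=True)
class UltrametricFamilySpec:
    n: int

    def __post_init__(self):
        if self.n < 6 or self.n % 2:
            raise ValueError("family U requires an even number of leaves n >= 6")

    @property
    def depth(self) -> int:
        return self.n - 1

    @property
    def n_cherries(self) -> int:
        return self.n // 2

    def stem_length(self, i: int) -> int:
        """Stem of the i-th cherry from the root (1-based); the deepest repeats its sibling's."""
        m = self.n_cherries
        return self.n - 2 * min(i, m - 1)

    def pendant_length(self, i: int) -> int:
        return min(i, self.n_cherries - 1)


def generate_U(n: int) -> RootedTree:
    """The n-leaf member of the reversible ultrametric family.

    Leaves are labelled ``x1..xn`` with ``{x_{2i-1}, x_{2i}}`` the ``i``-th
    cherry from the bottom, so ``x_{n-1}, x_n`` sit nearest the root.
    """
    spec = UltrametricFamilySpec(n)
    m = spec.n_cherries
    t = RootedTree()
    t.root = t.new_vertex()

    def add_cherry(parent: int, i_from_root: int) -> None:
        i_from_bottom = m + 1 - i_from_root
        v = t.new_vertex()
        t.add_edge(parent, v, Fraction(spec.stem_length(i_from_root)))
        for k in (2 * i_from_bottom - 1, 2 * i_from_bottom):
            leaf = t.new_vertex(f"x{k}")
            t.add_edge(v, leaf, Fraction(spec.pendant_length(i_from_root)))

    spine = t.root
    for i in range(1, m - 1):
        nxt = t.new_vertex()
        t.add_edge(spine, nxt, Fraction(1))
        add_cherry(spine, i)
        spine = nxt
    # the lowest spine vertex carries the two deepest cherries
    add_cherry(spine, m)
    add_cherry(spine, m - 1)
    t.validate(require_lengths=True)
    if not t.is_ultrametric():  # pragma: no cover - construction guarantees this
        raise TreeError("family generator produced a non-ultrametric tree")
    return t


def even_index_event(tree: RootedTree) -> ExtinctionEvent:
    """Extinction of every leaf ``x{k}`` with even ``k`` (one per cherry on U)."""
    extinct = {lab for lab in tree.leaf_labels() if int(lab.lstrip("x")) % 2 == 0}
    return tree.event(extinct)


@dataclass(frozen=True)
class Prop10Result:
    passes: bool
    witness: Optional[Tuple[str, str]] = None  # (surviving non-cherry leaf, surviving member of A)


def _require_binary(tree: RootedTree) -> None:
    for v in tree.preorder():
        if not tree.is_leaf(v) and len(tree.children[v]) != 2:
            raise TreeError("this check is defined for binary trees only")


def check_prop10(tree: RootedTree, event: ExtinctionEvent) -> Prop10Result:
    """Necessary condition for an FP reversal on an ultrametric binary tree.

    For each surviving leaf ``x`` outside every cherry (parent ``v``, cluster
    ``{x} | A``), all of ``A`` must be extinct; otherwise the pair
    ``(x, survivor in A)`` witnesses that no reversal is possible.
    """
    _require_binary(tree)
    if not tree.is_ultrametric():
        raise TreeError("check requires ultrametric edge lengths")
    cherry_leaves = set()
    for _, leaves in tree.m_cherries():
        cherry_leaves.update(leaves)
    for name in sorted(event.survivors, key=natural_key):
        if name in cherry_leaves:
            continue
        leaf = tree.leaf_by_name(name)
        v = tree.parent.get(leaf)
        if v is None:
            continue
        a_set = tree.cluster_of_vertex(v) - {name}
        surviving_a = sorted(a_set & set(event.survivors), key=natural_key)
        if surviving_a:
            return Prop10Result(passes=False, witness=(name, surviving_a[0]))
    return Prop10Result(passes=True)


def check_cor11(tree: RootedTree) -> bool:
    """True iff every leaf belongs to a cherry (necessary for a one-per-cherry
    ultrametric FP reversal)."""
    _require_binary(tree)
    cherry_leaves = set()
    for _, leaves in tree.m_cherries():
        cherry_leaves.update(leaves)
    return set(tree.leaf_labels()) <= cherry_leaves


def ultrametric_reversal_report(
    tree: RootedTree, rule: AllocationRule, event: ExtinctionEvent
) -> RankingComparison:
    """Relaxed-reversal comparison (strictly ordered pairs must flip; ties may persist)."""
    if not tree.is_ultrametric():
        raise TreeError("report requires ultrametric edge lengths")
    before = scores(tree, rule)
    after = scores(tree.prune_and_suppress(event), rule)
    return compare_rankings(before, after, set(event.survivors))
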