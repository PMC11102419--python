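"""In-package reference trees and seeded synthetic generators.

The 11-leaf example tree and the 12-leaf ultrametric tree are reconstructions
pinned by the printed ratio/score tables they must reproduce; the validation
lives in the test suite.  Synthetic generators are deterministic given a seed
and emit exact rational lengths only.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Dict, List, Tuple

from .exact import Scalar
from .indices import AllocationRule, table_rule
from .tree import RootedTree, parse_newick
from .ultrametric import generate_U

__all__ = [
    "fig3_tree",
    "fig3_theta_rule",
    "fig7_lengths",
    "u12_tree",
    "caterpillar",
    "synthetic_tree",
    "FixtureRegistry",
    "REGISTRY",
]

# Eleven-leaf binary example: a five-leaf caterpillar-like side and a
# five-leaf side of two cherries, plus one root-adjacent leaf.
_FIG3_NEWICK = (
    "((((((x1:1,x2:1)w:1,x3:1)v:1,x4:1)s:1,x5:1)q:1,"
    "(((x6:1,x7:1)y:1,x8:1)t:1,(x9:1,x10:1)u:1)r:1)p:1,x11:1);"
)


def fig3_tree() -> RootedTree:
    """The 11-leaf example tree with unit lengths and named interior vertices."""
    return parse_newick(_FIG3_NEWICK, require_lengths=True)


def fig3_theta_rule() -> AllocationRule:
    """The arbitrary table-defined index on the 11-leaf example tree.

    Its ratio numerators (out of 8, for the drawn-left child) at vertices
    p, q, r, s and t/v are 4, 8, 5, 0 and 2; cherry vertices get 1/2 : 1/2.
    On this tree the drawn-left child is also first in canonical key order
    at every named vertex, so terms bind directly to sorted class keys.
    """
    t = fig3_tree()
    shapes = t.shapes_at_all_vertices()
    left_num = {"p": 4, "q": 8, "r": 5, "s": 0, "t": 2, "v": 2, "w": 4, "y": 4, "u": 4}
    assignments: Dict[Tuple[str, ...], Tuple[Fraction, ...]] = {}
    for name, num in left_num.items():
        v = t.vertex_by_label(name)
        keys = tuple(shapes[c].key for c in t.children[v])
        if tuple(sorted(keys)) != keys:  # pragma: no cover - fixed fixture property
            raise AssertionError("drawn order deviates from canonical order")
        assignments[keys] = (Fraction(num, 8), Fraction(8 - num, 8))
    return table_rule(assignments, name="theta")


def fig7_lengths() -> Dict[int, Scalar]:
    """Edge lengths (with symbolic eps parts) realising the worked big-M reversal.

    Produced by running the big-M construction with M = 32 under Equal-Splits
    on the 11-leaf example; keyed by child vertex of :func:`fig3_tree`.
    """
    from .indices import builtin_rule
    from .reversal import theorem9_construct

    tree = fig3_tree()
    workings, cert = theorem9_construct(tree, builtin_rule("es"), M=Fraction(32))
    return {v: cert.tree.length[v] for _, v in cert.tree.edges()}


def u12_tree() -> RootedTree:
    """The 12-leaf reversible ultrametric tree (nested cherries, depth 11)."""
    return generate_U(12)


def caterpillar(n: int, unit_lengths: bool = True) -> RootedTree:
    """Rooted caterpillar on ``x1..xn``: ``x1, x2`` form the cherry, ``xn`` is root-adjacent."""
    if n < 2:
        raise ValueError("caterpillar needs n >= 2")
    t = RootedTree()
    t.root = t.new_vertex()
    length = Fraction(1) if unit_lengths else None
    top = t.root
    for k in range(n, 2, -1):
        leaf = t.new_vertex(f"x{k}")
        nxt = t.new_vertex()
        t.add_edge(top, nxt, length)
        t.add_edge(top, leaf, length)
        top = nxt
    for k in (1, 2):
        leaf = t.new_vertex(f"x{k}")
        t.add_edge(top, leaf, length)
    t.validate()
    return t


def _random_length(rng: random.Random) -> Fraction:
    return Fraction(rng.randint(1, 60), rng.randint(1, 6))


def synthetic_tree(n: int, seed: int, mode: str = "binary") -> RootedTree:
    """Seeded random tree on ``x1..xn`` with positive rational lengths.

    Modes: ``binary`` (random merges), ``multifurcating`` (random-arity
    merges), ``caterpillar`` (shape fixed, random lengths), ``ultrametric``
    (random binary topology with clock-consistent depths).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    rng = random.Random((seed, n, mode).__repr__())
    if mode == "caterpillar":
        t = caterpillar(n, unit_lengths=False)
        for _, v in t.edges():
            t.length[v] = _random_length(rng)
        t.validate(require_lengths=True)
        return t

    t = RootedTree()
    roots: List[int] = []
    for i in range(1, n + 1):
        roots.append(t.new_vertex(f"x{i}"))

    if mode == "ultrametric":
        height: Dict[int, Fraction] = {v: Fraction(0) for v in roots}
        while len(roots) > 1:
            a, b = rng.sample(range(len(roots)), 2)
            va, vb = roots[a], roots[b]
            parent = t.new_vertex()
            h = max(height[va], height[vb]) + _random_length(rng)
            t.add_edge(parent, va, h - height[va])
            t.add_edge(parent, vb, h - height[vb])
            height[parent] = h
            roots = [r for i, r in enumerate(roots) if i not in (a, b)] + [parent]
        t.root = roots[0]
        t.validate(require_lengths=True)
        return t

    if mode not in ("binary", "multifurcating"):
        raise ValueError(f"unknown mode {mode!r}")
    while len(roots) > 1:
        k = 2 if mode == "binary" else rng.randint(2, min(4, len(roots)))
        picks = sorted(rng.sample(range(len(roots)), k), reverse=True)
        parent = t.new_vertex()
        for i in picks:
            t.add_edge(parent, roots[i], _random_length(rng))
            del roots[i]
        roots.append(parent)
    t.root = roots[0]
    t.validate(require_lengths=True)
    return t


@dataclass(frozen=True)
class FixtureRegistry:
    """Named fixtures with provenance notes."""

    entries: Dict[str, Tuple[Callable[[], RootedTree], str]]

    def names(self) -> List[str]:
        return sorted(self.entries)

    def build(self, name: str) -> RootedTree:
        if name not in self.entries:
            raise KeyError(f"unknown fixture {name!r}")
        return self.entries[name][0]()

    def provenance(self, name: str) -> str:
        return self.entries[name][1]


REGISTRY = FixtureRegistry(
    entries={
        "fig3": (
            fig3_tree,
            "11-leaf binary example with named interior vertices; unit lengths; "
            "pinned by the published ratio table and worked scores",
        ),
        "u12": (
            u12_tree,
            "12-leaf reversible ultrametric family member; pinned by the published "
            "before/after FP and ES score table",
        ),
        "cat6": (lambda: caterpillar(6), "six-leaf unit-length caterpillar"),
    }
)
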