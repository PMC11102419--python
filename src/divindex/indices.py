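"""Diversity indices as ratio-of-allocation rules.

A rule maps the ordered child shapes at a vertex to a ratio of allocations
(non-negative rationals summing to one, one term per child).  Coefficients
follow the consistent form: the coefficient of leaf ``x`` for edge ``e`` is
the product, over interior vertices on the path from the terminal vertex of
``e`` down to ``x``, of the ratio term for the child subtree containing ``x``.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Dict, List, Optional, Sequence, Tuple

from .exact import Scalar, as_fraction
from .tree import RootedTree, Shape, TreeError

__all__ = [
    "AllocationRule",
    "CoefficientTable",
    "RuleError",
    "builtin_rule",
    "table_rule",
    "BUILTIN_RULE_NAMES",
    "coefficients",
    "scores",
    "fp_score_direct",
    "es_score_direct",
    "classify_interior",
    "rigidity_probe",
    "InteriorClassification",
    "RigidityResult",
]


class RuleError(ValueError):
    """An allocation rule was applied outside its domain or returned a bad ratio."""


RatioFn = Callable[[Tuple[Shape, ...]], Tuple[Fraction, ...]]


@dataclass(frozen=True)
class AllocationRule:
    """A named local rule: ordered child shapes -> ratio of allocations."""

    name: str
    ratio_fn: RatioFn

    def ratio(self, child_shapes: Tuple[Shape, ...]) -> Tuple[Fraction, ...]:
        if len(child_shapes) == 1:
            # suppressed-root chains in induced subtrees: the sole child gets all
            return (Fraction(1),)
        terms = tuple(as_fraction(t) for t in self.ratio_fn(child_shapes))
        if len(terms) != len(child_shapes):
            raise RuleError(f"rule {self.name!r} returned {len(terms)} terms for arity {len(child_shapes)}")
        if sum(terms) != 1:
            raise RuleError(f"rule {self.name!r} ratio does not sum to 1: {terms}")
        if any(t < 0 or t > 1 for t in terms):
            raise RuleError(f"rule {self.name!r} returned a term outside [0,1]: {terms}")
        # neutrality: identical child shapes must receive identical terms
        by_key: Dict[str, Fraction] = {}
        for shape, term in zip(child_shapes, terms):
            if shape.key in by_key and by_key[shape.key] != term:
                raise RuleError(f"rule {self.name!r} violates neutrality on shape {shape.key}")
            by_key[shape.key] = term
        return terms


@dataclass
class CoefficientTable:
    """Coefficients gamma(x, e) of an index on one tree.

    ``gamma[child_vertex_of_edge][leaf_vertex]`` holds the coefficient; absent
    leaves (not descended from the edge) have coefficient zero.
    """

    tree: RootedTree
    rule_name: str
    gamma: Dict[int, Dict[int, Fraction]]

    def value(self, taxon: str, edge: Tuple[int, int]) -> Fraction:
        u, v = edge
        if self.tree.parent.get(v) != u:
            raise TreeError(f"unknown edge {edge}")
        leaf = self.tree.leaf_by_name(taxon)
        return self.gamma[v].get(leaf, Fraction(0))


def coefficients(tree: RootedTree, rule: AllocationRule) -> CoefficientTable:
    """Coefficient table of ``rule`` on ``tree`` in consistent form."""
    shapes = tree.shapes_at_all_vertices()
    # subtree_coeff[v][leaf] = product of ratio terms from v down to leaf
    subtree_coeff: Dict[int, Dict[int, Fraction]] = {}
    ratio_cache: Dict[Tuple[str, ...], Tuple[Fraction, ...]] = {}
    for v in tree.postorder():
        if tree.is_leaf(v):
            subtree_coeff[v] = {v: Fraction(1)}
            continue
        if v == tree.root:
            continue  # the root has no ancestral edge, so its ratio is never used
        kids = tree.children[v]
        child_shapes = tuple(shapes[c] for c in kids)
        cache_key = tuple(s.key for s in child_shapes)
        terms = ratio_cache.get(cache_key)
        if terms is None:
            terms = rule.ratio(child_shapes)
            ratio_cache[cache_key] = terms
        table: Dict[int, Fraction] = {}
        for c, term in zip(kids, terms):
            for leaf, coeff in subtree_coeff[c].items():
                table[leaf] = term * coeff
        subtree_coeff[v] = table
    gamma = {v: subtree_coeff[v] for v in tree.preorder() if v != tree.root}
    return CoefficientTable(tree=tree, rule_name=rule.name, gamma=gamma)


def scores(
    tree: RootedTree,
    rule: AllocationRule,
    table: Optional[CoefficientTable] = None,
) -> Dict[str, Scalar]:
    """Exact diversity index scores per taxon: sum_e gamma(x,e) * l(e)."""
    tree.validate(require_lengths=True)
    if table is None:
        table = coefficients(tree, rule)
    out: Dict[int, Scalar] = {leaf: Fraction(0) for leaf in tree.leaves()}
    for v in tree.preorder():
        if v == tree.root:
            continue
        length = tree.length[v]
        for leaf, coeff in table.gamma[v].items():
            out[leaf] = out[leaf] + length * coeff
    return {tree.label[leaf]: val for leaf, val in out.items()}


# ---------------------------------------------------------------------------
# direct formulas (independent of the ratio framework; used as oracles)


def fp_score_direct(tree: RootedTree, taxon: str) -> Scalar:
    """Fair Proportion: sum over root-path edges of length / cluster size."""
    tree.validate(require_lengths=True)
    leaf = tree.leaf_by_name(taxon)
    total: Scalar = Fraction(0)
    for v in tree.root_path_edges(leaf):
        total = total + tree.length[v] * Fraction(1, len(tree.leaves(v)))
    return total


def es_score_direct(tree: RootedTree, taxon: str) -> Scalar:
    """Equal-Splits: sum over root-path edges of length / product of out-degrees below."""
    tree.validate(require_lengths=True)
    leaf = tree.leaf_by_name(taxon)
    path = tree.root_path_edges(leaf)
    total: Scalar = Fraction(0)
    for i, v in enumerate(path):
        # product of out-degrees of interior vertices on the path from v to the leaf
        prod = 1
        for w in path[i:]:
            if not tree.is_leaf(w):
                prod *= len(tree.children[w])
        total = total + tree.length[v] * Fraction(1, prod)
    return total


# ---------------------------------------------------------------------------
# built-in rules


def _require_binary(shapes: Tuple[Shape, ...], name: str) -> None:
    if len(shapes) != 2:
        raise RuleError(f"rule {name!r} is defined on binary vertices only (got out-degree {len(shapes)})")


def _fp_ratio(shapes: Tuple[Shape, ...]) -> Tuple[Fraction, ...]:
    total = sum(s.n_leaves for s in shapes)
    return tuple(Fraction(s.n_leaves, total) for s in shapes)


def _es_ratio(shapes: Tuple[Shape, ...]) -> Tuple[Fraction, ...]:
    d = len(shapes)
    return tuple(Fraction(1, d) for _ in shapes)


def _two_way(shapes: Tuple[Shape, ...], key, hi: Fraction, name: str) -> Tuple[Fraction, ...]:
    """hi to the child with the larger key value, 1/2:1/2 on ties."""
    _require_binary(shapes, name)
    ka, kb = key(shapes[0]), key(shapes[1])
    if ka == kb:
        return (Fraction(1, 2), Fraction(1, 2))
    if ka > kb:
        return (hi, 1 - hi)
    return (1 - hi, hi)


def _proportional(shapes: Tuple[Shape, ...], key, name: str) -> Tuple[Fraction, ...]:
    values = [key(s) for s in shapes]
    total = sum(values)
    if total == 0:
        d = len(shapes)
        return tuple(Fraction(1, d) for _ in shapes)
    return tuple(Fraction(v, total) for v in values)


def make_alpha_rule(high: Fraction = Fraction(2, 3)) -> AllocationRule:
    return AllocationRule("alpha", lambda s: _two_way(s, lambda t: t.n_leaves, as_fraction(high), "alpha"))


def make_delta_rule(high: Fraction = Fraction(3, 4)) -> AllocationRule:
    return AllocationRule(
        "delta_cherry", lambda s: _two_way(s, lambda t: t.n_cherries, as_fraction(high), "delta_cherry")
    )


def _eta_ratio(shapes: Tuple[Shape, ...]) -> Tuple[Fraction, ...]:
    _require_binary(shapes, "eta_hybrid")
    breadth = sum(s.n_leaves for s in shapes)
    return _es_ratio(shapes) if breadth >= 5 else _fp_ratio(shapes)


def _epsilon_ratio(shapes: Tuple[Shape, ...]) -> Tuple[Fraction, ...]:
    _require_binary(shapes, "epsilon_singleparent")
    return _proportional(shapes, lambda s: s.n_single_leaf_parents, "epsilon_singleparent")


def _zeta_ratio(shapes: Tuple[Shape, ...]) -> Tuple[Fraction, ...]:
    _require_binary(shapes, "zeta_squares")
    return _proportional(shapes, lambda s: s.n_leaves**2, "zeta_squares")


BUILTIN_RULE_NAMES = (
    "fp",
    "es",
    "alpha",
    "beta",
    "gamma_min",
    "delta_cherry",
    "epsilon_singleparent",
    "zeta_squares",
    "eta_hybrid",
)

_ALIASES = {"gamma": "gamma_min", "delta": "delta_cherry", "epsilon": "epsilon_singleparent",
            "zeta": "zeta_squares", "eta": "eta_hybrid"}


def builtin_rule(name: str) -> AllocationRule:
    """One of the built-in indices; alpha..eta are binary-only."""
    name = _ALIASES.get(name, name)
    if name == "fp":
        return AllocationRule("fp", _fp_ratio)
    if name == "es":
        return AllocationRule("es", _es_ratio)
    if name == "alpha":
        return make_alpha_rule()
    if name == "beta":
        return AllocationRule("beta", lambda s: _two_way(s, lambda t: t.n_leaves, Fraction(1), "beta"))
    if name == "gamma_min":
        return AllocationRule("gamma_min", lambda s: _two_way(s, lambda t: t.n_leaves, Fraction(0), "gamma_min"))
    if name == "delta_cherry":
        return make_delta_rule()
    if name == "epsilon_singleparent":
        return AllocationRule("epsilon_singleparent", _epsilon_ratio)
    if name == "zeta_squares":
        return AllocationRule("zeta_squares", _zeta_ratio)
    if name == "eta_hybrid":
        return AllocationRule("eta_hybrid", _eta_ratio)
    raise RuleError(f"unknown rule name {name!r}")


def table_rule(
    assignments: Dict[Tuple[str, ...], Sequence[Fraction]],
    name: str = "table",
    allow_default: bool = False,
) -> AllocationRule:
    """Rule defined per equivalence class.

    Keys are multisets of child shape keys, given as tuples sorted
    lexicographically; values are ratio terms aligned with the sorted key
    order.  Unassigned classes raise unless ``allow_default`` permits the
    uniform ratio.
    """
    frozen = {tuple(k): tuple(as_fraction(t) for t in v) for k, v in assignments.items()}
    for key, terms in frozen.items():
        if tuple(sorted(key)) != key:
            raise RuleError(f"class key must be sorted: {key}")
        if len(terms) != len(key):
            raise RuleError(f"ratio arity mismatch for class {key}")
        if sum(terms) != 1:
            raise RuleError(f"ratio for class {key} does not sum to 1")
        seen: Dict[str, Fraction] = {}
        for k, t in zip(key, terms):
            if k in seen and seen[k] != t:
                raise RuleError(f"assignment for class {key} violates neutrality")
            seen[k] = t

    def ratio_fn(shapes: Tuple[Shape, ...]) -> Tuple[Fraction, ...]:
        order = sorted(range(len(shapes)), key=lambda i: shapes[i].key)
        key = tuple(shapes[i].key for i in order)
        terms = frozen.get(key)
        if terms is None:
            if allow_default:
                d = len(shapes)
                return tuple(Fraction(1, d) for _ in shapes)
            raise RuleError(f"no ratio assigned for class {key}")
        out: List[Fraction] = [Fraction(0)] * len(shapes)
        for pos, term in zip(order, terms):
            out[pos] = term
        return tuple(out)

    return AllocationRule(name, ratio_fn)


# ---------------------------------------------------------------------------
# classification


@dataclass(frozen=True)
class InteriorClassification:
    boundary: bool
    witness: Optional[Tuple[int, int]] = None  # (vertex, zero term index)

    @property
    def kind(self) -> str:
        return "boundary" if self.boundary else "interior"


def classify_interior(rule: AllocationRule, tree: RootedTree) -> InteriorClassification:
    """Boundary iff some ratio term on this tree equals zero."""
    shapes = tree.shapes_at_all_vertices()
    for v in tree.preorder():
        if v == tree.root or tree.is_leaf(v):
            continue
        terms = rule.ratio(tuple(shapes[c] for c in tree.children[v]))
        for i, t in enumerate(terms):
            if t == 0:
                return InteriorClassification(boundary=True, witness=(v, i))
    return InteriorClassification(boundary=False)


@dataclass(frozen=True)
class RigidityResult:
    """Outcome of the rigidity semi-decision.

    A witness (two singular classes of different breadth with the same ratio)
    proves rigidity; its absence up to the probed bound proves nothing.
    """

    witness: Optional[Tuple[int, int, Tuple[Fraction, ...]]]
    max_breadth: int

    @property
    def rigid_witness_found(self) -> bool:
        return self.witness is not None


def _caterpillar_shape(n: int) -> Shape:
    shape = Shape((Shape(), Shape()))
    for _ in range(n - 2):
        shape = Shape((shape, Shape()))
    return shape


def rigidity_probe(rule: AllocationRule, max_breadth: int) -> RigidityResult:
    """Search caterpillar-realisable singular classes up to ``max_breadth``.

    A breadth-``b`` singular class is realised by a vertex whose children are a
    caterpillar shape on ``b - 1`` leaves and a single leaf.
    """
    if max_breadth < 3:
        raise ValueError("max_breadth must be >= 3")
    ratios: Dict[int, Tuple[Fraction, ...]] = {}
    for breadth in range(2, max_breadth + 1):
        big = Shape() if breadth == 2 else _caterpillar_shape(breadth - 1)
        try:
            ratios[breadth] = rule.ratio((big, Shape()))
        except RuleError:
            continue
    breadths = sorted(ratios)
    for i, b1 in enumerate(breadths):
        for b2 in breadths[i + 1 :]:
            if ratios[b1] == ratios[b2]:
                return RigidityResult(witness=(b1, b2, ratios[b1]), max_breadth=max_breadth)
    return RigidityResult(witness=None, max_breadth=max_breadth)
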