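"""Extinction events: necessary deletions, fixed leaves and ranking comparison."""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .exact import Scalar
from .indices import AllocationRule, coefficients
from .tree import ExtinctionEvent, RootedTree, TreeError, natural_key

__all__ = [
    "Ranking",
    "RankingComparison",
    "DeletionConstraint",
    "NecessaryExtinctions",
    "ranking",
    "compare_rankings",
    "necessary_extinctions",
    "fixed_leaves",
    "score_change_functionals",
    "caterpillar_es_robustness",
]


@dataclass(frozen=True)
class Ranking:
    """Taxa ordered by descending score; equal scores grouped as ties."""

    ordered_taxa: Tuple[str, ...]
    ties: Tuple[Tuple[str, ...], ...]
    strict: bool


def ranking(score_vector: Dict[str, Scalar], taxa: Optional[Sequence[str]] = None) -> Ranking:
    names = sorted(score_vector) if taxa is None else sorted(taxa)
    ordered = sorted(names, key=lambda x: (_neg_key(score_vector[x]), x))
    groups: List[List[str]] = []
    for x in ordered:
        if groups and score_vector[groups[-1][-1]] == score_vector[x]:
            groups[-1].append(x)
        else:
            groups.append([x])
    strict = all(len(g) == 1 for g in groups)
    return Ranking(tuple(ordered), tuple(tuple(g) for g in groups), strict)


def _neg_key(value: Scalar):
    from .exact import Eps

    if isinstance(value, Eps):
        return (-value.a, -value.b)
    return (-value, Fraction(0))


@dataclass(frozen=True)
class RankingComparison:
    """Exact pairwise comparison of two score vectors over a survivor set."""

    reversed_strict: bool
    reversed_relaxed: bool
    concordant_pairs: int
    discordant_pairs: int
    tau: Optional[Fraction]
    before_strict: bool
    after_strict: bool


def _sign(a: Scalar, b: Scalar) -> int:
    if a == b:
        return 0
    return 1 if a > b else -1


def compare_rankings(
    before: Dict[str, Scalar], after: Dict[str, Scalar], survivors: Optional[Set[str]] = None
) -> RankingComparison:
    """Compare rankings before/after over ``survivors`` (default: after's domain).

    ``reversed_strict`` follows the strict reversal definition: both rankings
    strict and every pair discordant.  ``reversed_relaxed`` is the ultrametric
    relaxation: every strictly ordered pair flips strictly, and at least one
    such pair exists.
    """
    names = sorted(after if survivors is None else survivors)
    for x in names:
        if x not in before or x not in after:
            raise TreeError(f"taxon {x!r} missing from a score vector")
    concordant = discordant = 0
    relaxed_ok = True
    flipped_pair = False
    for i, x in enumerate(names):
        for y in names[i + 1 :]:
            sb = _sign(before[x], before[y])
            sa = _sign(after[x], after[y])
            if sb * sa > 0:
                concordant += 1
            elif sb * sa < 0:
                discordant += 1
            if sb != 0:
                if sa == -sb:
                    flipped_pair = True
                else:
                    relaxed_ok = False
    n_pairs = len(names) * (len(names) - 1) // 2
    before_strict = len({before[x] for x in names}) == len(names)
    after_strict = len({after[x] for x in names}) == len(names)
    reversed_strict = before_strict and after_strict and discordant == n_pairs
    reversed_relaxed = relaxed_ok and flipped_pair
    tau = Fraction(concordant - discordant, n_pairs) if n_pairs else None
    return RankingComparison(
        reversed_strict=reversed_strict,
        reversed_relaxed=reversed_relaxed,
        concordant_pairs=concordant,
        discordant_pairs=discordant,
        tau=tau,
        before_strict=before_strict,
        after_strict=after_strict,
    )


# ---------------------------------------------------------------------------
# necessary extinctions


@dataclass(frozen=True)
class DeletionConstraint:
    """Delete at least ``required`` of ``group`` (leaves adjacent to ``vertex``)."""

    vertex: int
    group: Tuple[str, ...]
    required: int


@dataclass(frozen=True)
class NecessaryExtinctions:
    constraints: Tuple[DeletionConstraint, ...]
    isolated_constraint: Optional[DeletionConstraint]
    minimum: int
    witness: FrozenSet[str]


def necessary_extinctions(tree: RootedTree, rigid: bool = False) -> NecessaryExtinctions:
    """Lower bounds on any strict-reversal extinction set.

    Every diversity index needs all but one leaf adjacent to each interior
    vertex deleted.  Rigid indices additionally need all but one isolated
    leaf deleted -- all of them if some maximal pendant subtree is a single
    leaf.  The witness keeps the lexicographically smallest leaf of each
    group.
    """
    if tree.n_leaves() < 3:
        raise TreeError("necessary_extinctions requires at least 3 leaves")
    constraints: List[DeletionConstraint] = []
    witness: Set[str] = set()
    for v in tree.preorder():
        if tree.is_leaf(v):
            continue
        group = sorted((tree.label[c] for c in tree.children[v] if tree.is_leaf(c)), key=natural_key)
        if len(group) >= 2:
            constraints.append(DeletionConstraint(v, tuple(group), len(group) - 1))
            witness.update(group[1:])
    minimum = sum(c.required for c in constraints)
    isolated_constraint: Optional[DeletionConstraint] = None
    if rigid:
        iso = sorted(tree.isolated_leaves(), key=natural_key)
        if iso:
            single_leaf_maximal = any(tree.is_leaf(c) for c in tree.children[tree.root])
            required = len(iso) if single_leaf_maximal else len(iso) - 1
            isolated_constraint = DeletionConstraint(tree.root, tuple(iso), required)
            extra = set(iso) if single_leaf_maximal else set(iso[1:])
            # isolated leaves never overlap the interior-adjacent groups above
            witness.update(extra)
            minimum += required
    return NecessaryExtinctions(
        constraints=tuple(constraints),
        isolated_constraint=isolated_constraint,
        minimum=minimum,
        witness=frozenset(witness),
    )


# ---------------------------------------------------------------------------
# fixed leaves


def score_change_functionals(
    tree: RootedTree, rule: AllocationRule, event: ExtinctionEvent
) -> Dict[str, Tuple[Fraction, ...]]:
    """Per-survivor score change as a linear functional of the edge lengths.

    Entry ``j`` of a survivor's vector is the change of its coefficient on the
    ``j``-th original edge (preorder): the coefficient of the merged induced
    edge covering it, minus the original coefficient (zero off the induced
    tree).  The score change of a survivor under any length assignment is the
    dot product of this vector with the lengths, so two survivors with equal
    vectors change by identical amounts for every assignment.
    """
    pruned, edge_map = tree.prune_with_edge_map(event)
    gamma_t = coefficients(tree, rule).gamma
    gamma_p = coefficients(pruned, rule).gamma
    covered: Dict[int, int] = {}  # original edge (child vertex) -> new edge key
    for new_edge, chain in edge_map.items():
        for orig in chain:
            covered[orig] = new_edge
    out: Dict[str, Tuple[Fraction, ...]] = {}
    for name in sorted(event.survivors):
        leaf = tree.leaf_by_name(name)
        vec: List[Fraction] = []
        for v in tree.preorder():
            if v == tree.root:
                continue
            g_orig = gamma_t[v].get(leaf, Fraction(0))
            g_new = gamma_p[covered[v]].get(leaf, Fraction(0)) if v in covered else Fraction(0)
            vec.append(g_new - g_orig)
        out[name] = tuple(vec)
    return out


def fixed_leaves(tree: RootedTree, rule: AllocationRule, event: ExtinctionEvent) -> Set[str]:
    """Leaves whose score is unchanged by ``event`` for every length assignment.

    Symbolic test: a survivor is fixed iff its score-change functional is the
    zero vector (coefficients match edge-by-edge through the merging).
    """
    functionals = score_change_functionals(tree, rule, event)
    return {name for name, vec in functionals.items() if not any(vec)}


# ---------------------------------------------------------------------------
# caterpillar robustness (Equal-Splits)


def caterpillar_es_robustness(n: int, subset: Set[str]) -> bool:
    """Whether ``subset`` could possibly reverse a strict ES ranking on a caterpillar.

    Leaves are named ``x1..xn`` with ``x1, x2`` the cherry and ``xn`` adjacent
    to the root.  Any proper subset of ``{x1..x_{n-2}}`` cannot reverse the
    ranking, so the checker returns ``False`` for those; ``True`` means "not
    ruled out by this criterion".
    """
    if n < 4:
        raise ValueError("caterpillar robustness check requires n >= 4")
    all_taxa = {f"x{i}" for i in range(1, n + 1)}
    unknown = set(subset) - all_taxa
    if unknown:
        raise TreeError(f"unknown taxa: {sorted(unknown)}")
    if set(subset) == all_taxa:
        raise TreeError("extinction set must be a proper subset of the taxa")
    robust_zone = {f"x{i}" for i in range(1, n - 1)}
    if set(subset) < robust_zone:
        return False
    return True
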