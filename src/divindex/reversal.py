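"""Constructions of extinction-induced complete ranking reversals.

Two constructive routes are implemented:

* an explicit big-M / infinitesimal edge assignment for interior indices,
  driven by the score-change values ``Delta`` of the survivors (the "M + k*eps"
  construction); and
* a recursive interleaving construction for non-rigid interior indices that
  nests the score ranges of sibling subtrees into each other's gaps, with a
  collision-removing perturbation step.

Both return a :class:`ReversalCertificate` whose verdict is always recomputed
from scratch by :func:`verify_reversal`.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .exact import Eps, Scalar, as_fraction, realize
from .extinction import RankingComparison, compare_rankings, score_change_functionals
from .indices import AllocationRule, classify_interior, rigidity_probe, scores
from .tree import ExtinctionEvent, RootedTree, TreeError, natural_key

__all__ = [
    "ConstructionError",
    "StructuralTieError",
    "ReversalCertificate",
    "Theorem9Workings",
    "build_F",
    "standard_event",
    "rigid_event",
    "theorem9_construct",
    "theorem5_construct",
    "lemma4_perturb",
    "verify_reversal",
    "safe_epsilon",
    "realize_lengths",
]


class ConstructionError(TreeError):
    """A construction's preconditions fail or the procedure cannot complete."""


class StructuralTieError(ConstructionError):
    """The requested event provably admits no strict reversal on this tree.

    Raised when two survivors have identical score-change functionals: their
    scores then change by the same amount under every length assignment, so
    their relative order can never flip.  Such instances defeat the big-M
    construction's distinctness argument (and the claim it supports): they
    arise when an extinction suppresses a vertex above two survivors whose
    coefficient patterns below the suppression point coincide.
    """

    def __init__(self, pair, message):
        super().__init__(message)
        self.pair = pair


# ---------------------------------------------------------------------------
# events


def standard_event(tree: RootedTree) -> ExtinctionEvent:
    """Delete all but one (lexicographically smallest) leaf adjacent to each interior vertex."""
    extinct: Set[str] = set()
    for v in tree.preorder():
        if tree.is_leaf(v):
            continue
        group = sorted((tree.label[c] for c in tree.children[v] if tree.is_leaf(c)), key=natural_key)
        extinct.update(group[1:])
    return tree.event(extinct)


def rigid_event(tree: RootedTree) -> ExtinctionEvent:
    """Delete all isolated leaves, plus all but one remaining leaf per interior vertex."""
    extinct: Set[str] = set(tree.isolated_leaves())
    for v in tree.preorder():
        if tree.is_leaf(v):
            continue
        group = sorted((tree.label[c] for c in tree.children[v] if tree.is_leaf(c)), key=natural_key)
        remaining = [x for x in group if x not in extinct]
        keep = remaining[0] if remaining else None
        extinct.update(x for x in group if x != keep)
    return tree.event(extinct)


# ---------------------------------------------------------------------------
# verification harness


@dataclass
class ReversalCertificate:
    tree: RootedTree  # with the constructed lengths installed
    event: ExtinctionEvent
    rule_name: str
    before: Dict[str, Scalar]
    after: Dict[str, Scalar]
    comparison: RankingComparison
    valid: bool
    requirement: str  # "strict" or "relaxed"
    top_survives: Optional[bool] = None
    method: Optional[str] = None


def verify_reversal(
    tree: RootedTree,
    rule: AllocationRule,
    event: ExtinctionEvent,
    requirement: str = "strict",
    method: Optional[str] = None,
) -> ReversalCertificate:
    """Recompute scores before/after from scratch and judge the reversal.

    Never trusts construction-side bookkeeping.
    """
    before = scores(tree, rule)
    after = scores(tree.prune_and_suppress(event), rule)
    comparison = compare_rankings(before, after, set(event.survivors))
    if requirement == "strict":
        valid = comparison.reversed_strict
    elif requirement == "relaxed":
        valid = comparison.reversed_relaxed
    else:
        raise ValueError(f"unknown requirement {requirement!r}")
    top = max(before.values())
    top_taxa = {x for x, s in before.items() if s == top}
    return ReversalCertificate(
        tree=tree,
        event=event,
        rule_name=rule.name,
        before=before,
        after=after,
        comparison=comparison,
        valid=valid,
        requirement=requirement,
        top_survives=bool(top_taxa & set(event.survivors)),
        method=method,
    )


# ---------------------------------------------------------------------------
# the big-M / infinitesimal construction


def build_F(tree: RootedTree) -> Tuple[List[Tuple[int, int]], List[Tuple[int, int]], List[Tuple[int, int]]]:
    """Edge sets driving the big-M construction.

    ``F_iso``: edges whose terminal vertex is the parent of an isolated leaf.
    ``F_ch``: edges whose terminal vertex is an m-cherry parent, excluding any
    edge with an ``F_iso`` edge on the root path of its initial vertex.
    ``F = F_iso + F_ch`` ordered by preorder index of the terminal vertex.
    """
    iso_names = tree.isolated_leaves()
    iso_parents = {tree.parent[tree.leaf_by_name(x)] for x in iso_names}
    f_iso = [(tree.parent[v], v) for v in iso_parents if v != tree.root]
    f_iso_children = {v for _, v in f_iso}
    f_ch: List[Tuple[int, int]] = []
    for v, _leaves in tree.m_cherries():
        if v == tree.root:
            continue
        u = tree.parent[v]
        blocked = any(w in f_iso_children for w in tree.root_path_edges(u))
        if not blocked:
            f_ch.append((u, v))
    order = {v: i for i, v in enumerate(tree.preorder())}
    f_all = sorted(f_iso + f_ch, key=lambda e: order[e[1]])
    f_iso.sort(key=lambda e: order[e[1]])
    f_ch.sort(key=lambda e: order[e[1]])
    return f_iso, f_ch, f_all


@dataclass
class Theorem9Workings:
    F_iso: List[Tuple[int, int]]
    F_ch: List[Tuple[int, int]]
    F: List[Tuple[int, int]]
    M: Fraction
    event: ExtinctionEvent
    delta: Dict[str, Eps]  # after - before under l'
    c_map: Dict[str, Eps]
    c: Eps
    pendant_lengths: Dict[str, Eps]
    survivor_order: List[str]  # descending Delta


def theorem9_construct(
    tree: RootedTree,
    rule: AllocationRule,
    M: Optional[Fraction] = None,
    event: Optional[ExtinctionEvent] = None,
) -> Tuple[Theorem9Workings, ReversalCertificate]:
    """Big-M construction for interior indices.

    Assigns ``M + k*eps`` to the ``F`` edges and ``eps`` elsewhere, then sets
    each survivor pendant to ``c - c_i + eps``.  With ``M=None`` the value is
    chosen automatically (doubling until the score-change values are distinct
    and at most one is zero, necessarily at a root-adjacent survivor).
    """
    cls = classify_interior(rule, tree)
    if cls.boundary:
        raise ConstructionError(
            f"rule {rule.name!r} is a boundary index on this tree (witness vertex {cls.witness[0]}); "
            "the big-M construction requires an interior index"
        )
    if event is None:
        event = rigid_event(tree)
    functionals = score_change_functionals(tree, rule, event)
    seen: Dict[tuple, str] = {}
    for name in sorted(functionals, key=natural_key):
        vec = functionals[name]
        if vec in seen:
            raise StructuralTieError(
                (seen[vec], name),
                f"no strict reversal exists for this event under {rule.name!r}: survivors "
                f"{seen[vec]!r} and {name!r} have identical score-change functionals, so their "
                "order cannot flip under any edge length assignment",
            )
        seen[vec] = name
    f_iso, f_ch, f_all = build_F(tree)
    f_index = {v: k for k, (_, v) in enumerate(f_all, start=1)}

    auto = M is None
    m_start = as_fraction(M) if M is not None else Fraction(2 * (len(tree.edges())))
    survivors = sorted(event.survivors, key=natural_key)
    root_adjacent = {tree.label[c] for c in tree.children[tree.root] if tree.is_leaf(c)}
    preorder_pos = {v: j for j, (_, v) in enumerate(tree.edges(), start=1)}
    last_problem = ""

    def assign(m_value: Fraction, power: int) -> Dict[int, Scalar]:
        out: Dict[int, Scalar] = {}
        for _, v in tree.edges():
            if v in f_index:
                out[v] = Eps(m_value, f_index[v])
            elif power:
                out[v] = Eps(0, len(f_index) + preorder_pos[v] ** power)
            else:
                out[v] = Eps(0, 1)
        return out

    # the uniform-eps assignment is tried first; symmetric subtrees below a
    # shared F edge can keep tied Delta values at every M, in which case
    # distinct per-edge eps multipliers (same eps->0 limits) break the ties
    attempts = [(m_start * 2**i, power) for i in range(12) for power in (0, 1, 2, 3)]
    if not auto:
        attempts = [(m_start, 0), (m_start, 1), (m_start, 2), (m_start, 3)]
    for m_value, eps_power in attempts:
        lengths = assign(m_value, eps_power)
        t_prime = tree.with_lengths(lengths)
        before = scores(t_prime, rule)
        after = scores(t_prime.prune_and_suppress(event), rule)
        delta = {x: _as_eps(after[x]) - _as_eps(before[x]) for x in survivors}
        keys = {(d.a, d.b) for d in delta.values()}
        zeros = [x for x in survivors if delta[x] == 0]
        if len(keys) == len(survivors) and len(zeros) <= 1 and all(x in root_adjacent for x in zeros):
            break
        last_problem = f"zeros={zeros}, distinct={len(keys)}/{len(survivors)}"
    else:
        if not auto:
            raise ConstructionError(
                f"M={m_start} is too small: score-change values are not usable ({last_problem})"
            )
        raise ConstructionError(  # pragma: no cover - ladder converges for interior rules
            f"could not choose M automatically ({last_problem})"
        )
    order = sorted(survivors, key=lambda x: (-delta[x].a, -delta[x].b))
    c_map = {x: (_as_eps(before[x]) + _as_eps(after[x])) / 2 for x in survivors}
    c = max(c_map.values())
    pendant: Dict[str, Eps] = {}
    final_lengths = dict(lengths)
    for x in survivors:
        # c - c_i plus the pendant's l' length keeps phi = c -/+ Delta/2 exact
        val = c - c_map[x] + _as_eps(lengths[tree.leaf_by_name(x)])
        if not val.is_positive():  # pragma: no cover - c is the maximum
            raise ConstructionError("non-positive constructed pendant length")
        pendant[x] = val
        final_lengths[tree.leaf_by_name(x)] = val

    final_tree = tree.with_lengths(final_lengths)
    cert = verify_reversal(final_tree, rule, event, requirement="strict", method="thm9")
    # closed-form identities: phi_T = c - Delta/2 and phi_Ttilde = c + Delta/2
    for x in survivors:
        if _as_eps(cert.before[x]) != c - delta[x] / 2 or _as_eps(cert.after[x]) != c + delta[x] / 2:
            raise ConstructionError(f"closed-form identity failed at {x}")
    workings = Theorem9Workings(
        F_iso=f_iso,
        F_ch=f_ch,
        F=f_all,
        M=m_value,
        event=event,
        delta=delta,
        c_map=c_map,
        c=c,
        pendant_lengths=pendant,
        survivor_order=order,
    )
    return workings, cert


def _as_eps(value: Scalar) -> Eps:
    if isinstance(value, Eps):
        return value
    return Eps(as_fraction(value), 0)


# ---------------------------------------------------------------------------
# epsilon realisation


def safe_epsilon(values: Sequence[Scalar]) -> Fraction:
    """A concrete positive rational for eps preserving every lexicographic order relation.

    Any two values with different constant parts keep their numeric order for
    eps below the returned bound; values with equal constant parts are ordered
    by their eps coefficients at any positive eps.
    """
    items = [_as_eps(v) for v in values]
    bound = Fraction(1)
    for i, u in enumerate(items):
        for w in items[i + 1 :]:
            if u.a != w.a:
                spread = abs(u.b - w.b)
                if spread:
                    bound = min(bound, abs(u.a - w.a) / (2 * spread))
    return bound


def realize_lengths(tree: RootedTree, eps_value: Optional[Fraction] = None) -> Tuple[RootedTree, Fraction]:
    """Replace symbolic eps lengths by a concrete rational value.

    When no value is given, one is derived from the tree's own lengths and the
    pairwise sums along root paths so that score comparisons survive the
    substitution.
    """
    if eps_value is None:
        pool: List[Scalar] = [tree.length[v] for _, v in tree.edges()]
        # root-to-leaf path sums discriminate most comparisons in practice
        for leaf in tree.leaves():
            total: Scalar = Fraction(0)
            for v in tree.root_path_edges(leaf):
                total = total + tree.length[v]
            pool.append(total)
        eps_value = safe_epsilon(pool) / 4
    lengths = {v: realize(tree.length[v], eps_value) for _, v in tree.edges()}
    return tree.with_lengths(lengths), eps_value


# ---------------------------------------------------------------------------
# perturbation step (collision removal)


def _survivor_values(
    tree: RootedTree,
    lengths: Dict[int, Scalar],
    rule: AllocationRule,
    event: ExtinctionEvent,
    survivors: Sequence[str],
) -> Tuple[Dict[str, Scalar], Dict[str, Scalar]]:
    t = tree.with_lengths(lengths)
    before = scores(t, rule)
    after = scores(t.prune_and_suppress(event), rule)
    return ({x: before[x] for x in survivors}, {x: after[x] for x in survivors})


def _collisions(
    before: Dict[str, Scalar], after: Dict[str, Scalar], allowed_fixed: Set[str]
) -> List[Tuple[str, str]]:
    out = []
    for x in sorted(before):
        for y in sorted(after):
            if before[x] == after[y] and not (x == y and x in allowed_fixed):
                out.append((x, y))
    return out


def _reversal_shape_ok(before: Dict[str, Scalar], after: Dict[str, Scalar]) -> bool:
    names = sorted(before)
    vals_b = [before[x] for x in names]
    vals_a = [after[x] for x in names]
    if len(set(vals_b)) != len(names) or len(set(vals_a)) != len(names):
        return False
    by_before = sorted(names, key=lambda x: _sort_key(before[x]))
    by_after = sorted(names, key=lambda x: _sort_key(after[x]))
    return by_before == list(reversed(by_after))


def _sort_key(value: Scalar):
    e = _as_eps(value)
    return (e.a, e.b)


def lemma4_perturb(
    tree: RootedTree,
    rule: AllocationRule,
    lengths: Dict[int, Scalar],
    event: ExtinctionEvent,
    survivors: Optional[Sequence[str]] = None,
    allowed_fixed: Optional[Set[str]] = None,
    skip_rigidity_check: bool = False,
    max_rounds: int = 400,
) -> Dict[int, Scalar]:
    """Extend edges until the combined before/after survivor scores are distinct.

    Preserves both the before (ascending) and after (descending) orderings.
    Self-collisions (a survivor scoring the same before and after) extend the
    edge above the survivor's parent; cross-collisions extend the survivor's
    pendant edge.  Extension amounts are half the smaller adjacent score gap,
    halved again whenever an extension would create new collisions.
    ``allowed_fixed`` survivors may keep equal before/after scores (at most
    one, adjacent to the root, per the rigid-index analysis).
    """
    if not skip_rigidity_check and rigidity_probe(rule, 8).rigid_witness_found:
        raise ConstructionError(
            f"rule {rule.name!r} shows a rigidity witness; the perturbation step requires a non-rigid index"
        )
    if survivors is None:
        survivors = sorted(event.survivors)
    allowed = allowed_fixed or set()
    lengths = dict(lengths)
    for _round in range(max_rounds):
        before, after = _survivor_values(tree, lengths, rule, event, survivors)
        pairs = _collisions(before, after, allowed)
        if not pairs:
            return lengths
        x, y = pairs[0]
        amount = _gap_amount(before, after, x)
        if not _apply_perturbation(tree, rule, lengths, event, survivors, allowed, x, y, amount):
            raise ConstructionError(
                f"could not remove score collision ({x!r}, {y!r}) under rule {rule.name!r}"
            )
    raise ConstructionError("perturbation did not converge")  # pragma: no cover


def _gap_amount(before: Dict[str, Scalar], after: Dict[str, Scalar], x: str) -> Scalar:
    order = sorted(before, key=lambda z: _sort_key(before[z]))
    i = order.index(x)
    candidates: List[Scalar] = []
    if i + 1 < len(order):
        gap = before[order[i + 1]] - before[x]
        if _is_positive(gap):
            candidates.append(gap / 2)
    if i - 1 >= 0:
        gap = after[order[i - 1]] - after[x]
        if _is_positive(gap):
            candidates.append(gap / 2)
    if not candidates:
        return Fraction(1)
    return min(candidates, key=_sort_key)


def _is_positive(value: Scalar) -> bool:
    return _sort_key(value) > (0, 0)


def _apply_perturbation(
    tree: RootedTree,
    rule: AllocationRule,
    lengths: Dict[int, Scalar],
    event: ExtinctionEvent,
    survivors: Sequence[str],
    allowed: Set[str],
    x: str,
    y: str,
    amount: Scalar,
) -> bool:
    leaf = tree.leaf_by_name(x)
    if x == y:
        # self-collision: extend the edge above x's parent, walking up if needed
        candidates = list(reversed(tree.root_path_edges(leaf)))[1:]  # parent edge first
    else:
        candidates = [leaf]
    n_before = len(_collisions(*_survivor_values(tree, lengths, rule, event, survivors), allowed))
    for edge_child in candidates:
        trial_amount = amount
        for _ in range(60):
            trial = dict(lengths)
            trial[edge_child] = trial[edge_child] + trial_amount
            before, after = _survivor_values(tree, trial, rule, event, survivors)
            if _orders_preserved(before, after) and len(_collisions(before, after, allowed)) < n_before:
                lengths.clear()
                lengths.update(trial)
                return True
            trial_amount = trial_amount / 2
    return False


def _orders_preserved(before: Dict[str, Scalar], after: Dict[str, Scalar]) -> bool:
    # the before (ascending) and after (descending) orders must mirror each other
    names = sorted(before, key=lambda z: _sort_key(before[z]))
    for a, b in zip(names, names[1:]):
        if not _is_positive(before[b] - before[a]):
            return False
        if not _is_positive(after[a] - after[b]):
            return False
    return True


# ---------------------------------------------------------------------------
# the recursive interleaving construction


def theorem5_construct(
    tree: RootedTree,
    rule: AllocationRule,
    event: Optional[ExtinctionEvent] = None,
) -> ReversalCertificate:
    """Recursive interleaving construction for non-rigid interior indices.

    The extinction event deletes all but one (lexicographically smallest) leaf
    adjacent to each interior vertex.  Child subtrees are solved recursively;
    each further subtree's score range is scaled into the gap between the
    lower and upper halves of the accumulated before/after score set, keeping
    the possibly-single-leaf subtree for last.  The top-scoring leaf of the
    full tree survives.
    """
    if tree.n_leaves() < 2:
        raise ConstructionError("need at least 2 leaves")
    if rigidity_probe(rule, 8).rigid_witness_found:
        raise ConstructionError(f"rule {rule.name!r} shows a rigidity witness; use the big-M construction")
    cls = classify_interior(rule, tree)
    if cls.boundary:
        raise ConstructionError(f"rule {rule.name!r} is a boundary index on this tree")
    if event is None:
        event = standard_event(tree)
    survivor_names = set(event.survivors)
    lengths: Dict[int, Scalar] = {}

    def subtree_of(v: int) -> RootedTree:
        t = RootedTree()
        t.root = v
        t._next_id = tree._next_id
        for w in tree.preorder(v):
            t.children[w] = list(tree.children[w])
            if w in tree.label:
                t.label[w] = tree.label[w]
            if w != v:
                t.parent[w] = tree.parent[w]
                t.length[w] = None
        return t

    def sub_event(sub: RootedTree) -> ExtinctionEvent:
        taxa = set(sub.leaf_labels())
        return ExtinctionEvent(
            extinct=frozenset(taxa - survivor_names), survivors=frozenset(taxa & survivor_names)
        )

    def sub_scores(sub: RootedTree) -> Tuple[Dict[str, Scalar], Dict[str, Scalar]]:
        t = sub.with_lengths({w: lengths[w] for w in sub.length})
        ev = sub_event(sub)
        before = scores(t, rule)
        after = scores(t.prune_and_suppress(ev), rule)
        surv = sorted(ev.survivors)
        return ({z: before[z] for z in surv}, {z: after[z] for z in surv})

    def min_gap(values: Sequence[Scalar]) -> Optional[Scalar]:
        distinct = sorted(set(_sort_key(v) for v in values))
        if len(distinct) < 2:
            return None
        gaps = [Fraction(b[0] - a[0]) for a, b in zip(distinct, distinct[1:]) if b[0] != a[0]]
        # all thm5 arithmetic is rational; eps parts never arise here
        return min(gaps) if gaps else None

    def solve(v: int) -> None:
        if tree.is_leaf(v):
            return
        kids = tree.children[v]
        leaf_kids = sorted((c for c in kids if tree.is_leaf(c)), key=lambda c: natural_key(tree.label[c]))
        nonleaf_kids = [c for c in kids if not tree.is_leaf(c)]
        for c in nonleaf_kids:
            solve(c)
        surviving_leaf_kid = next(
            (c for c in leaf_kids if tree.label[c] in survivor_names), None
        )
        for c in kids:
            lengths[c] = Fraction(1)  # provisional connecting/pendant lengths
        order_pos = {w: i for i, w in enumerate(tree.preorder())}
        units = sorted(
            nonleaf_kids,
            key=lambda c: (-len(set(subtree_labels(c)) & survivor_names), order_pos[c]),
        )
        if surviving_leaf_kid is not None:
            units.append(surviving_leaf_kid)

        sub_v = subtree_of(v)
        ev_v = sub_event(sub_v)
        allowed_fixed = (
            {tree.label[surviving_leaf_kid]} if surviving_leaf_kid is not None else set()
        )
        prev: List[str] = []
        for idx, u in enumerate(units):
            unit_surv = sorted(set(subtree_labels(u)) & survivor_names)
            # connecting-edge length: half the smallest internal score gap, so
            # attaching the unit cannot reorder its internal rankings
            if not tree.is_leaf(u):
                b_u, a_u = sub_scores(subtree_of(u))
                g = min_gap(list(b_u.values()) + list(a_u.values()))
                lengths[u] = g / 2 if g is not None else Fraction(1)
            if idx == 0:
                _ensure_distinct(sub_v, ev_v, unit_surv, allowed_fixed)
            else:
                b_p, a_p = sub_scores(sub_v)
                vals = sorted(_sort_key(s)[0] for z in prev for s in (b_p[z], a_p[z]))
                K = len(prev)
                shift = vals[K - 1]
                delta = vals[K] - vals[K - 1]
                if delta <= 0:  # pragma: no cover - distinctness is enforced upstream
                    raise ConstructionError("empty interleaving gap")
                if idx < len(units) - 1:
                    _ensure_distinct(sub_v, ev_v, unit_surv, allowed_fixed)
                b_u, a_u = sub_scores(sub_v)
                max_b = max(_sort_key(s)[0] for z in unit_surv for s in (b_u[z], a_u[z]))
                factor = delta / (2 * max_b)
                for w in tree.preorder(u):
                    if w in lengths:
                        lengths[w] = lengths[w] * factor
                for w in tree.preorder(u):
                    if tree.is_leaf(w):
                        lengths[w] = lengths[w] + shift
            prev.extend(unit_surv)

        # final tidy-up at this level: all survivor before/after values distinct
        _ensure_distinct(sub_v, ev_v, sorted(set(prev)), allowed_fixed)
        b_all, a_all = sub_scores(sub_v)
        if b_all and not _reversal_shape_ok(b_all, a_all):  # pragma: no cover - safety net
            raise ConstructionError(f"interleaving failed at vertex {v}")
        # deleted leaf children stay strictly below every survivor score
        if b_all:
            floor = min(_sort_key(s)[0] for s in b_all.values())
            j = 2
            for c in leaf_kids:
                if c is not surviving_leaf_kid:
                    lengths[c] = floor / j
                    j += 1

    def subtree_labels(v: int) -> List[str]:
        return [tree.label[w] for w in tree.preorder(v) if tree.is_leaf(w)]

    def _ensure_distinct(
        sub_v: RootedTree, ev_v: ExtinctionEvent, names: List[str], allowed_fixed: Set[str]
    ) -> None:
        if len(names) == 0:
            return
        sub_lengths = {w: lengths[w] for w in sub_v.length}
        new = lemma4_perturb(
            sub_v,
            rule,
            sub_lengths,
            ev_v,
            survivors=names,
            allowed_fixed=allowed_fixed,
            skip_rigidity_check=True,
        )
        lengths.update(new)

    solve(tree.root)
    final = tree.with_lengths(lengths)
    return verify_reversal(final, rule, event, requirement="strict", method="thm5")
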