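"""Rooted phylogenetic trees with exact edge lengths.

Vertices are integer ids.  Edges are directed parent -> child and identified
by their child vertex.  Edge lengths are exact rationals (or ``Eps`` values
carrying an infinitesimal part, used by the reversal constructions).  No
stored vertex other than the root may have out-degree one.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Iterable, List, Optional, Set, Tuple

from .exact import Eps, Scalar, as_fraction

__all__ = [
    "RootedTree",
    "Shape",
    "EquivalenceClassInfo",
    "ExtinctionEvent",
    "NewickError",
    "TreeError",
    "parse_newick",
    "write_newick",
]


class TreeError(ValueError):
    """Structural problem with a rooted tree."""


def natural_key(label: str):
    """Sort key treating digit runs numerically, so x9 precedes x10."""
    import re

    return tuple(int(part) if part.isdigit() else part for part in re.split(r"(\d+)", label))


class NewickError(TreeError):
    """Malformed Newick input."""


# ---------------------------------------------------------------------------
# shapes


class Shape:
    """Canonical rooted unlabelled tree shape.

    ``key`` is a canonical string (children sorted lexicographically by their
    own keys) so two pendant subtrees are isomorphic iff their keys match.
    """

    __slots__ = ("children", "key", "n_leaves", "n_cherries", "n_single_leaf_parents")

    _LEAF_KEY = "*"

    def __init__(self, children: Tuple["Shape", ...] = ()):
        self.children = tuple(sorted(children, key=lambda s: s.key))
        if not self.children:
            self.key = self._LEAF_KEY
            self.n_leaves = 1
            self.n_cherries = 0
            self.n_single_leaf_parents = 0
        else:
            self.key = "(" + ",".join(c.key for c in self.children) + ")"
            self.n_leaves = sum(c.n_leaves for c in self.children)
            leaf_children = sum(1 for c in self.children if c.is_leaf)
            self.n_cherries = sum(c.n_cherries for c in self.children)
            if len(self.children) == 2 and leaf_children == 2:
                self.n_cherries += 1
            self.n_single_leaf_parents = sum(c.n_single_leaf_parents for c in self.children)
            if leaf_children == 1:
                self.n_single_leaf_parents += 1

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Shape) and self.key == other.key

    def __hash__(self) -> int:
        return hash(self.key)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Shape({self.key!r})"


LEAF_SHAPE = Shape()


@dataclass(frozen=True)
class EquivalenceClassInfo:
    """A ``~``-equivalence class of non-root interior vertices."""

    representative: int
    member_vertices: Tuple[int, ...]
    child_shape_multiset: Tuple[str, ...]  # sorted shape keys
    breadth: int
    singular: bool


@dataclass(frozen=True)
class ExtinctionEvent:
    """A split of the taxon set into extinct species and survivors."""

    extinct: frozenset
    survivors: frozenset

    @staticmethod
    def from_extinct(taxa: Iterable[str], extinct: Iterable[str]) -> "ExtinctionEvent":
        all_taxa = frozenset(taxa)
        gone = frozenset(extinct)
        unknown = gone - all_taxa
        if unknown:
            raise TreeError(f"unknown taxa in extinction set: {sorted(unknown)}")
        survivors = all_taxa - gone
        if not survivors:
            raise TreeError("extinction event leaves no survivors")
        return ExtinctionEvent(extinct=gone, survivors=survivors)


# ---------------------------------------------------------------------------
# the tree itself


class RootedTree:
    """Rooted phylogenetic tree with ordered children and exact edge lengths."""

    def __init__(self):
        self.root: int = 0
        self.children: Dict[int, List[int]] = {}
        self.parent: Dict[int, int] = {}
        self.length: Dict[int, Optional[Scalar]] = {}  # keyed by child vertex
        self.label: Dict[int, str] = {}  # leaf labels, plus optional interior names
        self._next_id: int = 0

    # -- construction -------------------------------------------------------
    def new_vertex(self, label: Optional[str] = None) -> int:
        v = self._next_id
        self._next_id += 1
        self.children[v] = []
        if label is not None:
            self.label[v] = label
        return v

    def add_edge(self, u: int, v: int, length: Optional[Scalar]) -> None:
        self.children[u].append(v)
        self.parent[v] = u
        self.length[v] = length

    # -- basic queries -------------------------------------------------------
    def is_leaf(self, v: int) -> bool:
        return not self.children[v]

    def vertices(self) -> List[int]:
        return self.preorder()

    def leaves(self, v: Optional[int] = None) -> List[int]:
        start = self.root if v is None else v
        return [w for w in self.preorder(start) if self.is_leaf(w)]

    def leaf_labels(self) -> List[str]:
        return sorted(self.label[v] for v in self.leaves())

    def n_leaves(self) -> int:
        return len(self.leaves())

    def preorder(self, start: Optional[int] = None) -> List[int]:
        out: List[int] = []
        stack = [self.root if start is None else start]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(reversed(self.children[v]))
        return out

    def postorder(self, start: Optional[int] = None) -> List[int]:
        return list(reversed(self._reverse_postorder(start)))

    def _reverse_postorder(self, start: Optional[int]) -> List[int]:
        out: List[int] = []
        stack = [self.root if start is None else start]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self.children[v])
        return out

    def edges(self) -> List[Tuple[int, int]]:
        """All edges as (parent, child), in preorder of the child."""
        return [(self.parent[v], v) for v in self.preorder() if v != self.root]

    def vertex_by_label(self, name: str) -> int:
        for v, lab in self.label.items():
            if lab == name:
                return v
        raise TreeError(f"no vertex labelled {name!r}")

    def leaf_by_name(self, name: str) -> int:
        v = self.vertex_by_label(name)
        if not self.is_leaf(v):
            raise TreeError(f"{name!r} is not a leaf")
        return v

    def edge_by_labels(self, parent_name: str, child_name: str) -> Tuple[int, int]:
        u = self.vertex_by_label(parent_name)
        v = self.vertex_by_label(child_name)
        if self.parent.get(v) != u:
            raise TreeError(f"({parent_name},{child_name}) is not an edge")
        return (u, v)

    def root_path_edges(self, v: int) -> List[int]:
        """Edges (child-vertex keyed) on the path root -> v, top-down."""
        out = []
        while v != self.root:
            out.append(v)
            v = self.parent[v]
        return list(reversed(out))

    def total_length(self) -> Scalar:
        total: Scalar = Fraction(0)
        for v in self.length:
            ln = self.length[v]
            if ln is None:
                raise TreeError("tree has missing edge lengths")
            total = total + ln
        return total

    def has_lengths(self) -> bool:
        return all(ln is not None for ln in self.length.values())

    # -- invariants ----------------------------------------------------------
    def validate(self, require_lengths: bool = False) -> None:
        if self.root in self.parent:
            raise TreeError("root must have in-degree 0")
        seen_labels: Set[str] = set()
        for v in self.preorder():
            if v != self.root:
                if v not in self.parent:
                    raise TreeError(f"vertex {v} has no parent")
                ln = self.length.get(v)
                if ln is not None:
                    pos = ln.is_positive() if isinstance(ln, Eps) else ln > 0
                    if not pos:
                        raise TreeError(f"non-positive edge length on edge into vertex {v}")
                elif require_lengths:
                    raise TreeError(f"missing edge length on edge into vertex {v}")
                if not self.is_leaf(v) and len(self.children[v]) < 2:
                    raise TreeError(f"interior vertex {v} has out-degree 1")
            if self.is_leaf(v):
                lab = self.label.get(v)
                if not lab:
                    raise TreeError(f"leaf {v} has no label")
                if lab in seen_labels:
                    raise TreeError(f"duplicate leaf label {lab!r}")
                seen_labels.add(lab)

    # -- copies --------------------------------------------------------------
    def copy(self) -> "RootedTree":
        t = RootedTree()
        t.root = self.root
        t.children = {v: list(cs) for v, cs in self.children.items()}
        t.parent = dict(self.parent)
        t.length = dict(self.length)
        t.label = dict(self.label)
        t._next_id = self._next_id
        return t

    def with_lengths(self, lengths: Dict[int, Scalar]) -> "RootedTree":
        """Copy of the tree with the per-edge lengths replaced.

        ``lengths`` is keyed by child vertex and must cover every edge.
        """
        t = self.copy()
        for v in t.length:
            if v not in lengths:
                raise TreeError(f"no length supplied for edge into vertex {v}")
            t.length[v] = lengths[v]
        return t

    # -- structural operations -----------------------------------------------
    def cluster(self, edge: Tuple[int, int]) -> Set[str]:
        """The set of taxa descended from the terminal vertex of ``edge``."""
        u, v = edge
        if self.parent.get(v) != u:
            raise TreeError(f"unknown edge {edge}")
        return {self.label[w] for w in self.leaves(v)}

    def cluster_of_vertex(self, v: int) -> Set[str]:
        return {self.label[w] for w in self.leaves(v)}

    def shape(self, v: Optional[int] = None) -> Shape:
        """Canonical shape of the pendant subtree rooted at ``v`` (default: whole tree)."""
        start = self.root if v is None else v
        shapes: Dict[int, Shape] = {}
        for w in self.postorder(start):
            if self.is_leaf(w):
                shapes[w] = LEAF_SHAPE
            else:
                shapes[w] = Shape(tuple(shapes[c] for c in self.children[w]))
        return shapes[start]

    def shapes_at_all_vertices(self) -> Dict[int, Shape]:
        shapes: Dict[int, Shape] = {}
        for w in self.postorder():
            if self.is_leaf(w):
                shapes[w] = LEAF_SHAPE
            else:
                shapes[w] = Shape(tuple(shapes[c] for c in self.children[w]))
        return shapes

    def m_cherries(self) -> List[Tuple[int, Set[str]]]:
        """All maximal sets of >= 2 leaves whose common parent has only leaf children."""
        out = []
        for v in self.preorder():
            cs = self.children[v]
            if len(cs) >= 2 and all(self.is_leaf(c) for c in cs):
                out.append((v, {self.label[c] for c in cs}))
        return out

    def isolated_leaves(self) -> Set[str]:
        """Leaves outside every m-cherry whose root path passes no other leaf parent.

        A leaf ``x`` with parent ``v != root`` is isolated when ``x`` belongs to
        no m-cherry and no vertex strictly between the root and ``v`` is the
        parent of a leaf.
        """
        in_cherry: Set[int] = set()
        for v, _ in self.m_cherries():
            in_cherry.update(self.children[v])
        out: Set[str] = set()
        for x in self.leaves():
            v = self.parent.get(x)
            if v is None or v == self.root or x in in_cherry:
                continue
            ok = True
            u = self.parent.get(v)
            while u is not None and u != self.root:
                if any(self.is_leaf(c) for c in self.children[u]):
                    ok = False
                    break
                u = self.parent.get(u)
            if ok:
                out.add(self.label[x])
        return out

    def is_ultrametric(self) -> bool:
        """Exact test: every root-to-leaf distance equal."""
        self.validate(require_lengths=True)
        depth: Dict[int, Scalar] = {self.root: Fraction(0)}
        target: Optional[Scalar] = None
        for v in self.preorder():
            if v != self.root:
                depth[v] = depth[self.parent[v]] + self.length[v]
            if self.is_leaf(v):
                if target is None:
                    target = depth[v]
                elif depth[v] != target:
                    return False
        return True

    def equivalence_classes(self) -> List[EquivalenceClassInfo]:
        """Partition of non-root interior vertices by child-shape multisets."""
        shapes = self.shapes_at_all_vertices()
        groups: Dict[Tuple[str, ...], List[int]] = {}
        for v in self.preorder():
            if v == self.root or self.is_leaf(v):
                continue
            key = tuple(sorted(shapes[c].key for c in self.children[v]))
            groups.setdefault(key, []).append(v)
        out = []
        for key, members in sorted(groups.items()):
            rep = members[0]
            out.append(
                EquivalenceClassInfo(
                    representative=rep,
                    member_vertices=tuple(members),
                    child_shape_multiset=key,
                    breadth=len(self.leaves(rep)),
                    singular=Shape._LEAF_KEY in key,
                )
            )
        return out

    # -- extinction ----------------------------------------------------------
    def event(self, extinct: Iterable[str]) -> ExtinctionEvent:
        return ExtinctionEvent.from_extinct(self.leaf_labels(), extinct)

    def prune_and_suppress(self, event: ExtinctionEvent) -> "RootedTree":
        return self.prune_with_edge_map(event)[0]

    def prune_with_edge_map(
        self, event: ExtinctionEvent
    ) -> Tuple["RootedTree", Dict[int, Tuple[int, ...]]]:
        """Induced subtree spanning the survivors and the root.

        Out-degree-one vertices (other than the root, which is always kept)
        are suppressed; the lengths of merged edges are summed.  Vertex ids of
        retained vertices are reused.  The second return value maps each new
        edge (keyed by child vertex) to the tuple of original edges, top-down,
        that were merged into it.
        """
        survivors = {self.leaf_by_name(name) for name in event.survivors}
        keep: Set[int] = set(survivors)
        for x in survivors:
            v = x
            while v != self.root:
                v = self.parent[v]
                keep.add(v)
        keep.add(self.root)

        t = RootedTree()
        t.root = self.root
        t._next_id = self._next_id
        t.children = {}
        edge_map: Dict[int, Tuple[int, ...]] = {}

        def build(v: int) -> None:
            t.children.setdefault(v, [])
            if v in self.label:
                t.label[v] = self.label[v]
            for c in self.children[v]:
                if c not in keep:
                    continue
                # walk down through suppressed out-degree-1 vertices
                chain = [c]
                w = c
                while True:
                    kept_children = [k for k in self.children[w] if k in keep]
                    if len(kept_children) == 1 and not self.is_leaf(w):
                        w = kept_children[0]
                        chain.append(w)
                    else:
                        break
                length: Optional[Scalar] = None
                if all(self.length.get(z) is not None for z in chain):
                    length = self.length[chain[0]]
                    for z in chain[1:]:
                        length = length + self.length[z]
                t.children.setdefault(w, [])
                t.add_edge(v, w, length)
                edge_map[w] = tuple(chain)
                build(w)

        build(self.root)
        return t, edge_map


# ---------------------------------------------------------------------------
# Newick I/O


def _parse_length(token: str) -> Scalar:
    token = token.strip()
    try:
        if "/" in token:
            num, den = token.split("/")
            value = Fraction(int(num), int(den))
        else:
            value = Fraction(token)
    except (ValueError, ZeroDivisionError) as exc:
        raise NewickError(f"invalid branch length {token!r}") from exc
    return value


def parse_newick(text: str, require_lengths: bool = False) -> RootedTree:
    """Parse a rooted Newick string into a :class:`RootedTree`.

    Lengths may be decimal (parsed exactly) or rational ``p/q``.  Interior
    labels are kept as annotations.  A root of out-degree one is rejected.
    """
    s = text.strip()
    if not s.endswith(";"):
        raise NewickError("Newick string must end with ';'")
    s = s[:-1].strip()
    tree = RootedTree()
    pos = 0

    def error(msg: str) -> NewickError:
        return NewickError(f"{msg} (at position {pos})")

    def parse_name() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        return s[start:pos].strip()

    def parse_clade() -> Tuple[int, Optional[Scalar]]:
        nonlocal pos
        if pos < len(s) and s[pos] == "(":
            pos += 1
            v = tree.new_vertex()
            while True:
                child, length = parse_clade()
                tree.add_edge(v, child, length)
                if pos >= len(s):
                    raise error("unbalanced parentheses")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise error(f"unexpected character {s[pos]!r}")
            name = parse_name()
            if name:
                tree.label[v] = name
        else:
            name = parse_name()
            if not name:
                raise error("empty leaf label")
            v = tree.new_vertex(name)
        length: Optional[Scalar] = None
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in "(),:;":
                pos += 1
            length = _parse_length(s[start:pos])
        return v, length

    root, root_length = parse_clade()
    if pos != len(s):
        raise NewickError(f"trailing characters after tree (at position {pos})")
    if root_length is not None:
        raise NewickError("length on the root is not supported")
    tree.root = root
    if not tree.is_leaf(root) and len(tree.children[root]) == 1:
        raise NewickError("root of out-degree 1 is not accepted; normalise the input")
    try:
        tree.validate(require_lengths=require_lengths)
    except NewickError:
        raise
    except TreeError as exc:
        raise NewickError(str(exc)) from exc
    return tree


def _format_length(value: Scalar) -> str:
    if isinstance(value, Eps):
        raise TreeError("cannot write infinitesimal lengths to Newick; realise eps first")
    q = as_fraction(value)
    if q.denominator == 1:
        return str(q.numerator)
    # exact decimal if the denominator is 2^a * 5^b, else p/q
    den = q.denominator
    for p in (2, 5):
        while den % p == 0:
            den //= p
    if den == 1:
        from decimal import Decimal

        return str(Decimal(q.numerator) / Decimal(q.denominator))
    return f"{q.numerator}/{q.denominator}"


def write_newick(tree: RootedTree, include_interior_labels: bool = True) -> str:
    def emit(v: int) -> str:
        if tree.is_leaf(v):
            core = tree.label[v]
        else:
            core = "(" + ",".join(emit(c) for c in tree.children[v]) + ")"
            if include_interior_labels and v in tree.label:
                core += tree.label[v]
        if v != tree.root:
            ln = tree.length.get(v)
            if ln is not None:
                core += ":" + _format_length(ln)
        return core

    return emit(tree.root) + ";"
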