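"""Phylogenetic tree container, Newick I/O, rerooting, random topologies
and monophyly queries.

The tree is the substrate of every analysis in this package: parsimony
reconstruction annotates its nodes, the signal test randomises it, and the
likelihood evaluator prunes along it.  Nodes carry parent/child links, an
optional tip label and an optional branch length in expected
substitutions per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Node",
    "PhyloTree",
    "NewickError",
    "MonophylyStatus",
    "Monophyly",
    "parse_newick",
    "write_newick",
    "reroot",
    "random_topology",
    "shuffle_tips",
    "monophyly_status",
    "prune_to",
]


class NewickError(ValueError):
    """Malformed Newick input; ``offset`` is the 0-based character position."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


class Node:
    """A tree node.  Tips have a non-empty ``label``; ``length`` is the
    length of the branch to the parent (``None`` if absent)."""

    __slots__ = ("label", "length", "parent", "children", "id")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.id: int = -1

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"internal({len(self.children)})"
        return f"<Node id={self.id} {kind} label={self.label!r}>"


class PhyloTree:
    """Rooted phylogenetic tree.

    Node ids are assigned in postorder on construction and are stable until
    the topology is modified.  A tree parsed from an unrooted (basal
    trifurcation) Newick string keeps ``unrooted_origin=True`` so callers
    can report root-dependent results appropriately.
    """

    def __init__(self, root: Node, unrooted_origin: bool = False):
        self.root = root
        self.unrooted_origin = unrooted_origin
        self._index()

    # -- structure ---------------------------------------------------------

    def _index(self) -> None:
        labels: set[str] = set()
        for i, node in enumerate(self.postorder()):
            node.id = i
            if node.is_tip:
                if not node.label:
                    raise ValueError("tip with empty label")
                if node.label in labels:
                    raise ValueError(f"duplicate tip label: {node.label!r}")
                labels.add(node.label)
            if node.length is not None and node.length < 0:
                raise ValueError(f"negative branch length {node.length}")
        self._tip_labels = labels

    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_tip]

    @property
    def tip_labels(self) -> set[str]:
        return set(self._tip_labels)

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    def node(self, key: int | str) -> Node:
        """Look up a node by id or by tip label."""
        for n in self.postorder():
            if n.id == key or (n.label is not None and n.label == key):
                return n
        raise KeyError(f"no node {key!r} in tree")

    def is_binary(self) -> bool:
        return all(
            len(n.children) == 2 for n in self.postorder() if not n.is_tip
        )

    def has_polytomy(self) -> bool:
        return any(len(n.children) > 2 for n in self.postorder())

    def copy(self) -> "PhyloTree":
        def rec(node: Node) -> Node:
            clone = Node(node.label, node.length)
            for child in node.children:
                clone.add_child(rec(child))
            return clone

        return PhyloTree(rec(self.root), self.unrooted_origin)

    # -- distances ---------------------------------------------------------

    def tip_distance_matrix(self) -> tuple[list[str], np.ndarray]:
        """All pairwise tip path lengths (branch lengths required)."""
        tips = self.tips()
        labels = sorted(t.label for t in tips)
        pos = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        dist = np.zeros((n, n))
        # leaf-to-leaf distances via per-node maps of descendant tip depths
        below: dict[Node, dict[int, float]] = {}
        for node in self.postorder():
            if node.is_tip:
                below[node] = {pos[node.label]: 0.0}
            else:
                merged: dict[int, float] = {}
                kids = [
                    {
                        t: d + (c.length or 0.0)
                        for t, d in below.pop(c).items()
                    }
                    for c in node.children
                ]
                for i in range(len(kids)):
                    for j in range(i + 1, len(kids)):
                        for a, da in kids[i].items():
                            for b, db in kids[j].items():
                                dist[a, b] = dist[b, a] = da + db
                    merged.update(kids[i])
                below[node] = merged
        return labels, dist

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree {self.n_tips} tips>"


# ---------------------------------------------------------------------------
# Newick parsing / writing
# ---------------------------------------------------------------------------

_UNQUOTED_FORBIDDEN = set("()[]{}/\\,;:=*'\"`<>& \t\n")


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Standard dialect: unquoted labels, single-quoted labels with ``''``
    escaping, branch lengths after ``:``, square-bracket comments skipped.
    An unrooted input (three or more children at the outermost level) is
    stored as-is with ``unrooted_origin=True``.

    Raises :class:`NewickError` with the character offset on syntax errors
    and ``ValueError`` on duplicate tip labels.
    """
    s = text
    pos = 0

    def skip_ws() -> None:
        nonlocal pos
        while pos < len(s):
            if s[pos].isspace():
                pos += 1
            elif s[pos] == "[":  # comment
                end = s.find("]", pos)
                if end < 0:
                    raise NewickError("unterminated comment", pos)
                pos = end + 1
            else:
                break

    def parse_label() -> str | None:
        nonlocal pos
        skip_ws()
        if pos < len(s) and s[pos] == "'":
            start = pos
            pos += 1
            out = []
            while True:
                if pos >= len(s):
                    raise NewickError("unterminated quoted label", start)
                ch = s[pos]
                if ch == "'":
                    if pos + 1 < len(s) and s[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                    else:
                        pos += 1
                        break
                else:
                    out.append(ch)
                    pos += 1
            return "".join(out)
        out = []
        while pos < len(s) and s[pos] not in _UNQUOTED_FORBIDDEN:
            out.append(s[pos])
            pos += 1
        if not out:
            return None
        # Newick convention: underscores in unquoted labels are spaces
        return "".join(out).replace("_", " ")

    def parse_length() -> float | None:
        nonlocal pos
        skip_ws()
        if pos < len(s) and s[pos] == ":":
            pos += 1
            skip_ws()
            start = pos
            while pos < len(s) and (s[pos] in "+-.eE" or s[pos].isdigit()):
                pos += 1
            try:
                return float(s[start:pos])
            except ValueError:
                raise NewickError("invalid branch length", start) from None
        return None

    def parse_clade() -> Node:
        nonlocal pos
        skip_ws()
        node = Node()
        if pos < len(s) and s[pos] == "(":
            open_pos = pos
            pos += 1
            while True:
                node.add_child(parse_clade())
                skip_ws()
                if pos >= len(s):
                    raise NewickError("unbalanced parenthesis", open_pos)
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise NewickError(f"unexpected character {s[pos]!r}", pos)
            node.label = parse_label()  # internal node label, kept verbatim
        else:
            label = parse_label()
            if label is None:
                raise NewickError("expected a label", pos)
            node.label = label
        node.length = parse_length()
        return node

    root = parse_clade()
    skip_ws()
    if pos >= len(s) or s[pos] != ";":
        raise NewickError("expected ';'", pos)
    pos += 1
    skip_ws()
    if pos != len(s):
        raise NewickError("trailing characters after ';'", pos)
    unrooted = len(root.children) > 2
    return PhyloTree(root, unrooted_origin=unrooted)


def _format_label(label: str) -> str:
    if label and not (set(label) & _UNQUOTED_FORBIDDEN):
        return label
    if " " in label and not (set(label) & (_UNQUOTED_FORBIDDEN - {" "})):
        return label.replace(" ", "_")
    return "'" + label.replace("'", "''") + "'"


def write_newick(tree: PhyloTree) -> str:
    """Serialise a tree to Newick.  Branch lengths keep 10 significant
    digits so a parse/write round trip preserves them to better than 1e-9."""

    def rec(node: Node) -> str:
        if node.is_tip:
            out = _format_label(node.label)
        else:
            out = "(" + ",".join(rec(c) for c in node.children) + ")"
            if node.label:
                out += _format_label(node.label)
        if node.length is not None:
            out += f":{node.length:.10g}"
        return out

    return rec(tree.root) + ";"


# ---------------------------------------------------------------------------
# Rerooting
# ---------------------------------------------------------------------------


def reroot(tree: PhyloTree, edge: int | str) -> PhyloTree:
    """Reroot on the branch above node ``edge`` (node id or tip label).

    The new root subdivides the chosen branch at its midpoint, so every
    tip-to-tip path length is preserved.  The unrooted topology (split set)
    is unchanged; an old root left with a single child is spliced out.
    """
    t = tree.copy()
    target = t.node(tree.node(edge).id)  # resolve on original ids, map by id
    if target.parent is None:
        return t  # already the root: nothing above to subdivide

    # walk up collecting the path root-ward, then reverse parent links
    new_root = Node()
    edge_len = target.length
    half = None if edge_len is None else edge_len / 2.0

    old_parent = target.parent
    old_parent.children.remove(target)
    new_root.add_child(target)
    target.length = half

    # re-hang the chain: old_parent becomes the second child of new_root
    prev = new_root
    prev_len = half
    node: Node | None = old_parent
    while node is not None:
        up = node.parent
        up_len = node.length
        if up is not None:
            up.children.remove(node)
        node.parent = None
        prev.add_child(node)
        node.length = prev_len
        prev, prev_len = node, up_len
        node = up

    # splice out the old root if it is now degree-2 (had 2 children)
    def splice(n: Node) -> None:
        if not n.is_tip and len(n.children) == 1 and n.parent is not None:
            child = n.children[0]
            if child.length is not None or n.length is not None:
                child.length = (child.length or 0.0) + (n.length or 0.0)
            parent = n.parent
            idx = parent.children.index(n)
            parent.children[idx] = child
            child.parent = parent

    for n in list(new_root.children):
        _splice_unary_chain(n, splice)
    return PhyloTree(new_root, tree.unrooted_origin)


def _splice_unary_chain(start: Node, splice) -> None:
    stack = [start]
    while stack:
        n = stack.pop()
        stack.extend(n.children)
        splice(n)


# ---------------------------------------------------------------------------
# Random topologies and label shuffles
# ---------------------------------------------------------------------------


def random_topology(
    labels: Sequence[str] | set[str],
    seed: int | np.random.Generator,
) -> PhyloTree:
    """Draw a rooted binary topology uniformly over all labelled rooted
    binary topologies on ``labels`` (no branch lengths).

    Sequential random addition: tips are inserted in random order, each on
    a branch chosen uniformly among all current branches including the
    branch above the root.  Every n-tip topology arises from exactly one
    (n-1)-tip topology by one insertion, so the draw is uniform over the
    (2n-3)!! rooted labelled topologies.
    """
    labs = sorted(labels)
    if len(labs) < 2:
        raise ValueError("need at least 2 tip labels")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    order = rng.permutation(len(labs))

    root = Node()
    root.add_child(Node(labs[order[0]]))
    root.add_child(Node(labs[order[1]]))
    # edges: nodes whose branch to the parent can be split; None = root edge
    edges: list[Node | None] = [root.children[0], root.children[1], None]
    for idx in order[2:]:
        tip = Node(labs[idx])
        e = edges[int(rng.integers(len(edges)))]
        new = Node()
        if e is None:
            new.add_child(root)
            new.add_child(tip)
            edges.append(root)
            root = new
        else:
            parent = e.parent
            parent.children[parent.children.index(e)] = new
            new.parent = parent
            new.add_child(e)
            new.add_child(tip)
            edges.append(new)
        edges.append(tip)
    return PhyloTree(root)


def shuffle_tips(
    tree: PhyloTree, seed: int | np.random.Generator
) -> PhyloTree:
    """Permute tip labels uniformly at random; topology and branch lengths
    are untouched."""
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    t = tree.copy()
    tips = t.tips()
    labels = [n.label for n in tips]
    perm = rng.permutation(len(labels))
    for node, k in zip(tips, perm):
        node.label = labels[k]
    t._index()
    return t


# ---------------------------------------------------------------------------
# Monophyly
# ---------------------------------------------------------------------------


class Monophyly(str, Enum):
    MONOPHYLETIC = "monophyletic"
    PARAPHYLETIC = "paraphyletic"
    POLYPHYLETIC = "polyphyletic"
    NOT_ASSESSABLE = "not_assessable"


@dataclass
class MonophylyStatus:
    """Outcome of a monophyly query for a named group on a rooted tree."""

    status: Monophyly
    clade_tips: frozenset[str] = field(default_factory=frozenset)
    n_intruders: int = 0
    dropped: frozenset[str] = field(default_factory=frozenset)

    def __str__(self) -> str:
        return self.status.value


def _mrca(tree: PhyloTree, group: set[str]) -> Node:
    """Smallest node whose subtree contains every tip in ``group``."""
    remaining: dict[int, int] = {}
    best: Node | None = None
    for node in tree.postorder():
        if node.is_tip:
            count = 1 if node.label in group else 0
        else:
            count = sum(remaining.pop(c.id) for c in node.children)
        remaining[node.id] = count
        if count == len(group):
            best = node
            break
    assert best is not None
    return best


def _clade_tipset(node: Node) -> frozenset[str]:
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_tip:
            out.append(n.label)
        else:
            stack.extend(n.children)
    return frozenset(out)


def monophyly_status(tree: PhyloTree, group: set[str]) -> MonophylyStatus:
    """Classify ``group`` as monophyletic / paraphyletic / polyphyletic on
    the rooted tree.

    Members absent from the tree are dropped (reported in ``dropped``); a
    group with fewer than 2 tips present is ``not_assessable``.  The group
    is monophyletic when the smallest clade spanning it contains no other
    tips; paraphyletic when the non-group tips inside that clade form a
    single clade themselves; polyphyletic otherwise.
    """
    if not group:
        raise ValueError("empty group")
    present = set(group) & tree.tip_labels
    dropped = frozenset(set(group) - present)
    if len(present) < 2:
        return MonophylyStatus(Monophyly.NOT_ASSESSABLE, dropped=dropped)
    span = _mrca(tree, present)
    clade = _clade_tipset(span)
    intruders = clade - present
    if not intruders:
        return MonophylyStatus(Monophyly.MONOPHYLETIC, clade, 0, dropped)
    intruder_span = _clade_tipset(_mrca(tree, set(intruders)))
    status = (
        Monophyly.PARAPHYLETIC
        if intruder_span == intruders
        else Monophyly.POLYPHYLETIC
    )
    return MonophylyStatus(status, clade, len(intruders), dropped)


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------


def prune_to(tree: PhyloTree, keep: set[str]) -> PhyloTree:
    """Restrict the tree to the tips in ``keep``.

    Unary internal nodes left by the pruning are spliced out with branch
    lengths summed, so tip-to-tip path lengths among kept tips are
    preserved.
    """
    keep = set(keep) & tree.tip_labels
    if len(keep) < 2:
        raise ValueError("pruned tree would have fewer than 2 tips")

    def rec(node: Node) -> Node | None:
        if node.is_tip:
            if node.label in keep:
                return Node(node.label, node.length)
            return None
        kept = [rec(c) for c in node.children]
        kept = [c for c in kept if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            if child.length is not None or node.length is not None:
                child.length = (child.length or 0.0) + (node.length or 0.0)
            elif node.length is not None:
                child.length = node.length
            return child
        clone = Node(node.label, node.length)
        for c in kept:
            clone.add_child(c)
        return clone

    root = rec(tree.root)
    assert root is not None
    if root.length is not None and tree.root.length is None:
        root.length = None  # root had no branch; drop accumulated length
    return PhyloTree(root, tree.unrooted_origin)


def robinson_foulds_splits(tree: PhyloTree) -> set[frozenset[str]]:
    """Non-trivial splits of the unrooted topology, each as the tip set on
    one side (the side not containing the alphabetically first tip)."""
    all_tips = frozenset(tree.tip_labels)
    anchor = min(all_tips)
    splits: set[frozenset[str]] = set()
    sets: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_tip:
            sets[node.id] = frozenset([node.label])
        else:
            s = frozenset().union(*(sets.pop(c.id) for c in node.children))
            sets[node.id] = s
            if 1 < len(s) < len(all_tips) - 1:
                splits.add(all_tips - s if anchor in s else s)
    return splits
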