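"""Parsimony length, most-parsimonious-reconstruction (MPR) state sets and
equivocal-branch detection for one discrete character on one tree.

Two engines share the work.  The Sankoff dynamic programme is the single
correctness path: it handles arbitrary step matrices (unordered unit-cost
"unweighted" parsimony, ordered ``|i-j|`` costs, or user matrices) and
polytomies, and a second top-down pass yields exact MPR sets — the set of
states a node takes in at least one globally minimal reconstruction.  A
bitmask Fitch pass is kept as an independent fast path for unit costs on
binary trees; the two are cross-checked against each other and against
exhaustive enumeration in the test suite.

The statsmodels-style surface is :class:`AncestralParsimony` (model) whose
``fit()`` returns :class:`ParsimonyResults`; ``fitch_length``, ``sankoff``
and ``count_transitions`` are the equivalent functional entry points.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .tree import Node, PhyloTree, write_newick

__all__ = [
    "StepMatrix",
    "ReconstructionResult",
    "ParsimonyResults",
    "AncestralParsimony",
    "fitch_length",
    "sankoff",
    "count_transitions",
]

_INF = np.inf
_ATOL = 1e-9


@dataclass(frozen=True)
class StepMatrix:
    """k x k nonnegative transformation costs with a zero diagonal."""

    costs: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.costs, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("step matrix must be square")
        if np.any(c < 0):
            raise ValueError("step costs must be nonnegative")
        if np.any(np.diag(c) != 0):
            raise ValueError("step matrix diagonal must be zero")
        object.__setattr__(self, "costs", c)

    @property
    def k(self) -> int:
        return self.costs.shape[0]

    @property
    def is_unit(self) -> bool:
        off = self.costs[~np.eye(self.k, dtype=bool)]
        return bool(np.all(off == 1))

    @property
    def is_symmetric(self) -> bool:
        return bool(np.allclose(self.costs, self.costs.T))

    @classmethod
    def unordered(cls, k: int) -> "StepMatrix":
        """Unit-cost (Fitch / "unweighted") costs: every change is 1 step."""
        return cls(1.0 - np.eye(k))

    @classmethod
    def ordered(cls, k: int) -> "StepMatrix":
        """Linear-scale (Wagner) costs: cost(i, j) = |i - j|."""
        idx = np.arange(k)
        return cls(np.abs(idx[:, None] - idx[None, :]).astype(float))


def _check_states(
    tree: PhyloTree, states: dict[str, int], k: int | None
) -> int:
    missing = tree.tip_labels - set(states)
    if missing:
        raise ValueError(
            "tips without a state: " + ", ".join(sorted(missing)[:5])
        )
    kmax = max(states[t] for t in tree.tip_labels) + 1
    if k is None:
        return kmax
    if kmax > k:
        raise ValueError(f"observed state {kmax - 1} >= alphabet size {k}")
    return k


# ---------------------------------------------------------------------------
# Fitch fast path (unit costs, binary trees)
# ---------------------------------------------------------------------------


def fitch_length(tree: PhyloTree, states: dict[str, int]) -> int:
    """Minimum number of unit-cost state changes on the tree (Fitch).

    Bottom-up set operations on bitmasks: a parent takes the intersection
    of its children's sets when non-empty, else the union with one extra
    step.  Trees with polytomies are delegated to the Sankoff engine with
    unit costs, which generalises correctly.
    """
    k = _check_states(tree, states, None)
    if tree.has_polytomy():
        res = sankoff(tree, states, StepMatrix.unordered(k), mpr=False)
        return int(res.length)
    steps = 0
    masks: dict[int, int] = {}
    for node in tree.postorder():
        if node.is_tip:
            masks[node.id] = 1 << states[node.label]
        else:
            a = masks.pop(node.children[0].id)
            b = masks.pop(node.children[1].id)
            inter = a & b
            if inter:
                masks[node.id] = inter
            else:
                masks[node.id] = a | b
                steps += 1
    return steps


# ---------------------------------------------------------------------------
# Sankoff engine
# ---------------------------------------------------------------------------


@dataclass
class ReconstructionResult:
    """Parsimony reconstruction of one character on one tree.

    ``mpr`` maps node id -> frozenset of states attained by at least one
    globally minimal reconstruction; a node is equivocal iff that set has
    more than one element.  For unit costs the length is an integer count
    of steps (= transitions).
    """

    character: str
    length: float
    mpr: dict[int, frozenset[int]]
    equivocal: dict[int, bool]
    tree: PhyloTree
    costs: StepMatrix
    state_labels: tuple[str, ...] = ()
    min_transitions: int | None = None

    def __post_init__(self):
        if not self.state_labels:
            self.state_labels = tuple(str(i) for i in range(self.costs.k))

    @property
    def n_equivocal(self) -> int:
        return sum(self.equivocal.values())

    def single_reconstruction(self) -> dict[int, int]:
        """One minimal reconstruction: the lowest state index at each
        equivocal node (one of possibly many; ties are kept in ``mpr``)."""
        return {v: min(s) for v, s in self.mpr.items()}

    def to_tsv(self) -> str:
        """Node id, tip label, MPR state set, equivocal flag."""
        out = io.StringIO()
        out.write("node_id\tlabel\tmpr_states\tequivocal\n")
        for node in self.tree.postorder():
            ss = ",".join(
                self.state_labels[s] for s in sorted(self.mpr[node.id])
            )
            out.write(
                f"{node.id}\t{node.label or ''}\t{ss}\t"
                f"{int(self.equivocal[node.id])}\n"
            )
        return out.getvalue()

    def annotated_newick(self) -> str:
        """Newick with a ``[&mpr=...]`` comment tag on every node."""
        labels = self.state_labels

        def rec(node: Node) -> str:
            tag = "[&mpr=" + "|".join(
                labels[s] for s in sorted(self.mpr[node.id])
            ) + "]"
            if node.is_tip:
                out = node.label.replace(" ", "_")
            else:
                out = "(" + ",".join(rec(c) for c in node.children) + ")"
            out += tag
            if node.length is not None:
                out += f":{node.length:.10g}"
            return out

        return rec(self.tree.root) + ";"

    def summary(self) -> str:
        lab = self.character or "character"
        lines = [
            f"Parsimony reconstruction: {lab}",
            f"  tips analysed      : {self.tree.n_tips}",
            f"  states in alphabet : {self.costs.k}",
            f"  parsimony length   : {self.length:g}",
            f"  equivocal nodes    : {self.n_equivocal}",
        ]
        if self.min_transitions is not None:
            lines.append(f"  min transitions    : {self.min_transitions}")
        return "\n".join(lines)


#: Results alias for the model API.
ParsimonyResults = ReconstructionResult


def sankoff(
    tree: PhyloTree,
    states: dict[str, int],
    costs: StepMatrix,
    character: str = "",
    state_labels: tuple[str, ...] = (),
    mpr: bool = True,
) -> ReconstructionResult:
    """Generalised (Sankoff) parsimony with an arbitrary step matrix.

    Bottom-up pass: ``S_v(s)`` is the minimal cost of the subtree at *v*
    given state *s*; each child contributes
    ``M_c(s) = min_t [cost(s, t) + S_c(t)]`` and contributions sum over
    children (polytomies need no special case).  The parsimony length is
    ``min_s S_root(s)``.

    Top-down pass (``mpr=True``): ``A_v(s)`` is the minimal cost of the
    rest of the tree given *v* in state *s*; a state belongs to MPR(v)
    iff ``A_v(s) + S_v(s)`` equals the global minimum.
    """
    k = _check_states(tree, states, costs.k)
    C = costs.costs

    S: dict[int, np.ndarray] = {}
    M: dict[int, np.ndarray] = {}  # child id -> contribution vector M_c
    for node in tree.postorder():
        if node.is_tip:
            vec = np.full(k, _INF)
            vec[states[node.label]] = 0.0
        else:
            vec = np.zeros(k)
            for c in node.children:
                mc = np.min(C + S[c.id][None, :], axis=1)
                M[c.id] = mc
                vec = vec + mc
        S[node.id] = vec

    root_id = tree.root.id
    length = float(np.min(S[root_id]))

    mpr_sets: dict[int, frozenset[int]] = {}
    equivocal: dict[int, bool] = {}
    if mpr:
        A: dict[int, np.ndarray] = {root_id: np.zeros(k)}
        for node in tree.preorder():
            total = A[node.id] + S[node.id]
            keep = np.nonzero(total <= length + _ATOL)[0]
            mpr_sets[node.id] = frozenset(int(s) for s in keep)
            equivocal[node.id] = len(keep) > 1
            for c in node.children:
                B = A[node.id] + S[node.id] - M[c.id]
                A[c.id] = np.min(B[:, None] + C, axis=0)

    if costs.is_unit:
        length = round(length)
    return ReconstructionResult(
        character, length, mpr_sets, equivocal, tree, costs,
        tuple(state_labels),
    )


def count_transitions(result: ReconstructionResult) -> int:
    """Minimal number of branches carrying a state change over all
    minimal-cost reconstructions.

    For unit costs this equals the parsimony length (each step is one
    changed branch).  For general costs it is computed by a lexicographic
    Sankoff pass minimising (cost, changed branches).
    """
    if result.costs.is_unit:
        return int(result.length)
    tree, costs = result.tree, result.costs
    states = {n.label: next(iter(result.mpr[n.id])) for n in tree.tips()}
    C = costs.costs
    k = costs.k

    S: dict[int, np.ndarray] = {}
    T: dict[int, np.ndarray] = {}  # min changed branches given (v, state)
    for node in tree.postorder():
        if node.is_tip:
            vec = np.full(k, _INF)
            vec[states[node.label]] = 0.0
            chg = np.zeros(k)
        else:
            vec = np.zeros(k)
            chg = np.zeros(k)
            notdiag = 1.0 - np.eye(k)
            for c in node.children:
                cand = C + S[c.id][None, :]          # (parent s, child t)
                mc = np.min(cand, axis=1)
                ties = cand <= mc[:, None] + _ATOL
                tcand = np.where(
                    ties, T[c.id][None, :] + notdiag, _INF
                )
                vec = vec + mc
                chg = chg + np.min(tcand, axis=1)
        S[node.id] = vec
        T[node.id] = chg

    root = tree.root.id
    best = np.min(S[root])
    mask = S[root] <= best + _ATOL
    min_changes = int(np.min(T[root][mask]))
    result.min_transitions = min_changes
    return min_changes


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------


class AncestralParsimony:
    """Parsimony ancestral-state reconstruction model for one discrete
    character on one rooted tree.

    Parameters
    ----------
    tree
        Rooted tree; tips with a missing state are pruned before analysis.
    states
        Mapping tip label -> state index, e.g. from
        ``CharacterMatrix.states_for``.
    costs
        ``"unordered"`` (default; every change = 1 step, the unweighted
        parsimony of classic character tracing), ``"ordered"``
        (cost ``|i - j|``, natural for depth intervals) or a
        :class:`StepMatrix`.
    n_states
        Alphabet size; inferred from the observed states if omitted.

    ``fit()`` returns :class:`ParsimonyResults` with the parsimony length,
    per-node MPR state sets and equivocal flags.
    """

    def __init__(
        self,
        tree: PhyloTree,
        states: dict[str, int],
        costs: str | StepMatrix = "unordered",
        n_states: int | None = None,
        character: str = "",
        state_labels: tuple[str, ...] = (),
    ):
        scored = {t for t in tree.tip_labels if states.get(t) is not None}
        if scored != tree.tip_labels:
            from .tree import prune_to

            tree = prune_to(tree, scored)
        self.tree = tree
        self.states = {t: int(states[t]) for t in tree.tip_labels}
        if n_states is None:
            n_states = max(self.states.values()) + 1
        if isinstance(costs, str):
            if costs == "unordered":
                costs = StepMatrix.unordered(n_states)
            elif costs == "ordered":
                costs = StepMatrix.ordered(n_states)
            else:
                raise ValueError(f"unknown cost mode {costs!r}")
        if costs.k < n_states:
            raise ValueError("cost matrix smaller than state alphabet")
        self.costs = costs
        self.character = character
        self.state_labels = tuple(state_labels)

    def fit(self) -> ParsimonyResults:
        return sankoff(
            self.tree,
            self.states,
            self.costs,
            character=self.character,
            state_labels=self.state_labels,
        )


# ---------------------------------------------------------------------------
# Array engine used by the null-distribution loop
# ---------------------------------------------------------------------------


def random_addition_arrays(
    n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random rooted binary topology over tips ``0..n-1`` in array
    form: two child arrays indexed by internal node ``n..2n-2``; the last
    allocated internal node is the root.

    Same sequential-addition draw as :func:`cladetrace.tree.random_topology`
    but without node objects; used by the randomisation test where many
    thousands of topologies are needed.
    """
    if n < 2:
        raise ValueError("need at least 2 tips")
    order = rng.permutation(n)
    left = np.empty(n - 1, dtype=np.int64)
    right = np.empty(n - 1, dtype=np.int64)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    left[0], right[0] = order[0], order[1]
    parent[order[0]] = parent[order[1]] = n
    root = n
    nxt = n + 1
    # edges: child-end node ids; -1 stands for the branch above the root
    edges = [int(order[0]), int(order[1]), -1]
    for tip in order[2:]:
        tip = int(tip)
        e = edges[int(rng.integers(len(edges)))]
        w = nxt
        nxt += 1
        if e == -1:
            left[w - n], right[w - n] = root, tip
            parent[root] = w
            parent[tip] = w
            edges.append(root)
            root = w
        else:
            p = parent[e]
            if left[p - n] == e:
                left[p - n] = w
            else:
                right[p - n] = w
            parent[w] = p
            left[w - n], right[w - n] = e, tip
            parent[e] = w
            parent[tip] = w
            edges.append(w)
        edges.append(tip)
    return np.stack([left, right]), parent


def fitch_steps_arrays(
    children: np.ndarray, parent: np.ndarray, tip_masks: np.ndarray
) -> int:
    """Fitch step count on an array-form binary topology.

    ``tip_masks[i]`` is the state bitmask of tip ``i``; internal node
    ``n + j`` has children ``children[:, j]``; the root is the node whose
    ``parent`` entry is -1.  An explicit-stack postorder keeps the pass
    linear in the number of nodes.
    """
    n = tip_masks.shape[0]
    masks = np.zeros(2 * n - 1, dtype=np.int64)
    masks[:n] = tip_masks
    root = int(np.nonzero(parent == -1)[0][0])
    steps = 0
    stack: list[int] = [root]
    order: list[int] = []
    while stack:
        v = stack.pop()
        if v >= n:
            order.append(v)
            stack.append(int(children[0, v - n]))
            stack.append(int(children[1, v - n]))
    for v in reversed(order):
        a, b = children[0, v - n], children[1, v - n]
        inter = masks[a] & masks[b]
        if inter:
            masks[v] = inter
        else:
            masks[v] = masks[a] | masks[b]
            steps += 1
    return steps
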