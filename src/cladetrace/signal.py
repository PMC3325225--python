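"""Phylogeny-character correlation test by randomisation.

A character carries phylogenetic signal when its parsimony length on the
observed tree is smaller than expected on random trees over the same tip
set.  The null distribution of lengths is built either from uniformly
drawn random topologies (the convention of classic character-tracing
software, and the default) or from tip-label shuffles of the observed
topology; significance is a one-tailed rank p-value with the add-one
correction, and the mean comparison is reported alongside as a z-like
descriptive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .characters import CharacterMatrix, validate_against_tree
from .parsimony import (
    StepMatrix,
    fitch_steps_arrays,
    random_addition_arrays,
    sankoff,
)
from .tree import PhyloTree, prune_to, random_topology

__all__ = [
    "NullDistribution",
    "SignalTestResults",
    "PhylogeneticSignalTest",
    "null_distribution",
    "signal_pvalue",
    "run_character_test",
]

METHODS = ("random_topology", "shuffle_tips")


@dataclass
class NullDistribution:
    """Parsimony lengths over N randomised trees plus the observed length."""

    character: str
    n_random: int
    null_lengths: np.ndarray
    observed: float
    method: str
    seed: int

    def __post_init__(self):
        self.null_lengths = np.asarray(self.null_lengths, dtype=float)
        if self.null_lengths.shape != (self.n_random,):
            raise ValueError("null_lengths length must equal n_random")

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_lengths))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_lengths, ddof=1)) if self.n_random > 1 else 0.0

    @property
    def pvalue(self) -> float:
        return signal_pvalue(self)

    @property
    def zscore(self) -> float:
        """(observed - null mean) / null s.d.; 0 for a degenerate null."""
        sd = self.null_sd
        if sd == 0:
            return 0.0
        return (self.observed - self.null_mean) / sd


def signal_pvalue(null: NullDistribution) -> float:
    """One-tailed rank p with the add-one correction:
    ``(1 + #{null <= observed}) / (N + 1)``.  Fewer steps than random
    trees = more phylogenetic signal, so small p means signal."""
    n_le = int(np.sum(null.null_lengths <= null.observed))
    return (1 + n_le) / (null.n_random + 1)


def _states_array(
    tree: PhyloTree, states: dict[str, int]
) -> tuple[list[str], np.ndarray]:
    labels = sorted(tree.tip_labels)
    return labels, np.array([states[t] for t in labels], dtype=np.int64)


def null_distribution(
    tree: PhyloTree,
    states: dict[str, int],
    costs: StepMatrix,
    n_random: int = 1000,
    method: str = "random_topology",
    seed: int = 0,
    character: str = "",
) -> NullDistribution:
    """Observed parsimony length plus ``n_random`` null lengths.

    ``random_topology`` draws a fresh uniform labelled topology per
    replicate (the observed topology is discarded, the tip set kept);
    ``shuffle_tips`` keeps the topology and permutes the labels.  Unit
    step matrices on binary trees use the bitmask Fitch pass, which the
    test suite verifies to agree with the Sankoff engine.
    """
    if method not in METHODS:
        raise ValueError(
            f"unknown method {method!r}; expected one of {METHODS}"
        )
    if tree.n_tips < 3:
        raise ValueError("null distribution needs at least 3 tips")
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    rng = np.random.default_rng(seed)

    observed = sankoff(tree, states, costs, mpr=False).length
    labels, svec = _states_array(tree, states)
    n = len(labels)
    use_fast = costs.is_unit

    null = np.empty(n_random)
    if use_fast:
        tip_masks_base = (np.int64(1) << svec)
        if method == "random_topology":
            for i in range(n_random):
                children, parent = random_addition_arrays(n, rng)
                null[i] = fitch_steps_arrays(children, parent, tip_masks_base)
        else:
            children, parent = _tree_to_arrays(tree, labels)
            for i in range(n_random):
                perm = rng.permutation(n)
                null[i] = fitch_steps_arrays(
                    children, parent, tip_masks_base[perm]
                )
    else:
        for i in range(n_random):
            if method == "random_topology":
                rtree = random_topology(labels, rng)
                null[i] = sankoff(rtree, states, costs, mpr=False).length
            else:
                # permuting the state vector over tips == relabelling tips
                perm = rng.permutation(n)
                shuffled = {
                    labels[j]: int(svec[perm[j]]) for j in range(n)
                }
                null[i] = sankoff(tree, shuffled, costs, mpr=False).length
    return NullDistribution(
        character, n_random, null, observed, method, seed
    )


def _tree_to_arrays(
    tree: PhyloTree, labels: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Array form of a binary tree for the fast Fitch pass.  Polytomies
    fall back to the object engine upstream."""
    if tree.has_polytomy():
        raise ValueError("array form requires a binary tree")
    n = len(labels)
    pos = {lab: i for i, lab in enumerate(labels)}
    ids: dict[int, int] = {}
    nxt = n
    left = np.empty(n - 1, dtype=np.int64)
    right = np.empty(n - 1, dtype=np.int64)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    for node in tree.postorder():
        if node.is_tip:
            ids[node.id] = pos[node.label]
        else:
            me = nxt
            nxt += 1
            ids[node.id] = me
            a, b = (ids[c.id] for c in node.children)
            left[me - n], right[me - n] = a, b
            parent[a] = parent[b] = me
    return np.stack([left, right]), parent


@dataclass
class SignalTestResults:
    """Results of a phylogenetic-signal randomisation test."""

    null: NullDistribution
    pruned_taxa: tuple[str, ...] = ()
    n_tips: int = 0

    @property
    def observed(self) -> float:
        return self.null.observed

    @property
    def pvalue(self) -> float:
        return self.null.pvalue

    @property
    def zscore(self) -> float:
        return self.null.zscore

    def to_dict(self) -> dict:
        n = self.null
        return {
            "character": n.character,
            "n_tips": self.n_tips,
            "observed_length": n.observed,
            "null_mean": n.null_mean,
            "null_sd": n.null_sd,
            "z_score": n.zscore,
            "p_value": n.pvalue,
            "n_random": n.n_random,
            "method": n.method,
            "seed": n.seed,
            "pruned_taxa": list(self.pruned_taxa),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def null_lengths_tsv(self) -> str:
        return "null_length\n" + "\n".join(
            f"{x:g}" for x in self.null.null_lengths
        ) + "\n"

    def summary(self) -> str:
        n = self.null
        verdict = (
            "fewer steps than random trees (signal)"
            if n.observed < n.null_mean
            else "no excess signal"
        )
        return "\n".join([
            f"Phylogenetic signal test: {n.character or 'character'}",
            f"  tips analysed   : {self.n_tips}",
            f"  observed length : {n.observed:g}",
            f"  null mean (sd)  : {n.null_mean:.3f} ({n.null_sd:.3f})",
            f"  z score         : {n.zscore:.3f}",
            f"  p value         : {n.pvalue:.6g}  "
            f"[N = {n.n_random}, method = {n.method}]",
            f"  interpretation  : {verdict}",
        ])


class PhylogeneticSignalTest:
    """Randomisation test of phylogeny-character correlation.

    Parameters
    ----------
    tree
        Observed (e.g. maximum-likelihood) tree.
    states
        Tip label -> state index for one discrete character.
    costs
        ``"unordered"`` (default), ``"ordered"`` or a :class:`StepMatrix`.

    ``fit(n_random, method, seed)`` returns :class:`SignalTestResults`.
    The observed length does not depend on the null method chosen.
    """

    def __init__(
        self,
        tree: PhyloTree,
        states: dict[str, int],
        costs: str | StepMatrix = "unordered",
        n_states: int | None = None,
        character: str = "",
    ):
        scored = {t for t in tree.tip_labels if states.get(t) is not None}
        self.pruned = tuple(sorted(tree.tip_labels - scored))
        if scored != tree.tip_labels:
            tree = prune_to(tree, scored)
        self.tree = tree
        self.states = {t: int(states[t]) for t in tree.tip_labels}
        if n_states is None:
            n_states = max(self.states.values()) + 1
        if isinstance(costs, str):
            costs = (
                StepMatrix.unordered(n_states)
                if costs == "unordered"
                else StepMatrix.ordered(n_states)
            )
        self.costs = costs
        self.character = character

    def fit(
        self,
        n_random: int = 1000,
        method: str = "random_topology",
        seed: int = 0,
    ) -> SignalTestResults:
        null = null_distribution(
            self.tree,
            self.states,
            self.costs,
            n_random=n_random,
            method=method,
            seed=seed,
            character=self.character,
        )
        return SignalTestResults(null, self.pruned, self.tree.n_tips)


def run_character_test(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    character: str,
    n_random: int = 1000,
    method: str = "random_topology",
    seed: int = 0,
    costs: str | StepMatrix = "unordered",
) -> SignalTestResults:
    """Full pipeline for one named character: validate the taxon sets,
    prune the tree to the shared scored taxa, then run the signal test."""
    if character not in matrix.characters:
        raise KeyError(
            f"character {character!r} not in matrix "
            f"(has: {', '.join(matrix.characters)})"
        )
    report = validate_against_tree(matrix, tree)
    char = matrix[character]
    scored = {
        t for t in report.intersection if char.data.get(t) is not None
    }
    pruned_tree = prune_to(tree, scored)
    states = matrix.states_for(character, sorted(scored))
    model = PhylogeneticSignalTest(
        pruned_tree,
        states,
        costs=costs,
        n_states=len(char.states),
        character=character,
    )
    res = model.fit(n_random=n_random, method=method, seed=seed)
    res.pruned_taxa = tuple(sorted(tree.tip_labels - scored))
    return res
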