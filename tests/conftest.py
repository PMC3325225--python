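"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's dynamic-programming and
pruning code paths: parsimony quantities are obtained by exhaustive
enumeration of ancestral labelings, likelihoods by explicit summation
over internal-state assignments and rate categories.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import settings

from cladetrace import PhyloTree, parse_newick

settings.register_profile("derandomised", derandomize=True, deadline=None)
settings.load_profile("derandomised")


@pytest.fixture
def balanced4() -> PhyloTree:
    return parse_newick("((A,B),(C,D));")


@pytest.fixture
def crossed4() -> PhyloTree:
    return parse_newick("((A,C),(B,D));")


# ---------------------------------------------------------------------------
# Parsimony oracle: exhaustive enumeration over ancestral labelings
# ---------------------------------------------------------------------------


def enumerate_parsimony(
    tree: PhyloTree, states: dict[str, int], costs: np.ndarray
):
    """(min cost, MPR sets per node id, min changed branches among minimal
    labelings) by brute force over all k^n_internal ancestral labelings."""
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_tip]
    k = costs.shape[0]

    best = np.inf
    mpr: dict[int, set[int]] = {n.id: set() for n in nodes}
    best_changes = None
    for labeling in itertools.product(range(k), repeat=len(internal)):
        assign = {n.id: s for n, s in zip(internal, labeling)}
        for n in nodes:
            if n.is_tip:
                assign[n.id] = states[n.label]
        cost = 0.0
        changes = 0
        for n in nodes:
            if n.parent is not None:
                cost += costs[assign[n.parent.id], assign[n.id]]
                changes += assign[n.parent.id] != assign[n.id]
        if cost < best - 1e-12:
            best = cost
            mpr = {n.id: {assign[n.id]} for n in nodes}
            best_changes = changes
        elif cost < best + 1e-12:
            for n in nodes:
                mpr[n.id].add(assign[n.id])
            best_changes = min(best_changes, changes)
    return best, {i: frozenset(s) for i, s in mpr.items()}, best_changes


def random_tree_states(rng, n_tips: int, k: int):
    """A uniform random topology plus random tip states covering at most
    k states (at least 1)."""
    from cladetrace import random_topology

    labels = [f"t{i}" for i in range(n_tips)]
    tree = random_topology(labels, rng)
    states = {lab: int(rng.integers(k)) for lab in labels}
    return tree, states


# ---------------------------------------------------------------------------
# Likelihood oracle: explicit summation
# ---------------------------------------------------------------------------


def brute_force_loglik(tree: PhyloTree, alignment, model) -> float:
    """GTR+I+G log-likelihood by summing over every assignment of states
    to internal nodes and every rate category, site by site."""
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_tip]
    tips = [n for n in nodes if n.is_tip]
    pi = np.asarray(model.freqs)
    rates = model.gamma_rates()
    pmats = {
        (n.id, i): model.transition_matrix(float(r) * n.length)
        for n in nodes
        if n.parent is not None
        for i, r in enumerate(rates)
    }

    total = 0.0
    for site in range(alignment.n_sites):
        obs = {n.label: alignment.row(n.label)[site] for n in tips}
        # variable part: average over categories of the full summation
        var = 0.0
        for ci in range(len(rates)):
            site_l = 0.0
            for labeling in itertools.product(
                range(4), repeat=len(internal)
            ):
                assign = {n.id: s for n, s in zip(internal, labeling)}
                term_states = []
                for n in tips:
                    code = obs[n.label]
                    term_states.append(
                        [code] if code < 4 else [0, 1, 2, 3]
                    )
                for tip_states in itertools.product(*term_states):
                    for n, s in zip(tips, tip_states):
                        assign[n.id] = s
                    term = pi[assign[tree.root.id]]
                    for n in nodes:
                        if n.parent is not None:
                            term *= pmats[(n.id, ci)][
                                assign[n.parent.id], assign[n.id]
                            ]
                    site_l += term
            var += site_l
        var /= len(rates)
        if model.p_inv > 0:
            compat = np.ones(4, dtype=bool)
            for lbl, code in obs.items():
                if code < 4:
                    onehot = np.zeros(4, dtype=bool)
                    onehot[code] = True
                    compat &= onehot
            inv = float(pi[compat].sum())
            site_lik = model.p_inv * inv + (1 - model.p_inv) * var
        else:
            site_lik = var
        total += np.log(site_lik)
    return float(total)
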