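"""Synthetic study generator: Yule trees, Mk discrete characters and
GTR+I+G sequence alignments with known ground truth.

The default configuration emulates the shape of a family-level COI
barcoding study of deep-sea chemosymbiotic clams: 87 taxa, a 630 bp
aligned COI-like fragment evolved under GTR+I+G (proportion of invariable
sites 0.39, gamma shape 0.54), and a 13-state depth-interval character
plus a 4-state habitat character evolved under the Mk model on a 53-taxon
ingroup subset.  The Mk rate is the signal knob: a low rate produces few
changes and hence strong phylogenetic signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .characters import (
    DEFAULT_DEPTH_EDGES,
    HABITAT_CATEGORIES,
    CharacterMatrix,
    DepthBinning,
)
from .molecular import Alignment, GTRModel
from .tree import Node, PhyloTree, write_newick

__all__ = [
    "SimulationConfig",
    "simulate_yule",
    "evolve_mk",
    "simulate_sequences",
    "make_fixture_study",
    "StudyBundle",
]

# COI-like defaults: transition-rich exchangeabilities and AT-rich
# composition; heterogeneity parameters match a published COI fit
# (p_inv = 0.39, alpha = 0.54).
DEFAULT_GTR = GTRModel(
    rates=(1.0, 6.0, 1.0, 1.0, 6.0, 1.0),
    freqs=(0.28, 0.16, 0.18, 0.38),
    p_inv=0.39,
    alpha=0.54,
    ncat=4,
)


@dataclass
class SimulationConfig:
    """Ground-truth generating parameters for one synthetic study."""

    n_taxa: int = 87
    n_ingroup: int = 53
    #: Yule birth rate per unit time.  0.28 gives an expected total tree
    #: length of ~190 time units for 53 taxa, i.e. ~9 expected character
    #: changes at the default char_rate — the order of magnitude of
    #: transitions a depth/habitat reconstruction shows at this scale,
    #: and far from the degenerate constant-character regime
    birth_rate: float = 0.28
    seq_length: int = 630
    #: branch-length multiplier taking Yule time units to expected
    #: substitutions/site for sequence simulation (root height ~0.4
    #: substitutions/site at 87 taxa, comparable to family-level COI
    #: divergence)
    brlen_scale: float = 0.03
    depth_states: int = 13
    habitat_states: int = 4
    #: Mk changes per unit (unscaled) branch length; 0.05 gives a handful
    #: of changes across the tree = strong phylogenetic signal
    char_rate: float = 0.05
    gtr: GTRModel = field(default_factory=lambda: DEFAULT_GTR)
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 2 or not (2 <= self.n_ingroup <= self.n_taxa):
            raise ValueError("need 2 <= n_ingroup <= n_taxa and n_taxa >= 2")
        for name in ("birth_rate", "seq_length", "brlen_scale", "char_rate"):
            if getattr(self, name) < 0 or (
                name in ("birth_rate", "seq_length", "brlen_scale")
                and getattr(self, name) == 0
            ):
                raise ValueError(f"{name} must be positive")
        if self.depth_states < 2:
            raise ValueError("depth_states must be >= 2")
        if self.habitat_states < 2:
            raise ValueError("habitat_states must be >= 2")


def simulate_yule(
    n: int, birth: float, seed: int | np.random.Generator
) -> PhyloTree:
    """Pure-birth (Yule) ultrametric tree with ``n`` tips.

    Starting from two lineages at the root, each of ``k`` extant lineages
    splits at total rate ``birth * k``; the tree is cut at the (unrealised)
    next speciation after reaching ``n`` lineages, so the expected root
    height is ``sum_{k=2..n} 1 / (birth * k)``.  Tip labels are ``t001``,
    ``t002``, ... in lineage order.
    """
    if n < 2:
        raise ValueError("need at least 2 tips")
    if birth <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    root = Node()
    # active lineages: (node, time it was born)
    active: list[tuple[Node, float]] = [(root.add_child(Node()), 0.0),
                                        (root.add_child(Node()), 0.0)]
    t = 0.0
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / (birth * k))
        idx = int(rng.integers(k))
        node, born = active.pop(idx)
        node.length = t - born
        active.append((node.add_child(Node()), t))
        active.append((node.add_child(Node()), t))
    t += rng.exponential(1.0 / (birth * n))
    width = max(3, len(str(n)))
    for i, (node, born) in enumerate(active):
        node.label = f"t{i + 1:0{width}d}"
        node.length = t - born
    return PhyloTree(root)


def _mk_child_state(
    state: int, k: int, rate: float, t: float, rng: np.random.Generator
) -> int:
    """Exact Mk transition: stay with the diagonal transition probability,
    otherwise uniform over the other k-1 states.

    Parameterisation: total leaving rate ``rate`` (each of the k-1 other
    states gained at rate/(k-1)), so for k = 2 the change probability on a
    branch of length t is (1 - exp(-2 rate t)) / 2.
    """
    mu = rate / (k - 1)  # per-pair rate
    p_same = 1.0 / k + (k - 1) / k * np.exp(-k * mu * t)
    if rng.random() < p_same:
        return state
    other = int(rng.integers(k - 1))
    return other if other < state else other + 1


def evolve_mk(
    tree: PhyloTree,
    k: int,
    rate: float,
    seed: int | np.random.Generator,
) -> tuple[dict[str, int], dict[int, int]]:
    """Simulate a symmetric k-state Markov (Mk) character root-to-tips.

    The root state is uniform.  Returns ``(tip_states, ancestral_states)``
    where the second maps node id -> true simulated state (tips included),
    for reconstruction-recovery tests.
    """
    if k < 2:
        raise ValueError("need at least 2 states")
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    states: dict[int, int] = {}
    tip_states: dict[str, int] = {}
    for node in tree.preorder():
        if node.parent is None:
            states[node.id] = int(rng.integers(k))
        else:
            if node.length is None:
                raise ValueError("tree must have branch lengths")
            states[node.id] = _mk_child_state(
                states[node.parent.id], k, rate, node.length, rng
            )
        if node.is_tip:
            tip_states[node.label] = states[node.id]
    return tip_states, states


def simulate_sequences(
    tree: PhyloTree,
    model: GTRModel,
    length: int,
    seed: int | np.random.Generator,
) -> Alignment:
    """Site-i.i.d. GTR+I+G simulation on a tree with branch lengths.

    Each site is invariable with probability ``p_inv`` (it keeps its root
    state everywhere); variable sites draw one of the discrete-gamma rate
    categories uniformly and evolve with branch lengths multiplied by the
    category rate.
    """
    if length < 1:
        raise ValueError("alignment length must be positive")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    pi = np.asarray(model.freqs)
    rates = model.gamma_rates()

    invariant = rng.random(length) < model.p_inv
    cat = rng.integers(len(rates), size=length)
    site_rate = np.where(invariant, 0.0, rates[cat])

    root_states = rng.choice(4, size=length, p=pi)
    seqs: dict[int, np.ndarray] = {}
    rows: dict[str, np.ndarray] = {}
    for node in tree.preorder():
        if node.parent is None:
            seqs[node.id] = root_states
        else:
            if node.length is None:
                raise ValueError("tree must have branch lengths")
            parent_seq = seqs[node.parent.id]
            child_seq = parent_seq.copy()
            for r in np.unique(site_rate):
                if r == 0.0:
                    continue
                cols = np.nonzero(site_rate == r)[0]
                P = model.transition_matrix(float(r) * node.length)
                cum = np.cumsum(P, axis=1)
                u = rng.random(cols.size)
                child_seq[cols] = np.argmax(
                    u[:, None] < cum[parent_seq[cols]], axis=1
                )
            seqs[node.id] = child_seq
        if node.is_tip:
            rows[node.label] = seqs[node.id]
    letters = np.array(list("ACGT"))
    taxa = sorted(rows)
    return Alignment(
        taxa, ["".join(letters[rows[t]]) for t in taxa]
    )


@dataclass
class StudyBundle:
    """One synthetic study with its ground truth."""

    tree: PhyloTree            # time-scale Yule tree (character simulation)
    seq_tree: PhyloTree        # same topology, lengths in subst./site
    matrix: CharacterMatrix
    alignment: Alignment
    truth: dict


def _scale_lengths(tree: PhyloTree, factor: float) -> PhyloTree:
    t = tree.copy()
    for node in t.postorder():
        if node.length is not None:
            node.length *= factor
    return t


def make_fixture_study(
    config: SimulationConfig, outdir: str | Path | None = None
) -> StudyBundle:
    """Generate a full synthetic study; optionally write it to ``outdir``.

    Files written: ``tree.nwk`` (substitutions scale), ``time_tree.nwk``,
    ``alignment.fasta``, ``characters.tsv`` (taxon, max_depth_m, habitat),
    ``characters.nex`` and ``truth.json`` (generating parameters, true
    ancestral states, true tree).  Deterministic per seed.
    """
    rng = np.random.default_rng(config.seed)
    tree = simulate_yule(config.n_taxa, config.birth_rate, rng)
    seq_tree = _scale_lengths(tree, config.brlen_scale)
    alignment = simulate_sequences(
        seq_tree, config.gtr, config.seq_length, rng
    )

    tips = sorted(tree.tip_labels)
    ingroup = sorted(
        tips[i] for i in rng.choice(
            len(tips), size=config.n_ingroup, replace=False
        )
    )
    depth_tips, depth_anc = evolve_mk(
        tree, config.depth_states, config.char_rate, rng
    )
    habitat_tips, habitat_anc = evolve_mk(
        tree, config.habitat_states, config.char_rate, rng
    )

    binning = DepthBinning(DEFAULT_DEPTH_EDGES[: config.depth_states - 1])
    # representative depth inside each interval so the TSV round-trips
    # through bin_depth to the same state index
    mids = _interval_depths(binning)
    habitat_labels = (
        HABITAT_CATEGORIES
        if config.habitat_states == len(HABITAT_CATEGORIES)
        else tuple(f"H{i}" for i in range(config.habitat_states))
    )

    import pandas as pd

    table = pd.DataFrame({
        "taxon": ingroup,
        "max_depth_m": [mids[depth_tips[t]] for t in ingroup],
        "habitat": [habitat_labels[habitat_tips[t]] for t in ingroup],
    })

    from .characters import Character

    matrix = CharacterMatrix(
        ingroup,
        [
            Character(
                "depth", binning.labels, True,
                {t: depth_tips[t] for t in ingroup},
            ),
            Character(
                "habitat", habitat_labels, False,
                {t: habitat_tips[t] for t in ingroup},
            ),
        ],
    )

    truth = {
        "config": _config_dict(config),
        "root_state": {
            "depth": depth_anc[tree.root.id],
            "habitat": habitat_anc[tree.root.id],
        },
        "ancestral_states": {
            "depth": {str(k): v for k, v in depth_anc.items()},
            "habitat": {str(k): v for k, v in habitat_anc.items()},
        },
        "ingroup": ingroup,
        "time_tree": write_newick(tree),
        "tree": write_newick(seq_tree),
    }

    bundle = StudyBundle(tree, seq_tree, matrix, alignment, truth)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "tree.nwk").write_text(write_newick(seq_tree) + "\n")
        (out / "time_tree.nwk").write_text(write_newick(tree) + "\n")
        alignment.to_fasta(out / "alignment.fasta")
        table.to_csv(out / "characters.tsv", sep="\t", index=False)
        matrix.to_nexus(out / "characters.nex")
        (out / "truth.json").write_text(
            json.dumps(truth, indent=2, sort_keys=True) + "\n"
        )
    return bundle


def _interval_depths(binning: DepthBinning) -> list[float]:
    """A representative depth inside each interval (midpoints; the open
    top interval uses its lower edge + 500 m)."""
    edges = binning.edges
    mids = [edges[0] / 2.0]
    mids += [(a + b) / 2.0 for a, b in zip(edges, edges[1:])]
    mids.append(edges[-1] + 500.0)
    return mids


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["gtr"] = {
        "rates": list(config.gtr.rates),
        "freqs": list(config.gtr.freqs),
        "p_inv": config.gtr.p_inv,
        "alpha": config.gtr.alpha,
        "ncat": config.gtr.ncat,
    }
    return d
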