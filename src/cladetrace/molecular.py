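"""Sequence-level computations: pairwise divergence, neighbor joining and
GTR+I+G log-likelihood evaluation on a fixed topology.

Divergence is the uncorrected p-distance with pairwise deletion of
gap/ambiguous columns — the convention behind percent-divergence
statements in COI barcoding work — with Kimura 2-parameter correction
available behind a flag.  The likelihood evaluator implements Felsenstein
pruning under the general time-reversible model with a proportion of
invariable sites and discrete-gamma rate heterogeneity; it evaluates
only — branch-length and parameter optimisation belong to dedicated ML
tree-search software and are out of scope here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .tree import Node, PhyloTree

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "GTRModel",
    "p_distance",
    "k2p_distance",
    "p_distance_matrix",
    "max_intragroup_divergence",
    "nj_tree",
    "discrete_gamma_rates",
    "tree_log_likelihood",
]

# nucleotide encoding: A C G T = 0..3; gap / ambiguity codes >= 4
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "-": 4, "?": 5, "N": 5}


class Alignment:
    """Aligned DNA sequences over {A, C, G, T, -, ?, N} (case-insensitive).

    Rows are stored as a uint8 matrix; anything outside A/C/G/T is treated
    as missing for distance computation and as a fully ambiguous partial
    likelihood in the pruning algorithm.
    """

    def __init__(self, taxa: list[str], rows: list[str]):
        if len(taxa) != len(rows):
            raise ValueError("one row per taxon required")
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxa in alignment")
        if not rows or not rows[0]:
            raise ValueError("alignment must have at least one column")
        width = len(rows[0])
        if any(len(r) != width for r in rows):
            raise ValueError("rows differ in length")
        self.taxa = list(taxa)
        mat = np.empty((len(rows), width), dtype=np.uint8)
        for i, row in enumerate(rows):
            for j, ch in enumerate(row.upper()):
                code = _CODE.get(ch)
                if code is None:
                    code = 5  # unknown IUPAC codes treated as missing
                mat[i, j] = code
        self.matrix = mat
        self._pos = {t: i for i, t in enumerate(taxa)}

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.matrix[self._pos[taxon]]

    def sequence(self, taxon: str) -> str:
        rev = "ACGT-?"
        return "".join(rev[c] if c < 6 else "?" for c in self.row(taxon))

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(self.sequence(t)), id=t, description="")
            for t in self.taxa
        ]
        SeqIO.write(records, str(path), "fasta")

    def to_phylip(self, path) -> None:
        """Relaxed PHYLIP (name, whitespace, sequence)."""
        with open(path, "w") as fh:
            fh.write(f" {self.n_taxa} {self.n_sites}\n")
            for t in self.taxa:
                fh.write(f"{t.replace(' ', '_')}  {self.sequence(t)}\n")


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def p_distance(alignment: Alignment, a: str, b: str) -> float:
    """Uncorrected proportion of differing sites between two rows,
    counting only columns where both symbols are in {A, C, G, T}."""
    ra, rb = alignment.row(a), alignment.row(b)
    comparable = (ra < 4) & (rb < 4)
    n = int(comparable.sum())
    if n == 0:
        raise ValueError(
            f"no comparable columns between {a!r} and {b!r}"
        )
    return float(np.sum(ra[comparable] != rb[comparable]) / n)


def k2p_distance(alignment: Alignment, a: str, b: str) -> float:
    """Kimura 2-parameter distance (optional model-corrected divergence)."""
    ra, rb = alignment.row(a), alignment.row(b)
    comparable = (ra < 4) & (rb < 4)
    n = int(comparable.sum())
    if n == 0:
        raise ValueError(f"no comparable columns between {a!r} and {b!r}")
    x, y = ra[comparable], rb[comparable]
    diff = x != y
    purine = np.isin(x, (0, 2)) == np.isin(y, (0, 2))
    p = float(np.sum(diff & purine) / n)   # transitions (within pur/pyr)
    q = float(np.sum(diff & ~purine) / n)  # transversions
    arg1 = 1 - 2 * p - q
    arg2 = 1 - 2 * q
    if arg1 <= 0 or arg2 <= 0:
        raise ValueError("K2P distance undefined (saturated pair)")
    return float(-0.5 * math.log(arg1) - 0.25 * math.log(arg2))


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative taxon-by-taxon distances, zero diagonal."""

    taxa: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape must match taxa")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be nonnegative")
        self.values = v

    def get(self, a: str, b: str) -> float:
        i, j = self.taxa.index(a), self.taxa.index(b)
        return float(self.values[i, j])

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.values, index=self.taxa, columns=self.taxa
        ).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))


def p_distance_matrix(
    alignment: Alignment, corrected: bool = False
) -> DistanceMatrix:
    dist_fn = k2p_distance if corrected else p_distance
    n = alignment.n_taxa
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = dist_fn(alignment, alignment.taxa[i], alignment.taxa[j])
            out[i, j] = out[j, i] = d
    return DistanceMatrix(list(alignment.taxa), out)


def max_intragroup_divergence(
    alignment: Alignment, group: list[str], corrected: bool = False
) -> float:
    """Maximum pairwise divergence within a group, as a percentage."""
    if len(group) < 2:
        raise ValueError("group must have at least 2 members")
    dist_fn = k2p_distance if corrected else p_distance
    best = 0.0
    for i in range(len(group)):
        for j in range(i + 1, len(group)):
            best = max(best, dist_fn(alignment, group[i], group[j]))
    return best * 100.0


# ---------------------------------------------------------------------------
# Neighbor joining (fixture-tree builder)
# ---------------------------------------------------------------------------


def nj_tree(dist: DistanceMatrix) -> PhyloTree:
    """Neighbor joining with Studier-Keppler branch lengths.

    On an exactly additive matrix the generating unrooted topology and
    branch lengths are recovered (lengths to 1e-9).  Negative branch-length
    estimates are clamped to zero with a warning.  The returned tree has a
    trifurcating root (unrooted convention) for 4+ taxa.
    """
    n = len(dist.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dist.values.astype(float).copy()
    nodes: list[Node] = [Node(t) for t in dist.taxa]
    active = list(range(n))
    clamped = 0

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(Q), Q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        a, b = active[i_], active[j_]
        dab = sub[i_, j_]
        la = 0.5 * dab + (r[i_] - r[j_]) / (2 * (m - 2))
        lb = dab - la
        if la < 0 or lb < 0:
            clamped += 1
            la, lb = max(la, 0.0), max(lb, 0.0)
        new = Node()
        na, nb = nodes[a], nodes[b]
        na.length, nb.length = float(la), float(lb)
        new.add_child(na)
        new.add_child(nb)
        # distances from the new node to every other active node
        rest = [x for x in active if x not in (a, b)]
        dnew = 0.5 * (D[a, rest] + D[b, rest] - dab)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, rest] = dnew
        D[rest, -1] = dnew
        nodes.append(new)
        active = rest + [len(nodes) - 1]

    # final three nodes joined at a trifurcating root
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    lens = [la, lb, lc]
    for idx, val in enumerate(lens):
        if val < 0:
            clamped += 1
            lens[idx] = 0.0
    root = Node()
    for x, ln in zip((a, b, c), lens):
        nodes[x].length = float(ln)
        root.add_child(nodes[x])
    if clamped:
        warnings.warn(
            f"{clamped} negative branch-length estimate(s) clamped to 0",
            stacklevel=2,
        )
    return PhyloTree(root, unrooted_origin=True)


# ---------------------------------------------------------------------------
# GTR+I+G
# ---------------------------------------------------------------------------


def discrete_gamma_rates(shape: float, ncat: int) -> np.ndarray:
    """Mean rates of ``ncat`` equal-probability categories of a
    Gamma(shape, shape) distribution (mean 1), normalised to mean exactly
    1 — the discrete-gamma construction of among-site rate variation."""
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    if ncat < 1:
        raise ValueError("need at least one rate category")
    if ncat == 1:
        return np.ones(1)
    # category boundaries on the Gamma(shape, scale=1/shape) quantile scale
    probs = np.arange(1, ncat) / ncat
    bounds = gamma_dist.ppf(probs, a=shape, scale=1.0 / shape)
    upper = np.concatenate([bounds, [np.inf]])
    lower = np.concatenate([[0.0], bounds])
    # E[X; X in (l, u)] for X ~ Gamma(a, rate a) equals the regularised
    # incomplete-gamma mass of Gamma(a+1, rate a) on the interval
    mass_hi = np.where(
        np.isinf(upper), 1.0, gammainc(shape + 1, shape * upper)
    )
    mass_lo = gammainc(shape + 1, shape * lower)
    rates = ncat * (mass_hi - mass_lo)
    return rates / rates.mean()


@dataclass(frozen=True)
class GTRModel:
    """General time-reversible substitution model with invariable sites
    and discrete-gamma rate heterogeneity.

    ``rates`` are the six exchangeabilities in order (AC, AG, AT, CG, CT,
    GT); ``freqs`` the stationary base frequencies (A, C, G, T).  The rate
    matrix is scaled to one expected substitution per site per unit branch
    length over the variable fraction of sites.
    """

    rates: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    freqs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    p_inv: float = 0.0
    alpha: float = 1.0
    ncat: int = 4

    def __post_init__(self):
        if len(self.rates) != 6 or any(r <= 0 for r in self.rates):
            raise ValueError("need 6 positive exchangeability rates")
        if len(self.freqs) != 4 or any(f <= 0 for f in self.freqs):
            raise ValueError("need 4 positive base frequencies")
        if abs(sum(self.freqs) - 1.0) > 1e-12:
            raise ValueError("base frequencies must sum to 1")
        if not (0 <= self.p_inv < 1):
            raise ValueError("p_inv must lie in [0, 1)")
        if self.alpha <= 0:
            raise ValueError("gamma shape must be positive")
        if self.ncat < 1:
            raise ValueError("ncat must be >= 1")

    def rate_matrix(self) -> np.ndarray:
        """Scaled GTR generator Q (rows sum to 0, mean rate 1)."""
        ac, ag, at, cg, ct, gt = self.rates
        pi = np.asarray(self.freqs)
        S = np.array([
            [0, ac, ag, at],
            [ac, 0, cg, ct],
            [ag, cg, 0, gt],
            [at, ct, gt, 0],
        ], dtype=float)
        Q = S * pi[None, :]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.sum(pi * np.diag(Q))
        return Q / mu

    def _eigen(self):
        pi = np.asarray(self.freqs)
        Q = self.rate_matrix()
        sq = np.sqrt(pi)
        B = (sq[:, None] * Q) / sq[None, :]
        w, U = np.linalg.eigh((B + B.T) / 2)
        return w, U, sq

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows index the ancestral state."""
        if t < 0:
            raise ValueError("branch length must be nonnegative")
        w, U, sq = self._eigen()
        E = U @ np.diag(np.exp(w * t)) @ U.T
        P = (E / sq[:, None]) * sq[None, :]
        return np.clip(P, 0.0, None)

    def gamma_rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.alpha, self.ncat)


def _tip_partials(codes: np.ndarray) -> np.ndarray:
    """(4, nsites) partial-likelihood matrix for one tip: one-hot for
    A/C/G/T, all-ones for gaps and ambiguity codes."""
    nsites = codes.shape[0]
    out = np.ones((4, nsites))
    obs = codes < 4
    out[:, obs] = 0.0
    out[codes[obs], np.nonzero(obs)[0]] = 1.0
    return out


def tree_log_likelihood(
    tree: PhyloTree, alignment: Alignment, model: GTRModel
) -> float:
    """GTR+I+G log-likelihood of an alignment on a fixed tree by
    Felsenstein pruning.

    Per site: ``L = p_inv * L_inv + (1 - p_inv) * mean_c L_c`` where
    ``L_inv`` sums the stationary frequencies of every state compatible
    with all tips at the site (0 if the site is observed variable) and
    ``L_c`` is the pruned likelihood with branch lengths multiplied by the
    c-th discrete-gamma rate.  Gaps and ambiguities contribute all-ones
    partial likelihoods.
    """
    tips = tree.tips()
    missing = [t.label for t in tips if t.label not in alignment._pos]
    if missing:
        raise ValueError(
            "tips absent from alignment: " + ", ".join(sorted(missing)[:5])
        )
    for node in tree.postorder():
        if node.parent is not None and node.length is None:
            raise ValueError("tree must have branch lengths on every branch")

    pi = np.asarray(model.freqs)
    nsites = alignment.n_sites
    rates = model.gamma_rates()
    w, U, sq = model._eigen()

    def pmat(t: float) -> np.ndarray:
        E = U @ (np.exp(w * t)[:, None] * U.T)
        P = (E / sq[:, None]) * sq[None, :]
        return np.clip(P, 0.0, None)

    tip_codes = {t.label: alignment.row(t.label) for t in tips}

    var_lik = np.zeros(nsites)
    for rate in rates:
        partials: dict[int, np.ndarray] = {}
        for node in tree.postorder():
            if node.is_tip:
                part = _tip_partials(tip_codes[node.label])
            else:
                part = np.ones((4, nsites))
                for c in node.children:
                    part *= pmat(rate * c.length) @ partials.pop(c.id)
            partials[node.id] = part
        var_lik += pi @ partials[tree.root.id]
    var_lik /= len(rates)

    if model.p_inv > 0:
        # states compatible with an invariant site: intersection over tips
        compat = np.ones((4, nsites), dtype=bool)
        for codes in tip_codes.values():
            obs = codes < 4
            idx = np.nonzero(obs)[0]
            tipmask = np.ones((4, nsites), dtype=bool)
            tipmask[:, idx] = False
            tipmask[codes[idx], idx] = True
            compat &= tipmask
        inv_lik = pi @ compat
        site_lik = model.p_inv * inv_lik + (1 - model.p_inv) * var_lik
    else:
        site_lik = var_lik
    if np.any(site_lik <= 0):
        raise ValueError("zero site likelihood (numerical underflow)")
    return float(np.sum(np.log(site_lik)))
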