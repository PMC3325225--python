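"""Divergence, neighbor joining, discrete-gamma rates and the GTR+I+G
likelihood evaluator against closed-form and brute-force oracles."""

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import gamma as gamma_dist

from cladetrace import (
    Alignment,
    DistanceMatrix,
    GTRModel,
    discrete_gamma_rates,
    k2p_distance,
    max_intragroup_divergence,
    nj_tree,
    p_distance,
    p_distance_matrix,
    parse_newick,
    random_topology,
    reroot,
    simulate_sequences,
    tree_log_likelihood,
    write_newick,
)
from cladetrace.tree import robinson_foulds_splits
from conftest import brute_force_loglik


class TestAlignment:
    def test_shape_and_errors(self):
        a = Alignment(["x", "y"], ["ACGT", "AC-T"])
        assert a.n_taxa == 2 and a.n_sites == 4
        with pytest.raises(ValueError):
            Alignment(["x", "y"], ["ACGT", "ACG"])
        with pytest.raises(ValueError):
            Alignment(["x", "x"], ["ACGT", "ACGT"])

    def test_fasta_round_trip(self, tmp_path):
        a = Alignment(["sp one", "sp_two"], ["ACGT-N", "ACGTAC"])
        p = tmp_path / "a.fasta"
        a.to_fasta(p)
        back = Alignment.from_fasta(p)
        assert back.n_sites == 6
        assert back.sequence(back.taxa[0]) == "ACGT-?"

    def test_phylip_written(self, tmp_path):
        a = Alignment(["x", "y"], ["ACGT", "ACGA"])
        p = tmp_path / "a.phy"
        a.to_phylip(p)
        head = p.read_text().splitlines()[0].split()
        assert head == ["2", "4"]


class TestPDistance:
    def test_identical_zero(self):
        a = Alignment(["x", "y"], ["ACGTACGT", "ACGTACGT"])
        assert p_distance(a, "x", "y") == 0.0

    def test_one_in_four(self):
        a = Alignment(["x", "y"], ["ACGT", "ACGA"])
        assert p_distance(a, "x", "y") == pytest.approx(0.25)

    def test_gap_columns_excluded(self):
        a = Alignment(["x", "y"], ["AC-T", "ACGT"])
        assert p_distance(a, "x", "y") == 0.0

    def test_no_comparable_columns(self):
        a = Alignment(["x", "y"], ["--AA", "TT--"])
        with pytest.raises(ValueError, match="comparable"):
            p_distance(a, "x", "y")

    def test_symmetry_on_random_alignments(self):
        rng = np.random.default_rng(0)
        letters = np.array(list("ACGT-"))
        rows = ["".join(rng.choice(letters, 60)) for _ in range(6)]
        a = Alignment([f"s{i}" for i in range(6)], rows)
        m = p_distance_matrix(a)
        np.testing.assert_allclose(m.values, m.values.T, atol=1e-12)
        assert np.all(np.diag(m.values) == 0)

    def test_k2p_reduces_towards_p_for_tiny_divergence(self):
        a = Alignment(["x", "y"], ["ACGT" * 100, "ACGT" * 99 + "ACGA"])
        p = p_distance(a, "x", "y")
        k = k2p_distance(a, "x", "y")
        assert k == pytest.approx(p, rel=0.01)


class TestIntragroupDivergence:
    def test_identical_group_zero(self):
        a = Alignment(["a", "b", "c"], ["ACGT"] * 3)
        assert max_intragroup_divergence(a, ["a", "b", "c"]) == 0.0

    def test_six_of_600(self):
        base = "ACGT" * 150
        mutated = "TGCA" + base[4:] + ""
        # 4 diffs of 600 -> worst pair 4/600; craft 6 diffs instead
        s2 = base[:594] + "TGCATG"
        a = Alignment(["a", "b", "c"], [base, base, s2])
        assert max_intragroup_divergence(a, ["a", "b", "c"]) == pytest.approx(
            100 * 6 / 600
        )

    def test_matches_all_pairs_bruteforce(self):
        rng = np.random.default_rng(1)
        letters = np.array(list("ACGT"))
        rows = ["".join(rng.choice(letters, 80)) for _ in range(7)]
        a = Alignment([f"s{i}" for i in range(7)], rows)
        group = [f"s{i}" for i in range(7)]
        expected = max(
            p_distance(a, x, y) * 100
            for i, x in enumerate(group)
            for y in group[i + 1:]
        )
        assert max_intragroup_divergence(a, group) == pytest.approx(expected)

    def test_group_of_one_rejected(self):
        a = Alignment(["a", "b"], ["AC", "AC"])
        with pytest.raises(ValueError):
            max_intragroup_divergence(a, ["a"])


def _additive_matrix(tree):
    labs, d = tree.tip_distance_matrix()
    return DistanceMatrix(labs, d)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float),
        )
        t = nj_tree(d)
        la = t.node("A").length
        lb = t.node("B").length
        lc = t.node("C").length
        assert la == pytest.approx((3 + 4 - 5) / 2)
        assert lb == pytest.approx((3 + 5 - 4) / 2)
        assert lc == pytest.approx((4 + 5 - 3) / 2)

    def test_exact_recovery_quartet(self):
        tree = parse_newick("((A:0.1,B:0.2):0.05,(C:0.3,D:0.4):0.07);")
        rec = nj_tree(_additive_matrix(tree))
        assert robinson_foulds_splits(rec) == robinson_foulds_splits(tree)
        labs, d0 = tree.tip_distance_matrix()
        labs2, d2 = rec.tip_distance_matrix()
        np.testing.assert_allclose(d0, d2, atol=1e-9)

    def test_exact_recovery_random_trees(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            n = int(rng.integers(4, 13))
            tree = random_topology([f"t{i}" for i in range(n)], rng)
            for node in tree.postorder():
                if node.parent is not None:
                    node.length = float(rng.uniform(0.05, 1.0))
            rec = nj_tree(_additive_matrix(tree))
            assert robinson_foulds_splits(rec) == robinson_foulds_splits(
                tree
            )
            labs, d0 = tree.tip_distance_matrix()
            labs2, d2 = rec.tip_distance_matrix()
            assert labs == labs2
            np.testing.assert_allclose(d0, d2, atol=1e-9)

    def test_matches_scikit_bio_topology(self):
        """Independent NJ implementation agrees on noisy (non-additive)
        matrices."""
        import io
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(9)
        for _ in range(10):
            n = 8
            tree = random_topology([f"t{i}" for i in range(n)], rng)
            for node in tree.postorder():
                if node.parent is not None:
                    node.length = float(rng.uniform(0.05, 1.0))
            labs, d = tree.tip_distance_matrix()
            noise = rng.uniform(0, 0.01, size=d.shape)
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0)
            dn = d + noise
            ours = nj_tree(DistanceMatrix(labs, dn))
            theirs = skbio_nj(SkbioDM(dn, ids=labs))
            theirs_nwk = str(theirs).strip()
            theirs_tree = parse_newick(theirs_nwk)
            assert robinson_foulds_splits(ours) == robinson_foulds_splits(
                theirs_tree
            )

    def test_negative_length_clamped_with_warning(self):
        d = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 1, 10], [1, 0, 2], [10, 2, 0]], dtype=float),
        )
        with pytest.warns(UserWarning, match="clamped"):
            t = nj_tree(d)
        assert all((n.length or 0) >= 0 for n in t.postorder())

    def test_nonsymmetric_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(
                ["A", "B"], np.array([[0, 1], [2, 0]], dtype=float)
            )


class TestDiscreteGamma:
    def test_single_category_is_one(self):
        np.testing.assert_allclose(discrete_gamma_rates(0.7, 1), [1.0])

    @pytest.mark.parametrize("alpha", [0.2, 0.54, 1.0, 3.7])
    def test_mean_one(self, alpha):
        r = discrete_gamma_rates(alpha, 4)
        assert r.mean() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(r) > 0)

    def test_matches_quadrature_alpha_054(self):
        """Category means by numerical integration of the gamma density
        (shape 0.54, the COI heterogeneity estimate)."""
        alpha, ncat = 0.54, 4
        edges = gamma_dist.ppf(
            np.arange(ncat + 1) / ncat, a=alpha, scale=1 / alpha
        )
        edges[-1] = np.inf
        expected = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            mass, _ = integrate.quad(
                lambda x: x * gamma_dist.pdf(x, a=alpha, scale=1 / alpha),
                lo,
                min(hi, 1e4),
            )
            expected.append(ncat * mass)
        got = discrete_gamma_rates(alpha, ncat)
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            discrete_gamma_rates(0.0, 4)
        with pytest.raises(ValueError):
            discrete_gamma_rates(1.0, 0)


class TestGTRModel:
    def test_validation(self):
        with pytest.raises(ValueError):
            GTRModel(freqs=(0.5, 0.5, 0.2, -0.2))
        with pytest.raises(ValueError):
            GTRModel(p_inv=1.0)

    def test_rate_matrix_scaled_rows_zero(self):
        m = GTRModel(
            rates=(1, 4, 1, 1, 4, 1), freqs=(0.3, 0.2, 0.2, 0.3)
        )
        Q = m.rate_matrix()
        np.testing.assert_allclose(Q.sum(axis=1), 0, atol=1e-12)
        pi = np.array(m.freqs)
        assert -np.sum(pi * np.diag(Q)) == pytest.approx(1.0)

    def test_transition_matrix_stochastic_and_reversible(self):
        m = GTRModel(
            rates=(1, 4, 2, 1, 5, 1), freqs=(0.28, 0.16, 0.18, 0.38)
        )
        P = m.transition_matrix(0.3)
        np.testing.assert_allclose(P.sum(axis=1), 1, atol=1e-10)
        pi = np.array(m.freqs)
        np.testing.assert_allclose(
            pi[:, None] * P, (pi[:, None] * P).T, atol=1e-10
        )


class TestLikelihood:
    def test_zero_length_identical_pair_is_log_freq(self):
        a = Alignment(["x", "y"], ["G", "G"])
        m = GTRModel(ncat=1)
        t = parse_newick("(x:0.0,y:0.0);")
        assert tree_log_likelihood(t, a, m) == pytest.approx(np.log(0.25))

    def test_jc_closed_form_two_taxa(self):
        """Equal-rate equal-frequency GTR = JC69; pairwise likelihood has
        the 1/4 + 3/4 exp(-4d/3) closed form."""
        a = Alignment(["x", "y"], ["ACGTAC", "ACGAAC"])
        m = GTRModel(ncat=1)
        for bl in (0.02, 0.1, 0.47):
            t = parse_newick(f"(x:{bl / 2},y:{bl / 2});")
            same = 0.25 * (0.25 + 0.75 * np.exp(-4 * bl / 3))
            diff = 0.25 * (0.25 - 0.25 * np.exp(-4 * bl / 3))
            expected = 5 * np.log(same) + 1 * np.log(diff)
            assert tree_log_likelihood(t, a, m) == pytest.approx(
                expected, abs=1e-9
            )

    def test_brute_force_oracle_gtr_ig(self):
        """4-tip tree, 3 sites (with a gap), full GTR+I+G against explicit
        summation over internal states, tip ambiguity and categories."""
        t = parse_newick("((A:0.1,B:0.3):0.15,(C:0.05,D:0.4):0.2);")
        a = Alignment(
            ["A", "B", "C", "D"],
            ["ACG", "AC-", "GCT", "ACT"],
        )
        m = GTRModel(
            rates=(1.0, 3.5, 0.8, 1.2, 4.1, 1.0),
            freqs=(0.28, 0.16, 0.18, 0.38),
            p_inv=0.39,
            alpha=0.54,
            ncat=3,
        )
        assert tree_log_likelihood(t, a, m) == pytest.approx(
            brute_force_loglik(t, a, m), abs=1e-8
        )

    def test_brute_force_oracle_six_tips(self):
        rng = np.random.default_rng(12)
        tree = random_topology([f"t{i}" for i in range(6)], rng)
        for node in tree.postorder():
            if node.parent is not None:
                node.length = float(rng.uniform(0.02, 0.5))
        letters = np.array(list("ACGT"))
        rows = ["".join(rng.choice(letters, 2)) for _ in range(6)]
        a = Alignment([f"t{i}" for i in range(6)], rows)
        m = GTRModel(
            rates=(1, 2, 1, 1, 2, 1),
            freqs=(0.25, 0.25, 0.25, 0.25),
            p_inv=0.2,
            alpha=0.8,
            ncat=2,
        )
        assert tree_log_likelihood(tree, a, m) == pytest.approx(
            brute_force_loglik(tree, a, m), abs=1e-8
        )

    def test_reroot_invariance(self):
        rng = np.random.default_rng(8)
        tree = random_topology([f"t{i}" for i in range(7)], rng)
        for node in tree.postorder():
            if node.parent is not None:
                node.length = float(rng.uniform(0.02, 0.4))
        m = GTRModel(
            rates=(1, 4, 1, 1, 4, 1),
            freqs=(0.3, 0.2, 0.2, 0.3),
            p_inv=0.39,
            alpha=0.54,
        )
        a = simulate_sequences(tree, m, 40, 5)
        base = tree_log_likelihood(tree, a, m)
        for target in ("t0", "t3", "t6"):
            rr = reroot(tree, target)
            assert tree_log_likelihood(rr, a, m) == pytest.approx(
                base, abs=1e-8
            )

    def test_likelihood_drops_under_gross_misparameterisation(self):
        """Sanity slope: the generating parameters beat grossly wrong
        ones on simulated data (not an optimisation claim)."""
        rng = np.random.default_rng(44)
        tree = random_topology([f"t{i}" for i in range(10)], rng)
        for node in tree.postorder():
            if node.parent is not None:
                node.length = float(rng.uniform(0.05, 0.3))
        true = GTRModel(
            rates=(1, 4, 1, 1, 4, 1), freqs=(0.28, 0.16, 0.18, 0.38),
            p_inv=0.3, alpha=0.7,
        )
        a = simulate_sequences(tree, true, 3000, 6)
        good = tree_log_likelihood(tree, a, true)
        stretched = tree.copy()
        for node in stretched.postorder():
            if node.length is not None:
                node.length *= 20.0
        assert good > tree_log_likelihood(stretched, a, true)
        wrong = GTRModel(
            rates=(1, 1, 1, 1, 1, 1), freqs=(0.7, 0.1, 0.1, 0.1),
            p_inv=0.0, alpha=5.0,
        )
        assert good > tree_log_likelihood(tree, a, wrong)

    def test_missing_branch_length_and_taxon(self):
        a = Alignment(["x", "y"], ["AC", "AC"])
        t = parse_newick("(x,y);")
        with pytest.raises(ValueError, match="branch length"):
            tree_log_likelihood(t, a, GTRModel())
        t2 = parse_newick("(x:0.1,z:0.1);")
        with pytest.raises(ValueError, match="absent"):
            tree_log_likelihood(t2, a, GTRModel())
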