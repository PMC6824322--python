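"""Window haplotypes, whitened GLS effects, shared segments, NJ trees."""

import random

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from popgwas import gwas, haplotype as hap, simulate as sim


@pytest.fixture(scope="module")
def window_pop():
    panel = sim.simulate_panel(300, 200, seed=41)
    return sim.sample_population(panel,
                                 sim.PopulationSpec("w", 120, 14), seed=42)


class TestExtractWindow:
    def test_full_window_has_41_snps(self, window_pop):
        lead = ("1", int(window_pop.positions[150]))
        hset = hap.extract_window(window_pop, lead, k=20)
        assert len(hset.positions) == 41
        assert hset.positions[hset.lead_index] == lead[1]
        assert np.array_equal(
            hset.positions, window_pop.positions[130:171])

    def test_truncated_at_chromosome_start(self, window_pop):
        lead = ("1", int(window_pop.positions[5]))
        with pytest.warns(UserWarning, match="truncated"):
            hset = hap.extract_window(window_pop, lead, k=20)
        assert len(hset.positions) == 26

    def test_missing_lead_raises(self, window_pop):
        with pytest.raises(KeyError):
            hap.extract_window(window_pop, ("1", 999_999_999), k=20)

    def test_monomorphic_population_single_haplotype(self, small_panel):
        pop = sim.sample_population(
            small_panel, sim.PopulationSpec("m", 30, 1), seed=1)
        hset = hap.extract_window(pop, ("1", int(pop.positions[60])), k=10)
        assert len(hset.haplotypes) == 1
        assert np.isclose(hset.frequencies[0], 1.0)

    def test_frequencies_sum_to_one(self, window_pop):
        hset = hap.extract_window(
            window_pop, ("1", int(window_pop.positions[100])), k=20)
        assert np.isclose(hset.frequencies.sum(), 1.0)
        # every diplotype entry refers to a known haplotype
        assert hset.diplotypes.max() < len(hset.haplotypes)


def _toy_hset(freq_counts, n_sites=6, seed=0):
    """HaplotypeSet with prescribed haplotype counts over 2n copies."""
    rng = np.random.default_rng(seed)
    haps = []
    while len({h for h in haps}) < len(freq_counts):
        haps = ["".join(map(str, rng.integers(0, 2, n_sites)))
                for _ in range(len(freq_counts))]
    copies = []
    for i, c in enumerate(freq_counts):
        copies += [i] * c
    rng.shuffle(copies)
    copies = np.array(copies).reshape(-1, 2)
    total = sum(freq_counts)
    return hap.HaplotypeSet(
        population="toy", chrom="1",
        positions=np.arange(1, n_sites + 1) * 100, lead_index=n_sites // 2,
        haplotypes=haps, frequencies=np.array(freq_counts) / total,
        diplotypes=copies)


class TestIncidence:
    def test_rare_pooling_is_strict(self):
        # frequencies 0.5/0.3/0.15/0.05: the 0.05 haplotype is pooled
        hset = _toy_hset([20, 12, 6, 2])
        H = hap.build_incidence(hset, min_freq=0.05)
        assert H.H.shape[1] == 4  # 3 retained + 1 rare column
        assert H.has_rare_column
        assert len(H.haplotypes) == 3

    def test_single_haplotype_column_of_twos(self):
        hset = _toy_hset([40])
        H = hap.build_incidence(hset, min_freq=0.05)
        assert H.H.shape == (20, 1)
        assert np.all(H.H == 2)

    def test_row_sums_always_two(self, window_pop):
        hset = hap.extract_window(
            window_pop, ("1", int(window_pop.positions[80])), k=20)
        H = hap.build_incidence(hset, 0.05)
        assert np.all(H.H.sum(axis=1) == 2)


class TestHaplotypeEffects:
    def _fixture(self, seed, n=40):
        rng = np.random.default_rng(seed)
        hset = _toy_hset([int(c) for c in
                          rng.multinomial(2 * n, [0.35, 0.3, 0.2, 0.15])],
                         seed=seed)
        counts = np.zeros((hset.n, len(hset.haplotypes)), int)
        for i, (a, b) in enumerate(hset.diplotypes):
            counts[i, a] += 1
            counts[i, b] += 1
        H = hap.HaplotypeIncidence(H=counts, haplotypes=hset.haplotypes,
                                   frequencies=hset.frequencies,
                                   has_rare_column=False)
        A = rng.standard_normal((hset.n, hset.n))
        G = gwas.GRM(matrix=A @ A.T / hset.n, n_markers=hset.n)
        y = rng.standard_normal(hset.n)
        vc = gwas.VarianceComponents(0.6, 0.4, 0.4 / 0.6, 0.6, 0.0)
        return y, H, vc, G

    def test_sigma_a_zero_reduces_to_ols(self):
        y, H, _, G = self._fixture(1)
        vc = gwas.VarianceComponents(0.0, 1.0, np.inf, 0.0, 0.0)
        eff = hap.estimate_haplotype_effects(y, H, vc, G)
        X = np.column_stack([np.ones(len(y)), H.H[:, 1:]])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(eff["beta"].to_numpy()[1:], beta[1:], atol=1e-8)

    def test_matches_dense_gls_oracle(self):
        y, H, vc, G = self._fixture(2)
        eff = hap.estimate_haplotype_effects(y, H, vc, G)
        n = len(y)
        V = vc.sigma_a2 * G.matrix + vc.sigma_e2 * np.eye(n)
        Vi = np.linalg.inv(V)
        X = np.column_stack([np.ones(n), H.H[:, 1:]])
        cov = np.linalg.inv(X.T @ Vi @ X)
        b = cov @ X.T @ Vi @ y
        assert np.allclose(eff["beta"].to_numpy()[1:], b[1:], rtol=1e-8)
        assert np.allclose(eff["se"].to_numpy()[1:],
                           np.sqrt(np.diag(cov))[1:]
                           * np.sqrt((y - X @ b) @ Vi @ (y - X @ b)
                                     / (n - X.shape[1])),
                           rtol=1e-8)

    def test_column_order_invariance(self):
        y, H, vc, G = self._fixture(3)
        eff1 = hap.estimate_haplotype_effects(y, H, vc, G)
        perm = [0, 2, 1, 3]  # keep reference first
        H2 = hap.HaplotypeIncidence(
            H=H.H[:, perm], haplotypes=[H.haplotypes[i] for i in perm],
            frequencies=H.frequencies[perm], has_rare_column=False)
        eff2 = hap.estimate_haplotype_effects(y, H2, vc, G)
        m1 = dict(zip(eff1["haplotype"], eff1["beta"]))
        m2 = dict(zip(eff2["haplotype"], eff2["beta"]))
        for k in m1:
            assert np.isclose(m1[k], m2[k], atol=1e-10)

    def test_reference_has_zero_beta_and_centered_test(self):
        y, H, vc, G = self._fixture(4)
        eff = hap.estimate_haplotype_effects(y, H, vc, G)
        ref = eff[eff["is_reference"]].iloc[0]
        assert ref["beta"] == 0.0 and np.isnan(ref["se"])
        assert np.isfinite(ref["beta_centered"])
        assert ref["se_centered"] > 0
        # centered effects are frequency-weighted deviations: their
        # weighted mean is zero
        w = eff["frequency"] / eff["frequency"].sum()
        assert abs((w * eff["beta_centered"]).sum()) < 1e-10


class TestWhitening:
    def test_whitened_noise_has_identity_covariance(self):
        rng = np.random.default_rng(7)
        n = 12
        A = rng.standard_normal((n, n))
        G = gwas.GRM(matrix=A @ A.T / n, n_markers=n)
        vc = gwas.VarianceComponents(0.7, 0.3, 0.3 / 0.7, 0.7, 0.0)
        Winv = hap.whitener(vc, G)
        V = vc.sigma_a2 * G.matrix + vc.sigma_e2 * np.eye(n)
        assert np.allclose(Winv @ V @ Winv.T, np.eye(n), atol=1e-6)
        # Monte Carlo: 500 draws of Zu+e whiten to identity covariance
        lam, U = G.eig
        draws = np.empty((500, n))
        for i in range(500):
            u = U @ (np.sqrt(vc.sigma_a2 * lam) * rng.standard_normal(n))
            e = np.sqrt(vc.sigma_e2) * rng.standard_normal(n)
            draws[i] = Winv @ (u + e)
        emp = np.cov(draws.T)
        assert np.abs(emp - np.eye(n)).max() < 0.25  # sampling error bound


class TestSharedSegment:
    def test_identical_haplotypes_whole_window(self):
        pos = np.arange(1, 11) * 50
        out = hap.shared_segment(["0110011010"] * 3, pos)
        assert out == (50, 500)

    def test_constructed_run_matches_enumeration(self):
        pos = np.arange(1, 11) * 100
        h1 = "0001111000"
        h2 = "1101111011"
        h3 = "0101111010"  # all three agree exactly at indices 2..7
        out = hap.shared_segment([h1, h2, h3], pos)
        assert out == (300, 800)

    def test_disagreement_everywhere_is_none(self):
        pos = np.array([10, 20, 30])
        assert hap.shared_segment(["000", "111"], pos) is None

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            hap.shared_segment([], np.array([]))

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_maximal_and_contiguous_vs_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        L = 15
        haps = ["".join(map(str, rng.integers(0, 2, L))) for _ in range(3)]
        pos = np.cumsum(rng.integers(1, 100, L))
        out = hap.shared_segment(haps, pos)
        # brute force over all intervals
        def all_agree(i, j):
            return all(h[i:j + 1] == haps[0][i:j + 1] for h in haps)
        best = None
        for i in range(L):
            for j in range(i, L):
                if all_agree(i, j):
                    if best is None or (j - i) > (best[1] - best[0]):
                        best = (i, j)
        if best is None:
            assert out is None
        else:
            assert out == (int(pos[best[0]]), int(pos[best[1]]))


class TestClassifySharing:
    def test_specific(self):
        f = {"A": 0.3, "B": 0.0, "C": 0.005}
        assert hap.classify_sharing(f, 0.05, 0.01) == "specific"

    def test_shared(self):
        assert hap.classify_sharing({"A": 0.2, "B": 0.25}, 0.05,
                                    0.01) == "shared"

    def test_absent(self):
        assert hap.classify_sharing({"A": 0.03, "B": 0.03}, 0.05,
                                    0.01) == "absent"

    def test_present_once_but_leaky_elsewhere_is_not_specific(self):
        f = {"A": 0.3, "B": 0.03}
        assert hap.classify_sharing(f, 0.05, 0.01) == "absent"

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            hap.classify_sharing({"A": 0.5}, 0.01, 0.05)


class TestHamming:
    def test_identical_zero(self):
        D = hap.hamming_distance_matrix(["0101", "0101"])
        assert np.all(D == 0)

    def test_complementary_full_length(self):
        D = hap.hamming_distance_matrix(["0101", "1010"])
        assert D[0, 1] == 4

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            hap.hamming_distance_matrix(["01", "011"])

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_matches_positionwise_loop(self, seed):
        rng = np.random.default_rng(seed)
        haps = ["".join(map(str, rng.integers(0, 2, 20)))
                for _ in range(4)]
        D = hap.hamming_distance_matrix(haps)
        for i in range(4):
            for j in range(4):
                expected = sum(a != b for a, b in zip(haps[i], haps[j]))
                assert D[i, j] == expected


def _random_additive_tree(seed, n_taxa=6):
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_taxa)])
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa,
        taxon_namespace=taxa, rng=random.Random(seed))
    rng = np.random.default_rng(seed)
    for e in tree.edges():
        if e.length is not None:
            e.length = float(rng.uniform(0.1, 1.0))
    labels = [t.label for t in taxa]
    pdm = tree.phylogenetic_distance_matrix()
    D = np.array([[pdm.distance(taxa.get_taxon(a), taxa.get_taxon(b))
                   for b in labels] for a in labels])
    return tree, taxa, labels, D


class TestNeighborJoining:
    def test_two_taxa_edge_sums_to_distance(self):
        nwk = hap.neighbor_joining(np.array([[0.0, 3.0], [3.0, 0.0]]),
                                   ["a", "b"])
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert np.isclose(tree.length(), 3.0)

    def test_three_taxa_closed_form(self):
        D = np.array([[0.0, 5.0, 9.0], [5.0, 0.0, 8.0], [9.0, 8.0, 0.0]])
        nwk = hap.neighbor_joining(D, ["a", "b", "c"])
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        lengths = {leaf.taxon.label: leaf.edge.length
                   for leaf in tree.leaf_node_iter()}
        assert np.isclose(lengths["a"], (5 + 9 - 8) / 2)
        assert np.isclose(lengths["b"], (5 + 8 - 9) / 2)
        assert np.isclose(lengths["c"], (9 + 8 - 5) / 2)

    def test_additive_distances_recover_tree_exactly(self):
        tree, taxa, labels, D = _random_additive_tree(5)
        nwk = hap.neighbor_joining(D, labels)
        mine = dendropy.Tree.get(data=nwk, schema="newick",
                                 taxon_namespace=taxa)
        for t in (tree, mine):
            t.is_rooted = False
            t.deroot()
            t.encode_bipartitions()
        rf = dendropy.calculate.treecompare.symmetric_difference(tree, mine)
        assert rf == 0
        pdm = mine.phylogenetic_distance_matrix()
        D2 = np.array([[pdm.distance(taxa.get_taxon(a), taxa.get_taxon(b))
                        for b in labels] for a in labels])
        assert np.abs(D - D2).max() < 1e-8

    def test_agrees_with_skbio_on_random_matrix(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(9)
        n = 7
        A = rng.uniform(1, 10, size=(n, n))
        D = (A + A.T) / 2
        np.fill_diagonal(D, 0.0)
        labels = [f"x{i}" for i in range(n)]
        nwk = hap.neighbor_joining(D, labels)
        ref = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
        taxa = dendropy.TaxonNamespace(labels)
        mine = dendropy.Tree.get(data=nwk, schema="newick",
                                 taxon_namespace=taxa)
        other = dendropy.Tree.get(data=str(ref), schema="newick",
                                  taxon_namespace=taxa)
        for t in (mine, other):
            t.is_rooted = False
            t.deroot()
            t.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(
            mine, other) == 0

    def test_negative_lengths_clamped_with_warning(self):
        # a blatantly non-additive matrix that forces a negative branch
        D = np.array([[0.0, 1.0, 9.0, 9.0],
                      [1.0, 0.0, 9.0, 9.0],
                      [9.0, 9.0, 0.0, 0.1],
                      [9.0, 9.0, 0.1, 0.0]])
        nwk = hap.neighbor_joining(D, list("abcd"))
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert all((e.length or 0) >= 0 for e in tree.edges())

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            hap.neighbor_joining(np.zeros((1, 1)), ["a"])
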