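import itertools
import math

import numpy as np
import pytest

from mhcdivkit.io_core import DistanceMatrix, FrequencySpectrum, PopulationSample, ValidationError
from mhcdivkit.population_structure import (
    bootstrap_support,
    da_distance,
    da_matrix,
    mds_from_distances,
    nj_tree,
    pca_frequencies,
    tree_bipartitions,
    wc_fst,
    wc_theta_pair,
)

from conftest import hw_sample


class TestWeirCockerhamTheta:
    def test_fixed_alternate_alleles_give_theta_one(self):
        pa = PopulationSample("A", [("x", "x")] * 10)
        pb = PopulationSample("B", [("y", "y")] * 10)
        assert wc_theta_pair(pa, pb) == pytest.approx(1.0)

    def test_null_theta_mean_near_zero(self):
        """Two samples from one spectrum: mean θ̂ within ±0.01 of 0."""
        rng = np.random.default_rng(42)
        freqs = np.array([0.4, 0.3, 0.2, 0.1])
        names = ["a", "b", "c", "d"]
        thetas = []
        for _ in range(500):
            pa = hw_sample("A", freqs, names, 500, rng)
            pb = hw_sample("B", freqs, names, 500, rng)
            try:
                thetas.append(wc_theta_pair(pa, pb))
            except ValidationError:
                continue
        assert abs(np.mean(thetas)) < 0.01

    def test_hand_computed_variance_components(self):
        """Two 2-allele populations, fully specified genotypes.

        Pop1 (n=4): AA, AA, AB, BB -> p1 = 5/8, h1(A) = h1(B) = 1/4.
        Pop2 (n=3): AB, BB, BB    -> p2 = 1/6, h2(A) = h2(B) = 1/3.
        Components transcribed step by step from the 1984 variance-component
        definitions and evaluated by hand below (allele A; allele B mirrors
        it with p -> 1−p, so Σa/Σ(a+b+c) equals the single-allele ratio).
        """
        n1, n2, r = 4.0, 3.0, 2.0
        p1, p2 = 5 / 8, 1 / 6
        h1, h2 = 1 / 4, 1 / 3
        n_bar = (n1 + n2) / 2
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
        expected = a / (a + b + c)

        pa = PopulationSample("P1", [("A", "A"), ("A", "A"), ("A", "B"), ("B", "B")])
        pb = PopulationSample("P2", [("A", "B"), ("B", "B"), ("B", "B")])
        assert wc_theta_pair(pa, pb) == pytest.approx(expected, abs=1e-12)

    def test_theta_invariant_to_allele_relabeling(self):
        rng = np.random.default_rng(1)
        pa = hw_sample("A", [0.5, 0.3, 0.2], ["x", "y", "z"], 30, rng)
        pb = hw_sample("B", [0.2, 0.3, 0.5], ["x", "y", "z"], 30, rng)
        relabel = {"x": "z2", "y": "a1", "z": "m5"}
        pa2 = PopulationSample("A", [(relabel[a], relabel[b]) for a, b in pa.genotypes])
        pb2 = PopulationSample("B", [(relabel[a], relabel[b]) for a, b in pb.genotypes])
        assert wc_theta_pair(pa, pb) == pytest.approx(wc_theta_pair(pa2, pb2))

    def test_overall_and_pairwise_structure_result(self):
        rng = np.random.default_rng(2)
        samples = [
            hw_sample(lbl, rng.dirichlet(np.ones(4)), ["a", "b", "c", "d"], 30, rng)
            for lbl in ("P1", "P2", "P3")
        ]
        res = wc_fst(samples)
        assert res.pairwise_fst.labels == ["P1", "P2", "P3"]
        np.testing.assert_allclose(res.pairwise_fst.values, res.pairwise_fst.values.T)
        assert res.pairwise_fst[("P1", "P2")] == pytest.approx(
            wc_theta_pair(samples[0], samples[1])
        )

    def test_jointly_monomorphic_is_error(self):
        pa = PopulationSample("A", [("x", "x")] * 5)
        pb = PopulationSample("B", [("x", "x")] * 5)
        with pytest.raises(ValidationError, match="monomorphic"):
            wc_theta_pair(pa, pb)


class TestDaDistance:
    def test_identical_spectra_give_zero(self):
        sp = FrequencySpectrum("p", {"a": 0.6, "b": 0.4}, gene_copies=10)
        assert da_distance(sp, sp) == pytest.approx(0.0)

    def test_disjoint_allele_sets_give_one(self):
        sp1 = FrequencySpectrum("p", {"a": 1.0}, gene_copies=10)
        sp2 = FrequencySpectrum("q", {"b": 1.0}, gene_copies=10)
        assert da_distance(sp1, sp2) == 1.0

    def test_half_overlap_closed_form(self):
        sp1 = FrequencySpectrum("p", {"a": 0.5, "b": 0.5}, gene_copies=10)
        sp2 = FrequencySpectrum("q", {"a": 1.0}, gene_copies=10)
        assert da_distance(sp1, sp2) == pytest.approx(1 - math.sqrt(0.5))

    def test_bounds_and_zero_iff_identical(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            f1 = rng.dirichlet(np.ones(5))
            f2 = rng.dirichlet(np.ones(5))
            sp1 = FrequencySpectrum("p", dict(zip("abcde", f1)), gene_copies=10)
            sp2 = FrequencySpectrum("q", dict(zip("abcde", f2)), gene_copies=10)
            d = da_distance(sp1, sp2)
            assert -1e-12 <= d <= 1.0
        assert da_distance(sp1, sp1) < 1e-12


def random_additive_tree(n_taxa, rng):
    """Random binary tree with positive branch lengths; returns its exact
    path-length (additive) matrix, built by merging clusters and recording
    leaf-to-cluster-root distances."""
    d = np.zeros((n_taxa, n_taxa))
    clusters = [{i: 0.0} for i in range(n_taxa)]  # leaf -> distance to root
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        a, b = clusters[i], clusters[j]
        la, lb = rng.uniform(0.1, 2.0, size=2)
        for x, dx in a.items():
            for y, dy in b.items():
                d[x, y] = d[y, x] = dx + la + dy + lb
        merged = {**{x: dx + la for x, dx in a.items()},
                  **{y: dy + lb for y, dy in b.items()}}
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return d


class TestNeighborJoining:
    def tree_path_matrix(self, tree, labels):
        tips = {t.name: t for t in tree.tips()}
        k = len(labels)
        out = np.zeros((k, k))
        for i, j in itertools.combinations(range(k), 2):
            out[i, j] = out[j, i] = tips[labels[i]].distance(tips[labels[j]])
        return out

    def test_recovers_known_quartet(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive matrix
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        dm = DistanceMatrix(list("ABCD"), d)
        tree = nj_tree(dm)
        np.testing.assert_allclose(
            self.tree_path_matrix(tree, list("ABCD")), d, atol=1e-9
        )
        splits = tree_bipartitions(tree, frozenset("ABCD"))
        assert frozenset("AB") in splits or frozenset("CD") in splits

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(list("ABC"), d))
        tips = {t.name: t.length for t in tree.tips()}
        assert tips["A"] == pytest.approx(0.5 * (3 + 4 - 5))
        assert tips["B"] == pytest.approx(0.5 * (3 + 5 - 4))
        assert tips["C"] == pytest.approx(0.5 * (4 + 5 - 3))

    def test_recovers_random_additive_trees(self):
        """NJ must reproduce the path-length matrix of random additive trees
        (≤8 taxa) to 1e-9 — the four-point condition oracle."""
        rng = np.random.default_rng(7)
        for rep in range(20):
            n = int(rng.integers(4, 9))
            d = random_additive_tree(n, rng)
            labels = [f"t{i}" for i in range(n)]
            tree = nj_tree(DistanceMatrix(labels, d))
            np.testing.assert_allclose(
                self.tree_path_matrix(tree, labels), d, atol=1e-9
            )

    def test_matches_skbio_on_additive_matrix(self):
        import skbio

        rng = np.random.default_rng(9)
        d = random_additive_tree(6, rng)
        labels = [f"t{i}" for i in range(6)]
        ours = nj_tree(DistanceMatrix(labels, d))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(d, labels))
        assert ours.compare_rfd(theirs) == 0.0

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValidationError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]])))

    def test_ultrametric_tie_case_has_zero_internal_branch(self):
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        tree = nj_tree(DistanceMatrix(list("ABCD"), d))
        internal = [n.length for n in tree.non_tips(include_self=False)]
        assert internal and min(internal) == pytest.approx(0.0, abs=1e-12)


class TestBootstrapSupport:
    def fixed_samples(self):
        return [
            PopulationSample("P1", [("a", "a")] * 10),
            PopulationSample("P2", [("b", "b")] * 10),
            PopulationSample("P3", [("c", "c")] * 10),
            PopulationSample("P4", [("d", "d")] * 10),
        ]

    def test_disjoint_fixed_populations_have_full_support(self):
        tree, support = bootstrap_support(self.fixed_samples(), reps=200, seed=0)
        assert support and all(v == 100.0 for v in support.values())

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        samples = [
            hw_sample(lbl, rng.dirichlet(np.ones(3)), ["a", "b", "c"], 20, rng)
            for lbl in ("P1", "P2", "P3", "P4")
        ]
        _, s1 = bootstrap_support(samples, reps=150, seed=9)
        _, s2 = bootstrap_support(samples, reps=150, seed=9)
        assert s1 == s2

    def test_interchangeable_pair_vs_distinct_pair(self):
        """Two populations sharing one spectrum and two fixed distinct ones:
        the split separating the distinct pair from the twins is certain."""
        rng = np.random.default_rng(6)
        twin_freqs = [0.5, 0.5, 0.0, 0.0]
        names = ["a", "b", "x", "y"]
        samples = [
            hw_sample("T1", twin_freqs, names, 40, rng),
            hw_sample("T2", twin_freqs, names, 40, rng),
            PopulationSample("F1", [("x", "x")] * 40),
            PopulationSample("F2", [("y", "y")] * 40),
        ]
        _, support = bootstrap_support(samples, reps=200, seed=3)
        key = frozenset({"T1", "T2"})
        if key in support:
            assert support[key] > 95.0

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValidationError, match="reps"):
            bootstrap_support(self.fixed_samples(), reps=50)


class TestMds:
    def test_three_equidistant_points_embed_exactly(self):
        d = np.full((3, 3), 1.0)
        np.fill_diagonal(d, 0.0)
        res = mds_from_distances(DistanceMatrix(list("abc"), d), k=2)
        assert res.rsq == pytest.approx(1.0)
        emb = res.coordinates
        for i, j in itertools.combinations(range(3), 2):
            assert np.linalg.norm(emb[i] - emb[j]) == pytest.approx(1.0, abs=1e-9)

    def test_planar_configuration_recovered(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(6, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        res = mds_from_distances(DistanceMatrix([f"p{i}" for i in range(6)], d), k=2)
        assert res.rsq == pytest.approx(1.0, abs=1e-12)
        emb = res.coordinates
        d_emb = np.sqrt(((emb[:, None] - emb[None, :]) ** 2).sum(-1))
        np.testing.assert_allclose(d_emb, d, atol=1e-9)

    def test_matches_skbio_pcoa_distances(self):
        from skbio.stats.ordination import pcoa

        rng = np.random.default_rng(10)
        pts = rng.normal(size=(5, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        res = mds_from_distances(DistanceMatrix([f"p{i}" for i in range(5)], d), k=2)
        import skbio as sk

        ref = pcoa(sk.DistanceMatrix(d, [f"p{i}" for i in range(5)]), number_of_dimensions=2)
        ref_coords = ref.samples.to_numpy()
        d_ref = np.sqrt(((ref_coords[:, None] - ref_coords[None, :]) ** 2).sum(-1))
        d_ours = np.sqrt(
            ((res.coordinates[:, None] - res.coordinates[None, :]) ** 2).sum(-1)
        )
        np.testing.assert_allclose(d_ours, d_ref, atol=1e-8)

    def test_noise_degrades_rsq_monotonically_in_expectation(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(8, 2))
        d0 = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        labels = [f"p{i}" for i in range(8)]
        mean_rsq = []
        for noise in (0.0, 0.3, 1.0):
            vals = []
            for rep in range(20):
                e = rng.normal(scale=noise, size=d0.shape)
                e = np.abs(e + e.T) / 2
                np.fill_diagonal(e, 0.0)
                vals.append(
                    mds_from_distances(DistanceMatrix(labels, d0 + e), k=2).rsq
                )
            mean_rsq.append(np.mean(vals))
        assert mean_rsq[0] > mean_rsq[1] > mean_rsq[2]

    def test_rank_deficit_flagged_and_zero_padded(self):
        # two points: 1-D geometry, second axis must be zero
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        res = mds_from_distances(DistanceMatrix(["a", "b"], d), k=2)
        assert res.rank_deficient
        np.testing.assert_allclose(res.coordinates[:, 1], 0.0)


class TestPcaFrequencies:
    def test_two_populations_single_component_along_difference(self):
        sp1 = FrequencySpectrum("p", {"a": 0.7, "b": 0.3}, gene_copies=10)
        sp2 = FrequencySpectrum("q", {"a": 0.3, "b": 0.7}, gene_copies=10)
        res = pca_frequencies([sp1, sp2])
        assert res.explained_variance[0] > 1e-12
        assert all(v < 1e-20 for v in res.explained_variance[1:])
        load = res.loadings["PC1"].to_numpy()
        diff = np.array([0.4, -0.4])
        cos = abs(load @ diff) / (np.linalg.norm(load) * np.linalg.norm(diff))
        assert cos == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_rows_add_no_variance(self):
        rng = np.random.default_rng(12)
        base = [
            FrequencySpectrum(f"p{i}", dict(zip("abcd", rng.dirichlet(np.ones(4)))), 10)
            for i in range(3)
        ]
        dup = base + [
            FrequencySpectrum("p0copy", base[0].frequencies, 10),
        ]
        ev_base = pca_frequencies(base).explained_variance
        ev_dup = pca_frequencies(dup).explained_variance
        assert np.count_nonzero(ev_base > 1e-18) == np.count_nonzero(ev_dup > 1e-18)

    def test_score_distances_equal_centered_row_distances(self):
        rng = np.random.default_rng(13)
        spectra = [
            FrequencySpectrum(f"p{i}", dict(zip("abcdef", rng.dirichlet(np.ones(6)))), 10)
            for i in range(5)
        ]
        res = pca_frequencies(spectra)
        x = np.array(
            [[sp.frequencies.get(a, 0.0) for a in sorted("abcdef")] for sp in spectra]
        )
        xc = x - x.mean(axis=0)
        d_rows = np.sqrt(((xc[:, None] - xc[None, :]) ** 2).sum(-1))
        s = res.coordinates
        d_scores = np.sqrt(((s[:, None] - s[None, :]) ** 2).sum(-1))
        np.testing.assert_allclose(d_scores, d_rows, atol=1e-9)

    def test_single_population_rejected(self):
        sp = FrequencySpectrum("p", {"a": 1.0}, gene_copies=10)
        with pytest.raises(ValidationError):
            pca_frequencies([sp])
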