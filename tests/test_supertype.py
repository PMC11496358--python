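import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from mhcdepth import (
    ZEncoding,
    assign_supertypes,
    dapc,
    extract_pbr,
    find_k,
    load_zscales,
    optim_a_score,
    translate_alleles,
    z_encode,
)


def blob_encoding(k, n_per=10, sigma=0.1, sep=10.0, dims=30, seed=0):
    """Synthetic alleles drawn from k well-separated latent centroids."""
    rng = np.random.default_rng(seed)
    centers = rng.normal(0, sep, size=(k, dims))
    rows, truth = [], []
    for c in range(k):
        rows.append(centers[c] + rng.normal(0, sigma, size=(n_per, dims)))
        truth.extend([c] * n_per)
    X = np.vstack(rows)
    labels = [f"A{i}" for i in range(len(X))]
    z = ZEncoding(labels, X, [f"p{i}" for i in range(dims // 5)])
    return z, np.array(truth)


class TestZScales:
    def test_table_shape_and_alanine_row(self):
        z = load_zscales()
        assert sorted(z.index) == sorted("ACDEFGHIKLMNPQRSTVWY")
        assert z.shape == (20, 5)
        assert z.loc["A"].tolist() == pytest.approx([0.24, -2.32, 0.60, -0.14, 1.30])

    def test_z_encode_rows(self):
        residues = pd.DataFrame([["A"], ["A"], ["W"]], index=["x", "y", "z"],
                                columns=["p1"])
        enc = z_encode(residues)
        assert enc.matrix.shape == (3, 5)
        assert np.array_equal(enc.matrix[0], enc.matrix[1])
        assert enc.matrix[2] == pytest.approx([-4.36, 3.94, 0.59, 3.44, -1.59])

    def test_non_standard_residue_errors(self):
        residues = pd.DataFrame([["X"]], index=["bad"], columns=["p1"])
        with pytest.raises(ValueError, match="non-standard"):
            z_encode(residues)


class TestExtractPbr:
    def test_positions(self):
        out = extract_pbr({"a": "MKV"}, [1, 3])
        assert out.loc["a"].tolist() == ["M", "V"]

    def test_stop_codon_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="stop"):
            out = extract_pbr({"a": "M*V", "b": "MKV"}, [1, 2])
        assert list(out.index) == ["b"]

    def test_empty_positions_error(self):
        with pytest.raises(ValueError):
            extract_pbr({"a": "MKV"}, [])

    def test_out_of_range_error(self):
        with pytest.raises(ValueError, match="out of range"):
            extract_pbr({"a": "MKV"}, [4])

    def test_translate_minus_strand(self):
        # plus-strand genomic CAT -> revcomp ATG -> Met
        assert translate_alleles({"a": "CAT"}, strand="-")["a"] == "M"


class TestFindK:
    def test_three_blobs_recovered(self):
        z, _ = blob_encoding(3, seed=1)
        sel = find_k(z, n_pca=10, max_k=8, n_replicates=20, n_starts=10, seed=2)
        assert sel.k == 3
        frac = sel.argmin_counts.get(3, 0) / sum(sel.argmin_counts.values())
        assert frac >= 0.95

    def test_identical_alleles_give_k_one(self):
        # one point mass (all alleles identical at the PBR) admits only k=1
        z, _ = blob_encoding(1, n_per=30, sigma=0.0, seed=3)
        sel = find_k(z, n_pca=10, max_k=6, n_replicates=10, n_starts=10, seed=4)
        assert sel.k == 1

    def test_single_diffuse_blob_finds_no_deep_structure(self):
        # with a genuine Gaussian cloud the log-WSS BIC always pays for a
        # couple of noise splits; absence of structure shows as a small k
        z, _ = blob_encoding(1, n_per=30, seed=3)
        sel = find_k(z, n_pca=10, max_k=8, n_replicates=10, n_starts=10, seed=4)
        assert sel.k <= 3

    def test_same_seed_identical_trace(self):
        z, _ = blob_encoding(3, seed=5)
        a = find_k(z, n_pca=10, max_k=6, n_replicates=5, n_starts=5, seed=9)
        b = find_k(z, n_pca=10, max_k=6, n_replicates=5, n_starts=5, seed=9)
        assert np.array_equal(a.bic_trace.values, b.bic_trace.values)
        assert a.k == b.k

    def test_max_k_reduced_with_warning(self):
        z, _ = blob_encoding(2, n_per=3, seed=6)
        with pytest.warns(UserWarning, match="reducing"):
            sel = find_k(z, n_pca=5, max_k=10, n_replicates=3, n_starts=3, seed=1)
        assert sel.k <= 5


class TestDapc:
    def test_separated_clusters_confident_posteriors(self):
        z, truth = blob_encoding(3, seed=7)
        model = dapc(z, truth, n_pca=10)
        own = model.posteriors.values[np.arange(z.n), truth]
        assert own.min() > 0.99
        assert model.discriminants.shape == (z.n, 2)  # all k-1 functions

    def test_label_permutation_invariance(self):
        z, truth = blob_encoding(3, seed=8)
        relabel = np.array([2, 0, 1])[truth]
        m1 = dapc(z, truth, n_pca=10)
        m2 = dapc(z, relabel, n_pca=10)
        assert adjusted_rand_score(m1.clusters, m2.clusters) == pytest.approx(1.0)

    def test_invalid_n_pca(self):
        z, truth = blob_encoding(2, seed=9)
        with pytest.raises(ValueError):
            dapc(z, truth, n_pca=0)

    def test_single_cluster_degenerate(self):
        z, _ = blob_encoding(1, seed=10)
        model = dapc(z, np.zeros(z.n, dtype=int), n_pca=5)
        assert model.k == 1 and model.discriminants is None
        assert (model.posteriors.values == 1.0).all()

    def test_input_order_invariance(self):
        z, truth = blob_encoding(3, seed=11)
        perm = np.random.default_rng(0).permutation(z.n)
        z_perm = ZEncoding(
            [z.labels[i] for i in perm], z.matrix[perm], z.pbr_positions
        )
        m1 = dapc(z, truth, n_pca=10)
        m2 = dapc(z_perm, truth[perm], n_pca=10)
        back = np.argsort(perm)
        assert adjusted_rand_score(m1.clusters, m2.clusters[back]) == pytest.approx(1.0)


class TestAScore:
    def test_noise_scores_near_zero(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(24, 20))
        z = ZEncoding([f"A{i}" for i in range(24)], X, [f"p{i}" for i in range(4)])
        clusters = rng.integers(0, 3, 24)
        res = optim_a_score(z, clusters, pc_candidates=[2, 5, 8], n_sim=10, seed=1)
        assert all(abs(v) < 0.35 for v in res["a_scores"].values())

    def test_separable_data_high_score(self):
        # ceiling for k balanced clusters is 1 - 1/k (here 2/3): observed
        # reassignment is 1, the permutation null cannot drop below chance
        z, truth = blob_encoding(3, seed=13)
        res = optim_a_score(z, truth, pc_candidates=[2, 4], n_sim=5, seed=2)
        assert max(res["a_scores"].values()) > 0.45

    def test_deterministic_given_seed(self):
        z, truth = blob_encoding(3, seed=14)
        a = optim_a_score(z, truth, pc_candidates=[2, 4], n_sim=5, seed=3)
        b = optim_a_score(z, truth, pc_candidates=[2, 4], n_sim=5, seed=3)
        assert a == b


class TestAssignSupertypes:
    def test_profiles_counted(self):
        z, truth = blob_encoding(2, n_per=2, seed=15)
        model = dapc(z, truth, n_pca=3)
        st_of = model.assignment()
        two_same = [l for l in z.labels if st_of[l] == st_of[z.labels[0]]][:2]
        _, profiles, _ = assign_supertypes(model, {"K1": two_same})
        assert profiles.loc["K1"].sum() == 2
        assert profiles.loc["K1"].max() == 2  # both alleles in one supertype

    def test_missing_allele_errors(self):
        z, truth = blob_encoding(2, n_per=2, seed=16)
        model = dapc(z, truth, n_pca=3)
        with pytest.raises(KeyError):
            assign_supertypes(model, {"K1": ["nope"]})

    def test_latent_centroid_recovery_ari(self):
        z, truth = blob_encoding(4, n_per=8, seed=17)
        sel = find_k(z, n_pca=10, max_k=8, n_replicates=10, n_starts=10, seed=18)
        model = dapc(z, sel.cluster_labels, n_pca=10)
        assert adjusted_rand_score(truth, model.clusters) > 0.95

    def test_gene_supertype_map(self):
        z, truth = blob_encoding(2, n_per=3, seed=19)
        # label alleles as gene:allele keys
        z2 = ZEncoding(
            [f"UA:H{i}" if t == 0 else f"UB:H{i}" for i, t in enumerate(truth)],
            z.matrix,
            z.pbr_positions,
        )
        model = dapc(z2, truth, n_pca=3)
        _, _, gene_map = assign_supertypes(model, {"K1": [z2.labels[0]]})
        assert set(gene_map) == {"UA", "UB"}
        assert len(gene_map["UA"]) == 1  # one supertype per homogeneous gene
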