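import numpy as np
import pytest

from omisurv.community_metrics import (DistanceMatrix, TreeIndex, bray_curtis,
                                       build_kernel_bank, distance_to_kernel,
                                       misaln_correlation, unifrac)
from omisurv.exceptions import (ConfigurationError, ParameterError,
                                ValidationError)
from omisurv.io_formats import CommunityMatrix, tree_from_newick
from omisurv.simulator import otu_names


def _cm(values, otus=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return CommunityMatrix(values, [f"s{i}" for i in range(n)],
                          otus or [f"o{j}" for j in range(p)],
                          community_level=bool(np.allclose(values.sum(1), 1)))


class TestBrayCurtis:
    def test_hand_values(self):
        Z = _cm([[1, 0], [0, 1], [0.5, 0.5], [0.25, 0.75]])
        D = bray_curtis(Z).data
        assert D[0, 1] == pytest.approx(1.0)       # disjoint support
        assert D[2, 2] == 0.0
        assert D[2, 3] == pytest.approx(0.25)      # sum|diff|/sum(sum)

    def test_identical_rows_zero(self):
        Z = _cm([[0.2, 0.8], [0.2, 0.8]])
        assert bray_curtis(Z).data[0, 1] == 0.0

    def test_all_zero_pair_warns_and_zero(self):
        Z = CommunityMatrix(np.array([[0.0, 0.0], [0.0, 0.0]]),
                            ["a", "b"], ["o1", "o2"], community_level=False)
        with pytest.warns(UserWarning):
            D = bray_curtis(Z)
        assert D.data[0, 1] == 0.0


def _naive_generalized_unifrac(Z, tree, otus, theta):
    """Branch-by-branch reference independent of the vectorised path."""
    n = Z.shape[0]
    D = np.zeros((n, n))
    branches = []
    for node in tree.postorder(include_self=False):
        tips = {t.name for t in ([node] if node.is_tip() else node.tips())}
        branches.append((node.length or 0.0,
                         [j for j, o in enumerate(otus) if o in tips]))
    for a in range(n):
        for b in range(n):
            num = den = 0.0
            for length, cols in branches:
                pa = Z[a, cols].sum()
                pb = Z[b, cols].sum()
                s = pa + pb
                if s > 0:
                    w = length * s ** theta
                    num += w * abs(pa - pb) / s
                    den += w
            D[a, b] = num / den if den > 0 else 0.0
    return D


class TestUniFrac:
    def test_identical_samples_zero_all_variants(self, composition, small_tree):
        Z = composition(n=1, p=8, seed=2)
        Z2 = CommunityMatrix(np.vstack([Z.values, Z.values]), ["a", "b"],
                             Z.otu_ids)
        tree = small_tree(p=8, seed=2)
        for variant in ("unweighted", "weighted", "generalized"):
            D = unifrac(Z2, tree, variant).data
            assert abs(D[0, 1]) < 1e-12

    def test_star_tree_disjoint_lineages(self):
        tree = tree_from_newick("(A:1,B:1);")
        Z = CommunityMatrix(np.array([[1.0, 0.0], [0.0, 1.0]]),
                            ["s1", "s2"], ["A", "B"])
        for variant in ("unweighted", "weighted"):
            assert unifrac(Z, tree, variant).data[0, 1] == pytest.approx(1.0)

    def test_unweighted_depends_on_presence_only(self, small_tree):
        rng = np.random.default_rng(8)
        tree = small_tree(p=9, seed=8)
        vals = rng.uniform(size=(5, 9)) * (rng.uniform(size=(5, 9)) > 0.4)
        Z1 = CommunityMatrix(vals / vals.sum(1, keepdims=True),
                             [f"s{i}" for i in range(5)], otu_names(9))
        rescaled = Z1.values * rng.uniform(0.2, 0.9, size=Z1.values.shape)
        Z2 = CommunityMatrix(rescaled, Z1.sample_ids, Z1.otu_ids,
                             community_level=False)
        d1 = unifrac(Z1, tree, "unweighted").data
        d2 = unifrac(Z2, tree, "unweighted").data
        np.testing.assert_allclose(d1, d2, atol=1e-12)

    def test_generalized_theta_one_is_weighted(self, composition, small_tree):
        Z = composition(n=5, p=10, zero_rows=1, seed=3)
        tree = small_tree(p=10, seed=3)
        dw = unifrac(Z, tree, "weighted").data
        dg = unifrac(Z, tree, "generalized", theta=1.0).data
        np.testing.assert_allclose(dw, dg, atol=1e-12)

    @pytest.mark.parametrize("theta", [0.0, 0.5, 1.0])
    def test_matches_naive_reference(self, composition, small_tree, theta):
        Z = composition(n=4, p=7, zero_rows=1, seed=theta.__hash__() % 100)
        tree = small_tree(p=7, seed=5)
        fast = unifrac(Z, tree, "generalized", theta=theta).data
        slow = _naive_generalized_unifrac(Z.values, tree, Z.otu_ids, theta)
        np.testing.assert_allclose(fast, slow, atol=1e-12)

    def test_matches_scikit_bio(self, small_tree):
        from skbio.diversity import beta_diversity

        rng = np.random.default_rng(17)
        for seed in (1, 2):
            p = 12
            tree = small_tree(p=p, seed=seed)
            counts = rng.integers(0, 25, size=(6, p))
            counts[0, : p // 2] = 0
            counts[:, 0] += 1
            Z = CommunityMatrix(counts / counts.sum(1, keepdims=True),
                                [f"s{i}" for i in range(6)], otu_names(p))
            du = unifrac(Z, tree, "unweighted").data
            dw = unifrac(Z, tree, "weighted").data
            ids = Z.sample_ids
            sku = beta_diversity("unweighted_unifrac", counts, ids=ids,
                                 taxa=Z.otu_ids, tree=tree).data
            skw = beta_diversity("weighted_unifrac", counts, ids=ids,
                                 taxa=Z.otu_ids, tree=tree,
                                 normalized=True).data
            np.testing.assert_allclose(du, sku, atol=1e-8)
            np.testing.assert_allclose(dw, skw, atol=1e-8)

    def test_missing_otu_listed(self, composition):
        Z = composition(n=3, p=4, seed=1)
        tree = tree_from_newick("(OTU0001:1,OTU0002:1);")
        with pytest.raises(ValidationError, match="OTU0003"):
            unifrac(Z, tree, "unweighted")

    def test_theta_out_of_range(self, composition, small_tree):
        with pytest.raises(ParameterError):
            unifrac(composition(seed=1), small_tree(p=10, seed=1),
                    "generalized", theta=1.5)


class TestDistanceToKernel:
    def test_two_sample_hand_case(self):
        D = DistanceMatrix(np.array([[0.0, 2.0], [2.0, 0.0]]), "toy")
        np.testing.assert_allclose(distance_to_kernel(D),
                                   [[1.0, -1.0], [-1.0, 1.0]], atol=1e-12)

    def test_zero_distance_gives_zero_kernel(self):
        D = DistanceMatrix(np.zeros((4, 4)), "zero")
        np.testing.assert_allclose(distance_to_kernel(D), 0.0, atol=1e-14)

    def test_non_euclidean_repair(self):
        # star-graph shortest-path counterexample: centered matrix of these
        # squared distances has a negative eigenvalue
        D = np.full((4, 4), 2.0)
        D[0, 1:] = D[1:, 0] = 1.0
        np.fill_diagonal(D, 0.0)
        n = 4
        J = np.eye(n) - np.ones((n, n)) / n
        raw = -0.5 * J @ (D * D) @ J
        assert np.linalg.eigvalsh(raw)[0] < -1e-8
        K = distance_to_kernel(DistanceMatrix(D, "star"))
        assert np.linalg.eigvalsh(K)[0] >= -1e-10

    def test_identity_when_already_psd(self, composition):
        Z = composition(n=5, p=8, seed=6)
        D = bray_curtis(Z)
        n = 5
        J = np.eye(n) - np.ones((n, n)) / n
        raw = -0.5 * J @ (D.data ** 2) @ J
        raw = 0.5 * (raw + raw.T)
        if np.linalg.eigvalsh(raw)[0] >= 0:
            np.testing.assert_allclose(distance_to_kernel(D), raw, atol=1e-10)

    def test_asymmetric_rejected(self):
        M = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValidationError):
            distance_to_kernel(M)


class TestMisalnCorrelation:
    def test_gamma_one_is_linear_kernel(self, composition):
        Z = composition(n=5, p=7, seed=2)
        np.testing.assert_allclose(misaln_correlation(Z, 1.0),
                                   Z.values @ Z.values.T, atol=1e-12)

    def test_zero_row_zero_correlation(self):
        Z = CommunityMatrix(np.array([[0.0, 0.0], [0.3, 0.7]]),
                            ["a", "b"], ["o1", "o2"], community_level=False)
        R = misaln_correlation(Z, 0.5)
        assert R[0, 0] == 0.0 and R[0, 1] == 0.0

    def test_half_power_hand_value(self):
        Z = CommunityMatrix(np.array([[0.25, 0.75]]), ["a"], ["o1", "o2"])
        R = misaln_correlation(Z, 0.5)
        assert R[0, 0] == pytest.approx(1.0)

    def test_nonpositive_gamma_rejected(self, composition):
        with pytest.raises(ParameterError):
            misaln_correlation(composition(seed=1), 0.0)


class TestKernelBank:
    def test_default_bank_has_eight_psd_matrices(self, composition, small_tree):
        Z = composition(n=8, p=10, seed=4)
        tree = small_tree(p=10, seed=4)
        bank = build_kernel_bank(Z, tree=tree)
        assert len(bank) == 8
        assert len(bank.misaln_labels) == 4 and len(bank.mirkats_labels) == 4
        rng = np.random.default_rng(0)
        r = rng.normal(size=8)
        for M in bank.matrices.values():
            assert np.allclose(M, M.T, atol=1e-10)
            assert np.linalg.eigvalsh(M)[0] >= -1e-10
            assert r @ M @ r >= -1e-10

    def test_single_gamma_no_kernels(self, composition):
        Z = composition(n=5, p=6, seed=5)
        bank = build_kernel_bank(Z, tree=None, gammas=(1.0,), kernels=())
        assert bank.labels == ["MiSALN(1)"]
        np.testing.assert_allclose(bank.matrices["MiSALN(1)"],
                                   Z.values @ Z.values.T, atol=1e-12)

    def test_tree_required_for_unifrac(self, composition):
        with pytest.raises(ConfigurationError):
            build_kernel_bank(composition(seed=1), tree=None)

    def test_bray_curtis_only_needs_no_tree(self, composition):
        bank = build_kernel_bank(composition(seed=1), tree=None,
                                 gammas=(), kernels=("bc",))
        assert bank.labels == ["MiRKAT-S(Kbc)"]
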