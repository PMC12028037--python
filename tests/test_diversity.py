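import itertools
import math

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from comstab import diversity as dv
from comstab.geodesic import geodesic_distance
from comstab.io_tables import FeatureTable


def dm(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or tuple(f"s{i}" for i in range(values.shape[0]))
    return dv.DistanceMatrix(tuple(ids), values)


class TestShannon:
    def test_uniform_vector_maximal(self):
        assert dv.shannon([1, 1, 1, 1]) == pytest.approx(math.log(4), abs=1e-12)

    def test_single_taxon_zero(self):
        assert dv.shannon([5, 0, 0]) == 0.0

    def test_direct_formula_value(self):
        # H(0.4, 0.3, 0.2, 0.1) evaluated term by term
        assert dv.shannon([4, 3, 2, 1]) == pytest.approx(1.27985, abs=1e-5)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        x = rng.integers(1, 50, size=8)
        assert dv.shannon(x) == pytest.approx(dv.shannon(x[::-1]), abs=1e-12)

    def test_base_flag(self):
        assert dv.shannon([1, 1], base=2) == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            dv.shannon([0, 0])


class TestBrayCurtis:
    def test_identical_rows_zero_disjoint_one(self):
        ft = FeatureTable(("a", "b", "c"), ("t1", "t2"),
                          np.array([[0.5, 0.5], [0.5, 0.5], [1.0, 0.0]]), mode="counts")
        d = dv.bray_curtis(ft)
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self):
        ft = FeatureTable(("x", "y"), ("t1", "t2", "t3"),
                          np.array([[0.5, 0.5, 0.0], [0.0, 0.5, 0.5]]), mode="counts")
        assert dv.bray_curtis(ft).values[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_matches_scikit_bio(self):
        skbio_dv = pytest.importorskip("skbio.diversity")
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 50, size=(6, 10)) + 1
        ft = FeatureTable(tuple(f"s{i}" for i in range(6)),
                          tuple(f"t{j}" for j in range(10)), counts.astype(float))
        ours = dv.bray_curtis(ft).values
        theirs = skbio_dv.beta_diversity("braycurtis", counts).data
        np.testing.assert_allclose(ours, theirs, atol=1e-12)


class TestPCoA:
    def test_euclidean_configuration_recovered(self):
        rng = np.random.default_rng(2)
        pts = rng.standard_normal((7, 2))
        d = dm(squareform(pdist(pts)))
        res = dv.pcoa(d, k=2)
        rec = squareform(pdist(res.coordinates))
        np.testing.assert_allclose(rec, d.values, atol=1e-9)

    def test_equilateral_triangle_splits_fifty_fifty(self):
        d = dm(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float))
        res = dv.pcoa(d, k=2)
        np.testing.assert_allclose(res.pct_explained, [50.0, 50.0], atol=1e-9)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1], abs=1e-12)

    def test_full_rank_reconstruction_of_bray_curtis(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 100, size=(6, 12)).astype(float)
        ft = FeatureTable(tuple(f"s{i}" for i in range(6)),
                          tuple(f"t{j}" for j in range(12)), counts)
        d = dv.bray_curtis(ft)
        res = dv.pcoa(d)
        B = res.coordinates @ res.coordinates.T
        # only valid if the matrix is fully Euclidean (no negative eigenvalues)
        gram_d = np.sqrt(np.maximum(np.add.outer(np.diag(B), np.diag(B)) - 2 * B, 0))
        if len(res.eigenvalues) == 5:  # all positive: exact embedding expected
            np.testing.assert_allclose(gram_d, d.values, atol=1e-6)


def anosim_oracle(dmat, groups):
    """Independent ANOSIM R from the rank definition, plain loops."""
    n = len(groups)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    ranks = rankdata([dmat[i, j] for i, j in pairs])
    within = [r for r, (i, j) in zip(ranks, pairs) if groups[i] == groups[j]]
    between = [r for r, (i, j) in zip(ranks, pairs) if groups[i] != groups[j]]
    return (np.mean(between) - np.mean(within)) / (n * (n - 1) / 4)


class TestAnosim:
    def test_perfect_separation_r_one(self):
        d = np.full((6, 6), 10.0)
        for a, b in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
            d[a, b] = d[b, a] = 1.0
        np.fill_diagonal(d, 0)
        r, p = dv.anosim(dm(d), ["g1"] * 3 + ["g2"] * 3, n_perm=99, seed=0)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_exhaustive_matches_brute_force(self):
        rng = np.random.default_rng(4)
        x = rng.random((6, 6))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        groups = ["a", "a", "a", "b", "b", "b"]
        r, p = dv.anosim(dm(d), groups, n_perm="exhaustive")
        assert r == pytest.approx(anosim_oracle(d, groups), abs=1e-12)
        perms = set(itertools.permutations(groups))
        r_null = [anosim_oracle(d, g) for g in perms]
        p_oracle = np.mean([rn >= r - 1e-12 for rn in r_null])
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_matches_scikit_bio_statistic(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(5)
        x = rng.random((8, 8))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        groups = ["a"] * 4 + ["b"] * 4
        r, _ = dv.anosim(dm(d), groups, n_perm=9, seed=0)
        skb = skbio_distance.anosim(skbio_distance.DistanceMatrix(d), grouping=groups,
                                    permutations=9)
        assert r == pytest.approx(skb["test statistic"], abs=1e-12)

    def test_single_member_group_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError, match="single member"):
            dv.anosim(dm(d), ["a", "a", "b"], n_perm=9)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(6)
        x = rng.random((8, 8))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        groups = ["a"] * 4 + ["b"] * 4
        assert dv.anosim(dm(d), groups, 199, seed=42) == dv.anosim(dm(d), groups, 199, seed=42)


def mantel_oracle(d1, d2):
    """Pearson correlation of upper triangles plus exhaustive permutation p."""
    n = d1.shape[0]
    iu = np.triu_indices(n, 1)

    def corr(perm):
        return np.corrcoef(d1[iu], d2[np.ix_(perm, perm)][iu])[0, 1]

    r_obs = corr(list(range(n)))
    rs = [corr(list(p)) for p in itertools.permutations(range(n))]
    p = np.mean([abs(r) >= abs(r_obs) - 1e-12 for r in rs])
    return r_obs, p


class TestMantel:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(7)
        x = rng.random((5, 5))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        r, _ = dv.mantel(dm(d), dm(d), n_perm=9, seed=0)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_constant_matrix_flagged(self):
        rng = np.random.default_rng(8)
        x = rng.random((5, 5))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        const = np.ones((5, 5)) - np.eye(5)
        with pytest.raises(ValueError, match="zero-variance"):
            dv.mantel(dm(d), dm(const), n_perm=9)

    def test_exhaustive_matches_brute_force(self):
        rng = np.random.default_rng(9)
        mats = []
        for _ in range(2):
            x = rng.random((5, 5))
            m = (x + x.T) / 2
            np.fill_diagonal(m, 0)
            mats.append(m)
        r, p = dv.mantel(dm(mats[0]), dm(mats[1]), method="pearson", n_perm="exhaustive")
        r_o, p_o = mantel_oracle(mats[0], mats[1])
        assert r == pytest.approx(r_o, abs=1e-12)
        assert p == pytest.approx(p_o, abs=1e-12)

    def test_id_mismatch_rejected(self):
        d = np.zeros((4, 4))
        with pytest.raises(ValueError, match="mismatch"):
            dv.mantel(dm(d), dm(d, ids=("a", "b", "c", "d")), n_perm=9)


class TestGeodesic:
    # reference distances computed with the geosphere WGS84 implementation
    ORACLE = [
        ((0.0, 0.0), (0.0, 1.0), 111319.490793),
        ((0.0, 0.0), (52.5, 13.4), 5951919.393354),
        ((52.5, 13.4), (39.9, 116.4), 7378963.047403),
        ((52.5, 13.4), (51.4775, -0.0015), 926255.582297),
        ((-33.9, 151.2), (40.7, -74.0), 15990627.264134),
        ((39.9, 116.4), (-33.9, 151.2), 8920744.757605),
    ]

    @pytest.mark.parametrize("a,b,expected", ORACLE)
    def test_against_independent_reference(self, a, b, expected):
        assert geodesic_distance(*a, *b) == pytest.approx(expected, abs=1e-3)

    def test_identical_points_zero(self):
        assert geodesic_distance(10.0, 20.0, 10.0, 20.0) == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            lat1, lat2 = rng.uniform(-80, 80, 2)
            lon1, lon2 = rng.uniform(-179, 179, 2)
            assert geodesic_distance(lat1, lon1, lat2, lon2) == pytest.approx(
                geodesic_distance(lat2, lon2, lat1, lon1), abs=1e-6)

    def test_matrix_from_metadata(self, toy_metadata):
        d = dv.geodesic_distance_matrix(toy_metadata)
        assert d.values[0, 1] > 0
        np.testing.assert_allclose(d.values, d.values.T)


class TestShannonProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    vectors = st.lists(st.floats(0, 1e6, allow_nan=False, allow_infinity=False),
                       min_size=2, max_size=12).filter(lambda v: sum(v) > 0)

    @given(vectors)
    @settings(max_examples=100, deadline=None)
    def test_bounded_by_log_richness_and_permutation_invariant(self, v):
        h = dv.shannon(v)
        m = sum(1 for x in v if x > 0)
        assert -1e-9 <= h <= math.log(max(m, 1)) + 1e-9
        assert dv.shannon(list(reversed(v))) == pytest.approx(h, abs=1e-9)
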