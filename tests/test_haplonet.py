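"""Haplotype collapsing, network construction, kinship and isolation by
distance."""

import itertools

import numpy as np
import pandas as pd
import pytest

from forgen import haplonet, simulate
from forgen.haplonet import SnpMatrix, _distance_matrix, _mst_length


def snp(rows, accessions=None, metadata=None):
    rows = np.array(rows, dtype=np.int8)
    if accessions is None:
        accessions = [f"acc{i}" for i in range(len(rows))]
    return SnpMatrix(genotypes=rows, accessions=accessions, metadata=metadata)


def hset_from(vectors):
    mat = snp(vectors)
    return haplonet.collapse_haplotypes(mat)


def brute_force_steiner(vectors, max_extra=2):
    """Minimum spanning-tree length over terminals plus up to ``max_extra``
    optimally chosen hypercube Steiner points (exhaustive search)."""
    terms = np.array(vectors, dtype=np.int8)
    L = terms.shape[1]
    cube = [np.array(c, dtype=np.int8) for c in itertools.product((0, 1), repeat=L)]
    term_set = {tuple(t) for t in terms}
    cands = [c for c in cube if tuple(c) not in term_set]
    best = _mst_length(_distance_matrix(terms))
    for k in range(1, max_extra + 1):
        for extra in itertools.combinations(cands, k):
            best = min(best, _mst_length(_distance_matrix(np.vstack([terms, *extra]))))
    return best


class TestFilterSites:
    def test_all_homozygous_is_noop(self):
        mat = snp([[0, 1], [1, 0], [0, 0]])
        out = haplonet.filter_sites(mat)
        assert out.genotypes.shape == (3, 2)

    def test_site_below_98_pct_homozygous_removed(self):
        geno = np.zeros((100, 2), dtype=np.int8)
        geno[:3, 0] = 2  # 97% homozygous at site 0
        out = haplonet.filter_sites(snp(geno))
        assert out.n_sites == 1 and out.sites == ["site1"]

    def test_het_accession_dropped_at_retained_site(self):
        geno = np.zeros((100, 1), dtype=np.int8)
        geno[0, 0] = 2  # 99% homozygous: site kept, accession dropped
        out = haplonet.filter_sites(snp(geno))
        assert out.n_sites == 1
        assert out.n_accessions == 99
        assert "acc0" not in out.accessions


class TestCollapseHaplotypes:
    def test_identical_accessions_one_haplotype(self):
        hs = hset_from([[0, 1]] * 5)
        assert hs.n_haplotypes == 1
        assert hs.counts[0] == 5

    def test_hand_grouping(self):
        hs = hset_from([[0, 0], [0, 0], [0, 1], [1, 1]])
        assert hs.n_haplotypes == 3
        assert list(hs.counts) == [2, 1, 1]

    def test_counts_sum_to_accessions(self):
        geno, meta = simulate.simulate_accession_panel(60, 12, n_groups=3, seed=4)
        hs = haplonet.collapse_haplotypes(snp(geno, list(meta["accession"]), meta))
        assert hs.counts.sum() == 60

    def test_het_calls_rejected(self):
        with pytest.raises(ValueError):
            haplonet.collapse_haplotypes(snp([[0, 2]]))


class TestBuildNetwork:
    def test_two_haplotypes_single_edge(self):
        g = haplonet.build_network(hset_from([[0, 0, 0], [1, 1, 1]]))
        assert g.number_of_edges() == 1
        assert list(g.edges(data="weight"))[0][2] == 3

    def test_median_vector_added_for_star_triple(self):
        g = haplonet.build_network(hset_from([[0, 0, 0], [1, 1, 0], [1, 0, 1]]), method="mjn")
        vectors = {g.nodes[n]["vector"] for n in g}
        assert (1, 0, 0) in vectors
        medians = [n for n in g if g.nodes[n]["kind"] == "median"]
        assert len(medians) == 1
        assert sorted(w for _, _, w in g.edges(data="weight")) == [1, 1, 1]

    def test_median_nodes_have_degree_at_least_three(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            vecs = list({tuple(rng.integers(0, 2, 6)) for _ in range(4)})
            if len(vecs) < 2:
                continue
            g = haplonet.build_network(hset_from(vecs), method="mjn")
            for n in g:
                if g.nodes[n]["kind"] == "median":
                    assert g.degree[n] >= 3

    def test_edge_weights_equal_hamming_distances(self):
        geno, _ = simulate.simulate_accession_panel(25, 8, seed=5)
        g = haplonet.build_network(hset_from(geno), method="mjn")
        for u, v, w in g.edges(data="weight"):
            assert w == haplonet.hamming(g.nodes[u]["vector"], g.nodes[v]["vector"])

    def test_mjn_no_longer_than_msn(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            vecs = list({tuple(rng.integers(0, 2, 5)) for _ in range(5)})
            if len(vecs) < 2:
                continue
            hs = hset_from(vecs)
            mjn = haplonet.build_network(hs, method="mjn")
            nodes = np.array([mjn.nodes[n]["vector"] for n in mjn], dtype=np.int8)
            msn_len = _mst_length(_distance_matrix(np.array(vecs, dtype=np.int8)))
            assert _mst_length(_distance_matrix(nodes)) <= msn_len

    def test_single_haplotype_errors(self):
        with pytest.raises(ValueError):
            haplonet.build_network(hset_from([[0, 1]]))


class TestGeodesic:
    def test_identical_points(self):
        assert haplonet.geodesic_distance(10.0, 20.0, 10.0, 20.0) == 0.0

    def test_antipodal_on_equator(self):
        assert haplonet.geodesic_distance(0, 0, 0, 180) == pytest.approx(20015.1, abs=0.1)

    def test_one_degree_of_longitude(self):
        assert haplonet.geodesic_distance(0, 0, 0, 1) == pytest.approx(111.19, abs=0.01)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            haplonet.geodesic_distance(91, 0, 0, 0)

    def test_pairwise_matches_scalar(self):
        lat, lon = [10, -35, 52], [4, 140, -3]
        D = haplonet.pairwise_geodesic(lat, lon)
        for i in range(3):
            for j in range(3):
                assert D[i, j] == pytest.approx(
                    haplonet.geodesic_distance(lat[i], lon[i], lat[j], lon[j]), abs=1e-6
                )


class TestRitlandKinship:
    def test_identical_accessions_at_half_frequency(self):
        mat = snp([[0, 1], [0, 1], [1, 0], [1, 0]])  # p = 0.5 both loci
        F = haplonet.ritland_kinship(mat)
        assert F[0, 1] == pytest.approx(1.0)

    def test_opposite_homozygotes(self):
        mat = snp([[0, 0], [0, 0], [1, 1], [1, 1]])
        F = haplonet.ritland_kinship(mat)
        assert F[0, 2] == pytest.approx(-1.0)

    def test_off_diagonal_mean_identity(self):
        rng = np.random.default_rng(9)
        geno = rng.integers(0, 2, size=(30, 40)).astype(np.int8)
        poly = (geno.mean(axis=0) > 0) & (geno.mean(axis=0) < 1)
        F = haplonet.ritland_kinship(snp(geno[:, poly]))
        n = len(F)
        off = F[~np.eye(n, dtype=bool)]
        assert off.mean() == pytest.approx(-1 / (n - 1), abs=1e-6)

    def test_monomorphic_locus_errors(self):
        with pytest.raises(ValueError, match="monomorphic"):
            haplonet.ritland_kinship(snp([[0, 0], [1, 0], [0, 0]]))


class TestIbdRegression:
    def _coords(self, n, rng):
        return pd.DataFrame({"lat": rng.uniform(-60, 60, n), "lon": rng.uniform(-170, 170, n)})

    def test_planted_signal_recovered(self):
        rng = np.random.default_rng(3)
        n = 25
        coords = self._coords(n, rng)
        D = haplonet.pairwise_geodesic(coords["lat"], coords["lon"])
        F = -0.01 * np.log(np.maximum(D, 1.0)) + rng.normal(0, 1e-4, (n, n))
        F = (F + F.T) / 2
        res = haplonet.ibd_regression(F, coords, n_perm=9999, seed=1)
        assert res.slope < 0
        assert res.p_perm <= 0.001

    def test_null_p_not_extreme(self):
        rng = np.random.default_rng(8)
        n = 20
        F = rng.normal(0, 0.1, (n, n))
        F = (F + F.T) / 2
        res = haplonet.ibd_regression(F, self._coords(n, rng), n_perm=999, seed=2)
        assert res.p_perm > 0.001

    def test_invariant_to_accession_relabelling(self):
        rng = np.random.default_rng(5)
        n = 12
        coords = self._coords(n, rng)
        F = rng.normal(0, 0.1, (n, n))
        F = (F + F.T) / 2
        res1 = haplonet.ibd_regression(F, coords, n_perm=499, seed=7)
        perm = rng.permutation(n)
        res2 = haplonet.ibd_regression(
            F[np.ix_(perm, perm)], coords.iloc[perm].reset_index(drop=True), n_perm=499, seed=7
        )
        assert res1.slope == pytest.approx(res2.slope)

    def test_too_few_accessions(self):
        with pytest.raises(ValueError):
            haplonet.ibd_regression(np.eye(3), pd.DataFrame({"lat": [0, 1, 2], "lon": [0, 1, 2]}))
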