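"""Nei standard distances on mixed-ploidy genotypes and PCoA with the
Lingoes correction."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.spatial import procrustes

from polyrank import popgen
from polyrank.formats_io import GenotypeMatrix
from polyrank.synthetic import simulate_genotypes


def make_matrix(dosages, ploidies, taxa=None):
    """dosages: (n, L, A) array (NaN rows = missing)."""
    dosages = np.asarray(dosages, float)
    n, L, _ = dosages.shape
    ids = [f"s{i}" for i in range(n)]
    return GenotypeMatrix(
        sample_ids=ids,
        taxon_of={s: (taxa[i] if taxa else "t") for i, s in enumerate(ids)},
        ploidy_of={s: ploidies[i] for i, s in enumerate(ids)},
        sites=[("chr1", l + 1, "A", ("G",)) for l in range(L)],
        dosages=dosages,
    )


class TestAlleleFrequencies:
    def test_diploid_and_tetraploid(self):
        g = make_matrix(
            [[[1, 1]], [[3, 1]]], [2, 4]
        )
        np.testing.assert_allclose(popgen.sample_allele_frequencies(g, "s0"), [[0.5, 0.5]])
        np.testing.assert_allclose(popgen.sample_allele_frequencies(g, "s1"), [[0.75, 0.25]])

    def test_missing_stays_missing(self):
        g = make_matrix([[[np.nan, np.nan]], [[2, 0]]], [2, 2])
        assert np.isnan(popgen.sample_allele_frequencies(g, "s0")).all()

    def test_unknown_sample(self):
        g = make_matrix([[[2, 0]], [[2, 0]]], [2, 2])
        with pytest.raises(KeyError):
            popgen.sample_allele_frequencies(g, "nope")


class TestNeiDistance:
    def test_identical_profiles_zero(self):
        g = make_matrix([[[1, 1], [2, 0]], [[1, 1], [2, 0]]], [2, 2])
        nd = popgen.nei_distance_matrix(g, min_shared_sites=1)
        assert nd.D[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_alleles_hit_cap(self):
        g = make_matrix([[[2, 0], [2, 0]], [[0, 2], [0, 2]]], [2, 2])
        nd = popgen.nei_distance_matrix(g, d_cap=10.0, min_shared_sites=1)
        assert nd.D[0, 1] == 10.0

    def test_hand_computed_single_site(self):
        # x = (0.5, 0.5), y = (0.75, 0.25): J_x=0.5, J_y=0.625, J_xy=0.5,
        # I = 0.5/sqrt(0.3125), D = -ln(0.894427) = 0.111572
        g = make_matrix([[[1, 1]], [[3, 1]]], [2, 4])
        nd = popgen.nei_distance_matrix(g, min_shared_sites=1)
        assert nd.D[0, 1] == pytest.approx(0.1115718, abs=1e-6)

    def test_matches_bruteforce_oracle(self):
        g, _ = simulate_genotypes(
            n_taxa=2, samples_per_taxon=5, n_sites=120, divergence_F=0.2,
            missing_rate=0.1, seed=42,
        )
        nd = popgen.nei_distance_matrix(g, min_shared_sites=1)
        ref = bruteforce_nei(g)
        np.testing.assert_allclose(nd.D, ref, atol=1e-12)

    def test_site_order_invariance(self):
        g, _ = simulate_genotypes(n_taxa=2, samples_per_taxon=3, n_sites=50,
                                  divergence_F=0.3, seed=5)
        nd = popgen.nei_distance_matrix(g, min_shared_sites=1)
        rng = np.random.default_rng(0)
        perm = rng.permutation(g.n_sites)
        g2 = GenotypeMatrix(
            sample_ids=g.sample_ids, taxon_of=g.taxon_of, ploidy_of=g.ploidy_of,
            sites=[g.sites[i] for i in perm], dosages=g.dosages[:, perm],
        )
        nd2 = popgen.nei_distance_matrix(g2, min_shared_sites=1)
        np.testing.assert_allclose(nd.D, nd2.D, atol=1e-12)

    def test_relabeling_permutes_consistently(self):
        g, _ = simulate_genotypes(n_taxa=2, samples_per_taxon=3, n_sites=60,
                                  divergence_F=0.2, seed=6)
        nd = popgen.nei_distance_matrix(g, min_shared_sites=1)
        new_order = nd.labels[::-1]
        nd2 = nd.reorder(new_order)
        for i, a in enumerate(new_order):
            for j, b in enumerate(new_order):
                assert nd2.D[i, j] == nd.D[nd.labels.index(a), nd.labels.index(b)]

    def test_zero_shared_sites_flagged_nan(self):
        nanrow = [np.nan, np.nan]
        g = make_matrix(
            [[[2, 0], nanrow], [nanrow, [0, 2]]], [2, 2]
        )
        nd = popgen.nei_distance_matrix(g, min_shared_sites=1)
        assert np.isnan(nd.D[0, 1])
        assert ("s0", "s1") in nd.flagged_pairs

    def test_planted_structure_within_below_between(self):
        # divergence F = 0.2 >= 0.1: within-taxon D < between-taxon D
        for seed in range(10):
            g, _ = simulate_genotypes(n_taxa=3, samples_per_taxon=4,
                                      n_sites=300, divergence_F=0.2, seed=seed)
            nd = popgen.nei_distance_matrix(g)
            taxa = [g.taxon_of[s] for s in nd.labels]
            n = len(taxa)
            within, between = [], []
            for i in range(n):
                for j in range(i + 1, n):
                    (within if taxa[i] == taxa[j] else between).append(nd.D[i, j])
            assert np.mean(within) < np.mean(between), f"seed {seed}"


def bruteforce_nei(g, d_cap=10.0):
    """Independent per-pair loop re-implementation (the oracle)."""
    n = g.n_samples
    D = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            sa, sb = g.sample_ids[a], g.sample_ids[b]
            fa = g.dosages[a] / g.ploidy_of[sa]
            fb = g.dosages[b] / g.ploidy_of[sb]
            jx = jy = jxy = 0.0
            m = 0
            for l in range(g.n_sites):
                if np.isnan(fa[l, 0]) or np.isnan(fb[l, 0]):
                    continue
                m += 1
                jx += sum(v * v for v in fa[l])
                jy += sum(v * v for v in fb[l])
                jxy += sum(u * v for u, v in zip(fa[l], fb[l]))
            if m == 0:
                D[a, b] = np.nan
                continue
            identity = (jxy / m) / np.sqrt((jx / m) * (jy / m))
            D[a, b] = d_cap if identity <= np.exp(-d_cap) else -np.log(min(identity, 1.0))
    return D


class TestPcoaLingoes:
    def test_euclidean_input_recovers_configuration(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(5, 2))
        D = squareform(pdist(pts))
        res = popgen.pcoa_lingoes(D)
        assert res.lingoes_constant == 0.0
        _, _, disparity = procrustes(pts, res.scores[:, :2])
        assert disparity < 1e-12

    def test_non_euclidean_corrected_eigenvalues(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(6, 3))
        D = squareform(pdist(pts)) ** 0.25
        res = popgen.pcoa_lingoes(D)
        assert res.eigenvalues.min() >= -1e-9
        assert res.lingoes_constant >= 0

    def test_corrected_distances_reproduced(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(7, 3))
        D = squareform(pdist(pts)) ** 0.25
        res = popgen.pcoa_lingoes(D)
        c = res.lingoes_constant
        expect = np.sqrt(D**2 + 2 * c)
        np.fill_diagonal(expect, 0.0)
        got = squareform(pdist(res.scores))
        np.testing.assert_allclose(got, expect, atol=1e-6)

    def test_two_samples(self):
        res = popgen.pcoa_lingoes(np.array([[0.0, 0.4], [0.4, 0.0]]))
        np.testing.assert_allclose(np.abs(res.scores[:, 0]), [0.2, 0.2], atol=1e-9)

    def test_nan_rejected(self):
        D = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="NaN"):
            popgen.pcoa_lingoes(D)

    def test_cross_check_against_skbio(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(4)
        pts = rng.normal(size=(8, 4))
        D = squareform(pdist(pts))
        mine = popgen.pcoa_lingoes(D)
        theirs = skbio_pcoa(D, method="eigh", number_of_dimensions=4)
        np.testing.assert_allclose(
            np.sort(mine.eigenvalues[mine.eigenvalues > 1e-9])[::-1][:4],
            theirs.eigvals.values[:4],
            rtol=1e-8,
        )
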