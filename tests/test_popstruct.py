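"""Differentiation estimators, AMOVA, PCoA and bottleneck screening."""

import numpy as np
import pytest

from tigerscape import popstruct as ps
from tigerscape import simdata
from tigerscape.genotypes import MultilocusGenotype as MG


def fixed_pops(allele_a=1, allele_b=2, n=5):
    a = [MG(f"a{i}", {"L1": (allele_a, allele_a)}, locality="A")
         for i in range(n)]
    b = [MG(f"b{i}", {"L1": (allele_b, allele_b)}, locality="B")
         for i in range(n)]
    return a + b


def wc_theta_oracle(genotypes_by_pop):
    """Independent two-population Weir-Cockerham theta from definitional
    sums, written with explicit per-allele loops (biallelic-ready)."""
    r = len(genotypes_by_pop)
    alleles = sorted({a for pop in genotypes_by_pop for g in pop for a in g})
    n_i = [len(pop) for pop in genotypes_by_pop]
    nbar = sum(n_i) / r
    nc = (r * nbar - sum(n ** 2 for n in n_i) / (r * nbar)) / (r - 1)
    num = den = 0.0
    for al in alleles:
        p_i = [sum(g.count(al) for g in pop) / (2 * len(pop))
               for pop in genotypes_by_pop]
        h_i = [sum(1 for g in pop if (al in g) and g[0] != g[1]) / len(pop)
               for pop in genotypes_by_pop]
        pbar = sum(n * p for n, p in zip(n_i, p_i)) / (r * nbar)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(n_i, h_i)) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


class TestFst:
    def test_fixed_difference_is_one(self):
        fst = ps.pairwise_fst(fixed_pops(), n_perm=0)
        assert fst.values[0, 1] == pytest.approx(1.0)

    def test_panmictic_near_zero(self, rng):
        alleles = rng.choice([1, 2, 3, 4], size=(100, 2))
        inds = [MG(f"i{k}", {"L": tuple(a)},
                   locality="A" if k < 50 else "B")
                for k, a in enumerate(alleles)]
        fst = ps.pairwise_fst(inds, n_perm=0)
        assert abs(fst.values[0, 1]) < 0.02

    def test_matches_definitional_oracle(self, rng):
        pops = []
        inds = []
        for lab, n in (("A", 10), ("B", 12)):
            geno = [tuple(sorted(rng.choice([1, 2], size=2,
                                            p=[0.3 if lab == "A" else 0.7,
                                               0.7 if lab == "A" else 0.3])))
                    for _ in range(n)]
            pops.append(geno)
            inds += [MG(f"{lab}{i}", {"L1": g}, locality=lab)
                     for i, g in enumerate(geno)]
        expected = wc_theta_oracle(pops)
        assert ps.wc_theta(inds) == pytest.approx(expected, abs=1e-12)

    def test_permutation_p_significant_when_fixed(self):
        fst = ps.pairwise_fst(fixed_pops(n=8), n_perm=199, seed=0)
        assert fst.p_values[0, 1] < 0.05


class TestRst:
    def test_identical_size_distributions(self, rng):
        sizes = rng.choice([10, 12, 14], size=(60, 2))
        inds = [MG(f"i{k}", {"L": tuple(s)},
                   locality="A" if k < 30 else "B")
                for k, s in enumerate(sizes)]
        rst = ps.pairwise_rst(inds, n_perm=0)
        assert abs(rst.values[0, 1]) < 0.05

    def test_shifted_means_approach_one(self):
        a = [MG(f"a{i}", {"L": (10, 10 + (i % 2))}, locality="A")
             for i in range(10)]
        b = [MG(f"b{i}", {"L": (40, 40 + (i % 2))}, locality="B")
             for i in range(10)]
        rst = ps.pairwise_rst(a + b, n_perm=0)
        assert rst.values[0, 1] > 0.95

    def test_matches_definitional_variance_oracle(self, rng):
        a_sizes = rng.integers(10, 16, size=(8, 2))
        b_sizes = rng.integers(12, 20, size=(9, 2))
        inds = ([MG(f"a{i}", {"L": tuple(s)}, locality="A")
                 for i, s in enumerate(a_sizes)]
                + [MG(f"b{i}", {"L": tuple(s)}, locality="B")
                   for i, s in enumerate(b_sizes)])
        pooled = np.concatenate([a_sizes.ravel(), b_sizes.ravel()]).astype(float)
        s_total = 2 * np.var(pooled, ddof=1)
        sw = np.average(
            [2 * np.var(a_sizes.ravel().astype(float), ddof=1),
             2 * np.var(b_sizes.ravel().astype(float), ddof=1)],
            weights=[a_sizes.size, b_sizes.size])
        expected = (s_total - sw) / s_total
        assert ps.rst_value(inds) == pytest.approx(expected, abs=1e-12)


class TestAmova:
    def test_identical_individuals_zero_components(self):
        inds = [MG(f"i{k}", {"L1": (1, 2)},
                   locality="A" if k < 4 else "B") for k in range(8)]
        res = ps.amova(inds, n_perm=0)
        assert all(abs(v) < 1e-12 for v in res.components.values())

    def test_disjoint_clusters_all_among(self):
        inds = []
        for ci, cluster in enumerate(("X", "Y")):
            for pi in range(2):
                for k in range(4):
                    inds.append(MG(f"{cluster}{pi}{k}",
                                   {"L1": (10 * (ci + 1), 10 * (ci + 1))},
                                   locality=f"{cluster}{pi}"))
        clusters = {f"{c}{p}": c for c in ("X", "Y") for p in range(2)}
        res = ps.amova(inds, clusters=clusters, n_perm=0)
        assert res.percentages["among_clusters"] == pytest.approx(100.0, abs=0.1)

    def test_two_level_hand_computed_sums(self):
        # 2 pops x 2 individuals; distances small enough to enumerate
        inds = [MG("a0", {"L1": (1, 1)}, locality="A"),
                MG("a1", {"L1": (1, 2)}, locality="A"),
                MG("b0", {"L1": (3, 3)}, locality="B"),
                MG("b1", {"L1": (3, 4)}, locality="B")]
        d2 = ps.allele_difference_matrix(inds)
        # within-pair distance = 1 mismatch; across pops = 2
        expected = np.array([[0, 1, 2, 2],
                             [1, 0, 2, 2],
                             [2, 2, 0, 1],
                             [2, 2, 1, 0]], dtype=float)
        np.testing.assert_allclose(d2, expected)
        res = ps.amova(inds, n_perm=0)
        # SS_total = sum d2 / (2N) = 20/8 = 2.5; SS_within = (1/2 + 1/2)
        # MS_among = (2.5 - 1)/1 = 1.5; MS_within = 1/2; n0 = 2
        # sigma_a = (1.5 - 0.5)/2 = 0.5, sigma_w = 0.5 -> PhiPT = 0.5
        assert res.phi["phi_pt"] == pytest.approx(0.5, abs=1e-12)

    def test_percentages_sum_to_100(self, two_pop_sample):
        inds, _, _ = two_pop_sample
        res = ps.amova(inds, n_perm=0)
        assert sum(res.percentages.values()) == pytest.approx(100.0, abs=0.1)

    def test_phi_pt_matrix_symmetric(self, two_pop_sample):
        inds, _, _ = two_pop_sample
        m = ps.phi_pt_matrix(inds[:20] + inds[30:50])
        np.testing.assert_allclose(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 0)


class TestLinearize:
    @pytest.mark.parametrize("d,expected", [
        (0.0, 0.0), (0.5, 1.0), (0.241, 0.241 / 0.759)])
    def test_values(self, d, expected):
        assert ps.linearize(d) == pytest.approx(expected)

    def test_strictly_increasing(self):
        xs = np.linspace(0, 0.99, 50)
        ys = ps.linearize(xs)
        assert np.all(np.diff(ys) > 0)

    def test_one_maps_to_inf_with_warning(self):
        with pytest.warns(UserWarning):
            assert np.isinf(ps.linearize(np.array([1.0]))[0])


class TestPcoa:
    def test_collinear_points_single_axis(self):
        pts = np.arange(4.0)[:, None]
        d = np.abs(pts - pts.T)
        res = ps.pcoa(d)
        assert res.explained[0] > 0.999

    def test_euclidean_recovery(self, rng):
        pts = rng.normal(size=(7, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = ps.pcoa(d)
        d2 = np.linalg.norm(res.coordinates[:, None, :2]
                            - res.coordinates[None, :, :2], axis=2)
        np.testing.assert_allclose(d, d2, atol=1e-8)

    def test_negative_eigenvalues_reported(self):
        # non-Euclidean: violates triangle-inequality embedding
        d = np.array([[0, 1, 1, 1], [1, 0, 1, 1],
                      [1, 1, 0, 3.9], [1, 1, 3.9, 0]])
        res = ps.pcoa(d)
        assert len(res.negative_eigenvalues) > 0

    def test_agrees_with_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa as sk_pcoa
        pts = rng.normal(size=(6, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        ours = ps.pcoa(d)
        theirs = sk_pcoa(skbio.DistanceMatrix(d))
        np.testing.assert_allclose(
            np.sort(ours.eigenvalues[ours.eigenvalues > 1e-8])[::-1],
            np.sort(np.asarray(theirs.eigvals[theirs.eigvals > 1e-8]))[::-1],
            atol=1e-8)


class TestBottleneck:
    def test_m_ratio_full_ladder(self):
        inds = [MG(f"i{k}", {"L": (10 + k % 3, 10 + (k + 1) % 3)})
                for k in range(12)]
        # alleles {10, 11, 12}: k = 3, range 2, M = 1
        assert ps.m_ratio(inds) == pytest.approx(1.0)

    def test_m_ratio_gapped(self):
        inds = [MG(f"i{k}", {"L": (10, 14) if k % 2 else (10, 10)})
                for k in range(10)]
        # alleles {10, 14}: k = 2, range 4, M = 0.4
        assert ps.m_ratio(inds) == pytest.approx(0.4)

    def test_mode_shift_l_shape_for_rich_low_freq_spectrum(self, rng):
        # skewed spectrum: a few common alleles, many rare ones
        states = np.arange(10, 26)
        w = 0.55 ** np.arange(len(states))
        w /= w.sum()
        inds = [MG(f"i{k}", {f"L{j}": tuple(sorted(rng.choice(
            states, size=2, p=w))) for j in range(6)})
            for k in range(60)]
        hist, l_shaped = ps.mode_shift(inds)
        assert hist.sum() > 0
        assert l_shaped

    def test_heterozygosity_excess_detects_crash(self):
        """A population crashed from Ne 500 to 10 shows stronger
        heterozygosity excess (larger standardized differences) than an
        equilibrium population of the same final size."""
        def simulate(crash, seed):
            cfg = simdata.SimConfig(
                seed=seed, n_pops=2, effective_size=300, n_generations=150,
                migration_matrix=simdata.default_migration_matrix(2, 0.0))
            pops, loci, _ = simdata.gen_metapopulation(cfg)
            geno = pops["P1"]
            rng = np.random.default_rng(seed + 1)
            if crash:
                for _ in range(4):
                    keep = rng.choice(len(geno), 10, replace=False)
                    pool = geno[keep]
                    pa = rng.integers(0, 10, size=10)
                    pb = rng.integers(0, 10, size=10)
                    L = geno.shape[1]
                    geno = np.stack([
                        pool[pa[:, None], np.arange(L)[None, :],
                             rng.integers(0, 2, (10, L))],
                        pool[pb[:, None], np.arange(L)[None, :],
                             rng.integers(0, 2, (10, L))]], axis=2)
            take = rng.choice(len(geno), min(10, len(geno)), replace=False)
            return [MG(f"x{i}", {loci[l]: tuple(geno[t, l])
                                 for l in range(geno.shape[1])})
                    for i, t in enumerate(take)]

        rng = np.random.default_rng(5)
        dh_eq, dh_crash = [], []
        for seed in (11, 12, 13):
            _, dh1 = ps.heterozygosity_excess_p(
                simulate(False, seed), n_sim=150, rng=rng)
            _, dh2 = ps.heterozygosity_excess_p(
                simulate(True, seed), n_sim=150, rng=rng)
            dh_eq += list(dh1.values())
            dh_crash += list(dh2.values())
        assert np.mean(dh_crash) > np.mean(dh_eq)

    def test_suite_runs_and_reports(self, two_pop_sample):
        inds, _, _ = two_pop_sample
        group = [i for i in inds if i.locality == "P1"][:12]
        res = ps.bottleneck_suite(group, n_sim=100,
                                  rng=np.random.default_rng(1))
        assert 0 < res.m_ratio <= 1
        assert 0 < res.wilcoxon_p["TPM"] <= 1
        assert res.mode_shift_classes.sum() > 0
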