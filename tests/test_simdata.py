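"""The synthetic-data generator: landscapes, drift, noise, detections."""

import numpy as np
import pytest
from scipy import ndimage

from tigerscape import popstruct, simdata
from tigerscape.genotypes import consensus_genotype


class TestConfig:
    def test_rates_validated(self):
        with pytest.raises(ValueError):
            simdata.SimConfig(dropout_rate=1.2)
        with pytest.raises(ValueError):
            simdata.SimConfig(detection_base=-0.1)

    def test_migration_row_sum_rejected(self):
        bad = np.array([[0.2, 0.9], [0.1, 0.9]])
        with pytest.raises(ValueError):
            simdata.SimConfig(n_pops=2, migration_matrix=bad)

    def test_default_matrix_rows_sum_to_one(self):
        m = simdata.default_migration_matrix(5, 0.01)
        np.testing.assert_allclose(m.sum(axis=1), 1.0)


class TestLandscape:
    def test_requested_patch_count(self):
        cfg = simdata.SimConfig(seed=1, grid_shape=(20, 20))
        land = simdata.gen_landscape(cfg, n_patches=2,
                                     settlement_fraction=0.0)
        assert land.n_patches == 2
        lab, n = ndimage.label(land.habitat)
        assert n == 2

    def test_same_seed_identical(self):
        cfg = simdata.SimConfig(seed=5)
        a = simdata.gen_landscape(cfg)
        b = simdata.gen_landscape(cfg)
        np.testing.assert_array_equal(a.habitat, b.habitat)
        np.testing.assert_array_equal(a.settlements, b.settlements)
        for k in a.covariates:
            np.testing.assert_array_equal(a.covariates[k], b.covariates[k])

    def test_settlement_band_separates_matrix(self):
        cfg = simdata.SimConfig(seed=2, grid_shape=(20, 20))
        land = simdata.gen_landscape(cfg, n_patches=4, settlement_band=True)
        band_col = 10
        # the band exists in the matrix and never on habitat
        assert land.settlements[:, band_col].any()
        assert not (land.settlements & land.habitat).any()

    def test_covariates_spatially_autocorrelated(self):
        cfg = simdata.SimConfig(seed=3)
        land = simdata.gen_landscape(cfg)
        f = land.covariates["forest"]
        lag1 = np.corrcoef(f[:, :-1].ravel(), f[:, 1:].ravel())[0, 1]
        assert lag1 > 0.5

    def test_tiny_grid_rejected(self):
        with pytest.raises(ValueError):
            simdata.gen_landscape(simdata.SimConfig(grid_shape=(4, 4)))


class TestMetapopulation:
    def test_isolation_builds_structure(self):
        cfg = simdata.SimConfig(
            seed=9, n_pops=2, effective_size=50, n_generations=200,
            migration_matrix=np.eye(2))
        _, _, ledger = simdata.gen_metapopulation(cfg)
        assert ledger.fst_true[0, 1] > 0.05

    def test_panmixia_near_zero_fst(self):
        """Fully mixing populations should show mean F_ST within +/- 0.01
        of zero across replicate simulations."""
        vals = []
        for seed in range(20):
            cfg = simdata.SimConfig(
                seed=seed, n_pops=2, effective_size=40, n_generations=40,
                migration_matrix=simdata.default_migration_matrix(2, 0.45))
            _, _, ledger = simdata.gen_metapopulation(cfg)
            vals.append(ledger.fst_true[0, 1])
        assert abs(np.mean(vals)) < 0.01

    def test_smaller_ne_more_drift(self):
        def mean_fst(ne, seeds):
            out = []
            for s in seeds:
                cfg = simdata.SimConfig(
                    seed=s, n_pops=2, effective_size=ne, n_generations=100,
                    migration_matrix=np.eye(2))
                _, _, led = simdata.gen_metapopulation(cfg)
                out.append(led.fst_true[0, 1])
            return np.mean(out)
        assert mean_fst(25, range(5)) > mean_fst(500, range(5))

    def test_same_seed_bit_identical(self):
        cfg = simdata.SimConfig(seed=4, n_pops=2, effective_size=30,
                                n_generations=50)
        a, _, la = simdata.gen_metapopulation(cfg)
        b, _, lb = simdata.gen_metapopulation(cfg)
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])
        np.testing.assert_array_equal(la.fst_true, lb.fst_true)

    def test_bad_migration_shape(self):
        cfg = simdata.SimConfig(seed=0, n_pops=3,
                                migration_matrix=np.eye(3))
        cfg.migration_matrix = np.eye(2)
        with pytest.raises(ValueError):
            simdata.gen_metapopulation(cfg)


class TestPlantMigrants:
    @pytest.fixture()
    def pops(self):
        cfg = simdata.SimConfig(seed=8, n_pops=2, effective_size=30,
                                n_generations=30)
        pops, loci, ledger = simdata.gen_metapopulation(cfg)
        return pops, loci, ledger

    def test_single_move_single_record(self, pops):
        p, _, ledger = pops
        p2, led = simdata.plant_migrants(p, [("P1", "P2", 1)], ledger,
                                         rng=np.random.default_rng(0))
        assert len(led.migrants) == 1
        assert len(p2["P2"]) == len(p["P2"]) + 1

    def test_gen2_draws_one_allele_per_pool(self):
        # disjoint allele pools make parental origin verifiable
        a = np.full((5, 3, 2), 10)
        b = np.full((5, 3, 2), 50)
        pops = {"A": a, "B": b}
        p2, led = simdata.plant_migrants(pops, [("A", "B", 2)],
                                         rng=np.random.default_rng(1))
        geno = p2["B"][-1]
        for locus in range(3):
            assert sorted(geno[locus]) == [10, 50]

    def test_source_equals_dest_rejected(self, pops):
        p, _, _ = pops
        with pytest.raises(ValueError):
            simdata.plant_migrants(p, [("P1", "P1", 1)])

    def test_unknown_population_rejected(self, pops):
        p, _, _ = pops
        with pytest.raises(KeyError):
            simdata.plant_migrants(p, [("P1", "XX", 1)])


class TestNoninvasiveSampling:
    @pytest.fixture()
    def pops(self):
        cfg = simdata.SimConfig(seed=12, n_pops=2, effective_size=30,
                                n_generations=30)
        return simdata.gen_metapopulation(cfg)

    def test_zero_dropout_replicates_identical(self, pops):
        p, loci, _ = pops
        cfg = simdata.SimConfig(seed=0, dropout_rate=0.0,
                                missing_locus_rate=0.0, replicate_count=3,
                                samples_per_pop=5)
        sets, truth = simdata.gen_noninvasive_samples(
            p, loci, cfg, rng=np.random.default_rng(1))
        for reps in sets:
            for r in reps[1:]:
                assert r.loci == reps[0].loci

    def test_false_homozygote_rate_matches_dropout_model(self, pops):
        """A heterozygote typed once with per-allele dropout d shows a
        false homozygote with probability 2 d (1 - d); measured over
        10,000 locus draws this must sit inside the binomial 99% CI."""
        p, loci, _ = pops
        d = 0.2
        cfg = simdata.SimConfig(seed=0, dropout_rate=d,
                                missing_locus_rate=0.0, replicate_count=1,
                                samples_per_pop=30)
        rng = np.random.default_rng(3)
        n_het = n_false_hom = 0
        for _ in range(30):
            sets, truth = simdata.gen_noninvasive_samples(p, loci, cfg,
                                                          rng=rng)
            for reps, (_, row) in zip(sets, truth.iterrows()):
                true_geno = {
                    loci[l]: tuple(sorted(p[row["population"]][row["index"], l]))
                    for l in range(len(loci))}
                for locus, t in true_geno.items():
                    if t[0] == t[1]:
                        continue
                    n_het += 1
                    call = reps[0].loci.get(locus)
                    if call is not None and call[0] == call[1]:
                        n_false_hom += 1
        expected = 2 * d * (1 - d)
        se = np.sqrt(expected * (1 - expected) / n_het)
        assert n_het > 5000
        assert abs(n_false_hom / n_het - expected) < 2.6 * se

    def test_total_locus_failure_breaks_consensus(self, pops):
        p, loci, _ = pops
        cfg = simdata.SimConfig(seed=0, missing_locus_rate=1.0,
                                replicate_count=5, samples_per_pop=3)
        sets, _ = simdata.gen_noninvasive_samples(
            p, loci, cfg, rng=np.random.default_rng(0))
        cons, _ = consensus_genotype(sets[0])
        assert cons.n_typed() == 0


class TestDetectionHistories:
    def test_perfect_detection_naive_matches_psi(self, rng):
        cfg = simdata.SimConfig(seed=0)
        hist, z = simdata.gen_detection_histories(
            np.full(2000, 0.5), 1.0, cfg, n_surveys=np.full(2000, 3),
            rng=rng)
        naive = np.mean([h.detected() for h in hist])
        assert naive == pytest.approx(0.5, abs=0.04)

    def test_closure_no_detection_when_unoccupied(self, rng):
        cfg = simdata.SimConfig(seed=0)
        hist, z = simdata.gen_detection_histories(
            np.full(300, 0.5), 0.4, cfg, n_surveys=np.full(300, 6), rng=rng)
        for h, occ in zip(hist, z):
            if not occ:
                assert not h.detected()

    def test_detection_fraction_closed_form(self, rng):
        """With psi=0.6 and p=0.3 over 5 surveys, occupied sites are
        detected with probability 1 - 0.7^5 = 0.832."""
        cfg = simdata.SimConfig(seed=0)
        hist, z = simdata.gen_detection_histories(
            np.full(4000, 0.6), 0.3, cfg, n_surveys=np.full(4000, 5),
            rng=rng)
        det_occ = np.mean([h.detected() for h, o in zip(hist, z) if o])
        assert det_occ == pytest.approx(1 - 0.7 ** 5, abs=0.02)

    def test_zero_survey_grid_flagged(self, rng):
        cfg = simdata.SimConfig(seed=0)
        hist, _ = simdata.gen_detection_histories(
            np.array([0.5, 0.5]), 0.3, cfg, n_surveys=np.array([0, 4]),
            rng=rng)
        assert hist[0].flagged == "unsurveyed"
        assert hist[0].outcomes == []

    def test_invalid_probabilities_rejected(self, rng):
        cfg = simdata.SimConfig(seed=0)
        with pytest.raises(ValueError):
            simdata.gen_detection_histories(np.array([1.5]), 0.3, cfg,
                                            rng=rng)


class TestResistanceMigration:
    def test_rows_sum_to_one_and_decay(self):
        rd = np.array([[0.0, 1.0, 5.0],
                       [1.0, 0.0, 2.0],
                       [5.0, 2.0, 0.0]])
        m = simdata.migration_from_resistance(rd, base_rate=0.05)
        np.testing.assert_allclose(m.sum(axis=1), 1.0)
        assert m[0, 1] > m[0, 2]      # lower resistance, more migrants
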