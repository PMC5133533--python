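"""Synthetic cohort generator: determinism, Mendelian consistency,
distributional checks, and the type-I-error machinery."""

import numpy as np
import pytest
from scipy.stats import kstest

from regskat.pedigree import kinship, relatedness_covariance
from regskat.simulate import (
    SimulationConfig,
    power_experiment,
    simulate_cohort,
    simulate_genotypes,
    simulate_pedigree,
    type1_experiment,
    write_cohort,
)

SMALL = dict(n_families=6, n_windows=5, variants_per_window=8)


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(variants_per_window=0)
        with pytest.raises(ValueError):
            SimulationConfig(category_probs=(0.5, 0.5, 0.1, 0, 0, 0))
        with pytest.raises(ValueError):
            SimulationConfig(sigma2_g=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(effect_model="telepathy")

    def test_pedigree_structure(self):
        ped = simulate_pedigree(SimulationConfig(n_families=3))
        assert len(ped.individuals) == 33  # 11 per family
        kin = kinship(ped)
        cov = relatedness_covariance(kin)
        assert np.allclose(np.diag(cov), 1.0)


class TestGeneDropping:
    def test_mendelian_consistency_everywhere(self, rng):
        """Each offspring's allele count must be achievable by one
        transmitted allele per parent."""
        ped = simulate_pedigree(SimulationConfig(n_families=4))
        mafs = rng.uniform(0.05, 0.4, size=60)
        G = simulate_genotypes(ped, mafs, rng)
        idx = {iid: k for k, iid in enumerate(ped.ids)}
        for ind in ped.individuals:
            if ind.father_id is None:
                continue
            child = G[idx[ind.individual_id]]
            lo = np.zeros_like(child)
            hi = np.zeros_like(child)
            for parent in (ind.father_id, ind.mother_id):
                pg = G[idx[parent]]
                lo += pg == 2
                hi += pg >= 1
            assert np.all(child >= lo) and np.all(child <= hi)

    def test_founder_allele_frequency_matches_target(self, rng):
        ped = simulate_pedigree(SimulationConfig(n_families=50))
        founders = [i for i, ind in enumerate(ped.individuals)
                    if ind.father_id is None and ind.mother_id is None]
        maf = 0.3
        G = simulate_genotypes(ped, np.full(200, maf), rng)
        emp = G[np.array(founders)].mean() / 2.0
        n_alleles = 2 * len(founders) * 200
        se = np.sqrt(maf * (1 - maf) / n_alleles)
        assert emp == pytest.approx(maf, abs=4 * se)


class TestCohort:
    def test_fixed_seed_is_reproducible(self):
        cfg = SimulationConfig(seed=11, **SMALL)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        assert np.array_equal(a.G, b.G)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.categories, b.categories)
        assert a.covariates.equals(b.covariates)

    def test_null_model_has_zero_effects(self):
        cohort = simulate_cohort(SimulationConfig(seed=3, **SMALL))
        assert np.all(cohort.beta == 0.0)

    def test_doubleton_planted_with_category1(self):
        cfg = SimulationConfig(seed=5, effect_model="doubleton",
                               effect_size=40.0, **SMALL)
        cohort = simulate_cohort(cfg)
        j = int(np.flatnonzero(cohort.beta)[0])
        g = cohort.G[:, j]
        assert g.sum() == 2.0 and g.max() == 1.0
        assert cohort.categories[j] == 1
        sl = cohort.window_slices[cfg.n_windows // 2]
        assert sl.start <= j < sl.stop

    def test_phenotype_replicates_share_fixed_part(self, rng):
        cohort = simulate_cohort(SimulationConfig(seed=9, **SMALL))
        Y = cohort.phenotypes(rng, n_replicates=3)
        assert Y.shape == (3, len(cohort.ids))
        assert not np.allclose(Y[0], Y[1])  # noise redrawn


class TestFileRoundTrip:
    def test_written_cohort_reproduces_matrix_through_readers(self, tmp_path):
        from regskat.annotate import categories_from_table, read_annotation
        from regskat.io import read_genotypes
        from regskat.pedigree import read_pedigree

        cfg = SimulationConfig(seed=21, **SMALL)
        cohort = simulate_cohort(cfg)
        paths = write_cohort(cohort, tmp_path)

        ped = read_pedigree(paths["ped"])
        assert ped.ids == cohort.ids

        variants, G = read_genotypes(paths["vcf"])
        assert np.array_equal(G, cohort.G)
        assert np.array_equal(variants["pos"].to_numpy(), cohort.positions)

        cats = categories_from_table(read_annotation(paths["annotations"]))
        assert [c.value for c in cats] == list(cohort.categories)


@pytest.fixture(scope="module")
def small_type1():
    cfg = SimulationConfig(n_families=10, n_windows=10,
                           variants_per_window=10, n_replicates=60, seed=17)
    return cfg, type1_experiment(cfg)


class TestExperiments:
    def test_same_seed_gives_identical_rates(self, small_type1):
        cfg, res = small_type1
        again = type1_experiment(cfg)
        assert again.rates == res.rates

    def test_alpha_one_rejects_everything(self, small_type1):
        _, res = small_type1
        assert np.all(res.p_values <= 1.0)
        assert float(np.mean(res.p_values < 1.0)) == 1.0

    def test_null_pvalues_roughly_uniform(self, small_type1):
        """KS uniformity per method over window x replicate null p-values."""
        _, res = small_type1
        for t in range(res.p_values.shape[2]):
            p = res.p_values[:, :, t].ravel()
            p = p[np.isfinite(p)]
            assert kstest(p, "uniform").pvalue > 0.01

    def test_type1_requires_null_model(self):
        with pytest.raises(ValueError):
            type1_experiment(SimulationConfig(effect_model="doubleton",
                                              effect_size=1.0))

    def test_informative_annotation_boosts_weighted_tests(self):
        """With causal variants confined to category 1, the
        annotation-weighted tests reject the causal window at least as
        often as their unweighted counterparts."""
        cfg = SimulationConfig(n_families=12, n_windows=4,
                               variants_per_window=10, n_replicates=60,
                               effect_model="category1", effect_size=1.5,
                               seed=29)
        res = power_experiment(cfg)
        assert res.power["regSKAT"] >= res.power["uwSKAT"]
        assert res.power["regT5"] >= res.power["T5"]
        assert res.power["regSKAT"] > 0.2
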