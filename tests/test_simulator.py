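"""Life-cycle simulator: initialization, generational step contracts,
null-allele injection, drift and reproducibility."""

import numpy as np
import pytest
from dataclasses import replace

import finescale as fs
from finescale.simulate import (DEFAULT_ALLELE_COUNTS, sample_window,
                                twenty_locus_scenario)


def _exp_het(pop):
    hs = []
    for l in range(pop.n_loci):
        c = pop.geno[:, l, :].ravel()
        c = c[c > 0]
        _, cnt = np.unique(c, return_counts=True)
        p = cnt / cnt.sum()
        hs.append(1 - (p ** 2).sum())
    return float(np.mean(hs))


class TestScenario:
    def test_reference_density_gives_180_individuals_on_9ha(self):
        s = fs.SimScenario(sigma_g=12, density=20)
        assert s.area_ha == pytest.approx(9.0)
        assert s.n_individuals == 180

    def test_kernel_decomposition_identity(self):
        s = fs.SimScenario(sigma_g=12, density=20, kernel_mode="seed_pollen")
        assert s.sigma_seed ** 2 + s.sigma_pollen ** 2 / 2 == pytest.approx(
            s.sigma_g ** 2, rel=1e-9)
        assert s.sigma_seed / s.sigma_pollen == pytest.approx(0.1)

    def test_named_scenarios_parameterization(self):
        scen = fs.named_scenarios()
        got = {k: (v.sigma_g, v.density) for k, v in scen.items()}
        assert got == {"HIGH-SGS": (12.0, 20.0), "Fl-like": (12.0, 35.0),
                       "Fh-like": (29.0, 50.0), "LOW-SGS": (72.0, 145.0)}

    def test_twenty_locus_mode_tiles_the_four_locus_panel(self):
        s20 = twenty_locus_scenario(fs.SimScenario(sigma_g=12, density=20))
        assert s20.n_loci == 20
        assert s20.alleles_per_locus == DEFAULT_ALLELE_COUNTS * 5

    def test_degenerate_scenarios_rejected(self):
        with pytest.raises(ValueError):
            fs.SimScenario(sigma_g=0, density=20)
        with pytest.raises(ValueError):
            fs.SimScenario(sigma_g=12, density=20, overlap=1.0)
        with pytest.raises(ValueError):
            fs.SimScenario(sigma_g=12, density=1, area_ha=1.0)


class TestInitPopulation:
    def test_fixed_allele_makes_monomorphic_locus(self):
        af = fs.AlleleFrequencies(["L1"], [{7: 1.0}], np.array([2]),
                                  np.array([1]))
        s = fs.SimScenario(sigma_g=12, density=20, area_ha=1.0, n_loci=1,
                           alleles_per_locus=[1], init_freqs=af, seed=0)
        pop = fs.init_population(s)
        assert (pop.geno == 7).all()

    def test_initial_frequencies_within_binomial_error(self):
        # 10 replicates of N=500: observed freqs close to their target
        af = fs.AlleleFrequencies(
            ["L1"], [{1: 0.5, 2: 0.3, 3: 0.2}], np.array([1000]),
            np.array([500]))
        devs = []
        for rep in range(10):
            s = fs.SimScenario(sigma_g=12, density=100, area_ha=5.0, n_loci=1,
                               alleles_per_locus=[3], init_freqs=af, seed=rep)
            pop = fs.init_population(s)
            obs = fs.allele_frequencies(pop)
            for a, p in af.freqs[0].items():
                se = np.sqrt(p * (1 - p) / (2 * pop.n_ind))
                devs.append(abs(obs.freqs[0][a] - p) / se)
        # ~3 sigma on every cell across 10 reps would be extreme
        assert np.mean(devs) < 1.5 and max(devs) < 4.5


class TestStepGeneration:
    def test_half_overlap_replaces_exactly_half(self):
        s = fs.SimScenario(sigma_g=12, density=100, area_ha=1.0, seed=1)
        rng = np.random.default_rng(1)
        pop = fs.init_population(s, rng)
        new = fs.step_generation(pop, s, rng, generation=1)
        assert new.n_ind == pop.n_ind
        changed = sum(a != b for a, b in zip(pop.ids, new.ids))
        assert changed == 50
        # recruits occupy the vacated sites: coordinates unchanged
        assert np.array_equal(new.x, pop.x) and np.array_equal(new.y, pop.y)

    def test_monomorphic_population_stays_monomorphic(self):
        af = fs.AlleleFrequencies(["L1"], [{3: 1.0}], np.array([2]),
                                  np.array([1]))
        s = fs.SimScenario(sigma_g=12, density=50, area_ha=1.0, n_loci=1,
                           alleles_per_locus=[1], init_freqs=af, seed=2)
        rng = np.random.default_rng(2)
        pop = fs.init_population(s, rng)
        for gen in range(5):
            pop = fs.step_generation(pop, s, rng, gen)
        assert (pop.geno == 3).all()

    def test_wide_kernel_limit_mother_choice_uniform(self):
        # sigma -> infinity: mothers drawn uniformly among candidates
        from scipy.stats import chisquare
        s = fs.SimScenario(sigma_g=1e9, density=50, area_ha=1.0, seed=3,
                           overlap=0.5)
        rng = np.random.default_rng(3)
        pop = fs.init_population(s, rng)
        from finescale.simulate import _gumbel_pick, _torus_d2
        d2 = _torus_d2(pop.x[:1], pop.y[:1], pop.x, pop.y, s.side_m)
        logw = np.repeat(-d2 / (2 * s.sigma_g ** 2), 10000, axis=0)
        picks = _gumbel_pick(logw, rng)
        counts = np.bincount(picks, minlength=pop.n_ind)
        _, p = chisquare(counts)
        assert p > 0.001

    def test_run_is_bit_reproducible_for_fixed_seed(self):
        s = fs.SimScenario(sigma_g=29, density=50, area_ha=1.0,
                           generations=4, seed=11)
        r1 = fs.run_scenario(s, n_reps=2)
        r2 = fs.run_scenario(s, n_reps=2)
        assert r1.records.equals(r2.records)
        for rep in r1.snapshots:
            assert np.array_equal(r1.snapshots[rep].geno,
                                  r2.snapshots[rep].geno)


class TestRunScenario:
    def test_generation_zero_population_is_unstructured(self):
        s = fs.SimScenario(sigma_g=12, density=68, area_ha=2.0,
                           generations=0, record_at=(0,), seed=4)
        inside = 0
        reps = 20
        for rep in range(reps):
            rng = np.random.default_rng(np.random.SeedSequence([4, rep]))
            pop = fs.init_population(s, rng)
            samp = sample_window(pop, s, rng)
            cg = fs.correlogram(samp, estimator="loiselle_F", n_perm=49,
                                n_boot=0, seed=rep)
            inside += bool(cg.perm_lo[0] <= cg.estimate[0] <= cg.perm_hi[0])
        assert inside >= int(0.9 * reps)

    def test_sgs_strength_ordered_by_neighbourhood_size(self):
        meds = {}
        for name, s in fs.named_scenarios().items():
            s = replace(s, generations=32, record_at=(32,), seed=6)
            res = fs.run_scenario(s, n_reps=8, keep_snapshots=False)
            meds[name] = res.records.query("generation == 32").F1.median()
        assert meds["HIGH-SGS"] > meds["Fl-like"] > meds["Fh-like"] \
            > meds["LOW-SGS"]

    def test_heterozygosity_drift_within_wright_bound(self):
        # near-panmictic scenario, N=580: expected-het decline over 64
        # turnover events stays under 10%
        s = replace(fs.named_scenarios()["LOW-SGS"], area_ha=4.0)
        declines = []
        for rep in range(6):
            rng = np.random.default_rng(np.random.SeedSequence([2, rep]))
            pop = fs.init_population(s, rng)
            h0 = _exp_het(pop)
            for gen in range(1, 65):
                pop = fs.step_generation(pop, s, rng, gen)
            declines.append((h0 - _exp_het(pop)) / h0)
        assert 0 < np.mean(declines) < 0.10


class TestNullAlleles:
    def test_zero_rate_is_identity(self, small_random_genotypes):
        rng = np.random.default_rng(0)
        out = fs.inject_null_alleles(small_random_genotypes, 0.0, rng)
        assert np.array_equal(out.geno, small_random_genotypes.geno)

    def test_rate_near_one_blanks_everything(self, small_random_genotypes):
        rng = np.random.default_rng(0)
        out = fs.inject_null_alleles(small_random_genotypes, 0.999999, rng)
        assert out.missing.mean() > 0.99

    def test_missing_rate_matches_q_squared(self):
        rng = np.random.default_rng(7)
        g, _ = fs.sample_island_model(1, 2500, 0.0, alleles_per_locus=[8, 8],
                                      rng=rng)
        out = fs.inject_null_alleles(g, 0.2, rng)
        rate = out.missing.mean()  # 10^4 genotypes total
        se = np.sqrt(0.04 * 0.96 / (2500 * 2))
        assert abs(rate - 0.04) < 4 * se

    def test_single_null_makes_apparent_homozygote(self):
        g = fs.GeoGenotypes(ids=["a"], plot=["P"], x=[0], y=[0],
                            geno=np.array([[[1, 2]]]), locus_names=["L"])
        rng = np.random.default_rng(1)
        seen_homs = set()
        for _ in range(50):
            out = fs.inject_null_alleles(g, 0.5, rng)
            a, b = out.geno[0, 0]
            assert (a, b) in {(1, 2), (1, 1), (2, 2), (0, 0)}
            if a == b and a != 0:
                seen_homs.add(a)
        assert seen_homs == {1, 2}
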