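"""F-statistics: Weir-Cockerham theta against brute-force variance
components, the EM null-allele estimator, the ENA correction and the
hierarchical indices."""

import numpy as np
import pytest

import finescale as fs
from finescale.fstats import _group_index, nested_components


def brute_force_theta(g, labels):
    """Independent two-level implementation: unbalanced nested ANOVA of
    allele indicators (gene copies within individuals within groups) with
    expected-sums-of-squares coefficients computed by explicit loops."""
    inv, uniq = _group_index(labels)
    num = den = 0.0
    for l in range(g.n_loci):
        typed = np.flatnonzero(~g.missing[:, l])
        alleles = sorted(set(g.geno[typed, l, :].ravel()))
        if len(alleles) < 2:
            continue
        # copy-level table: (value, group, individual)
        copies = [(int(a), int(inv[i]), int(i))
                  for i in typed for a in g.geno[i, l]]
        m = len(copies)
        for target in alleles:
            y = [1.0 if v == target else 0.0 for v, _, _ in copies]
            # uncorrected sums per grouping
            def T(keyfun):
                sums, ns = {}, {}
                for (yv, c) in zip(y, copies):
                    k = keyfun(c)
                    sums[k] = sums.get(k, 0.0) + yv
                    ns[k] = ns.get(k, 0) + 1
                return sum(s * s / ns[k] for k, s in sums.items()), ns
            T0 = sum(y) ** 2 / m
            T1, n_g = T(lambda c: c[1])
            T2, n_i = T(lambda c: (c[1], c[2]))
            T3 = sum(v * v for v in y)
            SS = [T1 - T0, T2 - T1, T3 - T2]
            # expected-value coefficients (Searle): C(G, eff)
            def C(ns_eff, parent_of, ns_par):
                return sum(n * n / ns_par[parent_of(k)]
                           for k, n in ns_eff.items())
            Ctot = {None: m}
            M = np.zeros((3, 3))
            M[0, 0] = m - C(n_g, lambda k: None, Ctot)
            M[0, 1] = C(n_i, lambda k: k[0], n_g) - C(n_i, lambda k: None, Ctot)
            M[0, 2] = len(n_g) - 1
            M[1, 1] = m - C(n_i, lambda k: k[0], n_g)
            M[1, 2] = len(n_i) - len(n_g)
            M[2, 2] = m - len(n_i)
            comp = np.linalg.solve(M, SS)
            num += comp[0]
            den += comp.sum()
    return num / den


class TestWcTheta:
    def test_identical_genotype_multisets_show_no_differentiation(self):
        geno = np.array([[[1, 2]], [[1, 1]], [[2, 2]], [[1, 2]]] * 2)
        g = fs.GeoGenotypes(ids=[str(i) for i in range(8)], plot=["P"] * 8,
                            x=np.arange(8.0), y=np.zeros(8), geno=geno,
                            locus_names=["L"])
        t = fs.wc_theta(g, [0] * 4 + [1] * 4, n_perm=199, seed=1)
        assert t.theta <= 0.0 + 1e-12
        assert t.p_value > 0.05

    def test_fixed_differences_give_theta_one(self):
        geno = np.array([[[1, 1]]] * 4 + [[[2, 2]]] * 4)
        g = fs.GeoGenotypes(ids=[str(i) for i in range(8)], plot=["P"] * 8,
                            x=np.arange(8.0), y=np.zeros(8), geno=geno,
                            locus_names=["L"])
        t = fs.wc_theta(g, [0] * 4 + [1] * 4, n_perm=0)
        assert t.theta == pytest.approx(1.0, abs=1e-12)

    def test_three_group_toy_matches_brute_force_components(self):
        rng = np.random.default_rng(1)
        geno = rng.integers(1, 4, size=(6, 2, 2))
        g = fs.GeoGenotypes(ids=[str(i) for i in range(6)], plot=["P"] * 6,
                            x=np.arange(6.0), y=np.zeros(6), geno=geno,
                            locus_names=["L1", "L2"])
        labels = [0, 0, 1, 1, 2, 2]
        t = fs.wc_theta(g, labels, n_perm=0)
        assert t.theta == pytest.approx(brute_force_theta(g, labels),
                                        abs=1e-12)

    def test_matches_brute_force_on_random_small_instances(self):
        for trial in range(20):
            rng = np.random.default_rng(100 + trial)
            n = int(rng.integers(6, 11))
            geno = rng.integers(1, 5, size=(n, 2, 2))
            geno[rng.random((n, 2)) < 0.1] = 0
            labels = rng.integers(0, 3, n)
            if len(set(labels.tolist())) < 2:
                labels[0], labels[1] = 0, 1
            g = fs.GeoGenotypes(ids=[str(i) for i in range(n)],
                                plot=["P"] * n, x=np.arange(float(n)),
                                y=np.zeros(n), geno=geno,
                                locus_names=["L1", "L2"])
            t = fs.wc_theta(g, labels, n_perm=0)
            assert t.theta == pytest.approx(brute_force_theta(g, labels),
                                            abs=1e-10)

    def test_type_one_error_calibrated(self):
        rej = 0
        for i in range(200):
            rng = np.random.default_rng(3000 + i)
            g, lab = fs.sample_island_model(2, 24, 0.0,
                                            alleles_per_locus=[10, 12],
                                            rng=rng)
            t = fs.wc_theta(g, lab, n_perm=99, seed=i)
            rej += t.p_value < 0.05
        assert rej / 200 <= 0.07


class TestEmNullFreq:
    def test_hardy_weinberg_data_gives_near_zero(self):
        rng = np.random.default_rng(7)
        g, _ = fs.sample_island_model(1, 200, 0.0, rng=rng)
        nf = fs.em_null_freq(g, np.zeros(g.n_ind))
        assert np.nanmean(nf.q) < 0.01

    def test_recovers_planted_null_frequency(self):
        rng = np.random.default_rng(7)
        g, _ = fs.sample_island_model(1, 200, 0.0, rng=rng)
        gn = fs.inject_null_alleles(g, 0.2, rng)
        nf = fs.em_null_freq(gn, np.zeros(g.n_ind))
        assert np.all(np.abs(nf.q - 0.2) < 0.05)

    def test_all_missing_locus_flagged(self):
        geno = np.zeros((6, 1, 2), dtype=int)
        g = fs.GeoGenotypes(ids=[str(i) for i in range(6)], plot=["P"] * 6,
                            x=np.arange(6.0), y=np.zeros(6), geno=geno,
                            locus_names=["L"])
        nf = fs.em_null_freq(g, np.zeros(6))
        assert np.isnan(nf.q[0, 0])
        assert any("all missing" in f for f in nf.flags)


class TestThetaEna:
    def test_reduces_to_plain_theta_without_nulls(self):
        # all-heterozygote data: no homozygote excess, no missing -> q = 0
        rng = np.random.default_rng(8)
        n = 40
        geno = np.empty((n, 2, 2), dtype=int)
        for l in range(2):
            a = rng.integers(1, 8, n)
            geno[:, l, 0] = a
            geno[:, l, 1] = a + rng.integers(1, 5, n)
        g = fs.GeoGenotypes(ids=[str(i) for i in range(n)], plot=["P"] * n,
                            x=np.arange(float(n)), y=np.zeros(n), geno=geno,
                            locus_names=["L1", "L2"])
        labels = np.repeat([0, 1], n // 2)
        tr = fs.theta_ena(g, labels)
        assert (tr.null_freq < 1e-6).all()
        assert tr.theta_ena == pytest.approx(tr.theta, abs=1e-12)

    def test_correction_tracks_truth_under_planted_nulls(self):
        # at 25% nulls the visible relative frequencies are undistorted,
        # so theta itself is nearly unbiased (the field result: negligible
        # influence of nulls on differentiation); the correction must stay
        # close to the null-free truth and never make things much worse
        err_raw, err_ena, close = [], [], 0
        sims = 30
        for i in range(sims):
            rng = np.random.default_rng(400 + i)
            g, lab = fs.sample_island_model(2, 60, 0.10, rng=rng)
            theta_true = fs.wc_theta(g, lab, n_perm=0).theta
            gn = fs.inject_null_alleles(g, 0.25, rng)
            tr = fs.theta_ena(gn, lab)
            err_raw.append(abs(tr.theta - theta_true))
            err_ena.append(abs(tr.theta_ena - theta_true))
            close += abs(tr.theta_ena - theta_true) < 0.03
        assert close >= int(0.8 * sims)
        assert np.mean(err_ena) <= np.mean(err_raw) + 0.005

    def test_unreliable_null_frequency_flagged(self):
        rng = np.random.default_rng(9)
        g, lab = fs.sample_island_model(2, 40, 0.1, rng=rng)
        gn = fs.inject_null_alleles(g, 0.72, rng)
        tr = fs.theta_ena(gn, lab)
        assert any(">= 0.5" in f for f in tr.flags)


class TestHierF:
    def test_null_hierarchy_shows_no_structure(self):
        fpt, fcp, rej_plot, rej_clu = [], [], 0, 0
        sims = 15
        for i in range(sims):
            rng = np.random.default_rng(7000 + i)
            g, _ = fs.sample_island_model(1, 120, 0.0, rng=rng)
            plots = np.repeat([0, 1, 2], 40)
            clus = np.repeat(np.arange(12), 10)
            hf = fs.hier_f(g, plots, clus, n_perm=49, seed=i)
            fpt.append(hf.f_plot_total)
            fcp.append(hf.f_clu_plot)
            rej_plot += hf.p_plot_total < 0.05
            rej_clu += hf.p_clu_plot < 0.05
        assert abs(np.mean(fpt)) < 0.01 and abs(np.mean(fcp)) < 0.01
        # nominal 5% level: a handful of rejections at most
        assert rej_plot <= 3 and rej_clu <= 3

    def test_recovers_island_model_hierarchy(self):
        rng = np.random.default_rng(77)
        g, pl, cl = fs.sample_hierarchical_island(10, 5, 20, 0.045, 0.067,
                                                  rng=rng)
        hf = fs.hier_f(g, pl, cl, n_perm=0)
        assert hf.f_plot_total == pytest.approx(0.045, abs=0.02)
        assert hf.f_clu_plot == pytest.approx(0.067, abs=0.02)

    def test_multiplicative_identity_holds_exactly(self):
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            g, pl, cl = fs.sample_hierarchical_island(3, 3, 12, 0.05, 0.08,
                                                      rng=rng)
            g.geno[rng.random((g.n_ind, g.n_loci)) < 0.1] = 0
            hf = fs.hier_f(g, pl, cl, n_perm=0)
            lhs = 1 - hf.f_ind_total
            rhs = (1 - hf.f_ind_clu) * (1 - hf.f_clu_plot) \
                * (1 - hf.f_plot_total)
            assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_merged_plots_reduce_to_two_level_theta(self, two_pop_theta10):
        g, truth = two_pop_theta10
        hf = fs.hier_f(g, np.zeros(g.n_ind), truth, n_perm=0)
        t = fs.wc_theta(g, truth, n_perm=0)
        assert hf.f_clu_plot == pytest.approx(t.theta, abs=1e-10)
        assert hf.f_plot_total == 0.0

    def test_non_nested_clusters_rejected(self, two_pop_theta10):
        g, truth = two_pop_theta10
        plots = np.arange(g.n_ind) % 2  # crosses the cluster boundaries
        with pytest.raises(ValueError, match="nested"):
            fs.hier_f(g, plots, truth)

    def test_nested_anova_matches_wc84_closed_form(self,
                                                   small_random_genotypes):
        g = small_random_genotypes
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 3, g.n_ind)
        t = fs.wc_theta(g, labels, n_perm=0)
        inv, _ = _group_index(labels)
        num = den = 0.0
        for l in range(g.n_loci):
            rows = np.flatnonzero(~g.missing[:, l])
            copies = np.concatenate([g.geno[rows, l, 0], g.geno[rows, l, 1]])
            alleles, aidx = np.unique(copies, return_inverse=True)
            lv = [np.concatenate([inv[rows]] * 2), np.concatenate([rows] * 2)]
            c = nested_components(aidx, alleles.size, lv).sum(axis=1)
            num += c[0]
            den += c.sum()
        assert t.theta == pytest.approx(num / den, abs=1e-12)
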