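"""Unit and property tests of the four PD statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from conftest import make_dataset, random_dataset
from oracles import anova_oracle, chisq_oracle, dosages, fst_oracle, nscm_oracle
from popdiff.errors import InvalidInputError
from popdiff.pd_measures import (
    PopulationSample,
    SnpDataset,
    allele_frequency,
    anova_f,
    chisq_homogeneity,
    fst_weir,
    fst_weir_frequencies,
    nscm_ssd,
)


class TestPopulationSample:
    def test_counts_must_sum_to_n(self):
        with pytest.raises(InvalidInputError):
            PopulationSample("A", 10, (5, 4, 2))

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            PopulationSample("A", 1, (2, -1, 0))

    def test_duplicate_population_ids_rejected(self):
        s = PopulationSample("A", 4, (1, 2, 1))
        with pytest.raises(InvalidInputError):
            SnpDataset("x", [s, s])

    @pytest.mark.parametrize(
        "counts,expected",
        [((25, 50, 25), 0.5), ((100, 0, 0), 1.0), ((10, 20, 70), 0.2)],
    )
    def test_allele_frequency(self, counts, expected):
        assert allele_frequency(PopulationSample("A", sum(counts), counts)) == expected

    def test_allele_frequency_empty_population(self):
        with pytest.raises(InvalidInputError):
            allele_frequency(PopulationSample("A", 0, (0, 0, 0)))


class TestFstWeir:
    def test_complete_fixation_gives_one(self):
        comp = fst_weir_frequencies([0.0, 1.0], [100, 100])
        assert comp.msg == 0 and comp.msp > 0
        assert comp.theta_hat == 1.0

    def test_zero_msp_gives_minus_one_over_nc_minus_one(self):
        comp = fst_weir_frequencies([0.5, 0.5, 0.5], [100, 100, 100])
        assert comp.msp == 0
        assert comp.n_c == 100
        assert comp.theta_hat == pytest.approx(-1 / 99, abs=1e-15)

    def test_monomorphic_everywhere_is_nan(self):
        assert math.isnan(fst_weir_frequencies([0.0, 0.0, 0.0], [50, 100, 30]).theta_hat)

    def test_matches_term_by_term_oracle_on_grid_row(self):
        comp = fst_weir_frequencies([0.1, 0.2, 0.3], [200, 200, 200])
        assert comp.theta_hat == pytest.approx(fst_oracle([0.1, 0.2, 0.3], [200, 200, 200]), abs=1e-12)

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(200):
            s = int(rng.integers(2, 6))
            p = rng.uniform(0, 1, size=s)
            n = rng.integers(2, 500, size=s)
            got = fst_weir_frequencies(p, n).theta_hat
            want = fst_oracle(list(p), list(n))
            assert got == pytest.approx(want, abs=1e-9) or (math.isnan(got) and math.isnan(want))

    def test_dataset_interface_uses_allele_units(self, rng):
        ds = random_dataset(rng)
        comp = fst_weir(ds)
        p = [allele_frequency(s) for s in ds.samples]
        n = [2 * s.n_individuals for s in ds.samples]
        assert comp.theta_hat == pytest.approx(fst_oracle(p, n), abs=1e-12)

    def test_requires_two_populations(self):
        with pytest.raises(InvalidInputError):
            fst_weir_frequencies([0.5], [100])

    def test_empty_population_rejected(self):
        ds = SnpDataset("x", [PopulationSample("A", 2, (1, 1, 0)), PopulationSample("B", 0, (0, 0, 0))])
        with pytest.raises(InvalidInputError):
            fst_weir(ds)

    @given(
        p=st.lists(st.floats(0.001, 0.999), min_size=2, max_size=5),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=100, derandomize=True)
    def test_allele_relabeling_invariance(self, p, seed):
        """theta is symmetric in allele frequency: p -> 1 - p leaves it unchanged."""
        n = list(np.random.default_rng(seed).integers(2, 300, size=len(p)))
        a = fst_weir_frequencies(p, n).theta_hat
        b = fst_weir_frequencies([1 - x for x in p], n).theta_hat
        assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b, abs=1e-9)

    def test_relabeling_preserves_degenerate_cases(self):
        assert math.isnan(fst_weir_frequencies([1.0, 1.0], [50, 50]).theta_hat)
        assert fst_weir_frequencies([1.0, 0.0], [50, 50]).theta_hat == 1.0

    def test_nc_collapses_to_common_size_when_balanced(self, rng):
        for _ in range(20):
            s = int(rng.integers(2, 6))
            ni = int(rng.integers(2, 400))
            p = rng.uniform(0, 1, size=s)
            assert fst_weir_frequencies(p, [ni] * s).n_c == pytest.approx(ni, abs=1e-9)

    def test_two_population_large_n_limit(self):
        """For two equal large samples theta approaches the classical
        (p1 - p2)^2 / (2 p_bar q_bar)-free moment form within O(1/n)."""
        p1, p2, n = 0.2, 0.6, 10**4
        pbar, qbar = (p1 + p2) / 2, 1 - (p1 + p2) / 2
        d2 = (p1 - p2) ** 2
        classical = d2 / (d2 / 2 + 2 * pbar * qbar)
        got = fst_weir_frequencies([p1, p2], [n, n]).theta_hat
        assert got == pytest.approx(classical, abs=1 / n * 10)

    def test_theta_never_exceeds_one(self, rng):
        for _ in range(100):
            ds = random_dataset(rng)
            th = fst_weir(ds).theta_hat
            assert math.isnan(th) or th <= 1.0 + 1e-12


class TestChisqHomogeneity:
    def test_homogeneous_table_gives_zero(self):
        # allele counts 50/150 in each population: (n_AA, n_Aa, n_aa) with p = 0.25
        ds = make_dataset([(0, 50, 50)] * 3)
        res = chisq_homogeneity(ds)
        assert res.value == pytest.approx(0, abs=1e-12)
        assert res.p_value == pytest.approx(1, abs=1e-12)

    def test_hand_summed_oracle(self):
        # allele tables [[30,70],[50,50],[70,30]] via (n_AA, n_Aa, n_aa)
        ds = make_dataset([(0, 30, 20), (0, 50, 0), (20, 30, 0)])
        table = [[30, 70], [50, 50], [70, 30]]
        x2, df = chisq_oracle(table)
        res = chisq_homogeneity(ds)
        assert df == 2
        assert res.value == pytest.approx(x2, abs=1e-9)
        assert res.p_value == pytest.approx(stats.chi2.sf(x2, 2), abs=1e-12)

    def test_equal_proportions_different_sizes(self):
        ds = make_dataset([(10, 20, 10), (20, 40, 20)])
        assert chisq_homogeneity(ds).value == pytest.approx(0, abs=1e-12)

    def test_fixed_allele_everywhere(self):
        ds = make_dataset([(10, 0, 0), (20, 0, 0)])
        res = chisq_homogeneity(ds)
        assert res.value == 0 and res.p_value == 1

    def test_matches_generic_contingency_oracle(self, rng):
        for _ in range(100):
            ds = random_dataset(rng, s=int(rng.integers(2, 5)))
            a = np.array([s.allele_count for s in ds.samples])
            tot = np.array([s.n_alleles for s in ds.samples])
            obs = np.stack([a, tot - a], axis=1)
            obs = obs[:, obs.sum(axis=0) > 0]
            if obs.shape[1] < 2:
                continue
            want = stats.chi2_contingency(obs, correction=False)
            got = chisq_homogeneity(ds)
            assert got.value == pytest.approx(want[0], abs=1e-9)
            assert got.p_value == pytest.approx(want[1], abs=1e-9)

    def test_genotype_table_variant(self, rng):
        ds = random_dataset(rng)
        obs = np.array([s.genotype_counts for s in ds.samples])
        obs = obs[:, obs.sum(axis=0) > 0]
        want = stats.chi2_contingency(obs, correction=False)
        got = chisq_homogeneity(ds, table="genotype")
        assert got.value == pytest.approx(want[0], abs=1e-9)


class TestAnovaF:
    def test_equal_group_means_give_zero_f(self):
        ds = make_dataset([(25, 50, 25)] * 3)
        res = anova_f(ds)
        assert res.f_stat == pytest.approx(0, abs=1e-12)
        assert res.p_value == pytest.approx(1, abs=1e-12)

    def test_degenerate_within_variance(self):
        ds = make_dataset([(10, 0, 0), (0, 0, 10)])
        res = anova_f(ds)
        assert res.f_stat == math.inf and res.p_value == 0

    def test_all_values_identical(self):
        ds = make_dataset([(10, 0, 0), (5, 0, 0)])
        res = anova_f(ds)
        assert math.isnan(res.f_stat) and res.p_value == 1.0

    def test_textbook_sums_of_squares_oracle(self):
        # dosages pop1: 0,1,2,1; pop2: 2,2,1,1; pop3: 0,0,1,1
        ds = make_dataset([(1, 2, 1), (2, 2, 0), (0, 2, 2)])
        f_want, _, _ = anova_oracle([[0, 1, 2, 1], [2, 2, 1, 1], [0, 0, 1, 1]])
        assert anova_f(ds).f_stat == pytest.approx(f_want, abs=1e-9)

    def test_matches_scipy_f_oneway(self, rng):
        for _ in range(100):
            ds = random_dataset(rng, s=int(rng.integers(2, 5)))
            groups = [dosages(s.genotype_counts) for s in ds.samples]
            if any(len(set(g)) for g in groups) and len({x for g in groups for x in g}) > 1:
                want = stats.f_oneway(*groups)
                got = anova_f(ds)
                if math.isfinite(got.f_stat):
                    assert got.f_stat == pytest.approx(want.statistic, abs=1e-9)
                    assert got.p_value == pytest.approx(want.pvalue, abs=1e-9)

    def test_two_groups_equal_squared_t(self, rng):
        """With two populations F equals the square of the pooled t statistic."""
        for _ in range(30):
            ds = random_dataset(rng, s=2)
            g1, g2 = (dosages(s.genotype_counts) for s in ds.samples)
            t = stats.ttest_ind(g1, g2, equal_var=True)
            got = anova_f(ds)
            if math.isfinite(got.f_stat):
                assert got.f_stat == pytest.approx(t.statistic**2, abs=1e-9)

    def test_weighted_effects_sum_to_zero(self, rng):
        ds = random_dataset(rng)
        res = anova_f(ds)
        n = [s.n_individuals for s in ds.samples]
        assert sum(ni * e for ni, e in zip(n, res.group_effects)) == pytest.approx(0, abs=1e-9)

    def test_needs_more_individuals_than_groups(self):
        ds = make_dataset([(1, 0, 0), (0, 1, 0), (0, 0, 1)])
        with pytest.raises(InvalidInputError):
            anova_f(ds)


class TestNscmSsd:
    def test_zero_distance_when_means_equal(self):
        panel = [make_dataset([(25, 50, 25)] * 3, "a"), make_dataset([(10, 30, 60)] * 3, "b")]
        comps = nscm_ssd(panel)
        assert comps[0].ss_d == pytest.approx(0, abs=1e-12)
        assert all(d == pytest.approx(0, abs=1e-12) for d in comps[0].d)

    def test_s0_is_median_of_pooled_sds(self, rng):
        panel = [random_dataset(rng, snp_id=f"s{i}") for i in range(3)]
        # force a common structure
        panel = [make_dataset([s.genotype_counts for s in panel[0].samples], f"s{i}") for i in range(1)] or panel
        panel = [random_dataset(rng, snp_id="x")]
        base = [s.genotype_counts for s in panel[0].samples]
        ns = [sum(c) for c in base]
        panel = []
        for i in range(3):
            counts = []
            for n in ns:
                p = rng.uniform(0.1, 0.9)
                counts.append(tuple(int(c) for c in rng.multinomial(n, [p * p, 2 * p * (1 - p), (1 - p) ** 2])))
            panel.append(make_dataset(counts, f"s{i}"))
        comps = nscm_ssd(panel)
        sks = sorted(c.pooled_sd for c in comps)
        assert comps[0].s0 == pytest.approx(sks[1], abs=1e-12)

    def test_step_by_step_oracle_on_toy_panel(self):
        panel_counts = [
            [(1, 2, 1), (2, 2, 0), (0, 2, 2)],
            [(0, 1, 3), (3, 1, 0), (1, 1, 2)],
        ]
        panel = [make_dataset(c, f"s{i}") for i, c in enumerate(panel_counts)]
        want, s0 = nscm_oracle(panel_counts, [4, 4, 4])
        comps = nscm_ssd(panel)
        assert comps[0].s0 == pytest.approx(s0, abs=1e-12)
        for c, w in zip(comps, want):
            assert c.ss_d == pytest.approx(w, abs=1e-9)

    def test_matches_oracle_on_random_panels(self, rng):
        for _ in range(30):
            ns = [int(rng.integers(4, 40)) for _ in range(3)]
            panel_counts = []
            for _ in range(int(rng.integers(1, 6))):
                counts = []
                for n in ns:
                    p = rng.uniform(0, 1)
                    counts.append(tuple(int(c) for c in rng.multinomial(n, [p * p, 2 * p * (1 - p), (1 - p) ** 2])))
                panel_counts.append(counts)
            panel = [make_dataset(c, f"s{i}") for i, c in enumerate(panel_counts)]
            want, _ = nscm_oracle(panel_counts, ns)
            got = [c.ss_d for c in nscm_ssd(panel)]
            for g, w in zip(got, want):
                assert g == pytest.approx(w, abs=1e-9) or (math.isinf(g) and math.isinf(w))

    def test_snp_order_invariance(self, rng):
        ns = [10, 12, 8]
        panel_counts = []
        for _ in range(5):
            counts = []
            for n in ns:
                p = rng.uniform(0.1, 0.9)
                counts.append(tuple(int(c) for c in rng.multinomial(n, [p * p, 2 * p * (1 - p), (1 - p) ** 2])))
            panel_counts.append(counts)
        panel = [make_dataset(c, f"s{i}") for i, c in enumerate(panel_counts)]
        fwd = {c.snp_id: c.ss_d for c in nscm_ssd(panel)}
        rev = {c.snp_id: c.ss_d for c in nscm_ssd(panel[::-1])}
        assert fwd == rev

    def test_empty_panel_rejected(self):
        with pytest.raises(InvalidInputError):
            nscm_ssd([])

    def test_mismatched_structure_rejected(self, rng):
        a = make_dataset([(2, 2, 0), (1, 2, 1)], "a")
        b = make_dataset([(2, 2, 0), (1, 2, 2)], "b")  # different n
        with pytest.raises(InvalidInputError):
            nscm_ssd([a, b])

    def test_literal_m_mode_scales_distances(self):
        panel = [make_dataset([(4, 0, 0), (0, 0, 4), (2, 0, 2)], "a")]
        sq = nscm_ssd(panel, m_mode="sqrt")[0]
        lit = nscm_ssd(panel, m_mode="literal")[0]
        assert sq.ss_d != lit.ss_d
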