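"""Synthetic-data generator: pedigree structure, Mendelian transmission,
variance-component ground truth, liability and ordinal coding."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famvar import (
    ConfigError,
    SimConfig,
    dichotomize_liability,
    encode_ordinal,
    simulate_genotypes,
    simulate_pedigree,
    simulate_study,
)
from famvar.pedigree import Pedigree, PedigreeError


def mendel_consistent(child, father, mother):
    """Independent trio checker: child dosage must be attainable from one
    allele of each parent."""
    pat_opts = {0} if father == 0 else {1} if father == 2 else {0, 1}
    mat_opts = {0} if mother == 0 else {1} if mother == 2 else {0, 1}
    return child in {a + b for a in pat_opts for b in mat_opts}


class TestPedigree:
    def test_minimal_family(self):
        cfg = SimConfig(n_families=1, offspring_range=(2, 2), third_generation=False)
        ped = simulate_pedigree(cfg)
        assert ped.n == 4
        assert len(ped.founders()) == 2
        assert len(ped.full_sib_pairs()) == 1
        assert len(ped.nuclear_families()) == 1

    def test_no_cycles_and_parents_present(self):
        cfg = SimConfig(n_families=500, offspring_range=(1, 3), seed=5)
        ped = simulate_pedigree(cfg)
        # independent cycle check via networkx topological sort
        import networkx as nx

        g = nx.DiGraph()
        for row in ped.trios().itertuples(index=False):
            g.add_edge(row.father_id, row.child_id)
            g.add_edge(row.mother_id, row.child_id)
        list(nx.topological_sort(g))  # raises on a cycle
        known = set(ped.ids)
        tab = ped.table
        listed = pd.concat([tab["father_id"], tab["mother_id"]]).dropna()
        assert set(listed) <= known

    def test_third_generation_links_families(self):
        cfg = SimConfig(n_families=40, offspring_range=(2, 2), mate_fraction=0.5, seed=9)
        ped = simulate_pedigree(cfg)
        assert (ped.table["generation"] == 2).any()
        comps = ped.extended_components()
        assert any(len(c) > 6 for c in comps)  # some merged extended families

    def test_zero_families_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(n_families=0)

    def test_generation_labels_consistent(self):
        cfg = SimConfig(n_families=30, offspring_range=(1, 2), seed=2)
        ped = simulate_pedigree(cfg)
        gen = ped.table.set_index("id")["generation"]
        for row in ped.trios().itertuples(index=False):
            assert gen[row.child_id] > gen[row.father_id]
            assert gen[row.child_id] > gen[row.mother_id]

    def test_single_known_parent_rejected(self):
        tab = pd.DataFrame(
            {
                "id": ["f", "m", "c"],
                "father_id": [None, None, "f"],
                "mother_id": [None, None, None],
                "sex": ["M", "F", "M"],
                "family_id": ["x"] * 3,
                "generation": [0, 0, 1],
            }
        )
        with pytest.raises(PedigreeError):
            Pedigree(tab)


class TestGenotypes:
    def test_forced_heterozygote(self):
        """AA x aa parents give dosage-1 children at every such SNP."""
        cfg = SimConfig(n_families=5, offspring_range=(2, 2), n_snps=50,
                        n_causal_snps=10, seed=1, third_generation=False)
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        idx = {i: k for k, i in enumerate(ped.ids)}
        for row in ped.trios().itertuples(index=False):
            f, m, c = (geno.dosages[idx[row.father_id]],
                       geno.dosages[idx[row.mother_id]],
                       geno.dosages[idx[row.child_id]])
            forced = ((f == 2) & (m == 0)) | ((f == 0) & (m == 2))
            assert (c[forced] == 1).all()

    def test_founder_frequency_matches_binomial(self):
        cfg = SimConfig(n_families=5000, offspring_range=(1, 1), n_snps=1,
                        n_causal_snps=1, maf_range=(0.3, 0.3), seed=3,
                        third_generation=False)
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        founders = np.isin(geno.ids, ped.founders())
        mean = geno.dosages[founders, 0].mean()
        se = np.sqrt(2 * 0.3 * 0.7 / founders.sum())
        assert abs(mean - 0.6) < 3 * se

    def test_gene_dropping_is_mendelian(self):
        cfg = SimConfig(n_families=60, offspring_range=(1, 3), n_snps=30,
                        n_causal_snps=5, seed=7)
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        idx = {i: k for k, i in enumerate(ped.ids)}
        for row in ped.trios().itertuples(index=False):
            for j in range(geno.m):
                assert mendel_consistent(
                    geno.dosages[idx[row.child_id], j],
                    geno.dosages[idx[row.father_id], j],
                    geno.dosages[idx[row.mother_id], j],
                )

    def test_fixed_seed_reproducible(self):
        cfg = SimConfig(n_families=20, offspring_range=(1, 2), n_snps=40,
                        n_causal_snps=5, seed=11)
        g1 = simulate_genotypes(simulate_pedigree(cfg), cfg)
        g2 = simulate_genotypes(simulate_pedigree(cfg), cfg)
        assert np.array_equal(g1.dosages, g2.dosages)


class TestPhenotype:
    def test_component_sharing_and_variances(self, small_study):
        """Couple/sib/family members share their environmental component
        exactly; each component's realized variance equals its target."""
        cfg, ped, geno, pheno, truth = small_study
        comp = truth.components.set_index("id")
        for a, b in truth.couples:
            assert comp.at[a, "u_C"] == comp.at[b, "u_C"]
        for sibs in ped.sibships():
            vals = comp.loc[sibs, "u_S"]
            assert vals.nunique() == 1
        fr = cfg.fractions
        for role in ("G", "K", "F", "C"):
            assert np.isclose(comp[f"u_{role}"].var(ddof=0), fr[role], atol=1e-10)

    def test_null_model_relative_correlation(self):
        cfg = SimConfig(n_families=400, offspring_range=(2, 2), n_snps=50,
                        n_causal_snps=5, var_fractions={}, seed=13,
                        third_generation=False)
        ped, geno, pheno, truth = simulate_study(cfg)
        tab = pheno.set_index("id")
        sib_pairs = ped.full_sib_pairs()
        a = tab.loc[[p[0] for p in sib_pairs], "trait"].to_numpy()
        b = tab.loc[[p[1] for p in sib_pairs], "trait"].to_numpy()
        r = np.corrcoef(a, b)[0, 1]
        assert abs(r) < 3 / np.sqrt(len(sib_pairs))

    def test_couple_correlation_reflects_shared_environment(self, small_study):
        cfg, ped, geno, pheno, truth = small_study
        tab = pheno.set_index("id")
        a = tab.loc[[p[0] for p in truth.couples], "trait"].to_numpy()
        b = tab.loc[[p[1] for p in truth.couples], "trait"].to_numpy()
        r = np.corrcoef(a, b)[0, 1]
        # couples share u_C and u_F: expect at least the C fraction
        assert r >= cfg.fractions["C"] - 3 / np.sqrt(len(truth.couples))

    def test_partner_effect_slope_recovered(self):
        cfg = SimConfig(n_families=2000, offspring_range=(1, 1), n_snps=200,
                        n_causal_snps=50, var_fractions={}, partner_effect=0.1,
                        seed=17, third_generation=False)
        ped, geno, pheno, truth = simulate_study(cfg)
        comp = truth.components.set_index("id")
        tab = pheno.set_index("id")
        own = tab.loc[[p[0] for p in truth.couples], "trait"].to_numpy()
        partner_g = comp.loc[[p[1] for p in truth.couples], "g_std"].to_numpy()
        slope = np.polyfit(partner_g, own, 1)[0]
        assert abs(slope - 0.1) < 3 * 1.0 / np.sqrt(len(truth.couples))

    def test_excess_fractions_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(var_fractions={"G": 0.6, "C": 0.6})

    def test_random_mating_null_genetic_value_correlation(self, small_study):
        cfg, ped, geno, pheno, truth = small_study
        comp = truth.components.set_index("id")
        founder_couples = [c for c in truth.couples
                           if c[0] in set(ped.founders())]
        a = comp.loc[[p[0] for p in founder_couples], "g_std"].to_numpy()
        b = comp.loc[[p[1] for p in founder_couples], "g_std"].to_numpy()
        r = np.corrcoef(a, b)[0, 1]
        assert abs(r) < 3 / np.sqrt(len(founder_couples))

    def test_genotypic_assortment_induces_genetic_similarity(self):
        cfg = SimConfig(n_families=1500, offspring_range=(1, 1), n_snps=300,
                        n_causal_snps=100, var_fractions={"G": 0.5},
                        assortment_rho=0.8, assort_on="genetic", seed=23,
                        third_generation=False)
        ped, geno, pheno, truth = simulate_study(cfg)
        comp = truth.components.set_index("id")
        a = comp.loc[[p[0] for p in truth.couples], "g_std"].to_numpy()
        b = comp.loc[[p[1] for p in truth.couples], "g_std"].to_numpy()
        r = np.corrcoef(a, b)[0, 1]
        assert r > 0.5  # strong genotypic assortment


class TestLiability:
    def test_case_fraction_matches_prevalence(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=997)
        out = dichotomize_liability(y, 0.48)
        assert abs(out.mean() - 0.48) <= 1.0 / len(y)
        # cases are exactly the top of the distribution
        assert y[out == 1].min() > y[out == 0].max()

    def test_median_split(self):
        y = np.arange(100, dtype=float)
        out = dichotomize_liability(y, 0.5)
        assert out.sum() == 50
        assert (out[50:] == 1).all()

    def test_threshold_location_at_48_percent(self):
        from scipy import stats

        rng = np.random.default_rng(1)
        y = rng.normal(size=200_000)
        out = dichotomize_liability(y, 0.48)
        threshold = y[out == 1].min()
        assert abs(threshold - stats.norm.ppf(0.52)) < 0.02

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            dichotomize_liability(np.ones(10), 0.5)
        with pytest.raises(ValueError):
            dichotomize_liability(np.random.default_rng(0).normal(size=10), 1.5)


class TestOrdinalEncoding:
    @pytest.mark.parametrize(
        "value,code",
        [(0, 0), (0.5, 1), (1, 2), (4, 2), (5, 3), (9, 3), (12, 4), (14, 4),
         (15, 5), (19, 5), (20, 6), (24, 6), (25, 7), (34, 8), (39, 9),
         (44, 10), (49, 11), (50, 12), (80, 12)],
    )
    def test_cigarettes_per_day_table(self, value, code):
        assert encode_ordinal(value, "cigarettes_per_day") == code

    @pytest.mark.parametrize(
        "value,code",
        [(3, 1), (4.9, 1), (5, 2), (9, 2), (10, 3), (14, 3), (15, 4), (17, 4),
         (19, 4), (20, 5), (30, 7), (49, 10), (50, 11), (70, 11)],
    )
    def test_onset_age_table(self, value, code):
        assert encode_ordinal(value, "onset_age") == code

    def test_unknown_onset_stays_missing(self):
        out = encode_ordinal([np.nan, 17.0], "onset_age")
        assert np.isnan(out[0]) and out[1] == 4

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            encode_ordinal(-1, "cigarettes_per_day")

    @given(st.floats(min_value=0, max_value=200, allow_nan=False))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_codes_monotone_in_value(self, v):
        c1 = encode_ordinal(v, "cigarettes_per_day")
        c2 = encode_ordinal(v + 1.0, "cigarettes_per_day")
        assert c2 >= c1
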