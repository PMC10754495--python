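"""Haplotype construction, matching semantics, match matrix and agreement."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ednaident.callsets import MISSING, Variant
from ednaident.matching import (
    MatchMatrix,
    agreement_scores,
    build_match_matrix,
    build_soil_haplotypes,
    filter_population_matched,
    intersect_variants,
    match_individual,
    rank_agreement,
)
from ednaident.simulate import SimPopulationConfig, SoilSimConfig, simulate_population, simulate_soil_sample

from conftest import make_hap, make_pop, make_soil


class TestIntersect:
    def setup_method(self):
        self.pop = make_pop([[1]], contig="S1")  # S1:100 A>G

    def test_exact_identity_retained(self):
        soil = make_soil([Variant("S1", 100, "A", "G")], [[1, 1]])
        assert intersect_variants(soil, self.pop).n_variants == 1

    def test_allele_mismatch_dropped(self):
        soil = make_soil([Variant("S1", 100, "A", "T")], [[1, 1]])
        assert intersect_variants(soil, self.pop).n_variants == 0

    def test_position_mismatch_dropped(self):
        soil = make_soil([Variant("S1", 101, "A", "G")], [[1, 1]])
        assert intersect_variants(soil, self.pop).n_variants == 0


class TestBuildHaplotypes:
    def variants(self, n):
        return [Variant("S1", 100 * (j + 1), "A", "G") for j in range(n)]

    def test_phased_het_block_yields_two_haplotypes(self):
        soil = make_soil(self.variants(3), [[0, 1], [1, 0], [0, 1]], phase_sets=[5, 5, 5])
        haps = build_soil_haplotypes(soil)
        assert len(haps) == 2
        assert sorted(h.alleles for h in haps) == [(0, 1, 0), (1, 0, 1)]
        assert all(h.n_sites == 3 and h.source_block == 5 for h in haps)

    def test_min_sites_threshold(self):
        soil = make_soil(self.variants(1), [[0, 1]], phase_sets=[5])
        assert build_soil_haplotypes(soil, min_sites=2) == []
        assert len(build_soil_haplotypes(soil, min_sites=1)) == 2

    def test_all_homozygous_block_dedups_to_one(self):
        soil = make_soil(self.variants(2), [[1, 1], [0, 0]], phase_sets=[5, 5])
        haps = build_soil_haplotypes(soil)
        assert len(haps) == 1
        assert haps[0].alleles == (1, 0)

    def test_unphased_het_excluded(self):
        soil = make_soil(self.variants(3), [[0, 1], [1, 0], [0, 1]],
                         phased=[True, False, True], phase_sets=[5, MISSING, 5])
        haps = build_soil_haplotypes(soil)
        assert all(h.n_sites == 2 for h in haps)

    def test_loose_homozygous_call_joins_enclosing_block(self):
        # hom call at 200 without PS sits inside the 100-300 phased block
        soil = make_soil(self.variants(3), [[0, 1], [1, 1], [0, 1]],
                         phased=[True, False, True], phase_sets=[5, MISSING, 5])
        haps = build_soil_haplotypes(soil)
        assert all(h.n_sites == 3 for h in haps)
        assert sorted(h.alleles for h in haps) == [(0, 1, 0), (1, 1, 1)]


class TestMatchIndividual:
    def test_consistency_rule_by_hand(self):
        # sites 100 (A>G) and 200 (A>T is irrelevant: same ref/alt letters here)
        pop = make_pop([[1, 2]])  # A/G at 100, G/G at 200 in ref/alt coding
        h = make_hap(pop, [0, 1], [1, 1])  # alt at both sites
        assert match_individual(h, pop, "A") == 1.0

    def test_allele_not_carried(self):
        pop = make_pop([[0]])
        h = make_hap(pop, [0], [1])
        assert match_individual(h, pop, "A", mode="consistency") == 0.0

    def test_missing_genotype_propagates(self):
        pop = make_pop([[1, MISSING]])
        h = make_hap(pop, [0, 1], [1, 1])
        assert np.isnan(match_individual(h, pop, "A"))

    def test_ref_allele_requires_at_most_one_alt(self):
        pop = make_pop([[2]])
        h = make_hap(pop, [0], [0])
        assert match_individual(h, pop, "A") == 0.0

    def test_site_absent_from_population_is_an_error(self):
        pop = make_pop([[1]])
        other = make_pop([[1, 1]])
        h = make_hap(other, [0, 1], [1, 1])
        with pytest.raises(ValueError, match="absent"):
            match_individual(h, pop, "A")

    def test_unknown_individual(self):
        pop = make_pop([[1]])
        h = make_hap(pop, [0], [1])
        with pytest.raises(KeyError):
            match_individual(h, pop, "Z")

    def test_phased_mode_requires_exact_chromosome(self):
        phased = [[[0, 1], [1, 0]]]  # chromosomes (0,1) and (1,0) across two sites
        pop = make_pop([[1, 1]], phased_alleles=phased)
        h01 = make_hap(pop, [0, 1], [0, 1])
        h00 = make_hap(pop, [0, 1], [0, 0])
        assert match_individual(h01, pop, "A", mode="phased") == 1.0
        assert match_individual(h00, pop, "A", mode="phased") == 0.0
        # consistency mode accepts both: each allele is carried somewhere
        assert match_individual(h00, pop, "A", mode="consistency") == 1.0

    @given(
        genotypes=st.lists(st.integers(min_value=0, max_value=2), min_size=1, max_size=5),
        data=st.data(),
    )
    def test_consistency_agrees_with_chromosome_enumeration(self, genotypes, data):
        """Oracle: enumerate every allele-per-site assignment compatible with
        the diploid genotypes and test haplotype membership directly."""
        k = len(genotypes)
        alleles = data.draw(st.lists(st.integers(0, 1), min_size=k, max_size=k))
        pop = make_pop([genotypes])
        h = make_hap(pop, list(range(k)), alleles)
        per_site = [{0: (0,), 1: (0, 1), 2: (1,)}[g] for g in genotypes]
        oracle = tuple(alleles) in set(itertools.product(*per_site))
        assert match_individual(h, pop, "A") == float(oracle)


class TestFilterAndMatrix:
    def test_filter_keeps_matched_drops_alien_and_all_missing(self):
        pop = make_pop([[2, 2], [0, 0]])
        matched = make_hap(pop, [0, 1], [1, 1])
        alien = make_hap(pop, [0, 1], [1, 0])  # A is hom-alt, B hom-ref: nobody carries (1,0)
        kept = filter_population_matched([matched, alien], pop)
        assert kept == [matched]
        missing_pop = make_pop([[MISSING, MISSING], [MISSING, MISSING]])
        assert filter_population_matched([matched], missing_pop) == []

    def test_imputation_is_row_mean_of_observed(self):
        raw = np.array([[1.0, np.nan, 0.0, 0.0]])
        M = MatchMatrix.from_raw(["h"], list("ABCD"), raw)
        assert M.imputed[0].tolist() == [1.0, pytest.approx(1 / 3), 0.0, 0.0]

    def test_rows_without_missing_unchanged(self):
        raw = np.array([[1.0, 0.0], [0.0, 1.0]])
        M = MatchMatrix.from_raw(["h1", "h2"], list("AB"), raw)
        assert (M.imputed == raw).all()

    def test_no_haplotypes_is_an_error(self):
        pop = make_pop([[1]])
        with pytest.raises(ValueError, match="no haplotypes"):
            build_match_matrix([], pop)

    def test_matrix_tsv_round_trip(self, tmp_path):
        raw = np.array([[1.0, np.nan], [0.0, 1.0]])
        M = MatchMatrix.from_raw(["h1", "h2"], ["indA", "indB"], raw)
        path = tmp_path / "m.tsv"
        M.to_tsv(path)
        back = MatchMatrix.from_tsv(path)
        assert back.individuals == M.individuals
        np.testing.assert_array_equal(back.raw, M.raw)
        np.testing.assert_allclose(back.imputed, M.imputed)


class TestAgreement:
    def test_scores_are_percent_of_evaluated(self):
        raw = np.array([
            [1.0, 1.0, np.nan],
            [1.0, 1.0, 1.0],
            [1.0, 0.0, 1.0],
            [0.0, 1.0, np.nan],
        ])
        M = MatchMatrix.from_raw(list("hijk"), list("ABC"), raw)
        rep = agreement_scores(M).set_index("individual")
        assert rep.loc["A", "score"] == 75.0  # 3 of 4
        assert rep.loc["B", "score"] == 75.0
        assert rep.loc["C", "n_evaluated"] == 2 and rep.loc["C", "score"] == 100.0

    def test_unassessable_individual_flagged(self):
        raw = np.array([[1.0, np.nan]])
        M = MatchMatrix.from_raw(["h"], list("AB"), raw)
        rep = agreement_scores(M).set_index("individual")
        assert not rep.loc["B", "assessable"]
        assert np.isnan(rep.loc["B", "score"])

    def test_permuting_individuals_permutes_report(self):
        rng = np.random.default_rng(3)
        raw = rng.choice([0.0, 1.0, np.nan], size=(8, 5), p=[0.4, 0.4, 0.2])
        ids = list("ABCDE")
        M1 = MatchMatrix.from_raw(list(range(8)), ids, raw)
        perm = [3, 1, 4, 0, 2]
        M2 = MatchMatrix.from_raw(list(range(8)), [ids[i] for i in perm], raw[:, perm])
        r1 = agreement_scores(M1).set_index("individual").sort_index()
        r2 = agreement_scores(M2).set_index("individual").sort_index()
        assert (r1["n_matched"] == r2["n_matched"]).all()
        np.testing.assert_array_equal(r1["score"].to_numpy(), r2["score"].to_numpy())

    def test_ranking_ties_break_by_identifier(self):
        raw = np.array([[1.0, 1.0, 0.0]])
        M = MatchMatrix.from_raw(["h"], ["B", "A", "C"], raw)
        ranked = rank_agreement(agreement_scores(M))
        assert ranked["individual"].tolist()[:2] == ["A", "B"]

    def test_error_free_single_source_scores_100_in_phased_mode(self):
        cfg = SimPopulationConfig(n_individuals=12, n_variants=200, missingness=0.02, seed=9)
        pop, truth = simulate_population(cfg)
        soil, gt = simulate_soil_sample(pop, truth, SoilSimConfig(
            contributors=["ind003"], weights=[1.0], n_observations=15,
            site_error=0.0, seed=10))
        haps = build_soil_haplotypes(soil)
        haps = filter_population_matched(haps, pop, mode="phased")
        M = build_match_matrix(haps, pop, mode="phased")
        rep = agreement_scores(M).set_index("individual")
        assert rep.loc["ind003", "score"] == 100.0
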