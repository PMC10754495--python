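"""VCF reading, validation, filtering and round-trip writing."""

import numpy as np
import pytest

from ednaident.callsets import (
    MISSING,
    PopulationCallset,
    Variant,
    filter_population_callset,
    read_population_vcf,
    read_soil_vcf,
    write_vcf,
)
from ednaident.simulate import SimPopulationConfig, SoilSimConfig, simulate_population, simulate_soil_sample

from conftest import make_pop

HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=S1,length=10000>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">\n'
)


def write_text_vcf(path, body, samples=("s1", "s2")):
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    path.write_text(HEADER + cols + "\n" + body)
    return path


class TestReadPopulation:
    def test_basic_two_samples_three_records(self, tmp_path):
        body = (
            "S1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1\n"
            "S1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t0/0\t./.\n"
            "S1\t300\t.\tG\tA\t.\tPASS\t.\tGT:PS\t0|1:100\t0/0:.\n"
        )
        pop = read_population_vcf(write_text_vcf(tmp_path / "p.vcf", body))
        assert pop.individuals == ["s1", "s2"]
        assert pop.n_variants == 3
        assert pop.genotypes.tolist() == [[1, 0, 1], [2, MISSING, 0]]
        # phased entry recorded with its phase set
        assert pop.phased_alleles[0, 2].tolist() == [0, 1]
        assert pop.phase_sets[0, 2] == 100

    def test_missing_genotype_is_not_zero(self, tmp_path):
        body = "S1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t./.\t0/0\n"
        pop = read_population_vcf(write_text_vcf(tmp_path / "p.vcf", body))
        assert pop.genotypes[0, 0] == MISSING
        assert pop.genotypes[1, 0] == 0

    def test_multiallelic_rejected_by_default(self, tmp_path):
        body = "S1\t100\t.\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t0/2\n"
        path = write_text_vcf(tmp_path / "p.vcf", body)
        with pytest.raises(ValueError, match="multiallelic"):
            read_population_vcf(path)
        pop = read_population_vcf(path, split_multiallelic=True)
        assert [v.alt for v in pop.variants] == ["G", "T"]

    def test_duplicate_record_is_an_error(self, tmp_path):
        body = (
            "S1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\n"
            "S1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/0\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_population_vcf(write_text_vcf(tmp_path / "p.vcf", body))

    def test_gvcf_reference_blocks_ignored(self, tmp_path):
        body = (
            "S1\t100\t.\tA\t<NON_REF>\t.\tPASS\t.\tGT\t0/0\t0/0\n"
            "S1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t0/1\t1/1\n"
        )
        pop = read_population_vcf(write_text_vcf(tmp_path / "p.vcf", body))
        assert pop.n_variants == 1
        assert pop.variants[0].pos == 200


class TestReadSoil:
    def test_phase_sets_group_calls(self, tmp_path):
        body = "".join(
            f"S1\t{pos}\t.\tA\tG\t.\tPASS\t.\tGT:PS\t0|1:100\n" for pos in (100, 200, 300, 400)
        )
        soil = read_soil_vcf(write_text_vcf(tmp_path / "s.vcf", body, samples=("soil",)))
        assert soil.n_variants == 4
        assert set(soil.phase_sets.tolist()) == {100}
        assert soil.phased.all()

    def test_unphased_het_kept_but_flagged(self, tmp_path):
        body = "S1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\n"
        soil = read_soil_vcf(write_text_vcf(tmp_path / "s.vcf", body, samples=("soil",)))
        assert soil.n_variants == 1
        assert not soil.phased[0]

    def test_two_samples_rejected(self, tmp_path):
        body = "S1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/1\n"
        with pytest.raises(ValueError, match="one sample"):
            read_soil_vcf(write_text_vcf(tmp_path / "s.vcf", body))

    def test_phase_set_spanning_contigs_rejected(self):
        from conftest import make_soil

        variants = [Variant("S1", 100, "A", "G"), Variant("S2", 100, "A", "G")]
        with pytest.raises(ValueError, match="spans contigs"):
            make_soil(variants, [[0, 1], [0, 1]], phase_sets=[7, 7])


class TestValidation:
    def test_variant_invariants(self):
        with pytest.raises(ValueError):
            Variant("S1", 0, "A", "G")
        with pytest.raises(ValueError):
            Variant("S1", 100, "A", "A")
        with pytest.raises(ValueError):
            Variant("S1", 100, "", "G")

    def test_genotype_shape_checked(self):
        with pytest.raises(ValueError, match="shape"):
            PopulationCallset(["a"], [Variant("S1", 100, "A", "G")],
                              np.zeros((2, 1), dtype=np.int8))

    def test_phase_must_agree_with_genotype(self):
        phased = [[[0, 0]]]  # pair sum 0 but genotype says 1
        with pytest.raises(ValueError, match="inconsistent"):
            make_pop([[1]], phased_alleles=phased)


class TestFilter:
    def test_boundary_missingness_is_strict(self):
        # variant 0: missing in 2 of 10 (20%) -> removed; variant 1: 1 of 10 -> kept
        g = np.ones((10, 2), dtype=np.int8)
        g[:2, 0] = MISSING
        g[0, 1] = MISSING
        out = filter_population_callset(make_pop(g), max_missing=0.20, min_maf=0.01)
        assert [v.pos for v in out.variants] == [200]

    def test_maf_arithmetic_over_nonmissing_alleles(self):
        # 10 individuals, one het: 1 alt of 20 alleles = 5% > 1% -> retained
        g = np.zeros((10, 2), dtype=np.int8)
        g[0, 0] = 1
        g[:, 1] = 0  # monomorphic: MAF 0 -> removed
        out = filter_population_callset(make_pop(g))
        assert [v.pos for v in out.variants] == [100]

    def test_idempotent_and_individuals_unchanged(self):
        rng = np.random.default_rng(11)
        g = rng.integers(-1, 3, size=(20, 50)).astype(np.int8)
        pop = make_pop(g, individuals=[f"i{k}" for k in range(20)])
        once = filter_population_callset(pop)
        twice = filter_population_callset(once)
        assert once.individuals == pop.individuals
        assert [v.key for v in twice.variants] == [v.key for v in once.variants]
        # every retained variant independently satisfies both criteria
        assert (once.missingness() < 0.20).all()
        assert (once.minor_allele_frequency() > 0.01).all()

    def test_empty_result_warns_not_raises(self):
        g = np.zeros((4, 3), dtype=np.int8)  # all monomorphic
        with pytest.warns(UserWarning, match="every variant"):
            out = filter_population_callset(make_pop(g))
        assert out.n_variants == 0

    def test_threshold_domain_checked(self):
        with pytest.raises(ValueError):
            filter_population_callset(make_pop([[1, 0]]), max_missing=1.5)


class TestRoundTrip:
    def test_population_round_trip_identity(self, tmp_path):
        cfg = SimPopulationConfig(n_individuals=8, n_variants=60, missingness=0.1, seed=4)
        pop, _ = simulate_population(cfg)
        path = write_vcf(pop, tmp_path / "pop.vcf")
        back = read_population_vcf(path)
        assert back.individuals == pop.individuals
        assert back.variants == pop.variants
        assert (back.genotypes == pop.genotypes).all()
        assert (back.phased_alleles == pop.phased_alleles).all()
        assert (back.phase_sets == pop.phase_sets).all()

    def test_soil_round_trip_identity(self, tmp_path):
        cfg = SimPopulationConfig(n_individuals=8, n_variants=60, missingness=0.0, seed=4)
        pop, truth = simulate_population(cfg)
        soil, _ = simulate_soil_sample(pop, truth, SoilSimConfig(
            contributors=["ind000"], weights=[1.0], n_observations=10, seed=5))
        path = write_vcf(soil, tmp_path / "soil.vcf")
        back = read_soil_vcf(path)
        assert back.variants == soil.variants
        assert (back.alleles == soil.alleles).all()
        assert (back.phased == soil.phased).all()
        assert (back.phase_sets == soil.phase_sets).all()

    def test_missing_and_phase_conventions_in_text(self, tmp_path):
        g = np.array([[MISSING, 1]], dtype=np.int8)
        phased = np.array([[[MISSING, MISSING], [1, 0]]], dtype=np.int8)
        ps = np.array([[MISSING, 77]], dtype=np.int64)
        pop = make_pop(g, phased_alleles=phased, phase_sets=ps)
        text = write_vcf(pop, tmp_path / "p.vcf").read_text()
        records = [l for l in text.splitlines() if not l.startswith("#")]
        assert records[0].endswith("./.:.")
        assert records[1].endswith("1|0:77")
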