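import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ednaident.callsets import PopulationCallset, SoilCallset, Variant
from ednaident.matching import Haplotype

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_pop(genotypes, individuals=None, contig="chr1", ref="A", alt="G",
             phased_alleles=None, phase_sets=None):
    """Population callset from an (I, V) genotype list; variants at 100, 200, ..."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_ind, n_var = g.shape
    individuals = individuals or [chr(ord("A") + i) for i in range(n_ind)]
    variants = [Variant(contig, 100 * (j + 1), ref, alt) for j in range(n_var)]
    kwargs = {}
    if phased_alleles is not None:
        kwargs["phased_alleles"] = np.asarray(phased_alleles, dtype=np.int8)
        kwargs["phase_sets"] = (np.asarray(phase_sets, dtype=np.int64)
                                if phase_sets is not None
                                else np.zeros((n_ind, n_var), dtype=np.int64))
    return PopulationCallset(individuals=list(individuals), variants=variants,
                             genotypes=g, **kwargs)


def make_hap(pop, site_indices, alleles, block=0):
    sites = tuple(pop.variants[j] for j in site_indices)
    return Haplotype(sites[0].contig, sites, tuple(alleles), source_block=block)


def make_soil(variants, alleles, phased=None, phase_sets=None, sample_id="soil"):
    n = len(variants)
    return SoilCallset(
        sample_id=sample_id,
        variants=list(variants),
        alleles=np.asarray(alleles, dtype=np.int8),
        phased=np.ones(n, dtype=bool) if phased is None else np.asarray(phased, dtype=bool),
        phase_sets=(np.zeros(n, dtype=np.int64) if phase_sets is None
                    else np.asarray(phase_sets, dtype=np.int64)),
    )


@pytest.fixture
def micro_matrix():
    """The 3-individual / 3-haplotype instance: h1, h2 only A; h3 only B."""
    from ednaident.matching import MatchMatrix

    raw = np.array([[1.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    return MatchMatrix.from_raw(["h1", "h2", "h3"], ["A", "B", "C"], raw)
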