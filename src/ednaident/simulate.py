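"""Synthetic population callsets and soil samples with full ground truth.

The generator emulates the statistical structure the identification pipeline
assumes, so every stage is testable without controlled-access data:

* a diploid population panel at biallelic variants laid out in phase blocks,
  with a drawn minor-allele-frequency spectrum, per-entry genotype
  missingness, and optional parent-offspring relationships (children inherit
  one whole haplotype per block from each parent, no within-block
  recombination);
* soil samples composed of haplotype observations drawn from weighted
  contributor mixtures, truncated to a drawn number of sites, corrupted by a
  per-site allele-flip error, and optionally interleaved with "alien"
  haplotypes absent from the panel (background DNA surviving mapping).

Sites are mutually independent given descent — no linkage disequilibrium
beyond shared inheritance is modeled, because the downstream analyses treat
phase blocks as exchangeable observations.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .callsets import MISSING, PopulationCallset, SoilCallset, Variant, write_vcf

_BASES = np.array(list("ACGT"))


@dataclass
class SimPopulationConfig:
    """Study conditions for the synthetic population panel."""

    n_individuals: int = 50
    n_variants: int = 1000
    contig: str = "chr1"
    spacing: int = 100  # bp between adjacent variant positions
    block_length: int = 5  # variants per phase block
    maf_range: tuple[float, float] = (0.05, 0.5)
    missingness: float = 0.05
    pedigree: list[tuple[str, str, str]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_variants < 1:
            raise ValueError("need at least one individual and one variant")
        if not (0 <= self.missingness < 0.5):
            raise ValueError("missingness must lie in [0, 0.5)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")

    def individual_ids(self) -> list[str]:
        return [f"ind{i:03d}" for i in range(self.n_individuals)]


@dataclass
class SoilSimConfig:
    """Study conditions for one synthetic soil sample."""

    contributors: list[str] = field(default_factory=list)
    weights: list[float] = field(default_factory=list)
    n_observations: int = 25  # haplotype observations (J)
    sites_mean: float = 4.0  # shifted-Poisson mean number of sites
    sites_min: int = 2
    site_error: float = 0.0  # per-site allele-flip probability
    alien_fraction: float = 0.0
    sample_id: str = "soil"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.contributors) != len(self.weights) or not self.contributors:
            raise ValueError("contributors and weights must be non-empty, equal-length")
        w = np.asarray(self.weights, dtype=float)
        if (w <= 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be positive and sum to 1")
        if not (0 <= self.site_error < 0.5):
            raise ValueError("site_error must lie in [0, 0.5)")
        if not (0 <= self.alien_fraction <= 1):
            raise ValueError("alien_fraction must lie in [0, 1]")
        if self.sites_mean < self.sites_min:
            raise ValueError("sites_mean must be >= sites_min")


@dataclass
class PopulationTruth:
    """Unmasked phased haplotypes underlying a simulated panel."""

    individuals: list[str]
    haplotypes: np.ndarray  # (I, V, 2) int8, never missing
    mafs: np.ndarray  # drawn per-site alt frequencies
    block_of_variant: np.ndarray  # (V,) block index
    blocks: list[np.ndarray]  # variant indices per block
    pedigree: list[tuple[str, str, str]]


@dataclass
class SoilGroundTruth:
    """Per-observation provenance of a simulated soil sample."""

    contributors: list[str]
    weights: list[float]
    source: list[str | None]  # contributor id, or None for alien observations
    chromosome: list[int]
    block: list[int]
    error_sites: list[list[int]]  # flipped variant positions per observation
    alien: list[bool]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "observation": range(len(self.source)),
                "source": [s if s is not None else "alien" for s in self.source],
                "chromosome": self.chromosome,
                "block": self.block,
                "n_errors": [len(e) for e in self.error_sites],
                "error_positions": [",".join(map(str, e)) for e in self.error_sites],
                "alien": self.alien,
            }
        )


def _make_variants(cfg: SimPopulationConfig, rng: np.random.Generator) -> list[Variant]:
    positions = (np.arange(cfg.n_variants) + 1) * cfg.spacing
    ref_idx = rng.integers(0, 4, cfg.n_variants)
    alt_idx = (ref_idx + rng.integers(1, 4, cfg.n_variants)) % 4
    return [
        Variant(cfg.contig, int(p), str(_BASES[r]), str(_BASES[a]))
        for p, r, a in zip(positions, ref_idx, alt_idx)
    ]


def _blocks(cfg: SimPopulationConfig) -> list[np.ndarray]:
    return [
        np.arange(start, min(start + cfg.block_length, cfg.n_variants))
        for start in range(0, cfg.n_variants, cfg.block_length)
    ]


def simulate_population(cfg: SimPopulationConfig) -> tuple[PopulationCallset, PopulationTruth]:
    """Draw a phased population panel; deterministic given ``cfg.seed``.

    Founder haplotype alleles are independent Bernoulli draws with the site's
    drawn alt frequency; pedigree children receive one whole haplotype per
    block from each parent. Genotype missingness is applied after the truth
    is stored, so the truth is always complete.
    """
    rng = np.random.default_rng(cfg.seed)
    ids = cfg.individual_ids()
    id_index = {name: i for i, name in enumerate(ids)}
    for child, pa, pb in cfg.pedigree:
        for name in (child, pa, pb):
            if name not in id_index:
                raise ValueError(f"pedigree references unknown individual {name!r}")

    variants = _make_variants(cfg, rng)
    mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], cfg.n_variants)
    hap = (rng.random((cfg.n_individuals, cfg.n_variants, 2)) < mafs[None, :, None]).astype(np.int8)

    blocks = _blocks(cfg)
    block_of = np.empty(cfg.n_variants, dtype=int)
    for b, idx in enumerate(blocks):
        block_of[idx] = b
    for child, pa, pb in cfg.pedigree:  # processed in order: chains allowed
        c, a, b_ = id_index[child], id_index[pa], id_index[pb]
        for idx in blocks:
            hap[c, idx, 0] = hap[a, idx, rng.integers(0, 2)]
            hap[c, idx, 1] = hap[b_, idx, rng.integers(0, 2)]

    truth = PopulationTruth(
        individuals=ids,
        haplotypes=hap.copy(),
        mafs=mafs,
        block_of_variant=block_of,
        blocks=blocks,
        pedigree=list(cfg.pedigree),
    )

    genotypes = hap.sum(axis=2).astype(np.int8)
    phased_alleles = hap.copy()
    phase_sets = np.empty((cfg.n_individuals, cfg.n_variants), dtype=np.int64)
    block_start_pos = np.asarray([variants[idx[0]].pos for idx in blocks])
    phase_sets[:, :] = block_start_pos[block_of][None, :]
    if cfg.missingness > 0:
        mask = rng.random(genotypes.shape) < cfg.missingness
        genotypes[mask] = MISSING
        phased_alleles[mask] = MISSING
        phase_sets[mask] = MISSING

    callset = PopulationCallset(
        individuals=ids,
        variants=variants,
        genotypes=genotypes,
        phased_alleles=phased_alleles,
        phase_sets=phase_sets,
        contig_lengths={cfg.contig: int(variants[-1].pos + 1)},
    )
    return callset, truth


def simulate_soil_sample(
    pop: PopulationCallset, truth: PopulationTruth, cfg: SoilSimConfig
) -> tuple[SoilCallset, SoilGroundTruth]:
    """Draw haplotype observations from a weighted contributor mixture.

    Each observation picks a contributor by weight, a chromosome copy and a
    phase block uniformly, truncates the block to a drawn number of sites,
    and flips each allele with probability ``site_error``. Alien
    observations substitute uniformly random alleles. Blocks are drawn
    without replacement — a diploid VCF carries at most two haplotypes per
    block and read multiplicity is not modeled — so ``n_observations`` must
    not exceed the number of blocks.
    """
    rng = np.random.default_rng(cfg.seed)
    id_index = {name: i for i, name in enumerate(truth.individuals)}
    for name in cfg.contributors:
        if name not in id_index:
            raise ValueError(f"contributor {name!r} not in population")
    n_blocks = len(truth.blocks)
    if cfg.n_observations > n_blocks:
        raise ValueError(
            f"cannot draw {cfg.n_observations} observations from {n_blocks} blocks"
        )

    chosen_blocks = rng.choice(n_blocks, size=cfg.n_observations, replace=False)
    weights = np.asarray(cfg.weights, dtype=float)

    var_idx: list[int] = []
    alleles: list[tuple[int, int]] = []
    phase_sets: list[int] = []
    gt = SoilGroundTruth(list(cfg.contributors), list(cfg.weights), [], [], [], [], [])
    for b in chosen_blocks:
        idx = truth.blocks[b]
        k = min(cfg.sites_min + rng.poisson(cfg.sites_mean - cfg.sites_min), len(idx))
        sites = idx[:k]
        is_alien = rng.random() < cfg.alien_fraction
        if is_alien:
            obs = rng.integers(0, 2, k).astype(np.int8)
            source, chrom = None, -1
        else:
            source = cfg.contributors[rng.choice(len(weights), p=weights)]
            chrom = int(rng.integers(0, 2))
            obs = truth.haplotypes[id_index[source], sites, chrom].copy()
        flips = rng.random(k) < cfg.site_error
        obs[flips] ^= 1
        errors = [int(pop.variants[s].pos) for s, f in zip(sites, flips) if f]

        ps = int(pop.variants[sites[0]].pos)
        for s, a in zip(sites, obs):
            var_idx.append(int(s))
            alleles.append((int(a), int(a)))  # one observed haplotype: emit homozygous
            phase_sets.append(ps)
        gt.source.append(source)
        gt.chromosome.append(chrom)
        gt.block.append(int(b))
        gt.error_sites.append(errors)
        gt.alien.append(bool(is_alien))

    order = np.argsort(var_idx, kind="stable")
    soil = SoilCallset(
        sample_id=cfg.sample_id,
        variants=[pop.variants[var_idx[i]] for i in order],
        alleles=np.asarray(alleles, dtype=np.int8)[order],
        phased=np.ones(len(var_idx), dtype=bool),
        phase_sets=np.asarray(phase_sets, dtype=np.int64)[order],
        contig_lengths=dict(pop.contig_lengths),
    )
    return soil, gt


# ---------------------------------------------------------------------------
# Named scenarios


def scenario_configs(scenario: str, seed: int = 0) -> tuple[SimPopulationConfig, SoilSimConfig]:
    """Study conditions for the built-in test scenarios.

    ``single``   one contributor, moderate panel, 2% per-site error;
    ``pair``     two equal contributors on a 10-individual shortlist;
    ``trio_with_relative``  three contributors with a parent-offspring pair
                 in the panel (the offspring is not a contributor), which
                 reproduces the relative-confusion phenomenon;
    ``crowded``  six contributors with uneven weights;
    ``mixture``  two contributors at 0.7/0.3 on a 5-candidate panel with
                 long, discriminative haplotypes and no error — isolates the
                 Bayesian mixing-proportion estimator.
    """
    if scenario == "single":
        pop = SimPopulationConfig(n_individuals=50, n_variants=1000, block_length=5,
                                  missingness=0.05, seed=seed)
        soil = SoilSimConfig(contributors=["ind000"], weights=[1.0], n_observations=25,
                             site_error=0.02, seed=seed + 1)
    elif scenario == "pair":
        pop = SimPopulationConfig(n_individuals=10, n_variants=1000, block_length=5,
                                  missingness=0.05, seed=seed)
        soil = SoilSimConfig(contributors=["ind000", "ind001"], weights=[0.5, 0.5],
                             n_observations=30, site_error=0.02, seed=seed + 1)
    elif scenario == "trio_with_relative":
        pop = SimPopulationConfig(n_individuals=21, n_variants=1000, block_length=5,
                                  missingness=0.05,
                                  pedigree=[("ind020", "ind000", "ind001")], seed=seed)
        soil = SoilSimConfig(contributors=["ind000", "ind002", "ind003"],
                             weights=[0.5, 0.3, 0.2], n_observations=30,
                             site_error=0.02, seed=seed + 1)
    elif scenario == "crowded":
        pop = SimPopulationConfig(n_individuals=30, n_variants=1500, block_length=5,
                                  missingness=0.05, seed=seed)
        soil = SoilSimConfig(contributors=[f"ind{i:03d}" for i in range(6)],
                             weights=[0.3, 0.2, 0.15, 0.15, 0.1, 0.1],
                             n_observations=40, site_error=0.02, seed=seed + 1)
    elif scenario == "mixture":
        pop = SimPopulationConfig(n_individuals=5, n_variants=720, block_length=12,
                                  missingness=0.0, seed=seed)
        soil = SoilSimConfig(contributors=["ind000", "ind001"], weights=[0.7, 0.3],
                             n_observations=40, sites_mean=10.0, seed=seed + 1)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return pop, soil


SCENARIOS = ("single", "pair", "trio_with_relative", "crowded", "mixture")


def make_fixture(outdir: str | Path, scenario: str, seed: int = 0) -> dict[str, Path]:
    """Write population VCF, soil VCF, truth TSV and the config used."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pop_cfg, soil_cfg = scenario_configs(scenario, seed=seed)
    pop, truth = simulate_population(pop_cfg)
    soil, gt = simulate_soil_sample(pop, truth, soil_cfg)
    paths = {
        "population_vcf": outdir / "population.vcf",
        "soil_vcf": outdir / "soil.vcf",
        "truth_tsv": outdir / "truth.tsv",
        "config_yaml": outdir / "config.yaml",
    }
    write_vcf(pop, paths["population_vcf"])
    write_vcf(soil, paths["soil_vcf"])
    gt.to_frame().to_csv(paths["truth_tsv"], sep="\t", index=False)
    config = {
        "scenario": scenario,
        "seed": seed,
        "population": dataclasses.asdict(pop_cfg),
        "soil": dataclasses.asdict(soil_cfg),
        "contributors": gt.contributors,
        "weights": gt.weights,
    }
    config = json.loads(json.dumps(config))  # tuples -> lists for safe YAML
    paths["config_yaml"].write_text(yaml.safe_dump(config, sort_keys=False))
    return paths
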