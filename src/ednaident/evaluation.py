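"""Replicated recovery studies on the synthetic study conditions.

These functions run the full identification chain — simulate a panel and a
soil sample, filter, match, score, and infer — many times with distinct
seeds, and report how often each analysis recovers the planted ground
truth. They back both the test suite and ``scripts/acceptance.py``, so the
measured rates always come from the same code path as the package's public
pipeline.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import matching
from .callsets import MISSING, PopulationCallset, SoilCallset, Variant
from .contributors import contributor_profile
from .mixture import gibbs_mixture
from .simulate import (
    SimPopulationConfig,
    SoilSimConfig,
    scenario_configs,
    simulate_population,
    simulate_soil_sample,
)


def match_matrix_for(
    pop_cfg: SimPopulationConfig,
    soil_cfg: SoilSimConfig,
    mode: str = "consistency",
    min_sites: int = 2,
):
    """Simulate one panel + soil sample and return (MatchMatrix, truth pair).

    Runs the same stages as the pipeline: population filter, variant
    intersection, haplotype construction, population-match filter.
    """
    from .callsets import filter_population_callset

    pop, truth = simulate_population(pop_cfg)
    soil, gt = simulate_soil_sample(pop, truth, soil_cfg)
    pop = filter_population_callset(pop)
    soil = matching.intersect_variants(soil, pop)
    haps = matching.build_soil_haplotypes(soil, min_sites=min_sites)
    haps = matching.filter_population_matched(haps, pop, mode=mode)
    M = matching.build_match_matrix(haps, pop, mode=mode) if haps else None
    return M, gt


def _reseed(pop_cfg: SimPopulationConfig, soil_cfg: SoilSimConfig, rep_seed: int):
    pop_cfg = dataclasses.replace(pop_cfg, seed=rep_seed)
    soil_cfg = dataclasses.replace(soil_cfg, seed=rep_seed + 10_000)
    return pop_cfg, soil_cfg


def single_contributor_recovery(n_replicates: int = 100, seed: int = 0) -> dict:
    """How often the true single contributor is the unique top agreement score.

    Study conditions: the ``single`` scenario (I=50, V=1000, 5-site blocks,
    5% missingness; one contributor, J=25, 2% per-site error).
    """
    pop_cfg0, soil_cfg0 = scenario_configs("single")
    successes = 0
    for rep in range(n_replicates):
        pop_cfg, soil_cfg = _reseed(pop_cfg0, soil_cfg0, seed + rep)
        M, gt = match_matrix_for(pop_cfg, soil_cfg)
        if M is None:
            continue
        report = matching.agreement_scores(M)
        truth_id = gt.contributors[0]
        scores = report.set_index("individual")["score"]
        top = scores.max()
        if scores.get(truth_id, -1.0) == top and (scores == top).sum() == 1:
            successes += 1
    return {"successes": successes, "n_replicates": n_replicates,
            "rate_percent": 100.0 * successes / n_replicates}


def pair_recovery(n_replicates: int = 50, seed: int = 0, n_max: int = 6) -> dict:
    """How often the contributor MLE returns n=2 and the true pair.

    Study conditions: the ``pair`` scenario (10-individual panel, two equal
    contributors, J=30, 2% per-site error).
    """
    pop_cfg0, soil_cfg0 = scenario_configs("pair")
    successes = 0
    n_hats: list[int] = []
    for rep in range(n_replicates):
        pop_cfg, soil_cfg = _reseed(pop_cfg0, soil_cfg0, seed + rep)
        M, gt = match_matrix_for(pop_cfg, soil_cfg)
        if M is None:
            continue
        profile = contributor_profile(M, n_max=n_max)
        n_hats.append(profile.n_estimate)
        truth_pair = tuple(sorted(gt.contributors))
        if (profile.n_estimate == 2 and not profile.is_lower_bound
                and profile.per_n[2].combination == truth_pair):
            successes += 1
    return {"successes": successes, "n_replicates": n_replicates,
            "rate_percent": 100.0 * successes / n_replicates,
            "n_estimates": n_hats}


def mixture_recovery(n_replicates: int = 50, seed: int = 0, tolerance: float = 0.15,
                     n_iter: int = 2000, burn_in: int = 100) -> dict:
    """How often both posterior mean proportions land within ``tolerance``.

    Study conditions: the ``mixture`` scenario (5-candidate panel, weights
    0.7/0.3, J=40, ~10-site haplotypes, no error) with the standard MCMC
    settings (2000 sweeps, burn-in 100).
    """
    pop_cfg0, soil_cfg0 = scenario_configs("mixture")
    truth_weights = dict(zip(soil_cfg0.contributors, soil_cfg0.weights))
    successes = 0
    estimates: list[dict[str, float]] = []
    for rep in range(n_replicates):
        pop_cfg, soil_cfg = _reseed(pop_cfg0, soil_cfg0, seed + rep)
        M, gt = match_matrix_for(pop_cfg, soil_cfg)
        if M is None:
            continue
        result = gibbs_mixture(M, n_iter=n_iter, burn_in=burn_in,
                               random_state=seed + 20_000 + rep)
        est = {c: float(result.proportions.get(c, 0.0)) for c in truth_weights}
        estimates.append(est)
        if all(abs(est[c] - w) <= tolerance for c, w in truth_weights.items()):
            successes += 1
    return {"successes": successes, "n_replicates": n_replicates,
            "rate_percent": 100.0 * successes / n_replicates,
            "estimates": estimates, "truth": truth_weights}


def relative_confusion(n_replicates: int = 50, seed: int = 0) -> dict:
    """Mean agreement score of an offspring vs unrelated individuals.

    A parent-offspring pair sits in the panel; soil comes from the parent
    only. The offspring shares one haplotype per block with the parent and
    should score clearly above the unrelated panel mean — the
    relative-confusion phenomenon that complicates individual
    identification in closely related populations.
    """
    parent, offspring = "ind000", "ind020"
    pop_cfg0 = SimPopulationConfig(n_individuals=21, n_variants=1000, block_length=5,
                                   missingness=0.05,
                                   pedigree=[(offspring, parent, "ind001")])
    soil_cfg0 = SoilSimConfig(contributors=[parent], weights=[1.0], n_observations=25,
                              site_error=0.02)
    offspring_scores: list[float] = []
    unrelated_scores: list[float] = []
    for rep in range(n_replicates):
        pop_cfg, soil_cfg = _reseed(pop_cfg0, soil_cfg0, seed + rep)
        M, _ = match_matrix_for(pop_cfg, soil_cfg)
        if M is None:
            continue
        scores = matching.agreement_scores(M).set_index("individual")["score"]
        offspring_scores.append(float(scores[offspring]))
        # ind001 is the offspring's other parent; exclude it from "unrelated"
        unrelated = scores.drop([parent, offspring, "ind001"])
        unrelated_scores.append(float(unrelated.mean()))
    return {
        "offspring_mean": float(np.mean(offspring_scores)),
        "unrelated_mean": float(np.mean(unrelated_scores)),
        "n_replicates": n_replicates,
    }


def planted_intersection_fixture(seed: int = 0, n_planted: int = 200, n_perturbed: int = 200):
    """A soil callset with exact population matches plus perturbed decoys.

    Returns (soil, pop, planted_keys): ``n_planted`` soil calls copied
    verbatim from the population callset and ``n_perturbed`` calls whose
    position or alt allele was altered so they no longer occur in it.
    """
    rng = np.random.default_rng(seed)
    pop_cfg = SimPopulationConfig(n_individuals=10, n_variants=n_planted + n_perturbed,
                                  missingness=0.0, seed=seed)
    pop, _ = simulate_population(pop_cfg)
    order = rng.permutation(pop.n_variants)
    planted_idx, perturbed_idx = order[:n_planted], order[n_planted:]

    variants: list[Variant] = []
    planted_keys = set()
    for i in planted_idx:
        v = pop.variants[i]
        variants.append(v)
        planted_keys.add(v.key)
    bases = "ACGT"
    for i in perturbed_idx:
        v = pop.variants[i]
        if rng.random() < 0.5:  # position shift (spacing leaves the slot free)
            variants.append(Variant(v.contig, v.pos + 1, v.ref, v.alt))
        else:  # allele swap
            alt = next(b for b in bases if b not in (v.ref, v.alt))
            variants.append(Variant(v.contig, v.pos, v.ref, alt))
    order2 = np.argsort([v.pos for v in variants], kind="stable")
    variants = [variants[i] for i in order2]
    n = len(variants)
    soil = SoilCallset(
        sample_id="planted",
        variants=variants,
        alleles=np.ones((n, 2), dtype=np.int8),
        phased=np.ones(n, dtype=bool),
        phase_sets=np.arange(n, dtype=np.int64),
        contig_lengths=dict(pop.contig_lengths),
    )
    return soil, pop, planted_keys
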