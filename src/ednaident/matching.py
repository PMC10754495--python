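"""Soil-haplotype construction and matching against a population panel.

A soil sample's phased variant calls are grouped by phase set; each block
yields (up to) two haplotypes — ordered runs of alleles on one chromosome
copy. Haplotypes are matched against every individual in the population
callset, producing a J x I match matrix of {0, 1, missing} indicators that
feeds all downstream inference:

* *agreement scores* — per individual, the percentage of haplotypes the
  individual carries, among those for which its genotypes are observed;
* the *mean-imputed* matrix view — missing indicators replaced by the row
  mean over observed individuals — consumed by the mixture model and the
  number-of-contributors likelihood.

Two match semantics are available. ``consistency`` (default) asks whether
the individual's diploid genotypes are compatible with carrying the
haplotype: an alt allele requires >= 1 alt copy, a ref allele requires
<= 1 alt copy. ``phased`` requires a single phased chromosome of the
individual to carry exactly the haplotype's alleles within one phase block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .callsets import MISSING, PopulationCallset, SoilCallset, Variant

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Haplotype:
    """An ordered run of (variant, allele) calls from one phase block."""

    contig: str
    sites: tuple[Variant, ...]
    alleles: tuple[int, ...]  # 0 = ref, 1 = alt, per site
    source_block: int

    def __post_init__(self) -> None:
        if len(self.sites) != len(self.alleles):
            raise ValueError("one allele per site required")
        positions = [v.pos for v in self.sites]
        if positions != sorted(positions) or len(set(positions)) != len(positions):
            raise ValueError("sites must have strictly increasing positions")
        if any(v.contig != self.contig for v in self.sites):
            raise ValueError("all sites must lie on the haplotype's contig")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def allele_strings(self) -> tuple[str, ...]:
        return tuple(v.alt if a else v.ref for v, a in zip(self.sites, self.alleles))

    def label(self) -> str:
        body = ",".join(f"{v.pos}{s}" for v, s in zip(self.sites, self.allele_strings))
        return f"{self.contig}:{self.source_block}:{body}"


def intersect_variants(soil: SoilCallset, pop: PopulationCallset) -> SoilCallset:
    """Keep soil calls whose (contig, pos, ref, alt) occurs in the population.

    This is the exact-identity filter that removes variants created by
    sequencing error or absent from the panel.
    """
    keep = [i for i, v in enumerate(soil.variants) if v.key in pop.index]
    logger.info("variant intersection: %d of %d soil calls retained", len(keep), soil.n_variants)
    if not keep:
        logger.warning("no soil variant matches the population callset")
    return soil.take_variants(np.asarray(keep, dtype=int))


def build_soil_haplotypes(soil: SoilCallset, min_sites: int = 2) -> list[Haplotype]:
    """Assemble haplotypes from the soil sample's phase blocks.

    Each phased block yields its two allele strings (one per chromosome
    copy); identical strings (all-homozygous blocks) collapse to one.
    Unphased heterozygous calls are excluded (their chromosome assignment is
    unknown); homozygous calls are phase-constant and join the enclosing
    block on their contig when one exists. Blocks with fewer than
    ``min_sites`` sites are discarded, and duplicate haplotype observations
    within the sample are removed.
    """
    blocks: dict[tuple[str, int], list[int]] = {}
    loose_hom: list[int] = []
    n_skipped_unphased_het = 0
    for i, v in enumerate(soil.variants):
        a, b = soil.alleles[i]
        if a == MISSING or b == MISSING:
            continue
        if soil.phased[i] and soil.phase_sets[i] != MISSING:
            blocks.setdefault((v.contig, int(soil.phase_sets[i])), []).append(i)
        elif a == b:
            loose_hom.append(i)
        else:
            n_skipped_unphased_het += 1
    if n_skipped_unphased_het:
        logger.info("haplotype construction: %d unphased heterozygous calls skipped",
                    n_skipped_unphased_het)

    # attach homozygous calls lacking a phase set to an enclosing block
    spans = {
        key: (min(soil.variants[i].pos for i in idx), max(soil.variants[i].pos for i in idx))
        for key, idx in blocks.items()
    }
    for i in loose_hom:
        v = soil.variants[i]
        for (contig, ps), (lo, hi) in spans.items():
            if contig == v.contig and lo <= v.pos <= hi:
                blocks[(contig, ps)].append(i)
                break

    haplotypes: list[Haplotype] = []
    seen: set[tuple] = set()
    for (contig, ps), idx in sorted(blocks.items()):
        idx = sorted(idx, key=lambda i: soil.variants[i].pos)
        if len(idx) < min_sites:
            continue
        sites = tuple(soil.variants[i] for i in idx)
        for copy in (0, 1):
            alleles = tuple(int(soil.alleles[i, copy]) for i in idx)
            key = (contig, sites, alleles)
            if key in seen:
                continue
            seen.add(key)
            haplotypes.append(Haplotype(contig, sites, alleles, source_block=ps))
    return haplotypes


def _site_columns(h: Haplotype, pop: PopulationCallset) -> np.ndarray:
    try:
        return np.asarray([pop.index[v.key] for v in h.sites], dtype=int)
    except KeyError as exc:
        raise ValueError(f"haplotype site {exc.args[0]} absent from population callset") from exc


def _match_rows(h: Haplotype, pop: PopulationCallset, mode: str) -> np.ndarray:
    """Vector of match indicators over all individuals: 1.0 / 0.0 / NaN."""
    cols = _site_columns(h, pop)
    alleles = np.asarray(h.alleles)
    if mode == "consistency":
        G = pop.genotypes[:, cols]  # (I, k)
        compatible = np.where(alleles[None, :] == 1, G >= 1, G <= 1)
        missing = (G == MISSING).any(axis=1)
        row = compatible.all(axis=1).astype(float)
        row[missing] = np.nan
        return row
    if mode == "phased":
        if pop.phased_alleles is None:
            raise ValueError("population callset carries no phase; use mode='consistency'")
        H = pop.phased_alleles[:, cols, :]  # (I, k, 2)
        PS = pop.phase_sets[:, cols]
        missing = (H == MISSING).any(axis=(1, 2)) | (PS == MISSING).any(axis=1)
        # cross-block phase is unknown -> treat as missing information
        multi_block = ~missing & (PS != PS[:, :1]).any(axis=1)
        carries = ((H[:, :, 0] == alleles).all(axis=1)) | ((H[:, :, 1] == alleles).all(axis=1))
        row = carries.astype(float)
        row[missing | multi_block] = np.nan
        return row
    raise ValueError(f"unknown match mode {mode!r}")


def match_individual(
    h: Haplotype, pop: PopulationCallset, individual: str, mode: str = "consistency"
) -> float:
    """Match one haplotype against one individual; returns 1.0, 0.0 or NaN.

    NaN (missing) is returned whenever any required genotype — or phase, in
    phased mode — of the individual is unobserved at a site of ``h``.
    """
    try:
        i = pop.individuals.index(individual)
    except ValueError:
        raise KeyError(f"individual {individual!r} not in callset") from None
    return float(_match_rows(h, pop, mode)[i])


def filter_population_matched(
    haps: list[Haplotype], pop: PopulationCallset, mode: str = "consistency"
) -> list[Haplotype]:
    """Retain haplotypes carried by at least one panel individual.

    Haplotypes matching nobody (e.g. created by sequencing error, or from
    non-target organisms) and haplotypes whose indicators are all missing
    are removed.
    """
    kept: list[Haplotype] = []
    n_all_missing = 0
    for h in haps:
        row = _match_rows(h, pop, mode)
        if np.isnan(row).all():
            n_all_missing += 1
        elif np.nanmax(row) == 1.0:
            kept.append(h)
    logger.info("population-match filter: %d of %d haplotypes retained (%d all-missing)",
                len(kept), len(haps), n_all_missing)
    return kept


@dataclass
class MatchMatrix:
    """J haplotypes x I individuals match indicators, raw and mean-imputed.

    ``raw`` holds 1.0 / 0.0 / NaN; ``imputed`` replaces each NaN by the mean
    of the row's observed entries, so downstream likelihoods see a complete
    real-valued matrix. Rows with no observed entry are removed before
    imputation.
    """

    haplotypes: list  # Haplotype or str labels (when read from TSV)
    individuals: list[str]
    raw: np.ndarray
    imputed: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.raw.shape

    def labels(self) -> list[str]:
        return [h.label() if isinstance(h, Haplotype) else str(h) for h in self.haplotypes]

    def to_frame(self, which: str = "raw") -> pd.DataFrame:
        data = self.raw if which == "raw" else self.imputed
        return pd.DataFrame(data, index=self.labels(), columns=self.individuals)

    def to_tsv(self, path) -> None:
        self.to_frame("raw").to_csv(path, sep="\t", index_label="haplotype", na_rep="NA")

    @classmethod
    def from_raw(cls, haplotypes: list, individuals: list[str], raw: np.ndarray) -> "MatchMatrix":
        raw = np.asarray(raw, dtype=float)
        observed = ~np.isnan(raw)
        keep = observed.any(axis=1)
        if not keep.all():
            logger.info("dropping %d fully-missing match rows", int((~keep).sum()))
            raw = raw[keep]
            haplotypes = [h for h, k in zip(haplotypes, keep) if k]
        if raw.shape[0] == 0:
            raise ValueError("no haplotypes retained")
        row_means = np.nanmean(raw, axis=1)
        imputed = np.where(np.isnan(raw), row_means[:, None], raw)
        return cls(haplotypes, list(individuals), raw, imputed)

    @classmethod
    def from_tsv(cls, path) -> "MatchMatrix":
        df = pd.read_csv(path, sep="\t", index_col="haplotype", na_values="NA")
        return cls.from_raw(list(df.index), list(df.columns), df.to_numpy(dtype=float))


def build_match_matrix(
    haps: list[Haplotype], pop: PopulationCallset, mode: str = "consistency"
) -> MatchMatrix:
    """Assemble the match matrix for population-filtered haplotypes."""
    if not haps:
        raise ValueError("no haplotypes retained")
    raw = np.stack([_match_rows(h, pop, mode) for h in haps])
    return MatchMatrix.from_raw(list(haps), list(pop.individuals), raw)


def agreement_scores(matrix: MatchMatrix) -> pd.DataFrame:
    """Per-individual haplotype agreement scores.

    For individual i, ``n_evaluated`` counts haplotypes with an observed
    indicator, ``n_matched`` those the individual carries, and
    ``score = 100 * n_matched / n_evaluated`` — the percentage of the
    sample's haplotypes the individual can be confirmed to share. An
    individual with nothing observed gets NaN and ``assessable = False``.
    """
    observed = ~np.isnan(matrix.raw)
    n_evaluated = observed.sum(axis=0)
    n_matched = np.nansum(matrix.raw == 1.0, axis=0).astype(int)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = 100.0 * n_matched / n_evaluated
    report = pd.DataFrame(
        {
            "individual": matrix.individuals,
            "n_matched": n_matched,
            "n_evaluated": n_evaluated,
            "score": score,
            "assessable": n_evaluated > 0,
        }
    )
    return report


def rank_agreement(report: pd.DataFrame) -> pd.DataFrame:
    """Rank individuals by score, ties broken by identifier (deterministic)."""
    return report.sort_values(["score", "individual"], ascending=[False, True],
                              kind="mergesort").reset_index(drop=True)
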