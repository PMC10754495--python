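"""Reading, validating, filtering and writing variant callsets.

Two kinds of callsets flow through the pipeline:

* a *population* callset — diploid genotypes for I individuals at V biallelic
  variants, the reference panel against which soil haplotypes are matched;
* a *soil* callset — a single sample's phased variant calls, whose phase sets
  (``PS`` tags) delimit the blocks from which haplotypes are built.

Both are plain VCF 4.x. Genotypes are stored as alt-allele counts (0/1/2) with
``MISSING`` (-1) for uncalled entries; optional phasing is stored as ordered
allele pairs plus a phase-set identifier per entry.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype / allele / phase-set entry.
MISSING = -1

_SYMBOLIC_ALTS = {"<NON_REF>", "<*>"}


@dataclass(frozen=True, order=True)
class Variant:
    """A biallelic variant keyed by (contig, 1-based position, ref, alt)."""

    contig: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.contig}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)


def _check_unique(variants: list[Variant]) -> dict[tuple, int]:
    index: dict[tuple, int] = {}
    for i, v in enumerate(variants):
        if v.key in index:
            raise ValueError(f"duplicate variant record {v.contig}:{v.pos} {v.ref}>{v.alt}")
        index[v.key] = i
    return index


@dataclass
class PopulationCallset:
    """Diploid genotypes for a panel of individuals at biallelic variants.

    Attributes
    ----------
    individuals : list of str
        Ordered sample identifiers (length I).
    variants : list of Variant
        Ordered variant records (length V).
    genotypes : ndarray of shape (I, V), int8
        Alt-allele counts in {0, 1, 2}, or ``MISSING``.
    phased_alleles : ndarray of shape (I, V, 2), int8, optional
        Ordered allele pair (0=ref, 1=alt) per entry when the panel carries
        phase; ``MISSING`` where unphased or uncalled.
    phase_sets : ndarray of shape (I, V), int64, optional
        Phase-set identifier per phased entry, ``MISSING`` elsewhere.
    """

    individuals: list[str]
    variants: list[Variant]
    genotypes: np.ndarray
    phased_alleles: np.ndarray | None = None
    phase_sets: np.ndarray | None = None
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        expected = (len(self.individuals), len(self.variants))
        if self.genotypes.shape != expected:
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} != (I, V) = {expected}"
            )
        self.index = _check_unique(self.variants)
        if self.phased_alleles is not None:
            self.phased_alleles = np.asarray(self.phased_alleles, dtype=np.int8)
            if self.phased_alleles.shape != expected + (2,):
                raise ValueError("phased_alleles must have shape (I, V, 2)")
            if self.phase_sets is None:
                raise ValueError("phased_alleles requires phase_sets")
            self.phase_sets = np.asarray(self.phase_sets, dtype=np.int64)
            both = (self.phased_alleles >= 0).all(axis=2) & (self.genotypes >= 0)
            pair_sum = self.phased_alleles.clip(min=0).sum(axis=2)
            if not (pair_sum[both] == self.genotypes[both]).all():
                raise ValueError("phased allele pair inconsistent with genotype count")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def missingness(self) -> np.ndarray:
        """Per-variant fraction of individuals with a missing genotype."""
        return (self.genotypes == MISSING).mean(axis=0)

    def minor_allele_frequency(self) -> np.ndarray:
        """Per-variant MAF over non-missing alleles (NaN where all missing)."""
        observed = self.genotypes != MISSING
        n_alleles = 2 * observed.sum(axis=0)
        alt = np.where(observed, self.genotypes, 0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            af = alt / n_alleles
        return np.minimum(af, 1.0 - af)

    def take_variants(self, idx: np.ndarray) -> "PopulationCallset":
        idx = np.asarray(idx)
        return PopulationCallset(
            individuals=list(self.individuals),
            variants=[self.variants[i] for i in idx],
            genotypes=self.genotypes[:, idx].copy(),
            phased_alleles=None if self.phased_alleles is None else self.phased_alleles[:, idx].copy(),
            phase_sets=None if self.phase_sets is None else self.phase_sets[:, idx].copy(),
            contig_lengths=dict(self.contig_lengths),
        )


@dataclass
class SoilCallset:
    """A single soil sample's (partially) phased diploid variant calls."""

    sample_id: str
    variants: list[Variant]
    alleles: np.ndarray  # (V, 2) int8, 0=ref 1=alt, MISSING allowed
    phased: np.ndarray  # (V,) bool
    phase_sets: np.ndarray  # (V,) int64, MISSING where absent
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.phased = np.asarray(self.phased, dtype=bool)
        self.phase_sets = np.asarray(self.phase_sets, dtype=np.int64)
        v = len(self.variants)
        if self.alleles.shape != (v, 2) or self.phased.shape != (v,) or self.phase_sets.shape != (v,):
            raise ValueError("soil callset array shapes inconsistent with variant count")
        self.index = _check_unique(self.variants)
        # a phase set must not span contigs
        contigs_by_ps: dict[int, str] = {}
        for var, ps in zip(self.variants, self.phase_sets):
            if ps == MISSING:
                continue
            prev = contigs_by_ps.setdefault(int(ps), var.contig)
            if prev != var.contig:
                raise ValueError(f"phase set {ps} spans contigs {prev} and {var.contig}")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def take_variants(self, idx: np.ndarray) -> "SoilCallset":
        idx = np.asarray(idx, dtype=int)
        return SoilCallset(
            sample_id=self.sample_id,
            variants=[self.variants[i] for i in idx],
            alleles=self.alleles[idx].copy(),
            phased=self.phased[idx].copy(),
            phase_sets=self.phase_sets[idx].copy(),
            contig_lengths=dict(self.contig_lengths),
        )


# ---------------------------------------------------------------------------
# Reading


def _variant_from_record(rec, split_multiallelic: bool) -> list[tuple[Variant, int]]:
    """Yield (Variant, alt_index) pairs for a pysam record; [] for non-variant blocks."""
    alts = [a for a in (rec.alts or ()) if a not in _SYMBOLIC_ALTS]
    if not alts:
        return []  # gVCF reference block or ALT-less record
    if len(alts) > 1 and not split_multiallelic:
        raise ValueError(
            f"multiallelic record at {rec.contig}:{rec.pos} "
            "(pass split_multiallelic=True to normalize)"
        )
    return [(Variant(rec.contig, rec.pos, rec.ref, alt), i + 1) for i, alt in enumerate(alts)]


def read_population_vcf(path: str | Path, split_multiallelic: bool = False) -> PopulationCallset:
    """Read a multi-sample VCF into a :class:`PopulationCallset`.

    Missing genotypes (``./.``) are preserved as ``MISSING``; phased genotypes
    with a ``PS`` tag populate ``phased_alleles``/``phase_sets``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:  # pragma: no cover - pysam error text varies
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    samples = list(vf.header.samples)
    contig_lengths = {c: vf.header.contigs[c].length or 0 for c in vf.header.contigs}

    variants: list[Variant] = []
    geno_cols: list[np.ndarray] = []
    phase_cols: list[np.ndarray] = []
    ps_cols: list[np.ndarray] = []
    any_phase = False
    for rec in vf:
        for variant, alt_idx in _variant_from_record(rec, split_multiallelic):
            g = np.full(len(samples), MISSING, dtype=np.int8)
            pa = np.full((len(samples), 2), MISSING, dtype=np.int8)
            ps = np.full(len(samples), MISSING, dtype=np.int64)
            for s, name in enumerate(samples):
                call = rec.samples[name]
                gt = call.get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                coded = [1 if a == alt_idx else 0 if a == 0 else MISSING for a in gt]
                if MISSING in coded:  # allele belongs to another split alt
                    continue
                g[s] = sum(coded)
                if call.phased and len(coded) == 2:
                    pa[s] = coded
                    ps_val = call.get("PS")
                    ps[s] = int(ps_val) if ps_val is not None else 0
                    any_phase = True
            variants.append(variant)
            geno_cols.append(g)
            phase_cols.append(pa)
            ps_cols.append(ps)
    vf.close()

    genotypes = (
        np.stack(geno_cols, axis=1) if variants else np.empty((len(samples), 0), dtype=np.int8)
    )
    kwargs = {}
    if any_phase:
        kwargs["phased_alleles"] = np.stack(phase_cols, axis=1)
        kwargs["phase_sets"] = np.stack(ps_cols, axis=1)
    return PopulationCallset(
        individuals=samples,
        variants=variants,
        genotypes=genotypes,
        contig_lengths=contig_lengths,
        **kwargs,
    )


def read_soil_vcf(path: str | Path, split_multiallelic: bool = False) -> SoilCallset:
    """Read a single-sample phased VCF (e.g. Medaka/WhatsHap output)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:  # pragma: no cover
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    samples = list(vf.header.samples)
    if len(samples) != 1:
        raise ValueError(f"soil VCF must have exactly one sample, found {len(samples)}")
    sample = samples[0]
    contig_lengths = {c: vf.header.contigs[c].length or 0 for c in vf.header.contigs}

    variants: list[Variant] = []
    alleles: list[tuple[int, int]] = []
    phased: list[bool] = []
    phase_sets: list[int] = []
    n_unphased_het = 0
    for rec in vf:
        for variant, alt_idx in _variant_from_record(rec, split_multiallelic):
            call = rec.samples[sample]
            gt = call.get("GT")
            if gt is None or any(a is None for a in gt) or len(gt) != 2:
                continue
            coded = tuple(1 if a == alt_idx else 0 if a == 0 else MISSING for a in gt)
            if MISSING in coded:
                continue
            is_phased = bool(call.phased)
            ps_val = call.get("PS")
            if not is_phased and coded[0] != coded[1]:
                n_unphased_het += 1
            variants.append(variant)
            alleles.append(coded)
            phased.append(is_phased)
            phase_sets.append(int(ps_val) if ps_val is not None else MISSING)
    vf.close()
    if n_unphased_het:
        logger.info("soil VCF %s: %d unphased heterozygous calls (excluded from haplotypes)",
                    path.name, n_unphased_het)
    return SoilCallset(
        sample_id=sample,
        variants=variants,
        alleles=np.asarray(alleles, dtype=np.int8).reshape(len(variants), 2),
        phased=np.asarray(phased, dtype=bool),
        phase_sets=np.asarray(phase_sets, dtype=np.int64),
        contig_lengths=contig_lengths,
    )


# ---------------------------------------------------------------------------
# Filtering


def filter_population_callset(
    callset: PopulationCallset,
    max_missing: float = 0.20,
    min_maf: float = 0.01,
) -> PopulationCallset:
    """Retain variants with missingness < ``max_missing`` and MAF > ``min_maf``.

    Both comparisons are strict, mirroring the usual "<20% missingness and
    >1% MAF" panel-filtering convention. MAF is computed over non-missing
    alleles only. Idempotent; never changes the individual set.
    """
    if not (0 < max_missing < 1) or not (0 < min_maf < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    miss = callset.missingness()
    maf = callset.minor_allele_frequency()
    keep = (miss < max_missing) & (np.nan_to_num(maf, nan=-1.0) > min_maf)
    kept = int(keep.sum())
    logger.info(
        "population filter: %d of %d variants retained (missingness < %g, MAF > %g)",
        kept, callset.n_variants, max_missing, min_maf,
    )
    if kept == 0:
        warnings.warn("population filter removed every variant", stacklevel=2)
    return callset.take_variants(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# Writing


def _format_gt(a: int, b: int, phased: bool, ps: int) -> str:
    sep = "|" if phased else "/"
    def tok(x: int) -> str:
        return "." if x == MISSING else str(int(x))
    gt = f"{tok(a)}{sep}{tok(b)}"
    return f"{gt}:{ps}" if ps != MISSING else f"{gt}:."


def _header_lines(contig_lengths: dict[str, int], variants: list[Variant], samples: list[str]) -> list[str]:
    contigs: dict[str, int] = dict(contig_lengths)
    for v in variants:
        length = contigs.get(v.contig, 0)
        contigs[v.contig] = max(length, v.pos + len(v.ref))
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c},length={l}>" for c, l in contigs.items()]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    return lines


def write_vcf(callset: PopulationCallset | SoilCallset, path: str | Path) -> Path:
    """Write a callset as plain VCF 4.2 text.

    Round-trip guarantee: reading the file back reproduces genotypes, phase,
    sample order and variant order exactly. Missing genotypes are emitted as
    ``./.``; phased entries use ``|`` and carry a ``PS`` tag.
    """
    path = Path(path)
    lines: list[str]
    if isinstance(callset, PopulationCallset):
        lines = _header_lines(callset.contig_lengths, callset.variants, callset.individuals)
        for j, v in enumerate(callset.variants):
            fields = [v.contig, str(v.pos), ".", v.ref, v.alt, ".", "PASS", ".", "GT:PS"]
            for i in range(callset.n_individuals):
                g = int(callset.genotypes[i, j])
                if callset.phased_alleles is not None and callset.phased_alleles[i, j, 0] != MISSING:
                    a, b = (int(x) for x in callset.phased_alleles[i, j])
                    fields.append(_format_gt(a, b, True, int(callset.phase_sets[i, j])))
                elif g == MISSING:
                    fields.append(_format_gt(MISSING, MISSING, False, MISSING))
                else:
                    a, b = (0, 1) if g == 1 else (g // 2, g // 2)
                    fields.append(_format_gt(a, b, False, MISSING))
            lines.append("\t".join(fields))
    elif isinstance(callset, SoilCallset):
        lines = _header_lines(callset.contig_lengths, callset.variants, [callset.sample_id])
        for j, v in enumerate(callset.variants):
            a, b = (int(x) for x in callset.alleles[j])
            fields = [v.contig, str(v.pos), ".", v.ref, v.alt, ".", "PASS", ".", "GT:PS",
                      _format_gt(a, b, bool(callset.phased[j]), int(callset.phase_sets[j]))]
            lines.append("\t".join(fields))
    else:
        raise TypeError(f"cannot write {type(callset).__name__} as VCF")
    path.write_text("\n".join(lines) + "\n")
    return path
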