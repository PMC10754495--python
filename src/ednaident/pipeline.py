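"""End-to-end orchestration: filter -> match -> score -> mix -> contributors.

``run_pipeline`` consumes a population VCF and a soil VCF, applies the panel
filters, intersects and matches haplotypes, and produces the three candidate
analyses (agreement scores, Bayesian mixing proportions, contributor MLE)
plus a consolidated ranked-candidates report. Every filter logs its
input/output counts. A single seed fans out deterministically to per-stage
seeds, so re-running an identical config reproduces all outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

from . import callsets, matching
from .contributors import contributor_profile
from .mixture import gibbs_mixture, summarize_mixture

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    population_vcf: str | Path = ""
    soil_vcf: str | Path = ""
    outdir: str | Path = "ednaident_out"
    mode: str = "consistency"  # match semantics
    min_sites: int = 2
    max_missing: float = 0.20
    min_maf: float = 0.01
    n_iter: int = 2000
    burn_in: int = 100
    alpha: float = 1.0
    eps: float = 1e-6
    n_max: int = 6
    strategy: str = "auto"
    exclude: list[str] = field(default_factory=list)
    seed: int = 0


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the run seed."""
    return zlib.crc32(f"{stage}:{seed}".encode()) % (2**31)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full identification analysis and write its report bundle.

    Returns the consolidated report dict (also written as ``report.json``).
    Raises with the failing stage's name on any stage error.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(name)s: %(message)s"))
    root = logging.getLogger("ednaident")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    counts: dict[str, int] = {}
    try:
        stage = "read_population"
        pop = callsets.read_population_vcf(cfg.population_vcf)
        counts["population_variants_in"] = pop.n_variants
        counts["population_individuals"] = pop.n_individuals

        stage = "filter_population"
        pop = callsets.filter_population_callset(pop, cfg.max_missing, cfg.min_maf)
        counts["population_variants_retained"] = pop.n_variants

        stage = "read_soil"
        soil = callsets.read_soil_vcf(cfg.soil_vcf)
        counts["soil_calls_in"] = soil.n_variants

        stage = "intersect_variants"
        soil = matching.intersect_variants(soil, pop)
        counts["soil_calls_retained"] = soil.n_variants

        stage = "build_haplotypes"
        haps = matching.build_soil_haplotypes(soil, min_sites=cfg.min_sites)
        counts["haplotypes_built"] = len(haps)

        stage = "filter_haplotypes"
        haps = matching.filter_population_matched(haps, pop, mode=cfg.mode)
        counts["haplotypes_retained"] = len(haps)

        stage = "match_matrix"
        M = matching.build_match_matrix(haps, pop, mode=cfg.mode)
        M.to_tsv(outdir / "match_matrix.tsv")
        hap_table = [
            {"label": h.label(), "contig": h.contig, "block": h.source_block,
             "positions": ",".join(str(v.pos) for v in h.sites),
             "alleles": ",".join(h.allele_strings)}
            for h in M.haplotypes
        ]
        with open(outdir / "haplotypes.tsv", "w") as fh:
            fh.write("label\tcontig\tblock\tpositions\talleles\n")
            for row in hap_table:
                fh.write("\t".join(str(row[k]) for k in
                                   ("label", "contig", "block", "positions", "alleles")) + "\n")

        stage = "agreement_scores"
        report = matching.agreement_scores(M)
        ranked = matching.rank_agreement(report)
        ranked.to_csv(outdir / "agreement.tsv", sep="\t", index=False)

        stage = "mixture"
        mix = gibbs_mixture(M, n_iter=cfg.n_iter, burn_in=cfg.burn_in, alpha=cfg.alpha,
                            eps=cfg.eps, random_state=stage_seed(cfg.seed, "mixture"))
        mix.proportions.to_csv(outdir / "mixture_proportions.tsv", sep="\t")
        mix.assignment.to_csv(outdir / "mixture_assignment.tsv", sep="\t")
        mix_summary = summarize_mixture(mix, exclude=tuple(cfg.exclude))

        stage = "contributors"
        profile = contributor_profile(M, n_max=min(cfg.n_max, pop.n_individuals),
                                      strategy=cfg.strategy)
        with open(outdir / "contributors.tsv", "w") as fh:
            fh.write("n\tcombination\tlikelihood\tlog_likelihood\tn_unexplained\n")
            for n, cl in sorted(profile.per_n.items()):
                fh.write(f"{n}\t{','.join(cl.combination)}\t{cl.likelihood:.6g}"
                         f"\t{cl.log_likelihood:.6g}\t{cl.n_unexplained}\n")

        stage = "report"
        top_agreement = ranked.iloc[0]
        bundle = {
            "counts": counts,
            "agreement_top": {
                "individual": str(top_agreement["individual"]),
                "score": float(top_agreement["score"]),
            },
            "agreement": ranked.to_dict(orient="records"),
            "mixture": mix_summary,
            "contributors": {
                "n_estimate": profile.n_estimate,
                "estimate_label": profile.estimate_label,
                "is_lower_bound": profile.is_lower_bound,
                "search_mode": profile.search_mode,
                "best_combination": list(profile.per_n[profile.n_estimate].combination),
                "per_n": {
                    str(n): {"combination": list(cl.combination),
                             "likelihood": cl.likelihood,
                             "n_unexplained": cl.n_unexplained}
                    for n, cl in profile.per_n.items()
                },
            },
            "config": {k: (str(v) if isinstance(v, Path) else v)
                       for k, v in dataclasses.asdict(cfg).items()},
        }
        (outdir / "report.json").write_text(json.dumps(bundle, indent=2, sort_keys=True))
        return bundle
    except Exception as exc:
        logger.error("pipeline stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
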