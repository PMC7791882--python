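"""End-to-end survey and phasing runs over files, plus packaged fixtures."""

from __future__ import annotations

import hashlib
import logging
import time

import numpy as np
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

from . import catalog, genotyping, maf, phasing, stats

log = logging.getLogger("trpoly")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline-wide knobs with the survey's standard defaults."""

    margin: int = 10            # bp; insertion-attribution margin
    min_iqr: float = 5.0        # units; "highly polymorphic" threshold
    gwas_max_dist: int = 100    # bp; very-near GWAS signal
    phase_max_dist: int = 10000  # bp; SNP eligible for phasing
    alpha: float = 0.05
    n_background_sets: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.margin < 0:
            raise ValueError("margin must be >= 0")
        for name in ("min_iqr", "gwas_max_dist", "phase_max_dist", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def digest(self) -> str:
        text = repr(sorted(self.__dict__.items()))
        return hashlib.sha256(text.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class DiseaseLocusRecord:
    """One published disease-repeat row: locus plus cohort statistics."""

    locus: catalog.RepeatLocus
    mean: float
    median: float
    iqr: float
    q1: float
    q3: float
    mean_len: int
    q1_len: int
    q3_len: int
    disease: str
    omim: str


def load_disease_loci() -> list[DiseaseLocusRecord]:
    """The packaged catalog of 33 triplet/quintuplet disease repeats.

    Coordinates are GRCh38, 0-based half-open; the statistics columns are
    the published 21-individual cohort values (quartiles of per-read
    copy-number change and the corresponding absolute lengths in bp).
    """
    out = []
    text = resources.files("trpoly.data").joinpath("disease_loci.tsv").read_text()
    lines = text.strip().split("\n")
    for line in lines[1:]:
        f = line.split("\t")
        locus = catalog.RepeatLocus(
            chrom=f[0], start=int(f[1]), end=int(f[2]), unit=f[3],
            gene=f[4], region=f[5],
        )
        out.append(DiseaseLocusRecord(
            locus=locus,
            mean=float(f[6]), median=float(f[7]), iqr=float(f[8]),
            q1=float(f[9]), q3=float(f[10]),
            mean_len=int(f[11]), q1_len=int(f[12]), q3_len=int(f[13]),
            disease=f[14], omim=f[15],
        ))
    return out


def _provenance(config: RunConfig) -> str:
    return f"# trpoly config_hash={config.digest()} seed={config.seed}\n"


@dataclass
class SurveyResult:
    summary: stats.CohortSummary
    gwas_hits: list
    background: dict[str, list] = field(default_factory=dict)
    outputs: dict[str, Path] = field(default_factory=dict)


def run_survey(
    maf_paths: Mapping[str, str | Path],
    annotation: str | Path | Sequence[catalog.RepeatLocus],
    refflat: str | Path | None = None,
    snps: str | Path | None = None,
    outdir: str | Path | None = None,
    config: RunConfig = RunConfig(),
    annotation_dialect: str = "bed4",
    compare: Sequence[tuple[str, str]] = (),
    disease_loci: Sequence[catalog.RepeatLocus] = (),
) -> SurveyResult:
    """Annotate, genotype every sample, join, summarize, filter.

    ``maf_paths`` maps sample label to a MAF alignment file.  ``compare``
    lists (canonical class, region) pairs for which matched background
    sets are drawn against ``disease_loci``.  Without a refFlat all loci
    stay intergenic (a warning is logged).
    """
    t0 = time.monotonic()
    if isinstance(annotation, (str, Path)):
        loci = catalog.read_repeat_annotation(annotation, dialect=annotation_dialect)
    else:
        loci = list(annotation)
    if refflat is not None:
        transcripts = catalog.read_refflat(refflat)
        loci = catalog.annotate_loci(loci, transcripts)
    else:
        log.warning("no refFlat given; all loci annotated intergenic")
    loci.sort(key=lambda l: (l.chrom, l.start))
    log.info("annotate: %d loci", len(loci))

    tables = {}
    for label, path in maf_paths.items():
        alignments = maf.read_maf(path)
        tables[label] = genotyping.genotype_sample(alignments, loci, config.margin)
        log.info("genotype %s: %d alignments", label, len(alignments))
    cohort = genotyping.join_samples(tables)
    summary = stats.cohort_summary(cohort)
    log.info("stats: %d/%d loci detected", len(summary.detected), len(cohort))

    gwas_hits = []
    if snps is not None:
        snp_records = stats.read_snp_catalog(snps)
        gwas_hits = stats.filter_polymorphic_near_gwas(
            summary.stats, snp_records,
            min_iqr=config.min_iqr, max_dist=config.gwas_max_dist,
        )
        log.info("gwas-filter: %d hits", len(gwas_hits))

    background = {}
    for cls, region in compare:
        targets = [l for l in disease_loci
                   if l.canonical_class.display_name == cls and l.region == region]
        if not targets:
            continue
        background[f"{cls}:{region}"] = stats.sample_background(
            summary.stats, cls, region, n=len(targets),
            n_sets=config.n_background_sets, exclude=targets, seed=config.seed,
        )

    outputs: dict[str, Path] = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stats_path = outdir / "locus_stats.tsv"
        with open(stats_path, "w") as fh:
            fh.write(_provenance(config))
            stats.stats_to_frame(summary.stats).to_csv(fh, sep="\t", index=False)
        outputs["stats"] = stats_path
        for label, rows in tables.items():
            p = outdir / f"genotypes_{label}.tsv"
            genotyping.write_genotype_table(rows, p)
            outputs[f"genotypes_{label}"] = p
        gwas_path = outdir / "gwas_hits.tsv"
        with open(gwas_path, "w") as fh:
            fh.write(_provenance(config))
            fh.write("chrom\tstart\tend\tunit\tiqr\trsid\tsnp_pos\tdistance\n")
            for s, snp, d in gwas_hits:
                fh.write(f"{s.locus.chrom}\t{s.locus.start}\t{s.locus.end}\t"
                         f"{s.locus.unit}\t{s.iqr}\t{snp.rsid}\t{snp.pos}\t{d}\n")
        outputs["gwas"] = gwas_path
    log.info("survey done in %.1f s", time.monotonic() - t0)
    return SurveyResult(summary=summary, gwas_hits=gwas_hits,
                        background=background, outputs=outputs)


def association_replicates(
    n_replicates: int,
    ld: str | float = "complete",
    delta_dist: dict[int, float] | None = None,
    n_individuals: int = 21,
    noise_sd: float = 1.0,
    unit: str = "CAG",
    copies: int = 10,
    seed: int = 0,
) -> list[float]:
    """Replicate p-values for the repeat-SNP association under simulated LD.

    Each replicate draws a fresh diploid population (two haplotypes per
    individual under Hardy-Weinberg, SNP base linked to the long allele
    per ``ld``), perturbs every allele's copy number with Gaussian read
    noise of ``noise_sd`` units, and runs the unpaired t-test on
    allele-level absolute lengths grouped by SNP base.  Used to measure
    statistical power (complete LD) and type-I error (independent SNP).
    """
    from .simulate import LocusSpec, SimConfig, SnpSpec, simulate_population

    dist = delta_dist or {0: 0.5, 10: 0.5}
    config = SimConfig(
        loci=(LocusSpec(unit=unit, copies=copies, delta_dist=dist),),
        n_individuals=n_individuals,
        snp=SnpSpec(offset=-150, ld=ld),
    )
    span, ulen = copies * len(unit), len(unit)
    rng = np.random.default_rng(seed)
    pvalues = []
    for rep in range(n_replicates):
        truth = simulate_population(
            config, seed=int(rng.integers(0, 2**31)))
        pairs = []
        for ind in truth.individuals:
            for h in (0, 1):
                delta = ind.hap_deltas[h, 0] + rng.normal(0.0, noise_sd)
                pairs.append((span + ulen * delta, ind.hap_snp_bases[h]))
        res = phasing.repeat_snp_association(pairs)
        pvalues.append(res.p if res.tested else 1.0)
    return pvalues


@dataclass
class PhaseRunResult:
    genotypes: dict[str, phasing.PhasedGenotype | None]
    association: phasing.AssociationResult
    outputs: dict[str, Path] = field(default_factory=dict)


def run_phase(
    maf_paths: Mapping[str, str | Path],
    locus: catalog.RepeatLocus,
    snp: stats.SnpRecord,
    outdir: str | Path | None = None,
    config: RunConfig = RunConfig(),
) -> PhaseRunResult:
    """Phase one locus against one SNP across a cohort and test association."""
    d = stats.snp_distance(locus, snp)
    if d is None or d >= config.phase_max_dist:
        raise ValueError(
            f"SNP {snp.rsid} is {d if d is not None else 'on another chromosome'} "
            f"from {locus.chrom}:{locus.start}-{locus.end}; "
            f"phasing requires < {config.phase_max_dist} bp"
        )
    genotypes = {}
    for label, path in maf_paths.items():
        alignments = maf.read_maf(path)
        genotypes[label] = phasing.phase_locus(
            alignments, locus, snp.pos, margin=config.margin, sample=label,
        )
    pairs = phasing.allele_length_pairs(genotypes.values(), locus)
    assoc = phasing.repeat_snp_association(pairs)
    outputs: dict[str, Path] = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        p = outdir / "phasing.tsv"
        with open(p, "w") as fh:
            fh.write(_provenance(config))
            fh.write("sample\tallele1_delta\tallele1_base\tallele2_delta\tallele2_base\n")
            for label, g in genotypes.items():
                if g is None:
                    fh.write(f"{label}\tNA\tNA\tNA\tNA\n")
                    continue
                fh.write(f"{label}\t{g.allele1.allele_delta}\t{g.allele1.snp_base or 'NA'}"
                         f"\t{g.allele2.allele_delta}\t{g.allele2.snp_base or 'NA'}\n")
        outputs["phasing"] = p
    return PhaseRunResult(genotypes=genotypes, association=assoc, outputs=outputs)
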