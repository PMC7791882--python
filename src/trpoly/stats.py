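"""Per-locus cohort variability statistics, background sampling, filters.

The polymorphism measure is the interquartile range (IQR) of per-read
copy-number changes pooled across all cohort samples.  Absolute repeat
lengths convert a delta quantile back to base pairs:
``length = ref_span + unit_len * quantile``, floored to integer bp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catalog import RepeatLocus
from .genotyping import CohortRow
from .units import CanonicalUnit, canonical_unit


def quantile(values: Sequence[float], q: float) -> float:
    """Linear-interpolation quantile: h = (n - 1) q between order stats."""
    if len(values) == 0:
        raise ValueError("quantile of empty list")
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    return float(np.quantile(np.asarray(values, dtype=float), q, method="linear"))


@dataclass(frozen=True)
class LocusStats:
    """Cohort summary for one locus (one table row)."""

    locus: RepeatLocus
    n_reads: int
    mean_delta: float | None = None
    median_delta: float | None = None
    q1: float | None = None
    q3: float | None = None
    mean_len: int | None = None
    q1_len: int | None = None
    q3_len: int | None = None
    low_coverage: bool = False

    @property
    def detected(self) -> bool:
        return self.n_reads > 0

    @property
    def iqr(self) -> float | None:
        if self.q1 is None:
            return None
        return self.q3 - self.q1


def absolute_length(locus: RepeatLocus, delta_quantile: float) -> int:
    """Absolute repeat length in bp for a delta quantile.

    ref_span + unit_len * quantile, floored to integer bp (matching how
    the published length columns truncate fractional quartiles).
    """
    return math.floor(locus.ref_span + locus.unit_len * delta_quantile)


_abs_len = absolute_length


def locus_stats(pooled_deltas: Sequence[int], locus: RepeatLocus) -> LocusStats:
    """Summarize pooled per-read deltas at one locus.

    An empty pool yields an undetected row (numeric fields None).  Loci
    with fewer than 3 pooled reads are flagged low-coverage but still
    summarized.
    """
    n = len(pooled_deltas)
    if n == 0:
        return LocusStats(locus=locus, n_reads=0)
    arr = np.asarray(pooled_deltas, dtype=float)
    q1 = quantile(arr, 0.25)
    q3 = quantile(arr, 0.75)
    mean = float(arr.mean())
    return LocusStats(
        locus=locus,
        n_reads=n,
        mean_delta=mean,
        median_delta=quantile(arr, 0.5),
        q1=q1,
        q3=q3,
        mean_len=_abs_len(locus, mean),
        q1_len=_abs_len(locus, q1),
        q3_len=_abs_len(locus, q3),
        low_coverage=n < 3,
    )


@dataclass(frozen=True)
class CohortSummary:
    stats: list[LocusStats]
    detection_rate: float
    per_sample_detection: dict[str, float]

    @property
    def detected(self) -> list[LocusStats]:
        return [s for s in self.stats if s.detected]


def cohort_summary(rows: Sequence[CohortRow]) -> CohortSummary:
    """Per-locus stats plus detection rates for a joined cohort.

    A locus is detected overall when any sample contributed a spanning
    read, and detected for a sample when that sample did.
    """
    stats = [locus_stats(row.pooled, row.locus) for row in rows]
    n = len(rows)
    detected = sum(1 for s in stats if s.detected)
    per_sample: dict[str, float] = {}
    if rows:
        labels = list(rows[0].samples)
        for label in labels:
            k = sum(1 for row in rows if row.samples[label].n_reads > 0)
            per_sample[label] = k / n
    return CohortSummary(
        stats=stats,
        detection_rate=detected / n if n else 0.0,
        per_sample_detection=per_sample,
    )


def fraction_iqr_at_most(stats: Iterable[LocusStats], threshold: float) -> float:
    """Fraction of detected loci with IQR <= threshold."""
    vals = [s.iqr for s in stats if s.detected]
    if not vals:
        raise ValueError("no detected loci")
    return sum(1 for v in vals if v <= threshold) / len(vals)


def sample_background(
    stats: Sequence[LocusStats],
    target_class: CanonicalUnit | str,
    target_region: str | Sequence[str],
    n: int,
    n_sets: int = 10,
    exclude: Iterable[RepeatLocus] = (),
    seed: int = 0,
) -> list[list[LocusStats]]:
    """Draw matched background locus sets for a disease-vs-rest comparison.

    Each of ``n_sets`` sets is a uniform sample (without replacement) of
    ``n`` loci of the same canonical unit class and genic region as the
    disease repeats, never drawing any excluded (disease) locus.
    Reproducible for a fixed seed.
    """
    if isinstance(target_class, str):
        target_class = canonical_unit(target_class)
    regions = {target_region} if isinstance(target_region, str) else set(target_region)
    excluded_keys = {loc.key for loc in exclude}
    pool = [
        s for s in stats
        if s.detected
        and s.locus.canonical_class.representative == target_class.representative
        and s.locus.region in regions
        and s.locus.key not in excluded_keys
    ]
    if len(pool) < n:
        raise ValueError(
            f"background pool has only {len(pool)} matching loci, need {n}"
        )
    rng = np.random.default_rng(seed)
    return [
        [pool[i] for i in rng.choice(len(pool), size=n, replace=False)]
        for _ in range(n_sets)
    ]


# ---------------------------------------------------------------------------
# GWAS-proximity filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpRecord:
    """One catalog SNP (0-based position)."""

    chrom: str
    pos: int
    rsid: str = "."
    ref: str = "N"
    alt: str = "N"
    trait: str = ""


def read_snp_catalog(path: str | Path) -> list[SnpRecord]:
    """SNP catalog TSV: chrom, pos0, rsid, ref, alt, trait."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos0"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: SNP catalog needs columns {sorted(required)}")
    return [
        SnpRecord(
            chrom=str(r.chrom), pos=int(r.pos0),
            rsid=str(getattr(r, "rsid", ".")),
            ref=str(getattr(r, "ref", "N")), alt=str(getattr(r, "alt", "N")),
            trait=str(getattr(r, "trait", "")),
        )
        for r in df.itertuples()
    ]


def snp_distance(locus: RepeatLocus, snp: SnpRecord) -> int | None:
    """bp distance from SNP to locus; 0 inside, None on other chromosomes."""
    if snp.chrom != locus.chrom:
        return None
    if locus.start <= snp.pos < locus.end:
        return 0
    return min(abs(snp.pos - locus.start), abs(snp.pos - (locus.end - 1)))


def filter_polymorphic_near_gwas(
    stats: Iterable[LocusStats],
    snps: Sequence[SnpRecord],
    min_iqr: float = 5.0,
    max_dist: int = 100,
) -> list[tuple[LocusStats, SnpRecord, int]]:
    """Highly polymorphic loci (IQR >= min_iqr) with a SNP closer than
    max_dist bp.  Use max_dist=10000 for the broader near-by search."""
    by_chrom: dict[str, list[SnpRecord]] = {}
    for snp in snps:
        by_chrom.setdefault(snp.chrom, []).append(snp)
    hits = []
    for s in stats:
        if not s.detected or s.iqr < min_iqr:
            continue
        for snp in by_chrom.get(s.locus.chrom, ()):
            d = snp_distance(s.locus, snp)
            if d is not None and d < max_dist:
                hits.append((s, snp, d))
    return hits


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def stats_to_frame(stats: Sequence[LocusStats]) -> pd.DataFrame:
    """Stats as a DataFrame mirroring the survey-table columns."""
    rows = []
    for s in stats:
        loc = s.locus
        rows.append({
            "chrom": loc.chrom, "start": loc.start, "end": loc.end,
            "unit": loc.unit, "class": loc.canonical_class.display_name,
            "gene": loc.gene or "", "region": loc.region,
            "n_reads": s.n_reads,
            "mean": s.mean_delta, "median": s.median_delta,
            "iqr": s.iqr, "q1": s.q1, "q3": s.q3,
            "mean_len": s.mean_len, "q1_len": s.q1_len, "q3_len": s.q3_len,
            "low_coverage": s.low_coverage,
        })
    return pd.DataFrame(rows)
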