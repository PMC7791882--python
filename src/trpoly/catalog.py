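"""Reference repeat annotations: loci, detection, file dialects, genic regions.

Coordinates are 0-based half-open everywhere (BED convention); annotation
dialects that use other conventions are normalized on load.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .units import CanonicalUnit, canonical_unit, minimal_period

REGIONS = ("coding", "utr5", "utr3", "noncoding_exon", "intron", "intergenic")
# Overlap priority when a locus touches several transcript features.
_REGION_RANK = {r: i for i, r in enumerate(REGIONS)}


@dataclass(frozen=True)
class RepeatLocus:
    """An annotated tandem repeat on the reference.

    ``ref_span`` (end - start) need not be a multiple of ``unit_len``:
    published annotations are frequently inexact about repeat boundaries.
    """

    chrom: str
    start: int
    end: int
    unit: str
    gene: str | None = None
    region: str = "intergenic"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(
                f"locus end must exceed start ({self.chrom}:{self.start}-{self.end})"
            )
        if self.region not in REGIONS:
            raise ValueError(f"unknown genic region {self.region!r}")
        canonical_unit(self.unit)  # validates the alphabet

    @property
    def unit_len(self) -> int:
        return len(self.unit)

    @property
    def ref_span(self) -> int:
        return self.end - self.start

    @property
    def canonical_class(self) -> CanonicalUnit:
        return canonical_unit(self.unit)

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.unit)


# ---------------------------------------------------------------------------
# tandem repeat detection
# ---------------------------------------------------------------------------

def find_tandem_repeats(
    seq: str,
    min_unit: int = 1,
    max_unit: int = 6,
    min_copies: int = 3,
    max_mismatch_frac: float = 0.0,
    chrom: str = "seq",
) -> list[RepeatLocus]:
    """Scan a sequence for tandem repeats.

    Finds maximal runs where a unit of length in [min_unit, max_unit]
    repeats at least ``min_copies`` times.  A run is reported under the
    minimal period of its repeating unit; runs whose minimal period falls
    outside the requested range are dropped.  With
    ``max_mismatch_frac > 0`` a run may continue through positions where
    seq[i] != seq[i - p], as long as the mismatch fraction within every
    sliding window of length max(2p, 10) stays at or below the threshold;
    the reported unit is then the most common exact p-mer among the run's
    complete copies.  Overlaps are resolved longest-run-first, ties by
    start then period, so output is deterministic.

    This is a plain periodicity scanner intended for test-scale sequences;
    genome-scale annotations should be loaded with
    :func:`read_repeat_annotation`.
    """
    if not seq:
        raise ValueError("sequence must be non-empty")
    if not (1 <= min_unit <= max_unit):
        raise ValueError("need 1 <= min_unit <= max_unit")
    seq = seq.upper()
    n = len(seq)
    candidates: list[tuple[int, int, int]] = []  # (start, end, period)
    for p in range(1, max_unit + 1):
        # match[i] true when seq[i] continues a p-periodic run
        i = p
        run_start = 0
        mismatches: list[int] = []
        window = max(2 * p, 10)
        pos = p
        while pos <= n:
            ok = pos < n and seq[pos] == seq[pos - p]
            if ok and max_mismatch_frac == 0.0:
                pos += 1
                continue
            if pos < n and not ok and max_mismatch_frac > 0.0:
                # tentatively allow the mismatch if every window stays legal
                mismatches = [m for m in mismatches if m > pos - window]
                frac = (len(mismatches) + 1) / min(window, pos + 1 - run_start)
                if frac <= max_mismatch_frac:
                    mismatches.append(pos)
                    pos += 1
                    continue
            if ok:
                pos += 1
                continue
            # run [run_start, pos) ended
            candidates.extend(_qualify(seq, run_start, pos, p, min_unit, max_unit, min_copies))
            run_start = pos - p + 1 if pos < n else pos
            mismatches = []
            pos += 1
        candidates.extend(_qualify(seq, run_start, n, p, min_unit, max_unit, min_copies))
    # dedupe identical intervals (a run can be found at several periods)
    best: dict[tuple[int, int], int] = {}
    for s, e, p in candidates:
        if (s, e) not in best or p < best[(s, e)]:
            best[(s, e)] = p
    ordered = sorted(best.items(), key=lambda kv: (-(kv[0][1] - kv[0][0]), kv[0][0], kv[1]))
    chosen: list[tuple[int, int, int]] = []
    for (s, e), p in ordered:
        if all(e <= cs or s >= ce for cs, ce, _ in chosen):
            chosen.append((s, e, p))
    loci = []
    for s, e, p in sorted(chosen):
        unit = _consensus_unit(seq, s, e, p)
        loci.append(RepeatLocus(chrom=chrom, start=s, end=e, unit=unit))
    return loci


def _qualify(seq, start, end, p, min_unit, max_unit, min_copies):
    """Yield (start, end, period) if run [start, end) qualifies at period p."""
    # a run must not end in tolerated mismatches
    while end - 1 >= start + p and seq[end - 1] != seq[end - 1 - p]:
        end -= 1
    if end - start < p * min_copies:
        return []
    unit = seq[start : start + p]
    mp = minimal_period(unit)
    if mp != p:
        return []  # reported under its own minimal period instead
    if not (min_unit <= p <= max_unit):
        return []
    return [(start, end, p)]


def _consensus_unit(seq: str, start: int, end: int, p: int) -> str:
    from collections import Counter

    copies = [seq[i : i + p] for i in range(start, end - p + 1, p)]
    counts = Counter(copies)
    top = max(counts.values())
    return sorted(u for u, c in counts.items() if c == top)[0]


# ---------------------------------------------------------------------------
# annotation readers
# ---------------------------------------------------------------------------

#: simpleRepeat.txt (UCSC/TRF) preset: 1-based column numbers.
SIMPLE_REPEAT_COLUMNS = {"chrom": 2, "start": 3, "end": 4, "unit": 17}

_DIALECTS = ("bed4", "simple_repeat", "genotype_table")


def read_repeat_annotation(
    path: str | Path,
    dialect: str = "bed4",
    column_map: dict[str, int] | None = None,
) -> list[RepeatLocus]:
    """Load repeat loci from an annotation file.

    dialects:
      * ``bed4`` — chrom, start, end, unit (tab-separated).
      * ``simple_repeat`` — UCSC simpleRepeat / TRF table; columns taken
        from ``column_map`` (1-based; default :data:`SIMPLE_REPEAT_COLUMNS`,
        with the unit falling back to the last column on short rows).
      * ``genotype_table`` — the locus columns of this package's genotype
        TSV (chrom, start, end, unit, gene, region, ...).

    All coordinates are returned 0-based half-open.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    cmap = dict(SIMPLE_REPEAT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    loci = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            try:
                if dialect == "bed4":
                    chrom, start, end, unit = fields[0], fields[1], fields[2], fields[3]
                    gene, region = None, "intergenic"
                elif dialect == "simple_repeat":
                    chrom = fields[cmap["chrom"] - 1]
                    start = fields[cmap["start"] - 1]
                    end = fields[cmap["end"] - 1]
                    ucol = cmap["unit"] - 1
                    unit = fields[ucol] if ucol < len(fields) else fields[-1]
                    gene, region = None, "intergenic"
                else:  # genotype_table
                    if fields[0] == "chrom":  # header
                        continue
                    chrom, start, end, unit = fields[:4]
                    gene = fields[4] if len(fields) > 4 and fields[4] else None
                    region = fields[5] if len(fields) > 5 and fields[5] else "intergenic"
                locus = RepeatLocus(
                    chrom=chrom, start=int(start), end=int(end),
                    unit=unit.upper(), gene=gene, region=region,
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            loci.append(locus)
    return loci


# ---------------------------------------------------------------------------
# gene models (refFlat) and genic-region assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Transcript:
    """One refFlat record (0-based half-open coordinates)."""

    gene: str
    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    @property
    def is_coding(self) -> bool:
        return self.cds_end > self.cds_start


def read_refflat(path: str | Path) -> list[Transcript]:
    """Parse a UCSC refFlat table (11 columns)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                starts = tuple(int(x) for x in f[9].rstrip(",").split(","))
                ends = tuple(int(x) for x in f[10].rstrip(",").split(","))
                if len(starts) != len(ends) or len(starts) != int(f[8]):
                    raise ValueError("exon list lengths disagree with exonCount")
                out.append(Transcript(
                    gene=f[0], name=f[1], chrom=f[2], strand=f[3],
                    tx_start=int(f[4]), tx_end=int(f[5]),
                    cds_start=int(f[6]), cds_end=int(f[7]),
                    exon_starts=starts, exon_ends=ends,
                ))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return out


def _region_for_transcript(locus: RepeatLocus, tx: Transcript) -> str | None:
    if tx.chrom != locus.chrom or locus.start >= tx.tx_end or locus.end <= tx.tx_start:
        return None
    best = "intron"
    for es, ee in zip(tx.exon_starts, tx.exon_ends):
        if locus.start >= ee or locus.end <= es:
            continue
        if not tx.is_coding:
            best = min(best, "noncoding_exon", key=_REGION_RANK.get)
            continue
        # the exonic overlap may touch CDS, left UTR and right UTR portions
        ov_start, ov_end = max(locus.start, es), min(locus.end, ee)
        if ov_start < tx.cds_end and ov_end > tx.cds_start:
            best = "coding"
        if ov_start < tx.cds_start:  # exon sequence left of CDS
            left = "utr5" if tx.strand == "+" else "utr3"
            best = min(best, left, key=_REGION_RANK.get)
        if ov_end > tx.cds_end:  # exon sequence right of CDS
            right = "utr3" if tx.strand == "+" else "utr5"
            best = min(best, right, key=_REGION_RANK.get)
    return best


def annotate_genic_region(
    locus: RepeatLocus, transcripts: Iterable[Transcript]
) -> tuple[str | None, str]:
    """Assign (gene, region) by overlap with gene models.

    Regions are ranked coding > utr5 > utr3 > noncoding_exon > intron >
    intergenic across all overlapping transcripts; the gene symbol comes
    from the transcript supplying the winning region.
    """
    gene, region = None, "intergenic"
    for tx in transcripts:
        r = _region_for_transcript(locus, tx)
        if r is not None and _REGION_RANK[r] < _REGION_RANK[region]:
            gene, region = tx.gene, r
    return gene, region


def annotate_loci(
    loci: Sequence[RepeatLocus], transcripts: Sequence[Transcript]
) -> list[RepeatLocus]:
    """Return loci with gene/region filled in from the gene models."""
    out = []
    for locus in loci:
        gene, region = annotate_genic_region(locus, transcripts)
        out.append(replace(locus, gene=gene, region=region))
    return out
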