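"""Per-read repeat copy-number-change estimation and genotype tables.

For each annotated repeat and each read whose alignment spans it, the
signed base-pair change is the total read insertion within a margin of
the repeat minus the total reference deletion inside the repeat; divided
by the unit length and rounded to the nearest integer it becomes the
read's copy-number change (delta) relative to the reference.

The margin (default 10 bp) controls how close to the repeat an insertion
must attach to be attributed to it: a small margin is less likely to
mistake a nearby unrelated insertion for an expansion, at the cost of
missing expansions of repeats with fuzzy annotated boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .catalog import RepeatLocus
from .maf import ReadAlignment

DEFAULT_MARGIN = 10  # bp; the upstream genotyper's default is 60


@dataclass(frozen=True)
class CopyChangeObservation:
    """One spanning read's integer repeat-unit change at one locus."""

    locus_key: tuple
    read_id: str
    delta_units: int
    delta_bases: int
    strand: str
    spanning: bool = True


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def estimate_copy_change(
    aln: ReadAlignment, locus: RepeatLocus, margin: int = DEFAULT_MARGIN
) -> CopyChangeObservation | None:
    """Estimate one read's copy-number change at one locus.

    Insertions are counted if their attachment coordinate lies in
    [start - margin, end + margin); deletions are counted by their
    overlap with the repeat itself.  Returns None unless the read has
    aligned columns strictly outside the margin-extended window on both
    sides (a spanning read), or if the chromosomes differ.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    if aln.chrom != locus.chrom:
        return None
    lo, hi = locus.start - margin, locus.end + margin
    if not (aln.aligned_min < lo and aln.aligned_max >= hi):
        return None
    ins = sum(n for pos, n in aln.insertions if lo <= pos < hi)
    dele = sum(
        min(de, locus.end) - max(ds, locus.start)
        for ds, de in aln.deletions
        if ds < locus.end and de > locus.start
    )
    delta_bases = ins - dele
    return CopyChangeObservation(
        locus_key=locus.key,
        read_id=aln.read_id,
        delta_units=_round_half_away(delta_bases / locus.unit_len),
        delta_bases=delta_bases,
        strand=aln.strand,
    )


@dataclass
class GenotypeRow:
    """One locus's spanning-read deltas for one sample, split by strand."""

    locus: RepeatLocus
    forward: list[int] = field(default_factory=list)
    reverse: list[int] = field(default_factory=list)

    @property
    def deltas(self) -> list[int]:
        return self.forward + self.reverse

    @property
    def n_reads(self) -> int:
        return len(self.forward) + len(self.reverse)


def genotype_sample(
    alignments: Iterable[ReadAlignment],
    loci: Sequence[RepeatLocus],
    margin: int = DEFAULT_MARGIN,
) -> list[GenotypeRow]:
    """Collect per-locus spanning-read deltas for one sample.

    Loci must be sorted by (chrom, start).  Delta lists are sorted
    descending (largest expansion first); loci with no spanning read get
    empty lists and count as undetected.
    """
    keys = [(loc.chrom, loc.start) for loc in loci]
    if keys != sorted(keys):
        raise ValueError("loci must be sorted by (chrom, start); sort them first")
    by_chrom: dict[str, list[ReadAlignment]] = {}
    for aln in alignments:
        by_chrom.setdefault(aln.chrom, []).append(aln)
    rows = []
    for locus in loci:
        row = GenotypeRow(locus=locus)
        for aln in by_chrom.get(locus.chrom, ()):
            obs = estimate_copy_change(aln, locus, margin)
            if obs is None:
                continue
            (row.forward if obs.strand == "+" else row.reverse).append(obs.delta_units)
        row.forward.sort(reverse=True)
        row.reverse.sort(reverse=True)
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# genotype table I/O (TSV)
# ---------------------------------------------------------------------------

_HEADER = ["chrom", "start", "end", "unit", "gene", "region", "forward", "reverse"]


def write_genotype_table(rows: Sequence[GenotypeRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for row in rows:
            loc = row.locus
            fh.write("\t".join([
                loc.chrom, str(loc.start), str(loc.end), loc.unit,
                loc.gene or "", loc.region,
                ",".join(map(str, row.forward)),
                ",".join(map(str, row.reverse)),
            ]) + "\n")


def _parse_deltas(token: str, path, lineno) -> list[int]:
    if not token:
        return []
    try:
        return [int(t) for t in token.split(",")]
    except ValueError as exc:
        raise ValueError(f"{path}: line {lineno}: non-integer delta in {token!r}") from exc


def read_genotype_table(path: str | Path) -> list[GenotypeRow]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("chrom\t"):
                continue
            f = line.split("\t")
            if len(f) < 8:
                raise ValueError(f"{path}: line {lineno}: expected 8 columns, got {len(f)}")
            locus = RepeatLocus(
                chrom=f[0], start=int(f[1]), end=int(f[2]), unit=f[3],
                gene=f[4] or None, region=f[5] or "intergenic",
            )
            rows.append(GenotypeRow(
                locus=locus,
                forward=_parse_deltas(f[6], path, lineno),
                reverse=_parse_deltas(f[7], path, lineno),
            ))
    return rows


# ---------------------------------------------------------------------------
# cohort join
# ---------------------------------------------------------------------------

@dataclass
class CohortRow:
    """One locus across samples; per-sample delta lists plus the pool."""

    locus: RepeatLocus
    samples: dict[str, GenotypeRow]

    @property
    def pooled(self) -> list[int]:
        """All spanning-read deltas from all samples, concatenated."""
        out: list[int] = []
        for row in self.samples.values():
            out.extend(row.deltas)
        return out

    @property
    def n_reads(self) -> int:
        return sum(r.n_reads for r in self.samples.values())


def join_samples(
    tables: Mapping[str, Sequence[GenotypeRow]] | Sequence[Sequence[GenotypeRow]],
) -> list[CohortRow]:
    """Merge per-sample genotype tables over a shared locus set.

    ``tables`` maps sample label to rows (a plain sequence gets labels
    sample1, sample2, ...).  Every table must cover exactly the same loci,
    keyed by (chrom, start, end, unit).
    """
    if not isinstance(tables, Mapping):
        tables = {f"sample{i + 1}": t for i, t in enumerate(tables)}
    if not tables:
        raise ValueError("no tables to join")
    labels = list(tables)
    keysets = {label: {row.locus.key for row in rows} for label, rows in tables.items()}
    universe = set().union(*keysets.values())
    missing = {
        label: sorted(universe - ks) for label, ks in keysets.items() if universe - ks
    }
    if missing:
        detail = "; ".join(f"{lab} lacks {m[:3]}" for lab, m in missing.items())
        raise ValueError(f"locus sets differ across samples: {detail}")
    first = tables[labels[0]]
    out = []
    for i, row in enumerate(first):
        per_sample = {}
        for label in labels:
            srow = tables[label][i]
            if srow.locus.key != row.locus.key:
                srow = next(r for r in tables[label] if r.locus.key == row.locus.key)
            per_sample[label] = srow
        out.append(CohortRow(locus=row.locus, samples=per_sample))
    return out
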