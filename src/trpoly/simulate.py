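"""Synthetic diploid long-read cohorts with ground-truth alignments.

The generator emulates the study design this package analyses: a small
reference with embedded tandem repeats, a cohort of diploid individuals
(default 21) whose alleles carry locus-specific copy-number changes
optionally in linkage with a nearby biallelic SNP, and noisy spanning
reads emitted together with their true alignments as MAF — so the whole
genotype/statistics/phasing chain can be validated against a complete
truth table without an external aligner.

Each haplotype's repeat-length difference from the reference appears in
the alignment as a single contiguous insertion or deletion run at a unit
boundary near the repeat midpoint, which is how aligners typically place
repeat expansions.  Sequencing noise is injected per base (substitutions,
then insertions, then deletions), with an optional rate boost inside
repeat spans to model the elevated indel error of nanopore reads in
low-complexity sequence.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .catalog import RepeatLocus, Transcript, annotate_loci, find_tandem_repeats
from .stats import SnpRecord
from .units import reverse_complement

_BASES = np.array(list("ACGT"))


class SimConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusSpec:
    """One repeat to embed: unit, reference copy count, allele spectrum."""

    unit: str
    copies: int
    start: int | None = None          # auto-spaced when None
    delta_dist: dict[int, float] = field(default_factory=lambda: {0: 1.0})
    region: str = "intergenic"
    gene: str | None = None

    def validate(self) -> None:
        if self.copies < 2:
            raise SimConfigError("a tandem repeat needs at least 2 copies")
        probs = np.array(list(self.delta_dist.values()), dtype=float)
        if (probs < 0).any() or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
            raise SimConfigError("delta distribution must be probabilities summing to 1")
        if min(self.delta_dist) < -(self.copies - 1):
            raise SimConfigError(
                "contraction larger than the reference repeat "
                f"(min delta {min(self.delta_dist)}, copies {self.copies})"
            )

    @property
    def span(self) -> int:
        return len(self.unit) * self.copies

    def dist_median(self) -> int:
        """Population median of the allele-delta distribution."""
        items = sorted(self.delta_dist.items())
        acc = 0.0
        for d, p in items:
            acc += p
            if acc >= 0.5 - 1e-12:
                return d
        return items[-1][0]


@dataclass(frozen=True)
class SnpSpec:
    """A biallelic SNP near one locus, optionally linked to its length."""

    locus_index: int = 0
    offset: int = -200     # bp relative to the locus start (negative = upstream)
    alt: str | None = None
    ld: str | float = "complete"   # "complete" | "independent" | r-squared
    alt_freq: float = 0.5          # marginal ALT frequency outside complete LD
    rsid: str = "rs_sim1"


@dataclass(frozen=True)
class ReadModel:
    """Read sampling and error parameters (rates are per base)."""

    coverage: float = 27.0          # total per individual, both haplotypes
    read_length_mean: int = 3000
    read_length_sd: int = 300
    min_read_length: int = 300
    substitution_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    repeat_indel_boost: float = 1.0

    def validate(self) -> None:
        if self.coverage <= 0:
            raise SimConfigError("coverage must be positive")
        for r in (self.substitution_rate, self.insertion_rate, self.deletion_rate):
            if not 0.0 <= r <= 1.0:
                raise SimConfigError("error rates must be in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Complete description of one synthetic cohort."""

    loci: tuple[LocusSpec, ...]
    seed: int = 0
    genome_length: int = 12000
    chrom: str = "chrSim"
    n_individuals: int = 21
    snp: SnpSpec | None = None
    read_model: ReadModel = field(default_factory=ReadModel)

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise SimConfigError("need at least one individual")
        for spec in self.loci:
            spec.validate()
        self.read_model.validate()

    @staticmethod
    def default() -> "SimConfig":
        """A 21-individual cohort with one polymorphic CAG repeat and a
        SNP in complete linkage with the expanded allele."""
        return SimConfig(
            loci=(
                LocusSpec(
                    unit="CAG", copies=10, region="coding",
                    delta_dist={0: 0.5, 10: 0.5},
                ),
            ),
            snp=SnpSpec(locus_index=0, offset=-200, ld="complete"),
        )


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------

@dataclass
class SimReference:
    chrom: str
    seq: str
    loci: list[RepeatLocus]
    transcripts: list[Transcript]
    snp: SnpRecord | None

    def fasta_text(self) -> str:
        buf = io.StringIO()
        SeqIO.write([SeqRecord(Seq(self.seq), id=self.chrom, description="")], buf, "fasta")
        return buf.getvalue()

    def bed_text(self) -> str:
        return "".join(
            f"{l.chrom}\t{l.start}\t{l.end}\t{l.unit}\n" for l in self.loci
        )

    def refflat_text(self) -> str:
        out = []
        for tx in self.transcripts:
            out.append("\t".join([
                tx.gene, tx.name, tx.chrom, tx.strand,
                str(tx.tx_start), str(tx.tx_end),
                str(tx.cds_start), str(tx.cds_end),
                str(len(tx.exon_starts)),
                ",".join(map(str, tx.exon_starts)) + ",",
                ",".join(map(str, tx.exon_ends)) + ",",
            ]))
        return "\n".join(out) + ("\n" if out else "")

    def snp_text(self) -> str:
        head = "chrom\tpos0\trsid\tref\talt\ttrait\n"
        if self.snp is None:
            return head
        s = self.snp
        return head + f"{s.chrom}\t{s.pos}\t{s.rsid}\t{s.ref}\t{s.alt}\t{s.trait}\n"


_MIN_FLANK = 200


def _place_loci(config: SimConfig) -> list[tuple[int, LocusSpec]]:
    spans = [s.span for s in config.loci]
    placed: list[tuple[int, LocusSpec]] = []
    explicit = [s for s in config.loci if s.start is not None]
    auto = [s for s in config.loci if s.start is None]
    for s in explicit:
        placed.append((s.start, s))
    if auto:
        free = config.genome_length - sum(spans)
        gap = free // (len(config.loci) + 1)
        if gap < _MIN_FLANK:
            raise SimConfigError(
                f"genome of {config.genome_length} bp cannot hold "
                f"{len(config.loci)} loci with {_MIN_FLANK} bp flanks"
            )
        pos = 0
        for s in config.loci:
            if s.start is not None:
                continue
            pos += gap
            placed.append((pos, s))
            pos += s.span
    placed.sort(key=lambda t: t[0])
    prev_end = 0
    for start, s in placed:
        if start - prev_end < _MIN_FLANK:
            raise SimConfigError(
                f"loci overlap or flanks shorter than {_MIN_FLANK} bp at {start}"
            )
        prev_end = start + s.span
    if config.genome_length - prev_end < _MIN_FLANK:
        raise SimConfigError("last locus too close to the genome end")
    return placed


def _scrub_flanks(seq: np.ndarray, intervals: list[tuple[int, int]],
                  max_unit: int, rng: np.random.Generator) -> None:
    """Re-randomize accidental tandem structure outside the designed loci."""
    protected = np.zeros(len(seq), dtype=bool)
    for s, e in intervals:
        protected[s:e] = True
    for _ in range(80):
        found = find_tandem_repeats(
            "".join(seq), min_unit=1, max_unit=max_unit, min_copies=3
        )
        dirty = []
        for loc in found:
            if (loc.start, loc.end) in intervals:
                continue
            idx = [i for i in range(loc.start, loc.end) if not protected[i]]
            dirty.extend(idx)
        if not dirty:
            return
        seq[dirty] = _BASES[rng.integers(0, 4, size=len(dirty))]
    raise RuntimeError("could not scrub flank tandem structure; genome too small?")


def simulate_reference(config: SimConfig, seed: int | None = None) -> SimReference:
    """Build the toy reference: sequence, repeat annotation, gene models, SNP.

    Deterministic for a fixed seed.  Unique flanks are scrubbed of any
    exact tandem structure (period up to the longest embedded unit,
    3+ copies), and the bases abutting each locus are forced not to
    extend the repeat run, so the annotation is exactly the maximal run.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    placed = _place_loci(config)
    seq = _BASES[rng.integers(0, 4, size=config.genome_length)].copy()
    intervals = [(start, start + s.span) for start, s in placed]
    for (start, s) in placed:
        seq[start : start + s.span] = list(s.unit * s.copies)
    max_unit = max(len(s.unit) for _, s in placed)
    _scrub_flanks(seq, intervals, max_unit, rng)
    # do not let flanking bases extend the repeat run
    for (start, s) in placed:
        end = start + s.span
        if seq[start - 1] == s.unit[-1]:
            choices = [b for b in "ACGT" if b != s.unit[-1]]
            seq[start - 1] = choices[rng.integers(0, 3)]
        if end < len(seq) and seq[end] == s.unit[0]:
            choices = [b for b in "ACGT" if b != s.unit[0]]
            seq[end] = choices[rng.integers(0, 3)]
    sequence = "".join(seq)

    transcripts = []
    for i, (start, s) in enumerate(placed):
        tx = _toy_transcript(config, i, start, s)
        if tx is not None:
            transcripts.append(tx)
    loci = [
        RepeatLocus(chrom=config.chrom, start=start, end=start + s.span, unit=s.unit)
        for start, s in placed
    ]
    loci = annotate_loci(loci, transcripts)

    snp = None
    if config.snp is not None:
        sp = config.snp
        anchor, spec = placed[sp.locus_index]
        pos = anchor + sp.offset
        if not 0 <= pos < config.genome_length:
            raise SimConfigError(f"SNP position {pos} outside the genome")
        if any(s <= pos < e for s, e in intervals):
            raise SimConfigError("SNP position falls inside a repeat locus")
        ref_base = sequence[pos]
        alt = sp.alt or next(b for b in "ACGT" if b != ref_base)
        if alt == ref_base:
            raise SimConfigError("SNP alt base equals the reference base")
        snp = SnpRecord(chrom=config.chrom, pos=pos, rsid=sp.rsid,
                        ref=ref_base, alt=alt, trait="simulated")
    return SimReference(
        chrom=config.chrom, seq=sequence, loci=loci,
        transcripts=transcripts, snp=snp,
    )


def _toy_transcript(config: SimConfig, i: int, start: int, s: LocusSpec) -> Transcript | None:
    if s.region == "intergenic":
        return None
    end = start + s.span
    gene = s.gene or f"GENE{i + 1}"
    name = f"{gene}.tx"
    tx_start = max(0, start - 150)
    tx_end = min(config.genome_length, end + 150)
    if s.region == "coding":
        cds = (max(tx_start, start - 50), min(tx_end, end + 50))
        exons = ((tx_start,), (tx_end,))
    elif s.region == "utr5":
        cds = (min(tx_end - 1, end + 50), min(tx_end, end + 120))
        exons = ((tx_start,), (tx_end,))
    elif s.region == "utr3":
        cds = (max(tx_start, start - 120), max(tx_start + 1, start - 50))
        exons = ((tx_start,), (tx_end,))
    elif s.region == "noncoding_exon":
        cds = (tx_start, tx_start)
        exons = ((tx_start,), (tx_end,))
    elif s.region == "intron":
        ex1 = (tx_start, max(tx_start + 1, start - 50))
        ex2 = (min(tx_end - 1, end + 50), tx_end)
        cds = (ex1[0], ex1[1])
        exons = ((ex1[0], ex2[0]), (ex1[1], ex2[1]))
    else:
        raise SimConfigError(f"cannot place a locus in region {s.region!r}")
    return Transcript(
        gene=gene, name=name, chrom=config.chrom, strand="+",
        tx_start=tx_start, tx_end=tx_end,
        cds_start=cds[0], cds_end=cds[1],
        exon_starts=exons[0], exon_ends=exons[1],
    )


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

@dataclass
class IndividualTruth:
    sample: str
    hap_deltas: np.ndarray      # shape (2, n_loci), integer deltas
    hap_snp_bases: tuple[str, str] | None

    def allele_deltas(self, locus_index: int) -> tuple[int, int]:
        pair = (int(self.hap_deltas[0, locus_index]), int(self.hap_deltas[1, locus_index]))
        return tuple(sorted(pair))


@dataclass
class TruthTable:
    individuals: list[IndividualTruth]
    loci: tuple[LocusSpec, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ind in self.individuals:
            for h in (0, 1):
                row = {"sample": ind.sample, "haplotype": h}
                for j in range(len(self.loci)):
                    row[f"delta_locus{j}"] = int(ind.hap_deltas[h, j])
                if ind.hap_snp_bases is not None:
                    row["snp_base"] = ind.hap_snp_bases[h]
                rows.append(row)
        return pd.DataFrame(rows)


def simulate_population(config: SimConfig, seed: int | None = None) -> TruthTable:
    """Draw 2N haplotypes independently (Hardy-Weinberg).

    Under complete LD the ALT base rides exactly on haplotypes whose delta
    at the linked locus exceeds the distribution median; under an r²
    setting the ALT/long-allele correlation is √r² in expectation; under
    "independent" the SNP base ignores the repeat.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n_loci = len(config.loci)
    individuals = []
    for i in range(config.n_individuals):
        deltas = np.zeros((2, n_loci), dtype=int)
        for j, spec in enumerate(config.loci):
            ds = np.array(sorted(spec.delta_dist), dtype=int)
            ps = np.array([spec.delta_dist[int(d)] for d in ds], dtype=float)
            ps = ps / ps.sum()
            deltas[:, j] = rng.choice(ds, size=2, p=ps)
        bases = None
        if config.snp is not None:
            sp = config.snp
            spec = config.loci[sp.locus_index]
            med = spec.dist_median()
            pair = []
            for h in (0, 1):
                long_hap = deltas[h, sp.locus_index] > med
                if sp.ld == "complete":
                    is_alt = long_hap
                elif sp.ld == "independent":
                    is_alt = rng.random() < sp.alt_freq
                else:
                    r = math.sqrt(float(sp.ld))
                    if rng.random() < r:
                        is_alt = long_hap
                    else:
                        p_long = sum(
                            p for d, p in spec.delta_dist.items() if d > med
                        )
                        is_alt = rng.random() < p_long
                pair.append("alt" if is_alt else "ref")
            bases = (pair[0], pair[1])
        individuals.append(IndividualTruth(
            sample=f"S{i + 1:02d}", hap_deltas=deltas, hap_snp_bases=bases,
        ))
    return TruthTable(individuals=individuals, loci=config.loci)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

@dataclass
class SimRead:
    read_id: str
    sample: str
    haplotype: int
    strand: str
    sequence: str               # in read orientation (as sequenced)
    ref_start: int
    ref_end: int
    maf_block: str


@dataclass
class SimReadSet:
    reads: list[SimRead]
    chrom: str

    def maf_text(self) -> str:
        return "".join(r.maf_block for r in self.reads)

    def fasta_text(self) -> str:
        buf = io.StringIO()
        SeqIO.write(
            [SeqRecord(Seq(r.sequence), id=r.read_id, description="") for r in self.reads],
            buf, "fasta",
        )
        return buf.getvalue()

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "read_id": r.read_id, "sample": r.sample, "haplotype": r.haplotype,
                "strand": r.strand, "ref_start": r.ref_start, "ref_end": r.ref_end,
            }
            for r in self.reads
        ])

    def by_sample(self) -> dict[str, list[SimRead]]:
        out: dict[str, list[SimRead]] = {}
        for r in self.reads:
            out.setdefault(r.sample, []).append(r)
        return out


@dataclass
class _HapColumns:
    """Column-wise reference<->haplotype alignment for one haplotype.

    Arrays are indexed by alignment column: ``ref_c``/``hap_c`` hold the
    base or "-", ``col_ref`` the reference coordinate (-1 at insertions),
    ``in_rep`` whether the column lies in a repeat span, and ``hap2col``
    maps haplotype coordinates to column indices.
    """

    ref_c: np.ndarray
    hap_c: np.ndarray
    col_ref: np.ndarray
    in_rep: np.ndarray
    hap2col: np.ndarray

    @property
    def hap_len(self) -> int:
        return len(self.hap2col)


def _haplotype_columns(
    reference: SimReference,
    spec_loci: Sequence[LocusSpec],
    deltas: Sequence[int],
    snp_base: str | None,
) -> _HapColumns:
    seq = reference.seq
    rep_mask = np.zeros(len(seq), dtype=bool)
    for locus in reference.loci:
        rep_mask[locus.start:locus.end] = True
    events = []  # (ref_pos, kind, payload)
    for locus, spec, delta in zip(reference.loci, spec_loci, deltas):
        if delta == 0:
            continue
        u = locus.unit_len
        copies = locus.ref_span // u
        if delta > 0:
            mid = locus.start + u * (copies // 2)
            events.append((mid, "I", spec.unit * delta))
        else:
            ndel = -delta
            ds = locus.start + u * ((copies - ndel) // 2)
            events.append((ds, "D", ds + ndel * u))
    events.sort()

    ref_parts, hap_parts, cref_parts, rep_parts = [], [], [], []
    snp = reference.snp

    def emit_m(a: int, b: int) -> None:
        if b <= a:
            return
        chunk = np.array(list(seq[a:b]))
        if snp is not None and snp_base == "alt" and a <= snp.pos < b:
            chunk = chunk.copy()
        hap_chunk = chunk.copy()
        if snp is not None and snp_base == "alt" and a <= snp.pos < b:
            hap_chunk[snp.pos - a] = snp.alt
        ref_parts.append(chunk)
        hap_parts.append(hap_chunk)
        cref_parts.append(np.arange(a, b))
        rep_parts.append(rep_mask[a:b])

    pos = 0
    for ref_pos, kind, payload in events:
        emit_m(pos, ref_pos)
        pos = ref_pos
        if kind == "I":
            n = len(payload)
            ref_parts.append(np.full(n, "-"))
            hap_parts.append(np.array(list(payload)))
            cref_parts.append(np.full(n, -1))
            rep_parts.append(np.full(n, True))
        else:
            n = payload - ref_pos
            ref_parts.append(np.array(list(seq[ref_pos:payload])))
            hap_parts.append(np.full(n, "-"))
            cref_parts.append(np.arange(ref_pos, payload))
            rep_parts.append(rep_mask[ref_pos:payload])
            pos = payload
    emit_m(pos, len(seq))

    ref_c = np.concatenate(ref_parts)
    hap_c = np.concatenate(hap_parts)
    col_ref = np.concatenate(cref_parts)
    in_rep = np.concatenate(rep_parts)
    hap2col = np.flatnonzero(hap_c != "-")
    return _HapColumns(ref_c=ref_c, hap_c=hap_c, col_ref=col_ref,
                       in_rep=in_rep, hap2col=hap2col)


_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _inject_errors(
    ref_c: np.ndarray, read_c: np.ndarray, col_ref: np.ndarray,
    in_rep: np.ndarray, model: ReadModel, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply substitutions, then insertions, then deletions, per base."""
    ref_c, read_c = ref_c.copy(), read_c.copy()
    col_ref = col_ref.copy()
    boost = np.where(in_rep, model.repeat_indel_boost, 1.0)
    has_read = read_c != "-"
    # substitutions (uniform over the three other bases)
    if model.substitution_rate > 0:
        hit = has_read & (rng.random(len(read_c)) < model.substitution_rate)
        if hit.any():
            idx = np.array([_BASE_IDX[b] for b in read_c[hit]])
            shift = rng.integers(1, 4, size=hit.sum())
            read_c[hit] = _BASES[(idx + shift) % 4]
    # insertions (one extra read base after the hit base)
    if model.insertion_rate > 0:
        p = np.minimum(model.insertion_rate * boost, 1.0)
        hit = np.flatnonzero(has_read & (rng.random(len(read_c)) < p))
        if hit.size:
            newb = _BASES[rng.integers(0, 4, size=hit.size)]
            ref_c = np.insert(ref_c, hit + 1, "-")
            read_c = np.insert(read_c, hit + 1, newb)
            col_ref = np.insert(col_ref, hit + 1, -1)
            in_rep = np.insert(in_rep, hit + 1, in_rep[hit])
            boost = np.where(in_rep, model.repeat_indel_boost, 1.0)
    # deletions (drop the read base; drop the column when it was inserted)
    if model.deletion_rate > 0:
        has_read = read_c != "-"
        p = np.minimum(model.deletion_rate * boost, 1.0)
        hit = has_read & (rng.random(len(read_c)) < p)
        aligned_hit = hit & (ref_c != "-")
        read_c[aligned_hit] = "-"
        drop = hit & (ref_c == "-")
        if drop.any():
            keep = ~drop
            ref_c, read_c, col_ref = ref_c[keep], read_c[keep], col_ref[keep]
    # trim to the first/last fully aligned column
    both = np.flatnonzero((ref_c != "-") & (read_c != "-"))
    if both.size == 0:
        return ref_c[:0], read_c[:0], col_ref[:0]
    sl = slice(both[0], both[-1] + 1)
    return ref_c[sl], read_c[sl], col_ref[sl]


def simulate_reads(
    reference: SimReference,
    truth: TruthTable,
    read_model: ReadModel | None = None,
    seed: int | None = None,
    config: SimConfig | None = None,
) -> SimReadSet:
    """Sample noisy spanning reads per haplotype with ground-truth MAF.

    Read count per haplotype targets half the configured per-individual
    coverage; lengths are normal (clipped below); starts are uniform.
    Each read is emitted fully aligned (no clipped tails), on a random
    strand, as one MAF block that is a valid alignment of the emitted
    read sequence to the reference.
    """
    if config is None:
        raise ValueError("pass the SimConfig used to build the truth table")
    model = read_model or config.read_model
    model.validate()
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    genome_len = len(reference.seq)
    reads: list[SimRead] = []
    counter = 0
    for ind in truth.individuals:
        for h in (0, 1):
            bases = ind.hap_snp_bases[h] if ind.hap_snp_bases else None
            cols = _haplotype_columns(reference, truth.loci, ind.hap_deltas[h], bases)
            hap_len = cols.hap_len
            n_reads = max(1, round(model.coverage / 2 * hap_len
                                   / model.read_length_mean))
            lengths = rng.normal(model.read_length_mean, model.read_length_sd,
                                 size=n_reads)
            lengths = np.clip(lengths.round().astype(int),
                              model.min_read_length, hap_len)
            for L in lengths:
                a = int(rng.integers(0, hap_len - L + 1))
                b = a + int(L)
                c0 = cols.hap2col[a]
                c1 = cols.hap2col[b - 1] + 1
                ref_c, read_c, col_ref = _inject_errors(
                    cols.ref_c[c0:c1], cols.hap_c[c0:c1], cols.col_ref[c0:c1],
                    cols.in_rep[c0:c1], model, rng,
                )
                if ref_c.size == 0:
                    continue
                counter += 1
                read_id = f"read{counter:05d}_{ind.sample}_h{h}"
                strand = "+" if rng.random() < 0.5 else "-"
                aligned_ref = col_ref[col_ref >= 0]
                ref_start = int(aligned_ref[0])
                ref_size = int(aligned_ref.size)
                ref_text = "".join(ref_c)
                read_text = "".join(read_c)
                read_seq_fwd = read_text.replace("-", "")
                rlen = len(read_seq_fwd)
                block = (
                    "a score=0\n"
                    f"s {reference.chrom} {ref_start} {ref_size} + {genome_len} {ref_text}\n"
                    f"s {read_id} 0 {rlen} {strand} {rlen} {read_text}\n\n"
                )
                sequence = (read_seq_fwd if strand == "+"
                            else reverse_complement(read_seq_fwd))
                reads.append(SimRead(
                    read_id=read_id, sample=ind.sample, haplotype=h,
                    strand=strand, sequence=sequence,
                    ref_start=ref_start, ref_end=ref_start + ref_size,
                    maf_block=block,
                ))
    return SimReadSet(reads=reads, chrom=reference.chrom)


# ---------------------------------------------------------------------------
# one-call convenience
# ---------------------------------------------------------------------------

@dataclass
class Simulation:
    config: SimConfig
    reference: SimReference
    truth: TruthTable
    reads: SimReadSet

    def write_outputs(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA/MAF/BED/refFlat/SNP/truth files; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "reference_fasta": outdir / "reference.fa",
            "reads_fasta": outdir / "reads.fa",
            "alignments_maf": outdir / "alignments.maf",
            "repeats_bed": outdir / "repeats.bed",
            "refflat": outdir / "refflat.txt",
            "snps_tsv": outdir / "snps.tsv",
            "truth_haplotypes": outdir / "truth_haplotypes.tsv",
            "truth_reads": outdir / "truth_reads.tsv",
        }
        paths["reference_fasta"].write_text(self.reference.fasta_text())
        paths["reads_fasta"].write_text(self.reads.fasta_text())
        paths["alignments_maf"].write_text(self.reads.maf_text())
        paths["repeats_bed"].write_text(self.reference.bed_text())
        paths["refflat"].write_text(self.reference.refflat_text())
        paths["snps_tsv"].write_text(self.reference.snp_text())
        self.truth.to_frame().to_csv(paths["truth_haplotypes"], sep="\t", index=False)
        self.reads.truth_frame().to_csv(paths["truth_reads"], sep="\t", index=False)
        return paths


def simulate(config: SimConfig, seed: int | None = None) -> Simulation:
    """Run the full reference -> population -> reads chain, deterministically.

    Stage seeds are spawned from one root so the same (config, seed) pair
    always reproduces the identical cohort.
    """
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    s_ref, s_pop, s_reads = [
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(3)
    ]
    reference = simulate_reference(config, seed=s_ref)
    truth = simulate_population(config, seed=s_pop)
    reads = simulate_reads(reference, truth, seed=s_reads, config=config)
    return Simulation(config=config, reference=reference, truth=truth, reads=reads)
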