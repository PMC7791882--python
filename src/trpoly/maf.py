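"""Reading LAST-style MAF alignments into per-read gapped coordinate maps.

Each "a" block holds two "s" lines, reference first.  Blocks are stored
with all coordinates on the reference forward strand; for reverse-strand
reads the MAF text already shows the read reverse-complemented, so the
stored read bases are in reference orientation and the base aligned over
any reference position can be read off directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import AlignIO


@dataclass
class ReadAlignment:
    """One read's gapped alignment to the reference (one MAF block).

    ``segments`` are the gapless aligned stretches as (ref_start,
    read_bases); ``insertions`` attach extra read bases immediately before
    the given reference coordinate; ``deletions`` are reference intervals
    with no read base.  Runs are normalized: adjacent insertion/deletion
    runs are paired into aligned (mismatch) columns.
    """

    read_id: str
    chrom: str
    strand: str
    read_length: int
    ref_start: int
    ref_end: int
    segments: list[tuple[int, str]] = field(default_factory=list)
    insertions: list[tuple[int, int]] = field(default_factory=list)
    deletions: list[tuple[int, int]] = field(default_factory=list)

    def base_at(self, ref_pos: int) -> str | None:
        """Read base aligned over ``ref_pos`` (reference orientation).

        Returns None when the position is deleted in the read or outside
        the aligned range.
        """
        for seg_start, bases in self.segments:
            if seg_start <= ref_pos < seg_start + len(bases):
                return bases[ref_pos - seg_start]
        return None

    @property
    def aligned_min(self) -> int:
        return self.ref_start

    @property
    def aligned_max(self) -> int:
        """Last reference coordinate with an aligned (non-gap) column."""
        return self.ref_end - 1


class MafParseError(ValueError):
    pass


def _build_alignment(
    read_id: str,
    chrom: str,
    strand: str,
    read_length: int,
    ref_start: int,
    ref_text: str,
    read_text: str,
) -> ReadAlignment:
    if len(ref_text) != len(read_text):
        raise MafParseError("aligned rows have different lengths")
    # Walk columns into an op list, then normalize I/D adjacency.
    ops: list[list] = []  # [kind, ref_pos, payload]
    pos = ref_start
    for rb, qb in zip(ref_text.upper(), read_text.upper()):
        if rb != "-" and qb != "-":
            if ops and ops[-1][0] == "M":
                ops[-1][2] += qb
            else:
                ops.append(["M", pos, qb])
            pos += 1
        elif rb == "-" and qb != "-":
            if ops and ops[-1][0] == "I" and ops[-1][1] == pos:
                ops[-1][2] += qb
            else:
                ops.append(["I", pos, qb])
        elif rb != "-" and qb == "-":
            if ops and ops[-1][0] == "D":
                ops[-1][2] += 1
            else:
                ops.append(["D", pos, 1])
            pos += 1
        # column of two gaps: ignore
    ops = _normalize(ops)
    # gap runs before the first / after the last aligned column carry no
    # anchoring information; drop them
    while ops and ops[0][0] != "M":
        ops.pop(0)
    while ops and ops[-1][0] != "M":
        ops.pop()
    aln = ReadAlignment(
        read_id=read_id, chrom=chrom, strand=strand, read_length=read_length,
        ref_start=ref_start, ref_end=pos,
    )
    for kind, p, payload in ops:
        if kind == "M":
            aln.segments.append((p, payload))
        elif kind == "I":
            aln.insertions.append((p, len(payload)))
        else:
            aln.deletions.append((p, p + payload))
    if not aln.segments:
        raise MafParseError("alignment block has no aligned columns")
    aln.ref_start = aln.segments[0][0]
    aln.ref_end = aln.segments[-1][0] + len(aln.segments[-1][1])
    return aln


def _normalize(ops: list[list]) -> list[list]:
    """Pair directly adjacent insertion and deletion runs into mismatches.

    Repeats until no I run touches a D run, merging contiguous same-kind
    runs along the way, so the final op list alternates M with isolated
    gap runs.
    """
    ops = [list(op) for op in ops]
    changed = True
    while changed:
        changed = False
        out: list[list] = []
        for op in ops:
            if not out:
                out.append(op)
                continue
            prev = out[-1]
            if prev[0] == "M" and op[0] == "M" and prev[1] + len(prev[2]) == op[1]:
                prev[2] += op[2]
            elif prev[0] == "I" and op[0] == "I" and prev[1] == op[1]:
                prev[2] += op[2]
            elif prev[0] == "D" and op[0] == "D" and prev[1] + prev[2] == op[1]:
                prev[2] += op[2]
            elif prev[0] == "I" and op[0] == "D" and prev[1] == op[1]:
                # I before [p, p+n): first k inserted bases align over ref
                bases, n = prev[2], op[2]
                k = min(len(bases), n)
                out.pop()
                out.append(["M", op[1], bases[:k]])
                if len(bases) > k:
                    out.append(["I", op[1] + k, bases[k:]])
                if n > k:
                    out.append(["D", op[1] + k, n - k])
                changed = True
            elif prev[0] == "D" and op[0] == "I" and prev[1] + prev[2] == op[1]:
                # D over [s, s+n) then I at s+n: align last k deleted refs
                n, bases = prev[2], op[2]
                k = min(n, len(bases))
                out.pop()
                if n > k:
                    out.append(["D", prev[1], n - k])
                out.append(["M", prev[1] + n - k, bases[:k]])
                if len(bases) > k:
                    out.append(["I", prev[1] + n, bases[k:]])
                changed = True
            else:
                out.append(op)
        ops = out
    return ops


def read_maf(path: str | Path) -> list[ReadAlignment]:
    """Parse a MAF file of pairwise blocks (reference "s" line first).

    Reverse-strand reads (strand "-" on the second s line) are kept on
    reference-forward coordinates; a reference s line on "-" is flipped.
    Multiple blocks per read are returned as separate alignments.
    """
    alignments = []
    with open(path) as fh:
        try:
            blocks = list(AlignIO.parse(fh, "maf"))
        except ValueError as exc:
            raise MafParseError(f"{path}: {exc}") from exc
    for idx, block in enumerate(blocks):
        if len(block) != 2:
            raise MafParseError(
                f"{path}: block {idx}: expected 2 's' lines, got {len(block)}"
            )
        ref, qry = block[0], block[1]
        r_ann, q_ann = ref.annotations, qry.annotations
        ref_text, qry_text = str(ref.seq), str(qry.seq)
        ref_start = int(r_ann["start"])
        if r_ann.get("strand", 1) in (-1, "-"):
            # flip the whole block onto the reference forward strand
            ref_start = int(r_ann["srcSize"]) - ref_start - int(r_ann["size"])
            ref_text = _revcomp_gapped(ref_text)
            qry_text = _revcomp_gapped(qry_text)
        strand = "-" if q_ann.get("strand", 1) in (-1, "-") else "+"
        for name, ann, text in (("ref", r_ann, ref_text), ("query", q_ann, qry_text)):
            if len(text) - text.count("-") != int(ann["size"]):
                raise MafParseError(
                    f"{path}: block {idx}: {name} size disagrees with alignment text"
                )
        try:
            aln = _build_alignment(
                read_id=qry.id,
                chrom=ref.id,
                strand=strand,
                read_length=int(q_ann["srcSize"]),
                ref_start=ref_start,
                ref_text=ref_text,
                read_text=qry_text,
            )
        except MafParseError as exc:
            raise MafParseError(f"{path}: block {idx}: {exc}") from exc
        alignments.append(aln)
    return alignments


_RC = str.maketrans("ACGTacgt-", "TGCAtgca-")


def _revcomp_gapped(text: str) -> str:
    return text.translate(_RC)[::-1]
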