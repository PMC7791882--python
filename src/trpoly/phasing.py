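"""Two-allele splitting, per-read SNP extraction, phasing and association.

A diploid individual's spanning reads at a repeat locus come from two
alleles.  Sorting the per-read deltas and minimizing total within-group
variance over every split point (exact 1-D two-means) separates the
alleles; each allele's base at a nearby SNP is then called by majority
vote over its member reads.  Across individuals, allele-level repeat
lengths grouped by SNP base are compared with an unpaired t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .catalog import RepeatLocus
from .genotyping import DEFAULT_MARGIN, estimate_copy_change
from .maf import ReadAlignment

MIN_READS = 3        # fewest reads for a two-allele call
MIN_GAP = 2          # units; closer allele medians are called homozygous
VOTE_THRESHOLD = 0.6  # majority fraction required for an allele's SNP base
MIN_VOTES = 2        # fewest reads covering the SNP for a vote


@dataclass(frozen=True)
class AlleleCall:
    """One allele of one individual at one locus."""

    allele_delta: float          # median delta of member reads
    member_ids: tuple[str, ...]
    snp_base: str | None = None
    support_fraction: float = 0.0


@dataclass(frozen=True)
class PhasedGenotype:
    """Both alleles of one individual, with SNP bases where callable."""

    allele1: AlleleCall
    allele2: AlleleCall
    homozygous: bool
    sample: str | None = None

    @property
    def alleles(self) -> tuple[AlleleCall, AlleleCall]:
        return (self.allele1, self.allele2)


def _within_ss(arr: np.ndarray) -> float:
    return float(((arr - arr.mean()) ** 2).sum()) if arr.size else 0.0


def split_alleles(
    deltas: Sequence[int | float],
    read_ids: Sequence[str] | None = None,
    min_reads: int = MIN_READS,
    min_gap: float = MIN_GAP,
) -> PhasedGenotype | None:
    """Split one individual's per-read deltas into two allele groups.

    Scans every split point of the sorted deltas for the minimum total
    within-group variance.  If the two group medians differ by less than
    ``min_gap`` units, or either group has fewer than min_reads/2 reads,
    the call is homozygous: both alleles share all reads and the pooled
    median.  Returns None (no-call) with fewer than ``min_reads`` reads.
    """
    n = len(deltas)
    if n < min_reads:
        return None
    if read_ids is None:
        read_ids = [str(i) for i in range(n)]
    order = sorted(range(n), key=lambda i: (deltas[i], read_ids[i]))
    svals = np.array([deltas[i] for i in order], dtype=float)
    sids = [read_ids[i] for i in order]

    best_k, best_cost = None, np.inf
    for k in range(1, n):
        cost = _within_ss(svals[:k]) + _within_ss(svals[k:])
        if cost < best_cost - 1e-12:
            best_cost, best_k = cost, k
    lo, hi = svals[:best_k], svals[best_k:]
    med_lo, med_hi = float(np.median(lo)), float(np.median(hi))
    homozygous = (
        (med_hi - med_lo) < min_gap
        or len(lo) < min_reads / 2
        or len(hi) < min_reads / 2
    )
    if homozygous:
        med = float(np.median(svals))
        call = AlleleCall(allele_delta=med, member_ids=tuple(sids))
        return PhasedGenotype(allele1=call, allele2=call, homozygous=True)
    return PhasedGenotype(
        allele1=AlleleCall(allele_delta=med_lo, member_ids=tuple(sids[:best_k])),
        allele2=AlleleCall(allele_delta=med_hi, member_ids=tuple(sids[best_k:])),
        homozygous=False,
    )


def snp_allele_per_read(aln: ReadAlignment, snp_pos: int) -> str | None:
    """The read's base over ``snp_pos`` on the reference forward strand.

    Reverse-strand alignments are already stored in reference orientation
    (the MAF text shows the reverse-complemented read), so no further
    complementing is needed.  None when deleted or outside the alignment.
    """
    return aln.base_at(snp_pos)


def _vote(
    bases: list[str], threshold: float = VOTE_THRESHOLD, min_votes: int = MIN_VOTES
) -> tuple[str | None, float]:
    if len(bases) < min_votes:
        return None, 0.0
    counts: dict[str, int] = {}
    for b in bases:
        counts[b] = counts.get(b, 0) + 1
    top = max(sorted(counts), key=counts.get)
    frac = counts[top] / len(bases)
    if frac < threshold:
        return None, frac
    return top, frac


def phase_locus(
    alignments: Iterable[ReadAlignment],
    locus: RepeatLocus,
    snp_pos: int,
    margin: int = DEFAULT_MARGIN,
    min_reads: int = MIN_READS,
    min_gap: float = MIN_GAP,
    vote_threshold: float = VOTE_THRESHOLD,
    min_votes: int = MIN_VOTES,
    sample: str | None = None,
) -> PhasedGenotype | None:
    """Phase one individual's repeat alleles with a nearby SNP.

    Genotypes the locus from the individual's alignments, splits the
    reads into two alleles, and assigns each allele the majority base its
    member reads carry over ``snp_pos``.  A genotype with both SNP bases
    missing is still reported; None only when the locus itself cannot be
    called (too few spanning reads).
    """
    alignments = list(alignments)
    deltas, ids, bases_by_read = [], [], {}
    for i, aln in enumerate(alignments):
        obs = estimate_copy_change(aln, locus, margin)
        if obs is None:
            continue
        rid = f"{aln.read_id}#{i}"  # disambiguate multi-block reads
        deltas.append(obs.delta_units)
        ids.append(rid)
        base = snp_allele_per_read(aln, snp_pos)
        if base is not None:
            bases_by_read[rid] = base
    geno = split_alleles(deltas, ids, min_reads=min_reads, min_gap=min_gap)
    if geno is None:
        return None
    voted = []
    for allele in geno.alleles:
        bases = [bases_by_read[r] for r in allele.member_ids if r in bases_by_read]
        base, frac = _vote(bases, vote_threshold, min_votes)
        voted.append(AlleleCall(
            allele_delta=allele.allele_delta,
            member_ids=allele.member_ids,
            snp_base=base,
            support_fraction=frac,
        ))
    return PhasedGenotype(
        allele1=voted[0], allele2=voted[1],
        homozygous=geno.homozygous, sample=sample,
    )


# ---------------------------------------------------------------------------
# cohort association
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationResult:
    """Unpaired t-test of allele repeat length (bp) against SNP base."""

    tested: bool
    bases: tuple[str, ...] = ()
    sizes: tuple[int, ...] = ()
    means: tuple[float, ...] = ()
    t: float | None = None
    p: float | None = None
    direction: str | None = None  # base associated with longer repeats
    reason: str | None = None


def repeat_snp_association(
    pairs: Iterable[tuple[float, str | None]],
    equal_var: bool = True,
) -> AssociationResult:
    """Test whether repeat length differs between SNP base groups.

    ``pairs`` are allele-level (absolute length bp, snp base); alleles
    with a missing base are excluded.  With more than two observed bases
    the two largest groups are compared.  Equal-variance two-sided t-test
    by default; set equal_var=False for Welch.
    """
    groups: dict[str, list[float]] = {}
    for length, base in pairs:
        if base is not None:
            groups.setdefault(base, []).append(float(length))
    if len(groups) < 2:
        return AssociationResult(tested=False, reason="fewer than two SNP base groups")
    top = sorted(groups, key=lambda b: (-len(groups[b]), b))[:2]
    g1, g2 = groups[top[0]], groups[top[1]]
    if min(len(g1), len(g2)) < 2:
        return AssociationResult(
            tested=False,
            bases=tuple(top),
            sizes=(len(g1), len(g2)),
            reason="a base group has fewer than 2 alleles",
        )
    with warnings.catch_warnings():
        # near-constant groups trip scipy's precision warning; the t=0/p=1
        # fallback below handles the fully degenerate case
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_ind(g1, g2, equal_var=equal_var)
    m1, m2 = float(np.mean(g1)), float(np.mean(g2))
    if np.isnan(p):  # zero variance in both groups with equal means
        t, p = 0.0, 1.0
    p = max(float(p), 5e-324)  # perfect separation: keep p in (0, 1]
    direction = top[0] if m1 >= m2 else top[1]
    return AssociationResult(
        tested=True,
        bases=tuple(top),
        sizes=(len(g1), len(g2)),
        means=(m1, m2),
        t=float(t),
        p=float(p),
        direction=direction,
    )


def allele_length_pairs(
    genotypes: Iterable[PhasedGenotype], locus: RepeatLocus
) -> list[tuple[float, str | None]]:
    """Allele-level (length bp, snp base) pairs for association testing."""
    pairs = []
    for g in genotypes:
        if g is None:
            continue
        for allele in g.alleles:
            length = locus.ref_span + locus.unit_len * allele.allele_delta
            pairs.append((length, allele.snp_base))
    return pairs
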