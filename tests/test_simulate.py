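"""Simulator correctness: determinism, alignment validity, truth recovery."""

import numpy as np
import pytest

from trpoly.genotyping import estimate_copy_change, genotype_sample
from trpoly.phasing import phase_locus
from trpoly.simulate import (
    LocusSpec,
    ReadModel,
    SimConfig,
    SimConfigError,
    SnpSpec,
    simulate,
    simulate_population,
    simulate_reference,
)
from trpoly.units import reverse_complement

from conftest import alignments_by_sample


def small_config(**kwargs):
    defaults = dict(
        loci=(LocusSpec(unit="CAG", copies=10, region="coding",
                        delta_dist={0: 0.5, 10: 0.5}),),
        genome_length=8000,
        n_individuals=4,
        snp=SnpSpec(offset=-150, ld="complete"),
        read_model=ReadModel(coverage=10, read_length_mean=2000,
                             read_length_sd=100),
    )
    defaults.update(kwargs)
    return SimConfig(**defaults)


class TestReference:
    def test_locus_annotation_matches_spec(self):
        ref = simulate_reference(small_config(), seed=3)
        (locus,) = ref.loci
        assert locus.ref_span == 30 and locus.unit == "CAG"
        assert ref.seq[locus.start:locus.end] == "CAG" * 10
        assert locus.region == "coding" and locus.gene == "GENE1"

    def test_same_seed_identical_sequence(self):
        a = simulate_reference(small_config(), seed=5)
        b = simulate_reference(small_config(), seed=5)
        assert a.seq == b.seq
        assert a.fasta_text() == b.fasta_text()

    def test_flanks_have_no_tandem_structure(self):
        from trpoly.catalog import find_tandem_repeats

        ref = simulate_reference(small_config(), seed=3)
        found = find_tandem_repeats(ref.seq, min_unit=1, max_unit=3, min_copies=3)
        assert [(l.start, l.end) for l in found] == \
               [(l.start, l.end) for l in ref.loci]

    def test_overlapping_loci_rejected(self):
        cfg = small_config(loci=(
            LocusSpec(unit="CAG", copies=10, start=1000),
            LocusSpec(unit="GGC", copies=10, start=1010),
        ))
        with pytest.raises(SimConfigError, match="overlap"):
            simulate_reference(cfg, seed=0)

    def test_snp_outside_loci_with_ref_alt(self):
        ref = simulate_reference(small_config(), seed=3)
        snp = ref.snp
        assert ref.seq[snp.pos] == snp.ref and snp.alt != snp.ref
        (locus,) = ref.loci
        assert not (locus.start <= snp.pos < locus.end)

    def test_region_placement_via_refflat(self):
        for region in ("utr5", "utr3", "intron", "noncoding_exon"):
            cfg = small_config(loci=(LocusSpec(
                unit="CAG", copies=10, region=region,
                delta_dist={0: 1.0}),), snp=None)
            ref = simulate_reference(cfg, seed=1)
            assert ref.loci[0].region == region, region


class TestPopulation:
    def test_degenerate_distribution(self):
        cfg = small_config(loci=(LocusSpec(unit="CAG", copies=10,
                                           delta_dist={0: 1.0}),), snp=None)
        truth = simulate_population(cfg, seed=2)
        for ind in truth.individuals:
            assert (ind.hap_deltas == 0).all()

    def test_allele_frequency_binomial_bound(self):
        cfg = small_config(n_individuals=1000, snp=None)
        truth = simulate_population(cfg, seed=8)
        deltas = np.concatenate([ind.hap_deltas[:, 0] for ind in truth.individuals])
        freq10 = (deltas == 10).mean()
        assert abs(freq10 - 0.5) < 0.05

    def test_complete_ld_links_alt_to_long_allele(self):
        truth = simulate_population(small_config(n_individuals=50), seed=4)
        for ind in truth.individuals:
            for h in (0, 1):
                expected = "alt" if ind.hap_deltas[h, 0] > 0 else "ref"
                assert ind.hap_snp_bases[h] == expected

    def test_r2_mode_correlates_partially(self):
        cfg = small_config(n_individuals=2000,
                           snp=SnpSpec(offset=-150, ld=0.49))
        truth = simulate_population(cfg, seed=6)
        longs, alts = [], []
        for ind in truth.individuals:
            for h in (0, 1):
                longs.append(int(ind.hap_deltas[h, 0] > 0))
                alts.append(int(ind.hap_snp_bases[h] == "alt"))
        r = np.corrcoef(longs, alts)[0, 1]
        assert 0.55 < r < 0.85  # target sqrt(0.49) = 0.7

    def test_invalid_probability_table(self):
        with pytest.raises(SimConfigError):
            simulate_population(small_config(loci=(
                LocusSpec(unit="CAG", copies=10, delta_dist={0: 0.6, 1: 0.6}),
            )), seed=0)


def reconstruct_from_maf_block(block):
    lines = [l for l in block.strip().split("\n") if l.startswith("s")]
    ref_f, read_f = lines
    read_fields = read_f.split()
    text = read_fields[6]
    strand = read_fields[4]
    seq = text.replace("-", "")
    return seq if strand == "+" else reverse_complement(seq)


class TestReads:
    def test_maf_revalidates_against_emitted_reads(self, sim_noisy):
        for read in sim_noisy.reads.reads:
            assert reconstruct_from_maf_block(read.maf_block) == read.sequence

    def test_noise_free_reads_have_single_gap_run(self, sim_noise_free):
        (locus,) = sim_noise_free.reference.loci
        truth = {i.sample: i for i in sim_noise_free.truth.individuals}
        for read in sim_noise_free.reads.reads[:200]:
            delta = int(truth[read.sample].hap_deltas[read.haplotype, 0])
            block = read.maf_block
            ref_text = block.split("\n")[1].split()[6]
            if delta > 0 and read.ref_start < locus.start and \
                    read.ref_end > locus.end:
                assert ref_text.count("-") == 3 * delta  # one insertion run
                assert "-" * (3 * delta) in ref_text

    def test_coverage_within_poisson_bound(self, sim_noise_free):
        total = sum(len(r.sequence) for r in sim_noise_free.reads.reads)
        genome = len(sim_noise_free.reference.seq)
        expected = 27 * genome * 21
        assert abs(total - expected) / expected < 0.2

    def test_full_chain_seed_determinism(self):
        a = simulate(small_config(), seed=13)
        b = simulate(small_config(), seed=13)
        assert a.reference.seq == b.reference.seq
        assert a.reads.maf_text() == b.reads.maf_text()
        assert a.truth.to_frame().equals(b.truth.to_frame())

    def test_write_outputs_round_trip(self, tmp_path):
        sim = simulate(small_config(), seed=13)
        paths = sim.write_outputs(tmp_path / "out")
        from trpoly.catalog import read_repeat_annotation
        from trpoly.maf import read_maf

        loci = read_repeat_annotation(paths["repeats_bed"], "bed4")
        assert [l.key for l in loci] == [l.key for l in sim.reference.loci]
        alns = read_maf(paths["alignments_maf"])
        assert len(alns) == len(sim.reads.reads)


class TestTruthRecovery:
    def test_noise_free_per_read_deltas_exact(self, sim_noise_free,
                                              sim_noise_free_alignments):
        (locus,) = sim_noise_free.reference.loci
        truth = {i.sample: i for i in sim_noise_free.truth.individuals}
        by_read = {r.read_id: r for r in sim_noise_free.reads.reads}
        n = 0
        for aln in sim_noise_free_alignments:
            obs = estimate_copy_change(aln, locus)
            if obs is None:
                continue
            r = by_read[aln.read_id]
            assert obs.delta_units == int(truth[r.sample].hap_deltas[r.haplotype, 0])
            n += 1
        assert n > 200  # plenty of spanning reads at 27x

    def test_noise_free_allele_recovery_exact(self, sim_noise_free,
                                              sim_noise_free_alignments):
        (locus,) = sim_noise_free.reference.loci
        per_sample = alignments_by_sample(sim_noise_free, sim_noise_free_alignments)
        for ind in sim_noise_free.truth.individuals:
            rows = genotype_sample(
                sorted(per_sample[ind.sample], key=lambda a: a.ref_start),
                [locus])
            geno = None
            from trpoly.phasing import split_alleles
            geno = split_alleles(rows[0].deltas)
            est = tuple(sorted((geno.allele1.allele_delta,
                                geno.allele2.allele_delta)))
            assert est == tuple(float(x) for x in ind.allele_deltas(0))

    def test_noisy_allele_recovery_within_one_unit(self, sim_noisy,
                                                   sim_noisy_alignments):
        (locus,) = sim_noisy.reference.loci
        per_sample = alignments_by_sample(sim_noisy, sim_noisy_alignments)
        ok = 0
        inds = sim_noisy.truth.individuals
        for ind in inds:
            from trpoly.phasing import split_alleles

            deltas = []
            for aln in per_sample[ind.sample]:
                obs = estimate_copy_change(aln, locus)
                if obs is not None:
                    deltas.append(obs.delta_units)
            geno = split_alleles(deltas)
            if geno is None:
                continue
            est = sorted((geno.allele1.allele_delta, geno.allele2.allele_delta))
            true = ind.allele_deltas(0)
            if all(abs(e - t) <= 1 for e, t in zip(est, true)):
                ok += 1
        assert ok / len(inds) >= 0.90

    def test_noisy_phasing_recovers_haplotype_bases(self, sim_noisy,
                                                    sim_noisy_alignments):
        (locus,) = sim_noisy.reference.loci
        snp = sim_noisy.reference.snp
        per_sample = alignments_by_sample(sim_noisy, sim_noisy_alignments)
        ok, tot = 0, 0
        for ind in sim_noisy.truth.individuals:
            g = phase_locus(per_sample[ind.sample], locus, snp.pos)
            if g is None or g.allele1.snp_base is None or g.allele2.snp_base is None:
                continue
            tot += 1
            hd = ind.hap_deltas[:, 0]
            short_h = int(np.argmin(hd))
            short_base = snp.alt if ind.hap_snp_bases[short_h] == "alt" else snp.ref
            long_base = snp.alt if ind.hap_snp_bases[1 - short_h] == "alt" else snp.ref
            a1, a2 = sorted(g.alleles, key=lambda a: a.allele_delta)
            if g.homozygous or (a1.snp_base, a2.snp_base) == (short_base, long_base):
                ok += 1
        assert tot >= 15               # most individuals phase at 25x
        assert ok / tot >= 0.95
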