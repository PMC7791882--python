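"""Shared fixtures: small seeded simulations and their parsed alignments."""

from __future__ import annotations

import pytest

from trpoly import read_maf
from trpoly.simulate import LocusSpec, ReadModel, SimConfig, SnpSpec, simulate


def _parse(sim, tmp_factory, name):
    path = tmp_factory.mktemp(name) / "alignments.maf"
    path.write_text(sim.reads.maf_text())
    return read_maf(path)


@pytest.fixture(scope="session")
def sim_noise_free():
    """21 diploids, one polymorphic CAG repeat, linked SNP, no errors."""
    return simulate(SimConfig.default(), seed=7)


@pytest.fixture(scope="session")
def sim_noise_free_alignments(sim_noise_free, tmp_path_factory):
    return _parse(sim_noise_free, tmp_path_factory, "nf")


@pytest.fixture(scope="session")
def sim_noisy():
    """Same cohort at 25x with 2% substitution / 2% insertion / 2% deletion."""
    config = SimConfig(
        loci=(
            LocusSpec(unit="CAG", copies=10, region="coding",
                      delta_dist={0: 0.5, 10: 0.5}),
        ),
        snp=SnpSpec(offset=-200, ld="complete"),
        read_model=ReadModel(coverage=25, substitution_rate=0.02,
                             insertion_rate=0.02, deletion_rate=0.02),
    )
    return simulate(config, seed=11)


@pytest.fixture(scope="session")
def sim_noisy_alignments(sim_noisy, tmp_path_factory):
    return _parse(sim_noisy, tmp_path_factory, "noisy")


def alignments_by_sample(sim, alignments):
    by_read = {r.read_id: r for r in sim.reads.reads}
    out: dict[str, list] = {}
    for aln in alignments:
        out.setdefault(by_read[aln.read_id].sample, []).append(aln)
    return out
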