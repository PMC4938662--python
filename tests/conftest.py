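"""Shared fixtures: simulated genome pairs at two problem sizes.

``small_sim`` keeps unit tests fast; ``study_sim`` is the full-size pair
(2 chromosomes x 2 Mb, 400 shared complete + 100 truncated + 30+30
genome-specific elements) used by the recovery tests.  Both are
session-scoped: simulation and annotation are deterministic, so sharing
them across tests loses nothing.
"""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from cactakit.discovery import annotate
from cactakit.polymorphism import call_polymorphisms
from cactakit.seqcore import KmerIndex
from cactakit.simulate import SimulationConfig, simulate_pair

SMALL_CFG = SimulationConfig(
    seed=11,
    n_chromosomes=2,
    chrom_length=400_000,
    elements_per_subfamily=25,
    n_truncated=20,
    n_polymorphic_a=8,
    n_polymorphic_b=8,
)

STUDY_CFG = SimulationConfig(seed=101)  # simulator defaults = study conditions


@pytest.fixture(scope="session")
def small_sim():
    return simulate_pair(SMALL_CFG)


@pytest.fixture(scope="session")
def small_ann(small_sim):
    return {
        "A": annotate(small_sim.genome_a, small_sim.library, genome_id="A"),
        "B": annotate(small_sim.genome_b, small_sim.library, genome_id="B"),
    }


@pytest.fixture(scope="session")
def small_calls(small_sim, small_ann):
    out = {}
    genomes = {"A": small_sim.genome_a, "B": small_sim.genome_b}
    idx = {g: {c: KmerIndex(s) for c, s in genomes[g].items()} for g in genomes}
    fam = {g: [(e.chrom, e.start, e.end) for e in small_ann[g].elements] for g in genomes}
    for src, tgt in (("A", "B"), ("B", "A")):
        complete = [e for e in small_ann[src].elements if e.complete]
        out[src] = call_polymorphisms(
            complete, genomes[src], genomes[tgt], fam[tgt], indexes=idx[tgt]
        )
    return out


@pytest.fixture(scope="session")
def study_sim():
    return simulate_pair(STUDY_CFG)


@pytest.fixture(scope="session")
def study_ann(study_sim):
    return {
        "A": annotate(study_sim.genome_a, study_sim.library, genome_id="A"),
        "B": annotate(study_sim.genome_b, study_sim.library, genome_id="B"),
    }


@pytest.fixture(scope="session")
def study_calls(study_sim, study_ann):
    genomes = {"A": study_sim.genome_a, "B": study_sim.genome_b}
    idx = {g: {c: KmerIndex(s) for c, s in genomes[g].items()} for g in genomes}
    fam = {g: [(e.chrom, e.start, e.end) for e in study_ann[g].elements] for g in genomes}
    out = {}
    for src, tgt in (("A", "B"), ("B", "A")):
        complete = [e for e in study_ann[src].elements if e.complete]
        out[src] = call_polymorphisms(
            complete, genomes[src], genomes[tgt], fam[tgt], indexes=idx[tgt]
        )
    return out


def truth_by_coord(sim, genome: str) -> dict:
    sub = sim.truth[sim.truth.genome == genome]
    return {(r.chrom, r.start, r.end): r for r in sub.itertuples()}
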