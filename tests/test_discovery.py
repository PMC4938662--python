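"""Structural and homology element discovery against simulator ground truth."""

import numpy as np
import pytest

from cactakit.discovery import (
    DiscoveryConfig,
    ValidationFailure,
    annotate,
    mask_with_library,
    scan_termini,
    validate_element,
)
from cactakit.seqcore import reverse_complement
from cactakit.simulate import (
    SimulationConfig,
    build_element,
    mutate_sequence,
    plant_element,
    random_genome,
)

from conftest import truth_by_coord


def _random_chrom(seed, n=20_000, gc=0.35):
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture
def planted():
    rng = np.random.default_rng(42)
    chrom = _random_chrom(7)
    el = build_element(rng, 400, 150)
    genome = {"chr1": plant_element(chrom, el, 9000)}
    return genome, el, 9003, 9403  # element interval after TSD duplication


class TestScanTermini:
    def test_planted_interval_among_candidates(self, planted):
        genome, _, s, e = planted
        assert ("chr1", s, e) in scan_termini(genome)

    def test_poly_a_genome_empty(self):
        assert scan_termini({"chr1": "A" * 5000}) == []

    def test_minus_strand_element_found(self):
        # a reverse-complemented element still reads CACTA...TAGTG on the
        # plus strand (the motifs are a revcomp pair), so the scan sees it
        rng = np.random.default_rng(1)
        chrom = _random_chrom(8)
        el = reverse_complement(build_element(rng, 380, 150))
        genome = {"chr1": plant_element(chrom, el, 5000)}
        assert ("chr1", 5003, 5383) in scan_termini(genome)


class TestValidateElement:
    def test_planted_perfect_element_complete_with_tsd(self, planted):
        genome, el, s, e = planted
        got = validate_element(genome, "chr1", s, e)
        assert got.complete and got.tsd == genome["chr1"][s - 3 : s]
        assert got.tir_length >= 145

    def test_mutated_left_tsd_rejected(self, planted):
        genome, _, s, e = planted
        seq = genome["chr1"]
        bad = {"chr1": seq[: s - 3] + _flip(seq[s - 3]) + seq[s - 2 :]}
        with pytest.raises(ValidationFailure, match="tsd"):
            validate_element(bad, "chr1", s, e)

    def test_random_tir_rejected(self):
        # CACTA...TAGTG termini but random interior: TIR identity ~0.25
        rng = np.random.default_rng(3)
        core = "".join(rng.choice(list("ACGT"), 390))
        chrom = _random_chrom(9, 5000)
        el = "CACTA" + core + "TAGTG"
        genome = {"chr1": plant_element(chrom, el, 2000)}
        with pytest.raises(ValidationFailure, match="tir"):
            validate_element(genome, "chr1", 2003, 2003 + len(el))

    def test_contig_edge_rejected(self):
        rng = np.random.default_rng(4)
        el = build_element(rng, 350, 145)
        genome = {"chr1": el + _random_chrom(10, 2000)}
        with pytest.raises(ValidationFailure, match="edge"):
            validate_element(genome, "chr1", 0, 350)


def _flip(base):
    return {"A": "C", "C": "A", "G": "T", "T": "G"}[base]


class TestMaskWithLibrary:
    def test_twenty_diverged_copies_all_hit(self):
        rng = np.random.default_rng(5)
        ancestor = build_element(rng, 400, 150)
        chrom = _random_chrom(11, 60_000)
        sites = range(2000, 58_000, 2800)
        for site in sites:
            copy = mutate_sequence(ancestor, 0.08, rng)
            chrom = plant_element(chrom, copy, site)  # sites shift, spacing stays
        hits = mask_with_library({"chr1": chrom}, {"anc": ancestor})
        assert len(hits) == len(range(2000, 58_000, 2800))

    def test_short_fragment_filtered_by_length(self):
        rng = np.random.default_rng(6)
        ancestor = build_element(rng, 400, 150)
        genome = {"chr1": plant_element(_random_chrom(12, 8000), ancestor[:40], 4000)}
        assert mask_with_library(genome, {"anc": ancestor}) == []

    def test_plain_genome_no_hits(self):
        rng = np.random.default_rng(13)
        ancestor = build_element(rng, 400, 150)
        assert mask_with_library({"chr1": _random_chrom(14, 30_000)}, {"anc": ancestor}) == []

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            mask_with_library({"chr1": "ACGT" * 100}, {})


class TestAnnotate:
    def test_complete_recall_exact_boundaries(self, small_sim, small_ann):
        truth = truth_by_coord(small_sim, "A")
        complete_truth = {k for k, r in truth.items() if r.complete}
        found = {(e.chrom, e.start, e.end) for e in small_ann["A"].elements if e.complete}
        recall = len(found & complete_truth) / len(complete_truth)
        assert recall >= 0.98

    def test_tsds_recovered_verbatim(self, small_sim, small_ann):
        truth = truth_by_coord(small_sim, "A")
        for el in small_ann["A"].elements:
            if el.complete and (el.chrom, el.start, el.end) in truth:
                assert el.tsd == truth[(el.chrom, el.start, el.end)].tsd

    def test_truncated_recall(self, small_sim, small_ann):
        trunc = [r for r in truth_by_coord(small_sim, "A").values() if not r.complete]
        els = small_ann["A"].elements
        n_found = sum(
            any(
                e.chrom == r.chrom
                and min(e.end, r.end) - max(e.start, r.start)
                >= 0.5 * min(e.end - e.start, r.end - r.start)
                for e in els
            )
            for r in trunc
        )
        assert n_found / len(trunc) >= 0.90

    def test_no_false_positives_on_simulated_genome(self, small_sim, small_ann):
        truth = list(truth_by_coord(small_sim, "A").values())
        for e in small_ann["A"].elements:
            assert any(
                e.chrom == r.chrom
                and min(e.end, r.end) - max(e.start, r.start)
                >= 0.5 * min(e.end - e.start, r.end - r.start)
                for r in truth
            ), f"unexpected call {e.element_id}"

    def test_strand_resolved_by_library(self, small_sim, small_ann):
        truth = truth_by_coord(small_sim, "A")
        checked = 0
        for e in small_ann["A"].elements:
            r = truth.get((e.chrom, e.start, e.end))
            if r is not None and e.complete and e.strand in "+-":
                assert e.strand == r.strand
                checked += 1
        assert checked > 50

    def test_masked_fraction_conservation(self, small_ann):
        res = small_ann["A"]
        assert res.summary["masked_bp"] == sum(e.length for e in res.elements)

    def test_deterministic(self, small_sim, small_ann):
        again = annotate(small_sim.genome_a, small_sim.library, genome_id="A")
        a = [(e.chrom, e.start, e.end, e.strand, e.complete) for e in again.elements]
        b = [(e.chrom, e.start, e.end, e.strand, e.complete) for e in small_ann["A"].elements]
        assert a == b

    def test_structural_only_close_to_full_annotation(self, small_sim, small_ann):
        bare = annotate(small_sim.genome_a, library=None, genome_id="A")
        with_lib = [e for e in small_ann["A"].elements if e.complete]
        assert abs(bare.summary["n_complete"] - len(with_lib)) <= 0.05 * len(with_lib)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_decoy_genome_precision(self, seed):
        cfg = SimulationConfig(seed=seed, n_chromosomes=1, chrom_length=300_000)
        genome = random_genome(cfg)
        rng = np.random.default_rng(99)
        library = {"anc": build_element(rng, 400, 150)}
        res = annotate(genome, library, genome_id="decoy")
        assert res.summary["n_total"] == 0
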