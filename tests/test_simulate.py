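"""Simulator ground-truth guarantees: TSD mechanics, divergence calibration,
reproducibility, and conservation of planted-element counts."""

import numpy as np
import pandas as pd
import pytest

from cactakit.seqcore import kimura2p, reverse_complement
from cactakit.simulate import (
    SimulationConfig,
    build_element,
    mutate_sequence,
    plant_element,
    random_genome,
    simulate_pair,
)

from conftest import SMALL_CFG, truth_by_coord


class TestPlantElement:
    def test_length_arithmetic(self):
        rng = np.random.default_rng(0)
        chrom = "".join(rng.choice(list("ACGT"), 10_000))
        el = build_element(rng, 400, 150)
        assert len(plant_element(chrom, el, 5000)) == 10_403

    def test_tsd_duplicated_on_both_sides(self):
        rng = np.random.default_rng(1)
        chrom = "".join(rng.choice(list("ACGT"), 2_000))
        el = build_element(rng, 350, 145)
        site = 800
        tsd = chrom[site : site + 3]
        new = plant_element(chrom, el, site)
        assert new[site : site + 3] == tsd
        assert new[site + 3 + 350 : site + 6 + 350] == tsd

    def test_roundtrip_extraction(self):
        rng = np.random.default_rng(2)
        chrom = "".join(rng.choice(list("ACGT"), 2_000))
        el = build_element(rng, 400, 150)
        new = plant_element(chrom, el, 1000)
        assert new[1003 : 1403] == el

    def test_site_out_of_range(self):
        with pytest.raises(ValueError):
            plant_element("ACGTACGT", "CACTATAGTG", 1)


class TestElementStructure:
    def test_termini_and_perfect_tir(self):
        rng = np.random.default_rng(3)
        el = build_element(rng, 446, 158)
        assert el.startswith("CACTA") and el.endswith("TAGTG")
        assert el[:158] == reverse_complement(el[-158:])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            build_element(np.random.default_rng(0), 300, 150)


class TestSimulatePair:
    def test_zero_rate_zero_specific_identical_genomes(self):
        cfg = SimulationConfig(
            seed=5, chrom_length=120_000, elements_per_subfamily=5, n_truncated=2,
            n_polymorphic_a=0, n_polymorphic_b=0, substitution_rate=0.0,
            n_genes=2, n_genic_intron=1, n_genic_exon=0, n_genic_polymorphic=0,
        )
        sim = simulate_pair(cfg)
        assert sim.genome_a == sim.genome_b

    def test_truth_row_conservation(self, small_sim):
        cfg = SMALL_CFG
        n_shared = cfg.n_subfamilies * cfg.elements_per_subfamily
        for g, n_spec in (("A", cfg.n_polymorphic_a), ("B", cfg.n_polymorphic_b)):
            sub = small_sim.truth[small_sim.truth.genome == g]
            assert len(sub) == n_shared + cfg.n_truncated + n_spec

    def test_truth_coordinates_recover_planted_structure(self, small_sim):
        genomes = {"A": small_sim.genome_a, "B": small_sim.genome_b}
        complete = small_sim.truth[small_sim.truth.complete]
        for r in complete.itertuples():
            seq = genomes[r.genome][r.chrom][r.start : r.end]
            assert seq.startswith("CACTA") and seq.endswith("TAGTG")
            g = genomes[r.genome][r.chrom]
            assert g[r.start - 3 : r.start] == r.tsd == g[r.end : r.end + 3]

    def test_fixed_seed_reproducible(self):
        cfg = SimulationConfig(
            seed=9, chrom_length=100_000, elements_per_subfamily=4, n_truncated=2,
            n_polymorphic_a=2, n_polymorphic_b=2, n_genes=2, n_genic_intron=1,
            n_genic_exon=0, n_genic_polymorphic=0,
        )
        s1, s2 = simulate_pair(cfg), simulate_pair(cfg)
        assert s1.genome_a == s2.genome_a and s1.genome_b == s2.genome_b
        pd.testing.assert_frame_equal(s1.truth, s2.truth)

    def test_tsd_w_fraction_matches_configured_bias(self, small_sim):
        tsds = small_sim.truth.loc[small_sim.truth.complete & (small_sim.truth.genome == "A"), "tsd"]
        ws = sum(c in "AT" for t in tsds for c in t)
        n = 3 * len(tsds)
        f = ws / n
        se = np.sqrt(0.85 * 0.15 / n)
        assert abs(f - SMALL_CFG.tsd_at_bias) < 3 * se

    def test_orthologous_divergence_near_2rT(self, small_sim):
        cfg = SMALL_CFG
        sh = small_sim.truth[small_sim.truth.shared & small_sim.truth.complete]
        genomes = {"A": small_sim.genome_a, "B": small_sim.genome_b}
        ks = []
        for _, grp in list(sh.groupby("ortholog_id"))[:80]:
            assert len(grp) == 2
            seqs = {}
            for r in grp.itertuples():
                s = genomes[r.genome][r.chrom][r.start : r.end]
                seqs[r.genome] = reverse_complement(s) if r.strand == "-" else s
            ks.append(kimura2p(seqs["A"], seqs["B"]).k)
        expected = 2 * cfg.substitution_rate * cfg.split_time
        mean, se = np.mean(ks), np.std(ks, ddof=1) / np.sqrt(len(ks))
        # terminal motifs are substitution-protected, which biases k down a
        # few percent; the 3-SE band must still cover 2rT
        assert abs(mean - expected) < 3 * se + 0.06 * expected

    def test_infeasible_packing_raises(self):
        cfg = SimulationConfig(
            seed=1, chrom_length=60_000, elements_per_subfamily=100, n_truncated=0,
            n_polymorphic_a=0, n_polymorphic_b=0, n_genes=1, n_genic_intron=1,
            n_genic_exon=0, n_genic_polymorphic=0,
        )
        with pytest.raises(RuntimeError, match="too many elements"):
            simulate_pair(cfg)

    def test_genic_truth_recorded(self, small_sim):
        genic = small_sim.truth[small_sim.truth.gene_id != ""]
        assert len(genic) > 0
        assert set(genic.gene_feature) <= {"intron", "exon"}
        assert (genic.gene_ordinal >= 1).all()


class TestMutationProcess:
    def test_rate_zero_identity(self):
        assert mutate_sequence("ACGTACGT", 0.0, np.random.default_rng(0)) == "ACGTACGT"

    def test_transition_bias(self):
        rng = np.random.default_rng(11)
        seq = "A" * 30_000
        mut = mutate_sequence(seq, 0.5, rng, ts_tv_ratio=2.0)
        changed = [c for c in mut if c != "A"]
        ts = sum(c == "G" for c in changed)
        # transitions should be ~2/3 of events
        assert abs(ts / len(changed) - 2 / 3) < 0.03

    def test_n_preserved(self):
        assert mutate_sequence("NNNN", 1.0, np.random.default_rng(0)) == "NNNN"


class TestRandomGenome:
    def test_gc_near_target(self):
        cfg = SimulationConfig(seed=3, chrom_length=200_000)
        g = random_genome(cfg)
        seq = "".join(g.values())
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - cfg.background_gc) < 0.01
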