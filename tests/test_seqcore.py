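"""Alignment, identity and K2P distance primitives against independent
oracles and closed-form values."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cactakit.seqcore import (
    SaturationError,
    align_global,
    align_local,
    gc_fraction,
    kimura2p,
    kimura2p_from_alignment,
    reverse_complement,
)
from cactakit.simulate import mutate_sequence

from oracles import gotoh_global_score, k2p_by_hand

dna = st.text(alphabet="ACGTN", min_size=0, max_size=60)


class TestReverseComplement:
    def test_cacta_maps_to_tagtg(self):
        # the CACTA-superfamily terminal motif pair is a revcomp pair
        assert reverse_complement("CACTA") == "TAGTG"

    def test_empty(self):
        assert reverse_complement("") == ""

    @settings(deadline=None, max_examples=50)
    @given(dna)
    def test_involution(self, s):
        assert reverse_complement(reverse_complement(s)) == s

    def test_rejects_non_dna_with_position(self):
        with pytest.raises(ValueError, match="position 2"):
            reverse_complement("ACXGT")


class TestGCFraction:
    @pytest.mark.parametrize(
        "seq,expected", [("GGCC", 1.0), ("AATT", 0.0), ("ACGTACGT", 0.5), ("ACGN", 2 / 3)]
    )
    def test_values(self, seq, expected):
        assert gc_fraction(seq) == pytest.approx(expected)

    def test_all_n_rejected(self):
        with pytest.raises(ValueError):
            gc_fraction("NNN")


class TestAlignGlobal:
    def test_identical(self):
        aln = align_global("ACGT", "ACGT")
        assert aln.identity == 1.0 and aln.matches == 4

    def test_single_mismatch(self):
        assert align_global("ACGT", "ACGA").identity == 0.75

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            align_global("", "ACGT")

    def test_score_matches_exhaustive_dp_oracle(self):
        rng = np.random.default_rng(42)
        pairs = [("ACACACTT", "ACACTT"), ("ACGT", "TGCA"), ("AAAA", "AAAAAAA")]
        for _ in range(40):
            n, m = rng.integers(1, 9, size=2)
            a = "".join(rng.choice(list("ACGT"), n))
            b = "".join(rng.choice(list("ACGT"), m))
            pairs.append((a, b))
        for a, b in pairs:
            assert align_global(a, b).score == pytest.approx(
                gotoh_global_score(a, b)
            ), f"score mismatch for {a} vs {b}"

    def test_repeat_contraction_case(self):
        # the alignment the package returns must itself be optimal
        aln = align_global("ACACACTT", "ACACTT")
        assert aln.score == gotoh_global_score("ACACACTT", "ACACTT")
        assert aln.aligned_a.replace("-", "") == "ACACACTT"
        assert aln.aligned_b.replace("-", "") == "ACACTT"


class TestAlignLocal:
    def _random_seq(self, rng, n, gc=0.5):
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        return "".join(rng.choice(list("ACGT"), size=n, p=p))

    def test_planted_query_found_exactly(self):
        rng = np.random.default_rng(0)
        query = self._random_seq(rng, 80)
        target = self._random_seq(rng, 5000)
        planted = target[:2000] + query + target[2000:]
        hits = align_local(query, planted, min_score=50)
        assert hits and hits[0].t_start == 2000 and hits[0].t_end == 2080
        assert hits[0].identity == 1.0 and hits[0].strand == "+"

    def test_absent_query_no_hit(self):
        rng = np.random.default_rng(1)
        query = self._random_seq(rng, 80, gc=0.5)
        target = self._random_seq(rng, 20000, gc=0.25)
        assert align_local(query, target, min_score=50) == []

    def test_query_equals_target(self):
        rng = np.random.default_rng(2)
        q = self._random_seq(rng, 200)
        hits = align_local(q, q, min_score=50)
        assert hits[0].t_start == 0 and hits[0].t_end == 200
        assert hits[0].score == pytest.approx(400.0)

    def test_minus_strand_hit(self):
        rng = np.random.default_rng(3)
        query = self._random_seq(rng, 80)
        target = self._random_seq(rng, 3000) + reverse_complement(query) + self._random_seq(rng, 1000)
        hits = align_local(query, target, min_score=50)
        assert hits[0].strand == "-" and hits[0].t_start == 3000


class TestKimura2P:
    def test_identical_is_zero(self):
        d = kimura2p("ACGTACGTAC", "ACGTACGTAC")
        assert d.k == 0.0 and d.p == 0.0 and d.q == 0.0

    def test_hand_computed_single_transition(self):
        # 10 sites, 1 transition (A->G), 0 transversions: K = -1/2 ln(0.8)
        a, b = "AACCGGTTAC", "GACCGGTTAC"
        d = kimura2p_from_alignment(a, b)
        assert d.k == pytest.approx(-0.5 * math.log(0.8), rel=1e-12)
        assert d.k == pytest.approx(0.1116, abs=5e-5)
        assert d.k == pytest.approx(k2p_by_hand(a, b), rel=1e-12)

    @settings(deadline=None, max_examples=30)
    @given(st.text(alphabet="ACGT", min_size=5, max_size=40))
    def test_symmetric(self, a):
        rng = np.random.default_rng(len(a))
        b = mutate_sequence(a, 0.2, rng)
        assert kimura2p(a, b).k == pytest.approx(kimura2p(b, a).k)

    def test_exceeds_observed_difference_at_small_distance(self):
        # first-order: k >= P + Q, within 10% at P+Q <= 0.05
        rng = np.random.default_rng(7)
        a = "".join(rng.choice(list("ACGT"), 2000))
        b = mutate_sequence(a, 0.03, rng)
        d = kimura2p_from_alignment(a, b)
        obs = d.p + d.q
        assert d.k >= obs
        assert d.k == pytest.approx(obs, rel=0.10)

    def test_saturation_flagged_not_nan_silent(self):
        d = kimura2p_from_alignment("AAAA", "GGGG")  # P=1 -> 1-2P-Q < 0
        assert d.saturated and math.isnan(d.k)

    def test_no_comparable_sites_raises(self):
        with pytest.raises(SaturationError):
            kimura2p_from_alignment("NNN", "ACG")

    def test_gap_and_n_columns_excluded(self):
        d = kimura2p_from_alignment("AC-GTN", "ACAGTA")
        assert d.sites_compared == 4

    def test_mutation_rate_recovery(self):
        # sequences mutated at per-site probability mu*t recover k ~ 2*mu*t
        # when both lineages diverge from a common ancestor
        rng = np.random.default_rng(123)
        mu_t = 0.02
        ks = []
        for _ in range(200):
            anc = "".join(rng.choice(list("ACGT"), 400))
            a = mutate_sequence(anc, mu_t, rng)
            b = mutate_sequence(anc, mu_t, rng)
            ks.append(kimura2p_from_alignment(a, b).k)
        mean = np.mean(ks)
        se = np.std(ks, ddof=1) / np.sqrt(len(ks))
        assert abs(mean - 2 * mu_t) < 3 * se
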