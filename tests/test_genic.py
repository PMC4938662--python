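"""Element classification against gene models (GFF3)."""

import pytest

from cactakit.discovery import TEElement
from cactakit.genic import classify_elements, genic_summary, load_transcripts

from conftest import truth_by_coord


def _el(chrom, start, end, genome="G", complete=True):
    return TEElement(
        genome=genome, chrom=chrom, start=start, end=end, strand="+", tir_length=150,
        tsd="AAT" if complete else None, complete=complete, family="CACTA1",
    )


def _gene_features(strand="+"):
    """A 3-exon gene on [1000, 4000): exons 1000-1400, 2400-2800, 3600-4000,
    with 60 bp 5'UTR and 80 bp 3'UTR at the transcript ends."""
    feats = [
        dict(chrom="chr1", type="gene", start=1000, end=4000, strand=strand, attributes={"ID": "g1"}),
        dict(chrom="chr1", type="mRNA", start=1000, end=4000, strand=strand,
             attributes={"ID": "g1.1", "Parent": "g1"}),
    ]
    exons = [(1000, 1400), (2400, 2800), (3600, 4000)]
    for i, (s, e) in enumerate(exons):
        feats.append(dict(chrom="chr1", type="exon", start=s, end=e, strand=strand,
                          attributes={"ID": f"g1.1.e{i}", "Parent": "g1.1"}))
    if strand == "+":
        utr5, utr3 = (1000, 1060), (3920, 4000)
    else:
        utr5, utr3 = (3940, 4000), (1000, 1080)
    for s, e in exons:
        cs, ce = s, e
        if utr5[0] >= s and utr5[1] <= e:
            cs, ce = (max(cs, utr5[1]), ce) if strand == "+" else (cs, min(ce, utr5[0]))
        if utr3[0] >= s and utr3[1] <= e:
            cs, ce = (cs, min(ce, utr3[0])) if strand == "+" else (max(cs, utr3[1]), ce)
        feats.append(dict(chrom="chr1", type="CDS", start=cs, end=ce, strand=strand,
                          attributes={"ID": "g1.1.cds", "Parent": "g1.1"}))
    feats.append(dict(chrom="chr1", type="five_prime_UTR", start=utr5[0], end=utr5[1], strand=strand,
                      attributes={"ID": "g1.1.u5", "Parent": "g1.1"}))
    feats.append(dict(chrom="chr1", type="three_prime_UTR", start=utr3[0], end=utr3[1], strand=strand,
                      attributes={"ID": "g1.1.u3", "Parent": "g1.1"}))
    return feats


class TestClassification:
    def test_element_inside_second_intron(self):
        ctx, = classify_elements([_el("chr1", 2900, 3300)], _gene_features())
        assert (ctx.gene_id, ctx.feature, ctx.ordinal) == ("g1", "intron", 2)

    def test_strand_aware_intron_ordinal(self):
        # same interval on a minus-strand gene is the FIRST intron
        ctx, = classify_elements([_el("chr1", 2900, 3300)], _gene_features("-"))
        assert (ctx.feature, ctx.ordinal) == ("intron", 1)

    def test_intergenic(self):
        ctx, = classify_elements([_el("chr1", 8000, 8400)], _gene_features())
        assert ctx.feature == "intergenic" and ctx.gene_id is None

    def test_element_in_cds(self):
        ctx, = classify_elements([_el("chr1", 2450, 2750)], _gene_features())
        assert (ctx.feature, ctx.ordinal) == ("CDS", 2)

    def test_element_in_three_prime_utr(self):
        ctx, = classify_elements([_el("chr1", 3925, 3995)], _gene_features())
        assert ctx.feature == "three_prime_UTR" and ctx.ordinal == 3

    def test_straddling_element_mixed_with_dominant(self):
        # spans intron 1 / exon 2 boundary; most overlap in the intron
        ctx, = classify_elements([_el("chr1", 2000, 2500)], _gene_features())
        assert ctx.feature == "mixed" and ctx.dominant == "intron"

    def test_utrs_inferred_when_absent(self):
        feats = [f for f in _gene_features() if "UTR" not in f["type"]]
        ctx, = classify_elements([_el("chr1", 3925, 3995)], feats)
        assert ctx.feature == "three_prime_UTR"

    def test_malformed_hierarchy_raises(self):
        feats = _gene_features()
        feats.append(dict(chrom="chr1", type="exon", start=5000, end=5200, strand="+",
                          attributes={"ID": "orphan", "Parent": "missing_mrna"}))
        with pytest.raises(ValueError, match="orphan"):
            classify_elements([_el("chr1", 100, 200)], feats)

    def test_longest_transcript_wins(self):
        feats = _gene_features()
        feats.append(dict(chrom="chr1", type="mRNA", start=1000, end=1400, strand="+",
                          attributes={"ID": "g1.2", "Parent": "g1"}))
        feats.append(dict(chrom="chr1", type="exon", start=1000, end=1400, strand="+",
                          attributes={"ID": "g1.2.e0", "Parent": "g1.2"}))
        t = load_transcripts(feats)
        assert len(t["g1"].exons) == 3

    def test_transcript_record_order_invariant(self):
        feats = _gene_features()
        ctx1, = classify_elements([_el("chr1", 2900, 3300)], feats)
        ctx2, = classify_elements([_el("chr1", 2900, 3300)], list(reversed(feats)))
        assert (ctx1.feature, ctx1.ordinal) == (ctx2.feature, ctx2.ordinal)


class TestAgainstSimulatorTruth:
    def test_planted_genic_elements_classified(self, small_sim, small_ann):
        truth = truth_by_coord(small_sim, "A")
        ctxs = classify_elements(small_ann["A"].elements, small_sim.genes_a)
        by_id = {c.element_id: c for c in ctxs}
        n_checked = 0
        for (chrom, s, e), r in truth.items():
            if not r.gene_id:
                continue
            ctx = by_id.get(f"A:{chrom}:{s}-{e}")
            assert ctx is not None and ctx.gene_id == r.gene_id
            if r.gene_feature == "intron":
                assert ctx.feature == "intron" and ctx.ordinal == r.gene_ordinal
            else:  # exonic plants land in CDS or UTR sub-features
                assert ctx.feature in ("CDS", "five_prime_UTR", "three_prime_UTR", "mixed")
            n_checked += 1
        assert n_checked >= 5

    def test_every_element_classified_once(self, small_ann, small_sim):
        ctxs = classify_elements(small_ann["A"].elements, small_sim.genes_a)
        assert len(ctxs) == len(small_ann["A"].elements)

    def test_summary_counts(self, small_sim, small_ann):
        ctxs = classify_elements(small_ann["A"].elements, small_sim.genes_a)
        summ = genic_summary(ctxs, small_ann["A"].elements)
        truth = small_sim.truth[(small_sim.truth.genome == "A") & (small_sim.truth.gene_id != "")]
        assert summ["n_genes_with_elements"] == truth.gene_id.nunique()
        # the simulator plants two elements into the first gene
        assert "gene001" in summ["genes_with_multiple_elements"]
        assert summ["counts_by_feature"].get("intron", 0) >= (truth.gene_feature == "intron").sum()
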