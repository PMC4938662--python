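"""Classification of elements relative to gene models (GFF3).

Each element gets exactly one :class:`GenicContext`: intergenic, or its
position within the gene it overlaps most — intron, CDS, 5'/3' UTR (with a
strand-aware 1-based ordinal: "1st intron" is the first intron in
transcript orientation), or "mixed" when the element straddles feature
boundaries, in which case the dominant-overlap feature is recorded with
ties broken CDS > UTR > intron.

Genes with several transcripts are classified against the longest
(spliced) transcript.  UTR features are used when present and inferred
from exon-minus-CDS otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gffutils
import pandas as pd

from .discovery import TEElement
from .io import write_gff3

_PRECEDENCE = {"CDS": 3, "five_prime_UTR": 2, "three_prime_UTR": 2, "intron": 1}


@dataclass
class GenicContext:
    element_id: str
    gene_id: str | None
    feature: str  # intergenic | intron | CDS | five_prime_UTR | three_prime_UTR | mixed
    ordinal: int  # 1-based intron/exon ordinal; 0 when not applicable
    overlap_bp: int
    dominant: str = ""  # dominant feature when mixed


@dataclass
class _Transcript:
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, plus-strand order
    cds: list[tuple[int, int]]
    utr5: list[tuple[int, int]]
    utr3: list[tuple[int, int]]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)]

    def intron_ordinal(self, idx_plus: int) -> int:
        n = len(self.exons) - 1
        return idx_plus + 1 if self.strand == "+" else n - idx_plus

    def exon_ordinal(self, idx_plus: int) -> int:
        return idx_plus + 1 if self.strand == "+" else len(self.exons) - idx_plus


def _load_db(gff: str | Path | list[dict]) -> gffutils.FeatureDB:
    if isinstance(gff, list):  # feature dicts (e.g. from the simulator)
        import os
        import tempfile

        tmp = tempfile.NamedTemporaryFile("w", suffix=".gff3", delete=False)
        try:
            tmp.close()
            write_gff3(tmp.name, gff)
            return gffutils.create_db(tmp.name, ":memory:", merge_strategy="create_unique", keep_order=True)
        finally:
            os.unlink(tmp.name)
    return gffutils.create_db(str(gff), ":memory:", merge_strategy="create_unique", keep_order=True)


def _interval(f: gffutils.Feature) -> tuple[int, int]:
    return (f.start - 1, f.end)  # GFF3 1-based closed -> 0-based half-open


def load_transcripts(gff: str | Path | list[dict]) -> dict[str, _Transcript]:
    """Longest transcript per gene, with exon/intron/CDS/UTR intervals.

    Raises on malformed hierarchies (an exon or CDS whose Parent is
    missing), naming the offending feature.
    """
    db = _load_db(gff)
    known_ids = {f.id for f in db.all_features()}
    for ftype in ("exon", "CDS"):
        for f in db.features_of_type(ftype):
            parents = f.attributes.get("Parent", [])
            if not parents or any(p not in known_ids for p in parents):
                raise ValueError(f"feature {f.id or ftype} at {f.seqid}:{f.start} has no valid Parent")
    out: dict[str, _Transcript] = {}
    for gene in db.features_of_type("gene"):
        best: _Transcript | None = None
        best_len = -1
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = sorted(_interval(f) for f in db.children(mrna, featuretype="exon"))
            if not exons:
                continue
            cds = sorted(_interval(f) for f in db.children(mrna, featuretype="CDS"))
            utr5 = sorted(_interval(f) for f in db.children(mrna, featuretype="five_prime_UTR"))
            utr3 = sorted(_interval(f) for f in db.children(mrna, featuretype="three_prime_UTR"))
            if not utr5 and not utr3 and cds:
                utr5, utr3 = _infer_utrs(exons, cds, gene.strand)
            spliced = sum(e - s for s, e in exons)
            if spliced > best_len:
                best_len = spliced
                best = _Transcript(gene.id, gene.seqid, gene.strand, exons, cds, utr5, utr3)
        if best is not None:
            out[gene.id] = best
    return out


def _infer_utrs(exons, cds, strand):
    """Exon minus CDS, split 5'/3' by position relative to the CDS span."""
    cds_lo, cds_hi = cds[0][0], cds[-1][1]
    before, after = [], []
    for s, e in exons:
        if s < cds_lo:
            before.append((s, min(e, cds_lo)))
        if e > cds_hi:
            after.append((max(s, cds_hi), e))
    return (before, after) if strand == "+" else (after, before)


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def classify_elements(
    elements: list[TEElement], gff: str | Path | list[dict]
) -> list[GenicContext]:
    """One deterministic classification per element against gene models."""
    transcripts = load_transcripts(gff)
    by_chrom: dict[str, list[_Transcript]] = {}
    for t in transcripts.values():
        by_chrom.setdefault(t.chrom, []).append(t)
    for lst in by_chrom.values():
        lst.sort(key=lambda t: t.start)

    contexts: list[GenicContext] = []
    for el in elements:
        span = (el.start, el.end)
        candidates = [
            t for t in by_chrom.get(el.chrom, []) if _overlap(span, (t.start, t.end)) > 0
        ]
        if not candidates:
            contexts.append(GenicContext(el.element_id, None, "intergenic", 0, 0))
            continue
        t = max(candidates, key=lambda t: (_overlap(span, (t.start, t.end)), t.gene_id))
        per_class: dict[str, int] = {}
        ordinals: dict[str, int] = {}
        for i, iv in enumerate(t.introns):
            ov = _overlap(span, iv)
            if ov:
                per_class["intron"] = per_class.get("intron", 0) + ov
                if ov > ordinals.get("_intron_ov", -1):
                    ordinals["intron"] = t.intron_ordinal(i)
                    ordinals["_intron_ov"] = ov
        for cls, ivs in (("CDS", t.cds), ("five_prime_UTR", t.utr5), ("three_prime_UTR", t.utr3)):
            best_ov = -1
            for iv in ivs:
                ov = _overlap(span, iv)
                if ov:
                    per_class[cls] = per_class.get(cls, 0) + ov
                    if ov > best_ov:
                        best_ov = ov
                        for j, (es, ee) in enumerate(t.exons):
                            if _overlap(iv, (es, ee)) > 0 and _overlap(span, (es, ee)) > 0:
                                ordinals[cls] = t.exon_ordinal(j)
                                break
        genic_bp = sum(per_class.values())
        outside_bp = el.length - _overlap(span, (t.start, t.end))
        classes = sorted(
            per_class, key=lambda c: (per_class[c], _PRECEDENCE.get(c, 0)), reverse=True
        )
        if not classes:
            contexts.append(GenicContext(el.element_id, None, "intergenic", 0, 0))
            continue
        dominant = classes[0]
        total_ov = _overlap(span, (t.start, t.end))
        if len(classes) == 1 and per_class[dominant] == el.length and outside_bp == 0:
            contexts.append(
                GenicContext(el.element_id, t.gene_id, dominant, ordinals.get(dominant, 0),
                             per_class[dominant])
            )
        else:
            contexts.append(
                GenicContext(el.element_id, t.gene_id, "mixed", ordinals.get(dominant, 0),
                             total_ov, dominant=dominant)
            )
    assert len(contexts) == len(elements)
    return contexts


def genic_summary(
    contexts: list[GenicContext], elements: list[TEElement] | None = None
) -> dict:
    """Counts by feature class, genes hit, and multi-element genes."""
    by_feature: dict[str, int] = {}
    genes: dict[str, int] = {}
    for c in contexts:
        by_feature[c.feature] = by_feature.get(c.feature, 0) + 1
        if c.gene_id:
            genes[c.gene_id] = genes.get(c.gene_id, 0) + 1
    complete_genes: set[str] = set()
    if elements is not None:
        complete_ids = {el.element_id for el in elements if el.complete}
        for c in contexts:
            if c.gene_id and c.element_id in complete_ids:
                complete_genes.add(c.gene_id)
    return dict(
        counts_by_feature=by_feature,
        n_genes_with_elements=len(genes),
        genes_with_multiple_elements=sorted(g for g, n in genes.items() if n >= 2),
        n_genes_with_complete_elements=len(complete_genes),
    )


def contexts_to_dataframe(contexts: list[GenicContext]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(element_id=c.element_id, gene_id=c.gene_id or "", feature=c.feature,
                 ordinal=c.ordinal, overlap_bp=c.overlap_bp, dominant=c.dominant)
            for c in contexts
        ]
    )
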