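"""Element discovery: structural scan, validation, library masking, annotation.

Discovery combines two evidence routes, mirroring how short TIR-transposon
families are annotated in practice:

* **structural**: scan for the conserved 5'-CACTA ... TAGTG-3' termini at a
  plausible element size, then validate the terminal inverted repeat (TIR)
  and the flanking 3-bp target site duplication (TSD).  Only candidates
  passing all three checks are *complete* elements.
* **homology**: mask the genome with a library of known family members
  (score > 250 and hit length > 50 bp by default); hits that do not
  correspond to a validated complete element are reported as *truncated*
  copies.

Note the CACTA/TAGTG termini are mutually reverse-complementary, so a
structural candidate is strand-ambiguous on its own; strand is resolved by
the orientation of the best overlapping library hit when a library is
provided (otherwise reported as ".").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqcore import (
    DEFAULT_SCORING,
    KmerIndex,
    LocalHit,
    Scoring,
    align_local,
    reverse_complement,
)

TERMINAL_5 = "CACTA"
TERMINAL_3 = "TAGTG"


@dataclass
class DiscoveryConfig:
    """Thresholds for structural and homology discovery."""

    min_len: int = 300
    max_len: int = 500
    tir_min: int = 50
    tir_max: int = 160
    tir_identity: float = 0.80
    min_score: float = 250.0
    min_hit_len: int = 50
    overlap_frac: float = 0.5  # two calls overlapping >= this (of the shorter) are one element
    scoring: Scoring = field(default_factory=Scoring)


@dataclass
class TEElement:
    """One annotated element (plus-strand coordinates, 0-based half-open)."""

    genome: str
    chrom: str
    start: int
    end: int
    strand: str
    tir_length: int
    tsd: str | None
    complete: bool
    family: str
    subfamily: str = ""
    source: str = "structural"  # structural | homology
    seq: str = field(default="", repr=False)

    @property
    def element_id(self) -> str:
        return f"{self.genome}:{self.chrom}:{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start

    def oriented_seq(self) -> str:
        return reverse_complement(self.seq) if self.strand == "-" else self.seq


@dataclass
class MaskHit:
    chrom: str
    start: int
    end: int
    strand: str
    score: float
    identity: float
    library_member: str


class ValidationFailure(Exception):
    """Candidate rejected, with a machine-readable reason."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


def scan_termini(
    genome: dict[str, str], min_len: int = 300, max_len: int = 500
) -> list[tuple[str, int, int]]:
    """All intervals starting with CACTA and ending with TAGTG within
    [min_len, max_len].  Both strands are covered implicitly: the two
    termini are reverse complements of one another, so a minus-strand
    element shows the same motif pair on the plus strand.  Candidates may
    overlap."""
    out: list[tuple[str, int, int]] = []
    for chrom, seq in genome.items():
        starts = _find_all(seq, TERMINAL_5)
        # element end e means seq[e-5:e] == TAGTG
        ends = np.array([p + 5 for p in _find_all(seq, TERMINAL_3)], dtype=np.int64)
        for s in starts:
            lo = np.searchsorted(ends, s + min_len, side="left")
            hi = np.searchsorted(ends, s + max_len, side="right")
            for e in ends[lo:hi]:
                out.append((chrom, int(s), int(e)))
    return out


def _find_all(seq: str, motif: str) -> list[int]:
    out = []
    i = seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + 1)
    return out


def tir_length_at(seq: str, tir_min: int, tir_max: int, tir_identity: float) -> int:
    """Longest L in [tir_min, tir_max] at which the first L bases match the
    reverse complement of the last L bases at >= tir_identity (ungapped).
    Returns 0 when no L qualifies."""
    limit = min(tir_max, (len(seq) - 4) // 2)
    if limit < tir_min:
        return 0
    head = seq[:limit]
    tail_rc = reverse_complement(seq[-limit:])
    m = np.frombuffer(head.encode(), np.uint8) == np.frombuffer(tail_rc.encode(), np.uint8)
    cum = np.cumsum(m)
    lengths = np.arange(1, limit + 1)
    ok = (cum / lengths >= tir_identity) & (lengths >= tir_min)
    idx = np.flatnonzero(ok)
    return int(lengths[idx[-1]]) if idx.size else 0


def validate_element(
    genome: dict[str, str],
    chrom: str,
    start: int,
    end: int,
    cfg: DiscoveryConfig | None = None,
    genome_id: str = "",
    family: str = "CACTA1",
) -> TEElement:
    """Validate a candidate interval as a complete element.

    Acceptance requires (i) the terminal 5-mers, (ii) a TIR of length >=
    ``tir_min`` at identity >= ``tir_identity``, (iii) identical 3-bp flanks
    (the TSD).  Raises :class:`ValidationFailure` with reason "edge",
    "termini", "tir" or "tsd" otherwise.
    """
    cfg = cfg or DiscoveryConfig()
    seq = genome[chrom][start:end]
    if start < 3 or end + 3 > len(genome[chrom]):
        raise ValidationFailure("edge")
    if not seq.startswith(TERMINAL_5) or not seq.endswith(TERMINAL_3):
        raise ValidationFailure("termini")
    tir_len = tir_length_at(seq, cfg.tir_min, cfg.tir_max, cfg.tir_identity)
    if tir_len == 0:
        raise ValidationFailure("tir")
    left = genome[chrom][start - 3 : start]
    right = genome[chrom][end : end + 3]
    if left != right or "N" in left:
        raise ValidationFailure("tsd")
    return TEElement(
        genome=genome_id,
        chrom=chrom,
        start=start,
        end=end,
        strand=".",
        tir_length=tir_len,
        tsd=left,
        complete=True,
        family=family,
        seq=seq,
    )


def mask_with_library(
    genome: dict[str, str],
    library: dict[str, str],
    min_score: float = 250.0,
    min_hit_len: int = 50,
    scoring: Scoring = DEFAULT_SCORING,
    indexes: dict[str, KmerIndex] | None = None,
) -> list[MaskHit]:
    """Homology hits of every library member on the genome, filtered by the
    score and length cutoffs; overlapping hits from different members are
    merged keeping the best-scoring attribution."""
    if not library:
        raise ValueError("library must be non-empty")
    raw: list[MaskHit] = []
    for chrom, seq in genome.items():
        if len(seq) < min_hit_len:
            continue
        idx = indexes[chrom] if indexes else KmerIndex(seq)
        for member, mseq in library.items():
            for hit in align_local(mseq, seq, scoring, min_score=min_score, min_len=min_hit_len, index=idx):
                raw.append(
                    MaskHit(chrom, hit.t_start, hit.t_end, hit.strand, hit.score, hit.identity, member)
                )
    raw.sort(key=lambda h: (-h.score, h.chrom, h.start))
    kept: list[MaskHit] = []
    for h in raw:
        if not any(_overlap_frac(h, k) >= 0.5 for k in kept if k.chrom == h.chrom):
            kept.append(h)
    kept.sort(key=lambda h: (h.chrom, h.start))
    return kept


def _overlap_frac(a, b) -> float:
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return inter / min(a.end - a.start, b.end - b.start)


@dataclass
class AnnotationResult:
    elements: list[TEElement]
    summary: dict
    rejections: dict[str, int]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            dict(
                element_id=e.element_id, genome=e.genome, chrom=e.chrom, start=e.start,
                end=e.end, strand=e.strand, tir_length=e.tir_length, tsd=e.tsd or "",
                complete=e.complete, family=e.family, subfamily=e.subfamily, source=e.source,
            )
            for e in self.elements
        ]
        return pd.DataFrame(rows)

    def to_gff3_features(self) -> list[dict]:
        feats = []
        for i, e in enumerate(self.elements):
            attrs = {
                "ID": f"TE{i + 1:05d}",
                "completeness": "complete" if e.complete else "truncated",
                "family": e.family,
            }
            if e.tsd:
                attrs["tsd"] = e.tsd
            if e.tir_length:
                attrs["tir_length"] = e.tir_length
            feats.append(
                dict(chrom=e.chrom, type="terminal_inverted_repeat_element", start=e.start,
                     end=e.end, strand=e.strand if e.strand != "." else ".", attributes=attrs)
            )
        return feats


def check_element_invariants(el: TEElement, genome: dict[str, str], cfg: DiscoveryConfig) -> None:
    """Hard invariants for every emitted complete element."""
    seq = genome[el.chrom][el.start : el.end]
    assert seq.startswith(TERMINAL_5) and seq.endswith(TERMINAL_3), el.element_id
    assert genome[el.chrom][el.start - 3 : el.start] == el.tsd == genome[el.chrom][el.end : el.end + 3]
    assert el.tir_length >= cfg.tir_min


def annotate(
    genome: dict[str, str],
    library: dict[str, str] | None = None,
    cfg: DiscoveryConfig | None = None,
    genome_id: str = "",
    family: str = "CACTA1",
) -> AnnotationResult:
    """Full annotation of one assembly: structural + homology discovery,
    overlap deduplication, summary counts.

    Deduplication keeps structural calls over homology calls, then the
    higher-scoring/longer call, treating calls overlapping >= 50% of the
    shorter one as the same element.
    """
    cfg = cfg or DiscoveryConfig()
    structural: list[TEElement] = []
    rejections: dict[str, int] = {}
    for chrom, s, e in scan_termini(genome, cfg.min_len, cfg.max_len):
        try:
            el = validate_element(genome, chrom, s, e, cfg, genome_id, family)
        except ValidationFailure as exc:
            rejections[exc.reason] = rejections.get(exc.reason, 0) + 1
            continue
        structural.append(el)
    # dedupe structural candidates (overlapping alternates from the motif scan)
    structural.sort(key=lambda el: (el.chrom, el.start, -(el.end - el.start)))
    dedup: list[TEElement] = []
    for el in structural:
        if not any(
            k.chrom == el.chrom and _overlap_frac(el, k) >= cfg.overlap_frac for k in dedup[-8:]
        ):
            dedup.append(el)
    structural = dedup

    elements: list[TEElement] = list(structural)
    if library:
        indexes = {c: KmerIndex(s) for c, s in genome.items() if len(s) >= cfg.min_hit_len}
        hits = mask_with_library(genome, library, cfg.min_score, cfg.min_hit_len, cfg.scoring, indexes)
        by_chrom: dict[str, list[TEElement]] = {}
        for el in structural:
            by_chrom.setdefault(el.chrom, []).append(el)
        for hit in hits:
            overlapping = [
                el for el in by_chrom.get(hit.chrom, []) if _overlap_frac(hit, el) >= cfg.overlap_frac
            ]
            if overlapping:
                for el in overlapping:  # strand is resolved by library orientation
                    if el.strand == ".":
                        el.strand = hit.strand
                continue
            elements.append(
                TEElement(
                    genome=genome_id, chrom=hit.chrom, start=hit.start, end=hit.end,
                    strand=hit.strand, tir_length=0, tsd=None, complete=False,
                    family=family, source="homology", seq=genome[hit.chrom][hit.start : hit.end],
                )
            )
    for el in elements:
        if el.complete:
            check_element_invariants(el, genome, cfg)
    elements.sort(key=lambda el: (el.chrom, el.start))
    masked_bp = sum(el.length for el in elements)
    genome_bp = sum(len(s) for s in genome.values())
    summary = dict(
        genome=genome_id,
        n_total=len(elements),
        n_complete=sum(el.complete for el in elements),
        n_truncated=sum(not el.complete for el in elements),
        masked_bp=masked_bp,
        masked_fraction=masked_bp / genome_bp if genome_bp else 0.0,
    )
    return AnnotationResult(elements=elements, summary=summary, rejections=rejections)
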