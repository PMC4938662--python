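"""Presence/absence (insertion polymorphism) calling between two assemblies.

Each complete element of the source assembly is tested in the target
assembly by anchoring its two 100-bp flanking sequences:

1. homologous sequence must be found for both flanks;
2. the flank hits must be adjoined (small inter-flank gap) in the target
   for an *absent* (polymorphic) verdict;
3. no family sequence may occur within or between the flank hits at an
   absent locus.

Flanks mapping to repetitive sequence (no clearly unique best hit) make the
element *ambiguous* rather than force a verdict, as do edge elements and
discordant flank placements.  A locus whose flanks surround family sequence
is called *present*.  Absence cannot distinguish an insertion on the source
branch from a precise excision on the target branch; verdicts therefore say
"absent", never which event produced it.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import pandas as pd

from .discovery import TEElement
from .seqcore import DEFAULT_SCORING, KmerIndex, LocalHit, Scoring, align_local


@dataclass
class FlankEvidence:
    chrom: str
    start: int
    end: int
    strand: str
    score: float
    identity: float
    n_hits: int  # hit multiplicity across the target


@dataclass
class PolymorphismCall:
    element_id: str
    source_genome: str
    verdict: str  # present | absent | ambiguous
    reason: str  # ok | edge | flank_unmapped | repeat | discordant | family_near_flank | unresolved
    left: FlankEvidence | None = None
    right: FlankEvidence | None = None
    gap: int | None = None
    locus_chrom: str | None = None
    locus_start: int | None = None
    locus_end: int | None = None
    family_between: bool = False
    family_within_flanks: bool = False


class _IntervalSet:
    """Sorted interval overlap queries per chromosome."""

    def __init__(self, intervals: list[tuple[str, int, int]]):
        self._by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        tmp: dict[str, list[tuple[int, int]]] = {}
        for c, s, e in intervals:
            tmp.setdefault(c, []).append((s, e))
        for c, ivs in tmp.items():
            ivs.sort()
            self._by_chrom[c] = ([s for s, _ in ivs], [e for _, e in ivs])

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        if chrom not in self._by_chrom or end <= start:
            return False
        starts, ends = self._by_chrom[chrom]
        i = bisect.bisect_left(starts, end)
        for j in range(max(0, i - 8), i):
            if ends[j] > start:
                return True
        return False


def _search_flank(
    flank: str,
    target: dict[str, str],
    indexes: dict[str, KmerIndex],
    scoring: Scoring,
    min_score: float,
) -> list[tuple[str, LocalHit]]:
    hits: list[tuple[str, LocalHit]] = []
    for chrom, seq in target.items():
        for h in align_local(flank, seq, scoring, min_score=min_score, min_len=30, index=indexes[chrom]):
            hits.append((chrom, h))
    hits.sort(key=lambda ch: (-ch[1].score, ch[0], ch[1].t_start))
    return hits


def call_polymorphisms(
    elements: list[TEElement],
    source_genome: dict[str, str],
    target_genome: dict[str, str],
    family_intervals: list[tuple[str, int, int]],
    flank: int = 100,
    gap_max: int = 20,
    uniqueness_ratio: float = 1.5,
    min_flank_score: float = 50.0,
    scoring: Scoring = DEFAULT_SCORING,
    indexes: dict[str, KmerIndex] | None = None,
) -> list[PolymorphismCall]:
    """One verdict per complete source element against the target assembly.

    ``family_intervals`` are the target's annotated family intervals
    (complete + truncated), used for the no-family-sequence criterion; pass
    the output of :func:`cactakit.discovery.annotate` on the target.

    A flank is considered uniquely mapped when its best hit scores at least
    ``uniqueness_ratio`` times the second best.  ``gap_max`` is the largest
    inter-flank gap still counting as "adjoined" (the empty site retains
    one TSD copy, so the expected gap at a true absence is ~3 bp).
    """
    fam = _IntervalSet(family_intervals)
    idx = indexes or {c: KmerIndex(s) for c, s in target_genome.items()}
    calls: list[PolymorphismCall] = []
    for el in elements:
        if not el.complete:
            raise ValueError(f"polymorphism calling needs complete elements; got {el.element_id}")
        src = source_genome[el.chrom]
        if el.start > len(src) or el.end > len(src):
            raise ValueError(f"element {el.element_id} does not fit its source chromosome")
        cid = el.element_id

        if el.start - 3 - flank < 0 or el.end + 3 + flank > len(src):
            calls.append(PolymorphismCall(cid, el.genome, "ambiguous", "edge"))
            continue
        left = src[el.start - 3 - flank : el.start - 3]
        right = src[el.end + 3 : el.end + 3 + flank]
        hits_l = _search_flank(left, target_genome, idx, scoring, min_flank_score)
        hits_r = _search_flank(right, target_genome, idx, scoring, min_flank_score)
        if not hits_l or not hits_r:
            calls.append(PolymorphismCall(cid, el.genome, "ambiguous", "flank_unmapped"))
            continue

        def unique(hits: list[tuple[str, LocalHit]]) -> bool:
            return len(hits) == 1 or hits[0][1].score >= uniqueness_ratio * hits[1][1].score

        ev = {}
        for side, hits in (("left", hits_l), ("right", hits_r)):
            c, h = hits[0]
            ev[side] = FlankEvidence(c, h.t_start, h.t_end, h.strand, h.score, h.identity, len(hits))
        if not (unique(hits_l) and unique(hits_r)):
            calls.append(PolymorphismCall(cid, el.genome, "ambiguous", "repeat", ev["left"], ev["right"]))
            continue
        bl, br = ev["left"], ev["right"]
        if bl.chrom != br.chrom or bl.strand != br.strand:
            calls.append(PolymorphismCall(cid, el.genome, "ambiguous", "discordant", bl, br))
            continue
        if bl.strand == "+":
            gap = br.start - bl.end
            locus = (bl.end, br.start)
        else:
            gap = bl.start - br.end
            locus = (br.end, bl.start)
        if gap < -5:
            calls.append(PolymorphismCall(cid, el.genome, "ambiguous", "discordant", bl, br, gap))
            continue
        lo, hi = min(locus), max(locus)
        fam_between = fam.overlaps(bl.chrom, lo, hi)
        fam_within = fam.overlaps(bl.chrom, bl.start, bl.end) or fam.overlaps(bl.chrom, br.start, br.end)
        common = dict(
            left=bl, right=br, gap=gap, locus_chrom=bl.chrom, locus_start=lo, locus_end=hi,
            family_between=fam_between, family_within_flanks=fam_within,
        )
        if gap <= gap_max:
            if fam_between or fam_within:
                calls.append(PolymorphismCall(cid, el.genome, "ambiguous", "family_near_flank", **common))
            else:
                calls.append(PolymorphismCall(cid, el.genome, "absent", "ok", **common))
        elif fam_between and gap >= 0.5 * el.length:
            calls.append(PolymorphismCall(cid, el.genome, "present", "ok", **common))
        else:
            calls.append(PolymorphismCall(cid, el.genome, "ambiguous", "unresolved", **common))
    assert len(calls) == len(elements), "verdict partition must cover every element"
    return calls


def calls_to_dataframe(calls: list[PolymorphismCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            dict(
                element_id=c.element_id, source_genome=c.source_genome, verdict=c.verdict,
                reason=c.reason, gap=c.gap,
                locus_chrom=c.locus_chrom, locus_start=c.locus_start, locus_end=c.locus_end,
                left_score=c.left.score if c.left else None,
                right_score=c.right.score if c.right else None,
                left_hits=c.left.n_hits if c.left else 0,
                right_hits=c.right.n_hits if c.right else 0,
                family_between=c.family_between, family_within_flanks=c.family_within_flanks,
            )
        )
    return pd.DataFrame(rows)


def polymorphic_density(n_polymorphic: int, assembly_size_mb: float) -> float:
    """Polymorphic elements per Mb (assembly size after gap removal)."""
    if assembly_size_mb <= 0:
        raise ValueError("assembly size must be positive")
    return n_polymorphic / assembly_size_mb


def subfamily_polymorphism_ratio(n_polymorphic: int, subfamily_size: int) -> float:
    """Fraction of a subfamily's elements that are polymorphic."""
    if subfamily_size <= 0:
        raise ValueError("subfamily size must be positive")
    return n_polymorphic / subfamily_size


def ordinal_label(n: int) -> str:
    suffix = "th"
    if n % 100 not in (11, 12, 13):
        suffix = {1: "st", 2: "nd", 3: "rd"}.get(n % 10, "th")
    return f"{n}{suffix}"


def genic_polymorphism_join(calls: list[PolymorphismCall], contexts: dict) -> pd.DataFrame:
    """Polymorphic (absent) elements that sit inside genes.

    ``contexts`` maps element id -> GenicContext (see
    :mod:`cactakit.genic`).  Output mirrors a per-gene table: element,
    gene, and a human-readable location such as "3rd intron".
    """
    rows = []
    for c in calls:
        if c.verdict != "absent":
            continue
        ctx = contexts.get(c.element_id)
        if ctx is None or ctx.feature == "intergenic":
            continue
        kind = "intron" if ctx.feature == "intron" else "exon"
        rows.append(
            dict(
                element_id=c.element_id,
                gene_id=ctx.gene_id,
                feature=ctx.feature,
                location=f"{ordinal_label(ctx.ordinal)} {kind}" if ctx.ordinal else ctx.feature,
            )
        )
    return pd.DataFrame(rows, columns=["element_id", "gene_id", "feature", "location"])
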