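"""Sequence primitives and the alignment / distance engine.

Everything downstream (element discovery, clustering, polymorphism calling,
divergence dating) funnels through the handful of operations defined here:

* :func:`reverse_complement` -- Watson-Crick complement over {A,C,G,T,N}.
* :func:`align_global` -- optimal global alignment under a BLASTN-like affine
  scheme (match +2, mismatch -3, gap open -5, gap extend -2 by default),
  delegating the dynamic programming to :class:`Bio.Align.PairwiseAligner`.
* :func:`align_local` -- seed-and-extend local hit search of a short query
  against a (possibly chromosome-scale) target, both strands.
* :func:`kimura2p` -- Kimura two-parameter distance
  ``K = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q))`` where P and Q are the observed
  transition and transversion proportions over comparable (ungapped, non-N)
  columns.
* :func:`gc_fraction` -- G+C fraction over unambiguous bases.

Conventions
-----------
Coordinates are 0-based half-open throughout.  Identity is computed
BLASTN-style: matches / alignment columns, counting internal gap columns but
excluding terminal overhangs; columns with an N are excluded from both
numerator and denominator.  Gap cost for a gap of length L is
``gap_open + (L - 1) * gap_extend`` (the first gap column is charged the open
score), which is the Biopython convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: transitions are A<->G and C<->T; everything else among {A,C,G,T} is a transversion
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


class SaturationError(ValueError):
    """Raised when a distance is requested from zero comparable sites."""


@dataclass(frozen=True)
class Scoring:
    """Affine alignment scoring parameters (BLASTN-like defaults)."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0


DEFAULT_SCORING = Scoring()


@dataclass
class PairwiseAlignment:
    """A pairwise alignment plus the summary statistics the pipeline uses.

    ``identity`` = matches / (matches + mismatches + internal gap columns);
    N-containing columns are not counted.  ``query_coverage`` is the fraction
    of query (sequence *a*) residues that lie inside the aligned core, i.e.
    between the first and last column where both sequences have a residue.
    """

    aligned_a: str
    aligned_b: str
    score: float
    matches: int
    mismatches: int
    gap_columns: int
    identity: float
    query_coverage: float


@dataclass
class K2PDistance:
    """Kimura two-parameter distance record.

    ``saturated`` flags the analytically undefined regime
    (``1 - 2P - Q <= 0`` or ``1 - 2Q <= 0``); ``k`` is NaN there rather than a
    silent garbage value.
    """

    p: float
    q: float
    k: float
    sites_compared: int
    saturated: bool = False


def validate_sequence(seq: str) -> str:
    """Uppercase ``seq`` and reject characters outside {A,C,G,T,N}.

    Raises ``ValueError`` naming the first offending position.
    """
    s = seq.upper()
    for i, ch in enumerate(s):
        if ch not in DNA_ALPHABET:
            raise ValueError(f"non-DNA character {ch!r} at position {i}")
    return s


def reverse_complement(seq: str) -> str:
    s = validate_sequence(seq)
    return s.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """G+C fraction over A/C/G/T bases (N excluded); error if none remain."""
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    acgt = gc + s.count("A") + s.count("T")
    if acgt == 0:
        raise ValueError("no unambiguous bases to compute GC content from")
    return gc / acgt


def make_aligner(scoring: Scoring = DEFAULT_SCORING, mode: str = "global") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def _alignment_stats(aligned_a: str, aligned_b: str, score: float, query_len: int) -> PairwiseAlignment:
    n = len(aligned_a)
    # core = columns between the first and last where both sequences have residues
    first = 0
    while first < n and (aligned_a[first] == "-" or aligned_b[first] == "-"):
        first += 1
    last = n - 1
    while last >= 0 and (aligned_a[last] == "-" or aligned_b[last] == "-"):
        last -= 1
    matches = mismatches = gaps = 0
    a_in_core = 0
    for i in range(first, last + 1):
        ca, cb = aligned_a[i], aligned_b[i]
        if ca != "-":
            a_in_core += 1
        if ca == "-" or cb == "-":
            gaps += 1
        elif ca == "N" or cb == "N":
            continue
        elif ca == cb:
            matches += 1
        else:
            mismatches += 1
    denom = matches + mismatches + gaps
    identity = matches / denom if denom else 0.0
    coverage = a_in_core / query_len if query_len else 0.0
    return PairwiseAlignment(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=score,
        matches=matches,
        mismatches=mismatches,
        gap_columns=gaps,
        identity=identity,
        query_coverage=coverage,
    )


def align_global(a: str, b: str, scoring: Scoring = DEFAULT_SCORING) -> PairwiseAlignment:
    """Optimal global alignment of ``a`` (query) against ``b``.

    Deterministic: of the optimal alignments, the engine's first-enumerated
    path is returned.
    """
    if not a or not b:
        raise ValueError("align_global requires two non-empty sequences")
    a = a.upper()
    b = b.upper()
    aln = make_aligner(scoring, "global").align(a, b)[0]
    return _alignment_stats(aln[0], aln[1], aln.score, len(a))


# ---------------------------------------------------------------------------
# k-mer index and seeded local search
# ---------------------------------------------------------------------------

_ENC = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(enc: np.ndarray, k: int) -> np.ndarray:
    """Base-4 rolling codes; windows containing N (code -1) are set to -1."""
    n = enc.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for i in range(k):
        col = enc[i : i + n]
        codes = codes * 4 + np.where(col < 0, 0, col)
        bad |= col < 0
    codes[bad] = -1
    return codes


class KmerIndex:
    """Sorted exact k-mer index over one target sequence (both-strand queries)."""

    def __init__(self, seq: str, k: int = 12):
        self.k = k
        self.length = len(seq)
        codes = _kmer_codes(_encode(seq.upper()), k)
        self._order = np.argsort(codes, kind="stable")
        self._sorted = codes[self._order]

    def positions(self, code: int) -> np.ndarray:
        lo = np.searchsorted(self._sorted, code, side="left")
        hi = np.searchsorted(self._sorted, code, side="right")
        return self._order[lo:hi]

    def seed_matches(self, query: str) -> np.ndarray:
        """(target_pos, query_pos) pairs of exact k-mer matches."""
        qcodes = _kmer_codes(_encode(query.upper()), self.k)
        valid = qcodes >= 0
        codes = qcodes[valid]
        qpos = np.flatnonzero(valid)
        if codes.size == 0:
            return np.empty((0, 2), dtype=np.int64)
        lo = np.searchsorted(self._sorted, codes, side="left")
        hi = np.searchsorted(self._sorted, codes, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            return np.empty((0, 2), dtype=np.int64)
        # flatten all [lo, hi) ranges into one gather
        offsets = np.repeat(np.cumsum(counts) - counts, counts)
        flat = np.repeat(lo, counts) + (np.arange(total) - offsets)
        return np.column_stack([self._order[flat], np.repeat(qpos, counts)])


@dataclass
class LocalHit:
    """One local alignment hit of a query on a target sequence."""

    t_start: int
    t_end: int
    strand: str
    score: float
    identity: float
    alignment: PairwiseAlignment = field(repr=False)


def _candidate_windows(matches: np.ndarray, qlen: int, tlen: int, pad: int = 60) -> list[tuple[int, int, int]]:
    """Merge seed positions into (start, end, n_seeds) target windows."""
    if matches.shape[0] == 0:
        return []
    # project each seed to the implied hit interval on the target
    starts = np.maximum(matches[:, 0] - matches[:, 1] - pad, 0)
    ends = np.minimum(matches[:, 0] + (qlen - matches[:, 1]) + pad, tlen)
    order = np.argsort(starts, kind="stable")
    windows: list[tuple[int, int, int]] = []
    cur_s, cur_e = int(starts[order[0]]), int(ends[order[0]])
    n_seeds = 1
    for idx in order[1:]:
        s, e = int(starts[idx]), int(ends[idx])
        if s <= cur_e:
            cur_e = max(cur_e, e)
            n_seeds += 1
        else:
            windows.append((cur_s, cur_e, n_seeds))
            cur_s, cur_e, n_seeds = s, e, 1
    windows.append((cur_s, cur_e, n_seeds))
    return windows


def _best_local_in_window(
    query: str, target: str, w_start: int, w_end: int, aligner: Align.PairwiseAligner,
    min_score: float, min_len: int, strand: str,
) -> list[LocalHit]:
    """Best local hit in a window, recursing into the flanks so tandem copies
    inside one merged window are each reported."""
    hits: list[LocalHit] = []
    stack = [(w_start, w_end)]
    while stack:
        ws, we = stack.pop()
        if we - ws < min_len:
            continue
        window = target[ws:we]
        alns = aligner.align(window, query)
        if alns.score < min_score:
            continue
        aln = alns[0]
        t0, t1 = int(aln.coordinates[0][0]), int(aln.coordinates[0][-1])
        if t1 - t0 < min_len:
            continue
        stats = _alignment_stats(aln[1], aln[0], aln.score, len(query))
        hits.append(
            LocalHit(
                t_start=ws + t0,
                t_end=ws + t1,
                strand=strand,
                score=float(aln.score),
                identity=stats.identity,
                alignment=stats,
            )
        )
        if t0 - 0 >= min_len:
            stack.append((ws, ws + t0))
        if (we - ws) - t1 >= min_len:
            stack.append((ws + t1, we))
    return hits


def align_local(
    query: str,
    target: str,
    scoring: Scoring = DEFAULT_SCORING,
    min_score: float = 50.0,
    min_len: int = 20,
    k: int = 12,
    index: KmerIndex | None = None,
    both_strands: bool = True,
    min_seeds: int = 2,
) -> list[LocalHit]:
    """All non-overlapping local hits of ``query`` on ``target``.

    Seed-and-extend: exact ``k``-mer seed matches are clustered into candidate
    windows and each window with at least ``min_seeds`` seeds is aligned
    locally; unseeded windows are never visited, so scores are exact for any
    hit sharing >= ``min_seeds`` exact k-mers with the query (comfortably
    true for hits above ~80% identity at k=12 over >=50 bp).  Hits are
    sorted by score descending, then by coordinate; overlapping hits are
    resolved best-score-first.

    A prebuilt :class:`KmerIndex` of the target may be passed to amortize
    indexing across many queries.
    """
    if not query or not target:
        raise ValueError("align_local requires non-empty query and target")
    query = query.upper()
    target = target.upper()
    idx = index if index is not None else KmerIndex(target, k=k)
    strands = [("+", query)]
    if both_strands:
        strands.append(("-", reverse_complement(query)))
    raw: list[LocalHit] = []
    aligner = make_aligner(scoring, "local")
    for strand, q in strands:
        matches = idx.seed_matches(q)
        for ws, we, n_seeds in _candidate_windows(matches, len(q), idx.length):
            if n_seeds < min_seeds:
                continue
            raw.extend(_best_local_in_window(q, target, ws, we, aligner, min_score, min_len, strand))
    raw.sort(key=lambda h: (-h.score, h.t_start, h.strand))
    chosen: list[LocalHit] = []
    for hit in raw:
        if all(hit.t_end <= c.t_start or hit.t_start >= c.t_end for c in chosen):
            chosen.append(hit)
    return chosen


# ---------------------------------------------------------------------------
# Kimura two-parameter distance
# ---------------------------------------------------------------------------

def kimura2p_from_alignment(aligned_a: str, aligned_b: str) -> K2PDistance:
    """K2P distance from an existing alignment (gap/N columns excluded)."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    sites = transitions = transversions = 0
    for ca, cb in zip(aligned_a.upper(), aligned_b.upper()):
        if ca in "-N" or cb in "-N":
            continue
        sites += 1
        if ca == cb:
            continue
        if (ca in _PURINES) == (cb in _PURINES):
            transitions += 1
        else:
            transversions += 1
    if sites == 0:
        raise SaturationError("no comparable (ungapped, non-N) sites")
    p = transitions / sites
    q = transversions / sites
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return K2PDistance(p=p, q=q, k=math.nan, sites_compared=sites, saturated=True)
    k = -0.5 * math.log(w1 * math.sqrt(w2))
    return K2PDistance(p=p, q=q, k=k, sites_compared=sites)


def kimura2p(a: str, b: str, scoring: Scoring = DEFAULT_SCORING) -> K2PDistance:
    """Globally align ``a`` and ``b``, then compute the K2P distance."""
    aln = align_global(a, b, scoring)
    return kimura2p_from_alignment(aln.aligned_a, aln.aligned_b)
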