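"""Greedy multi-round subfamily clustering of complete elements.

The grouping rule: in each round the first unassigned element (under a
deterministic, content-based order) becomes the query and representative of
a new subfamily; every unassigned element with global-alignment identity
>= ``id_thresh`` to the query over >= ``cov_thresh`` of the query's length
joins that subfamily and leaves the pool.  Rounds repeat until the pool is
empty.  Subfamilies are ranked by size (ties by representative order) and
labeled SF1, SF2, ...

The identity threshold defaults to 0.85 over 0.85 of the element size (the
85/85 rule).  Coverage is measured on the query's length by default; a
``coverage_on="min"`` flag switches to the shorter of the two.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .discovery import TEElement
from .seqcore import DEFAULT_SCORING, Scoring, align_global


@dataclass
class SubfamilyAssignment:
    label: str  # SF1, SF2, ... by size rank
    representative: str  # the round's query element id
    members: list[str]
    size: int


def _records(elements: Iterable) -> list[tuple[str, str, tuple]]:
    """Normalize input to (id, oriented sequence, sort key)."""
    out = []
    for el in elements:
        if isinstance(el, TEElement):
            if not el.complete:
                raise ValueError(f"non-complete element in clustering input: {el.element_id}")
            out.append((el.element_id, el.oriented_seq(), (el.genome, el.chrom, el.start)))
        else:
            eid, seq = el
            out.append((eid, seq.upper(), (eid,)))
    return out


def cluster_greedy(
    elements: Iterable,
    id_thresh: float = 0.85,
    cov_thresh: float = 0.85,
    order: str = "coordinate",
    coverage_on: str = "query",
    scoring: Scoring = DEFAULT_SCORING,
) -> list[SubfamilyAssignment]:
    """Greedy multi-round grouping at >= ``id_thresh`` identity over
    >= ``cov_thresh`` coverage.

    ``elements`` is a list of complete :class:`TEElement` or (id, sequence)
    pairs.  ``order`` fixes the query order: "coordinate" sorts by
    (genome, chromosome, start) — content-based, so record order does not
    matter — and "longest" takes elements longest-first.
    """
    recs = _records(elements)
    if not recs:
        raise ValueError("need at least one element")
    if order == "coordinate":
        recs.sort(key=lambda r: r[2])
    elif order == "longest":
        recs.sort(key=lambda r: (-len(r[1]), r[2]))
    else:
        raise ValueError(f"unknown order policy {order!r}")

    pool = list(recs)
    raw: list[SubfamilyAssignment] = []
    while pool:
        qid, qseq, _ = pool[0]
        members = [qid]
        rest = []
        for eid, seq, key in pool[1:]:
            aln = align_global(qseq, seq, scoring)
            if coverage_on == "query":
                cov = aln.query_coverage
            else:
                shorter = min(len(qseq), len(seq))
                cov = aln.query_coverage * len(qseq) / shorter
            if aln.identity >= id_thresh and cov >= cov_thresh:
                members.append(eid)
            else:
                rest.append((eid, seq, key))
        raw.append(SubfamilyAssignment(label="", representative=qid, members=members, size=len(members)))
        pool = rest

    raw.sort(key=lambda a: (-a.size, a.representative))
    for i, a in enumerate(raw):
        a.label = f"SF{i + 1}"
    _check_partition(raw, len(recs))
    return raw


def _check_partition(assignments: list[SubfamilyAssignment], n: int) -> None:
    seen: set[str] = set()
    prev = None
    for a in assignments:
        assert a.representative in a.members
        assert a.size == len(a.members)
        for m in a.members:
            assert m not in seen, f"element {m} assigned twice"
            seen.add(m)
        if prev is not None:
            assert a.size <= prev, "sizes must be non-increasing by rank"
        prev = a.size
    assert len(seen) == n, "assignments must partition the input"


def subfamily_summary(assignments: list[SubfamilyAssignment]) -> pd.DataFrame:
    """Per-subfamily size table with cumulative fraction of elements by rank."""
    total = sum(a.size for a in assignments)
    rows = []
    cum = 0
    for a in assignments:
        cum += a.size
        rows.append(
            dict(
                subfamily=a.label,
                size=a.size,
                representative=a.representative,
                cumulative_fraction=cum / total if total else 0.0,
            )
        )
    return pd.DataFrame(rows)


def top_fraction(sizes: list[int], total: int, k: int) -> float:
    """Fraction of all elements covered by the k largest subfamilies, as a
    percentage."""
    if total <= 0:
        raise ValueError("total must be positive")
    return 100.0 * sum(sorted(sizes, reverse=True)[:k]) / total


def singleton_count(assignments: list[SubfamilyAssignment]) -> int:
    return sum(1 for a in assignments if a.size == 1)
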