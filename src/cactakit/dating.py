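"""Divergence dating: ortholog pairing, molecular-clock calibration,
divergence histograms, and neighbor-joining trees.

The clock model is the standard transposon one: orthologous element pairs
(the same ancestral insertion in both genomes) have been diverging since
the genomes split, so their mean Kimura-2P distance K̄ satisfies
``K̄ = 2 r T`` for split time T and substitution rate r.  Calibration
inverts this (``r = K̄ / 2T``); any element divergence k then converts to a
time ``t = k / 2r``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .discovery import TEElement
from .polymorphism import PolymorphismCall
from .seqcore import DEFAULT_SCORING, K2PDistance, Scoring, kimura2p


@dataclass
class OrthologPair:
    a_id: str
    b_id: str
    distance: K2PDistance
    locus_chrom: str
    locus_start: int
    locus_end: int


@dataclass
class RateCalibration:
    k_mean: float
    k_median: float
    t_split: float  # years
    r: float  # substitutions/site/year
    n_pairs: int
    n_saturated: int = 0


def pair_orthologs(
    calls_ab: list[PolymorphismCall],
    calls_ba: list[PolymorphismCall],
    elements_a: list[TEElement],
    elements_b: list[TEElement],
    scoring: Scoring = DEFAULT_SCORING,
) -> tuple[list[OrthologPair], dict]:
    """One-to-one ortholog pairs from reciprocal present calls.

    An A element called present in B is paired with the complete B element
    lying between its flank anchors, provided that B element is itself
    called present toward A (mutual anchoring at the same locus).
    Conflicting anchors (two A elements claiming one B element) drop both
    and are reported.
    """
    a_by_id = {el.element_id: el for el in elements_a}
    b_by_id = {el.element_id: el for el in elements_b}
    present_b = {c.element_id for c in calls_ba if c.verdict == "present"}
    b_sorted: dict[str, list[TEElement]] = {}
    for el in elements_b:
        if el.complete:
            b_sorted.setdefault(el.chrom, []).append(el)
    for lst in b_sorted.values():
        lst.sort(key=lambda e: e.start)

    links: dict[str, str] = {}
    claimed: dict[str, list[str]] = {}
    for call in calls_ab:
        if call.verdict != "present" or call.locus_chrom is None:
            continue
        candidates = [
            el
            for el in b_sorted.get(call.locus_chrom, [])
            if el.start < call.locus_end and el.end > call.locus_start
            and min(el.end, call.locus_end) - max(el.start, call.locus_start) >= 0.5 * el.length
        ]
        if len(candidates) != 1:
            continue
        b_el = candidates[0]
        if b_el.element_id not in present_b:
            continue
        links[call.element_id] = b_el.element_id
        claimed.setdefault(b_el.element_id, []).append(call.element_id)

    conflicts = {b: a_list for b, a_list in claimed.items() if len(a_list) > 1}
    pairs: list[OrthologPair] = []
    for a_id, b_id in links.items():
        if b_id in conflicts:
            continue
        a_el, b_el = a_by_id[a_id], b_by_id[b_id]
        dist = kimura2p(a_el.oriented_seq(), b_el.oriented_seq(), scoring)
        pairs.append(OrthologPair(a_id, b_id, dist, b_el.chrom, b_el.start, b_el.end))
    report = dict(
        n_present_ab=sum(c.verdict == "present" for c in calls_ab),
        n_paired=len(pairs),
        n_conflicts=len(conflicts),
        conflict_loci=sorted(conflicts),
    )
    return pairs, report


def calibrate_rate(pairs: list[OrthologPair] | list[float], t_split: float) -> RateCalibration:
    """Substitution rate from mean ortholog divergence: ``r = K̄ / (2 T)``.

    Accepts :class:`OrthologPair` objects or raw k values; saturated pairs
    are excluded from the mean and counted.
    """
    if t_split <= 0:
        raise ValueError("t_split must be positive")
    ks: list[float] = []
    n_sat = 0
    for p in pairs:
        if isinstance(p, OrthologPair):
            if p.distance.saturated:
                n_sat += 1
                continue
            ks.append(p.distance.k)
        else:
            ks.append(float(p))
    if not ks:
        raise ValueError("no usable pairs to calibrate from")
    k_mean = float(np.mean(ks))
    return RateCalibration(
        k_mean=k_mean,
        k_median=float(np.median(ks)),
        t_split=t_split,
        r=k_mean / (2.0 * t_split),
        n_pairs=len(ks),
        n_saturated=n_sat,
    )


def divergence_to_time(k: float, r: float) -> float:
    """Years since divergence: ``t = k / (2 r)``."""
    if r <= 0:
        raise ValueError("substitution rate must be positive")
    return k / (2.0 * r)


@dataclass
class DivergenceProfile:
    distances: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    mode_bin: tuple[float, float]
    n_pairs: int
    n_saturated: int


def divergence_profile(
    seqs: list[str], bin_width: float = 0.01, scoring: Scoring = DEFAULT_SCORING
) -> DivergenceProfile:
    """All-by-all pairwise K2P distances within one subfamily, binned.

    Requires >= 2 members; yields exactly n(n-1)/2 pair distances (saturated
    pairs excluded from the histogram and counted).
    """
    n = len(seqs)
    if n < 2:
        raise ValueError("divergence profile needs >= 2 members")
    ks = []
    n_sat = 0
    for i in range(n):
        for j in range(i + 1, n):
            d = kimura2p(seqs[i], seqs[j], scoring)
            if d.saturated:
                n_sat += 1
            else:
                ks.append(d.k)
    dist = np.array(ks)
    top = max(float(dist.max()), bin_width) if dist.size else bin_width
    edges = np.arange(0.0, top + bin_width, bin_width)
    if edges[-1] <= top:
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(dist, bins=edges)
    mode_i = int(np.argmax(counts))
    return DivergenceProfile(
        distances=dist,
        bin_edges=edges,
        counts=counts,
        mode_bin=(float(edges[mode_i]), float(edges[mode_i + 1])),
        n_pairs=n * (n - 1) // 2,
        n_saturated=n_sat,
    )


def compare_profiles(p1: DivergenceProfile, p2: DivergenceProfile) -> tuple[float, float]:
    """Welch t-test between two subfamilies' distance sets: (t, p-value)."""
    t, p = stats.ttest_ind(p1.distances, p2.distances, equal_var=False)
    return float(t), float(p)


@dataclass
class NJTree:
    tree: TreeNode = field(repr=False)
    n_negative_clamped: int = 0

    @property
    def newick(self) -> str:
        return str(self.tree).strip()

    def path_distance(self, a: str, b: str) -> float:
        return float(self.tree.find(a).distance(self.tree.find(b)))


def nj_tree(matrix: np.ndarray | pd.DataFrame, taxa: list[str] | None = None) -> NJTree:
    """Neighbor-joining tree from a symmetric zero-diagonal distance matrix.

    Negative branch-length estimates (a known NJ artifact on non-additive
    matrices) are clamped to zero and counted.  Taxon label order fixes the
    agglomeration tie-break, so output is deterministic.
    """
    if isinstance(matrix, pd.DataFrame):
        taxa = list(matrix.index)
        mat = matrix.to_numpy(dtype=float)
    else:
        mat = np.asarray(matrix, dtype=float)
        if taxa is None:
            taxa = [f"t{i + 1}" for i in range(mat.shape[0])]
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(mat), 0.0):
        raise ValueError("distance matrix diagonal must be zero")
    if mat.shape[0] == 2:
        tree = TreeNode.read([f"({taxa[0]}:{mat[0, 1]:.10g},{taxa[1]}:0.0);"])
        return NJTree(tree=tree, n_negative_clamped=0)
    dm = DistanceMatrix(mat, ids=taxa)
    tree = nj(dm, neg_as_zero=False)
    n_clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            n_clamped += 1
    return NJTree(tree=tree, n_negative_clamped=n_clamped)
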