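"""Two-genome simulator with planted CACTA-like elements and full ground truth.

The simulator emulates the statistical structure the downstream analyses
assume, so every stage of the pipeline can be validated against a known
answer:

* multi-chromosome background sequence at ~35% GC, built as a mosaic of
  AT-rich islands (lower GC) in a slightly GC-richer matrix, so that
  island-preferring insertion reproduces the empirical AT-richness of
  element flanks relative to the genome;
* subfamily-structured elements 330-446 bp long with 145-158 bp perfect
  terminal inverted repeats and 5'-CACTA ... TAGTG-3' termini;
* insertion with a 3-bp target site duplication (TSD) whose A/T ("W")
  content per position equals ``tsd_at_bias`` exactly by construction
  (the target 3-mer's W/S class pattern is drawn first, then a matching
  host site is located);
* chromosome-scale density structure: telomeric enrichment and centromeric
  depletion via region-weighted site sampling;
* an ancestral genome evolved along two branches of ``split_time`` years at
  ``substitution_rate`` substitutions/site/year under a Kimura-2P process
  (transition:transversion 2:1), so orthologous element pairs diverge by
  ~2*r*T; genome-specific insertions (and optionally precise excisions)
  applied per branch afterwards;
* synthetic multi-exon gene models with elements planted into introns or
  exons, written as GFF3.

Every planted copy is recorded in a truth table (one row per element per
genome) used by recovery and precision tests.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ckio
from .seqcore import reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_ENC = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].astype(np.int8)


def _decode(enc: np.ndarray) -> str:
    out = np.where(enc >= 0, _BASES[np.clip(enc, 0, 3)], np.uint8(ord("N")))
    return out.astype(np.uint8).tobytes().decode("ascii")


@dataclass
class SimulationConfig:
    """All knobs of the simulator; defaults are the study conditions.

    Lengths in bp, times in years, rates in substitutions/site/year.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 2_000_000
    background_gc: float = 0.35
    island_fraction: float = 0.25
    island_gc: float = 0.21
    island_weight: float = 10.0
    island_size: int = 2_000

    n_subfamilies: int = 4
    elements_per_subfamily: int = 100
    subfamily_divergence: float = 0.35
    copy_divergence: float = 0.035
    specific_divergence: float = 0.01
    element_length_range: tuple[int, int] = (330, 446)
    tir_length_range: tuple[int, int] = (145, 158)
    tsd_at_bias: float = 0.85

    telomere_fraction: float = 0.05
    telomere_enrichment: float = 3.0
    centromere_fraction: float = 0.20
    centromere_depletion: float = 0.2

    split_time: float = 110_000.0
    substitution_rate: float = 6.63e-8
    ts_tv_ratio: float = 2.0
    protect_motifs: bool = True

    n_truncated: int = 100
    truncated_length_range: tuple[int, int] = (160, 330)
    n_polymorphic_a: int = 30
    n_polymorphic_b: int = 30
    precise_excision_fraction: float = 0.0

    n_genes: int = 8
    n_genic_intron: int = 4
    n_genic_exon: int = 1
    n_genic_polymorphic: int = 2

    min_spacing: int = 700
    family_name: str = "CACTA1"

    def __post_init__(self) -> None:
        for name in ("background_gc", "island_fraction", "island_gc", "tsd_at_bias",
                     "copy_divergence", "specific_divergence", "precise_excision_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.element_length_range
        tlo, thi = self.tir_length_range
        if hi < lo or thi < tlo:
            raise ValueError("length ranges must be (low, high) with low <= high")
        if lo < 2 * tlo + 10:
            raise ValueError("element_length_range too small for tir_length_range")
        matrix_gc = (self.background_gc - self.island_fraction * self.island_gc) / (
            1.0 - self.island_fraction
        )
        if not 0.0 < matrix_gc < 1.0:
            raise ValueError("island_gc/island_fraction incompatible with background_gc")


@dataclass
class SimResult:
    """Simulated genomes, gene models, element library and ground truth."""

    genome_a: dict[str, str]
    genome_b: dict[str, str]
    truth: pd.DataFrame
    genes_a: list[dict]
    genes_b: list[dict]
    library: dict[str, str]
    regions_a: dict[str, list[tuple[int, int, str]]]
    regions_b: dict[str, list[tuple[int, int, str]]]
    config: SimulationConfig

    def centromere_bed(self, genome: str = "A") -> list[tuple[str, int, int]]:
        regions = self.regions_a if genome == "A" else self.regions_b
        return [
            (chrom, s, e)
            for chrom, items in regions.items()
            for (s, e, label) in items
            if label == "centromere"
        ]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ckio.write_fasta(outdir / "genome_A.fa", self.genome_a)
        ckio.write_fasta(outdir / "genome_B.fa", self.genome_b)
        ckio.write_fasta(outdir / "library.fa", self.library)
        ckio.write_tsv(outdir / "truth.tsv", self.truth)
        for g, genes, regions in (
            ("A", self.genes_a, self.regions_a),
            ("B", self.genes_b, self.regions_b),
        ):
            ckio.write_gff3(outdir / f"genes_{g}.gff3", genes)
            sub = self.truth[self.truth.genome == g]
            ckio.write_bed(
                outdir / f"truth_{g}.bed",
                [
                    (r.chrom, r.start, r.end, r.element_id, 0, r.strand)
                    for r in sub.itertuples()
                ],
            )
            ckio.write_bed(
                outdir / f"regions_{g}.bed",
                [
                    (chrom, s, e, label)
                    for chrom, items in regions.items()
                    for (s, e, label) in items
                ],
            )


# ---------------------------------------------------------------------------
# mutation machinery (Kimura-2P process, substitutions only)
# ---------------------------------------------------------------------------

def _substitute(
    enc: np.ndarray,
    p: float,
    rng: np.random.Generator,
    ts_tv_ratio: float,
    protected: np.ndarray | None = None,
) -> np.ndarray:
    """Apply per-site substitutions at probability ``p`` in place-safe copy.

    Transitions (A<->G, C<->T) occur with probability R/(R+1) per event; each
    transversion with probability 1/(2(R+1)).  Encoded as XOR: ^2 is the
    transition partner, ^1 and ^3 the two transversions.
    """
    if p <= 0:
        return enc.copy()
    out = enc.copy()
    mask = rng.random(enc.size) < p
    mask &= enc >= 0
    if protected is not None:
        mask &= ~protected
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return out
    u = rng.random(idx.size)
    p_ts = ts_tv_ratio / (ts_tv_ratio + 1.0)
    xor = np.where(u < p_ts, 2, np.where(u < p_ts + (1 - p_ts) / 2, 1, 3)).astype(np.int8)
    out[idx] = out[idx] ^ xor
    return out


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator, ts_tv_ratio: float = 2.0) -> str:
    """Point-mutate ``seq`` at per-site probability ``rate`` (K2P process)."""
    return _decode(_substitute(_encode(seq), rate, rng, ts_tv_ratio))


def _mutate_class_preserving(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute within the W/S class (A<->T, C<->G) at probability ``rate``.

    Used only to derive subfamily ancestors from the family consensus: it
    diverges the sequences without drifting their GC content, so the
    genome-wide base composition stays at its configured value.  The
    evolutionary divergence the pipeline *measures* (per-copy and per-branch
    mutation) always uses the K2P process instead.
    """
    enc = _encode(seq)
    out = enc.copy()
    mask = (rng.random(enc.size) < rate) & (enc >= 0)
    out[mask] ^= 3  # A(0)<->T(3), C(1)<->G(2)
    return _decode(out)


# ---------------------------------------------------------------------------
# background genome
# ---------------------------------------------------------------------------

def _random_chromosome(
    rng: np.random.Generator, length: int, cfg: SimulationConfig
) -> tuple[str, np.ndarray]:
    """One chromosome plus its AT-rich-island mask."""
    n_blocks = length // cfg.island_size
    n_islands = int(round(n_blocks * cfg.island_fraction))
    island_blocks = rng.choice(n_blocks, size=n_islands, replace=False) if n_islands else np.empty(0, int)
    island_mask = np.zeros(length, dtype=bool)
    for b in island_blocks:
        island_mask[b * cfg.island_size : (b + 1) * cfg.island_size] = True
    matrix_gc = (cfg.background_gc - cfg.island_fraction * cfg.island_gc) / (1.0 - cfg.island_fraction)
    gc_p = np.where(island_mask, cfg.island_gc, matrix_gc)
    is_gc = rng.random(length) < gc_p
    halves = rng.integers(0, 2, size=length)
    # A=0 C=1 G=2 T=3
    enc = np.where(is_gc, np.where(halves == 0, 1, 2), np.where(halves == 0, 0, 3)).astype(np.int8)
    return _decode(enc), island_mask


def random_genome(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> dict[str, str]:
    """Background-only genome (no planted elements) -- decoy input for
    precision tests."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    return {
        f"chr{i + 1:02d}": _random_chromosome(rng, cfg.chrom_length, cfg)[0]
        for i in range(cfg.n_chromosomes)
    }


def _region_table(length: int, cfg: SimulationConfig) -> list[tuple[int, int, str]]:
    tl = int(length * cfg.telomere_fraction)
    cs = int(length * (0.5 - cfg.centromere_fraction / 2))
    ce = int(length * (0.5 + cfg.centromere_fraction / 2))
    return [
        (0, tl, "telomere"),
        (cs, ce, "centromere"),
        (length - tl, length, "telomere"),
    ]


def _site_weights(length: int, island_mask: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    w = np.ones(length)
    for s, e, label in _region_table(length, cfg):
        w[s:e] *= cfg.telomere_enrichment if label == "telomere" else cfg.centromere_depletion
    w[island_mask] *= cfg.island_weight
    margin = 1_000
    w[:margin] = 0.0
    w[-margin:] = 0.0
    return w


# ---------------------------------------------------------------------------
# element construction
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.35) -> str:
    is_gc = rng.random(length) < gc
    halves = rng.integers(0, 2, size=length)
    enc = np.where(is_gc, np.where(halves == 0, 1, 2), np.where(halves == 0, 0, 3)).astype(np.int8)
    return _decode(enc)


def build_element(rng: np.random.Generator, length: int, tir_length: int, gc: float = 0.35) -> str:
    """A structurally perfect element: CACTA-led TIR, internal region,
    reverse-complement TIR ending in TAGTG."""
    if length < 2 * tir_length + 10:
        raise ValueError("element too short for the requested TIR length")
    tir5 = "CACTA" + _random_seq(rng, tir_length - 5, gc)
    internal = _random_seq(rng, length - 2 * tir_length, gc)
    return tir5 + internal + reverse_complement(tir5)


def _restructure(element: str, tir_length: int) -> str:
    """Re-impose perfect TIR symmetry and termini after mutation."""
    tir5 = "CACTA" + element[5:tir_length]
    internal = element[tir_length : len(element) - tir_length]
    return tir5 + internal + reverse_complement(tir5)


def _fix_termini(element: str) -> str:
    return "CACTA" + element[5:-5] + "TAGTG"


def plant_element(chrom: str, element: str, site: int) -> str:
    """Insert ``element`` at ``site``, duplicating the 3-bp target site.

    The 3-mer at ``[site, site+3)`` ends up on both sides of the element; the
    chromosome grows by ``len(element) + 3``.  The element occupies
    ``[site+3, site+3+len(element))`` in the returned sequence.
    """
    if site < 3 or site > len(chrom) - 3:
        raise ValueError(f"site {site} must be >= 3 bases from either end")
    return chrom[: site + 3] + element + chrom[site:]


# ---------------------------------------------------------------------------
# coordinate bookkeeping through insertions/deletions
# ---------------------------------------------------------------------------

class CoordinateShifter:
    """Maps coordinates through a set of insertions/deletions.

    Events are (position, delta) in the ORIGINAL coordinate system: an
    insertion of d bases at position p (sequence[:p] + new + sequence[p:])
    is (p, +d); a deletion of [p, p+d) is (p, -d).
    """

    def __init__(self, events: list[tuple[int, int]]):
        events = sorted(events)
        self._pos = np.array([p for p, _ in events], dtype=np.int64)
        self._cum = np.cumsum([d for _, d in events]).astype(np.int64) if events else np.empty(0, np.int64)

    def map_start(self, p: int) -> int:
        i = int(np.searchsorted(self._pos, p, side="right"))
        return p + (int(self._cum[i - 1]) if i else 0)

    def map_end(self, p: int) -> int:
        i = int(np.searchsorted(self._pos, p, side="left"))
        return p + (int(self._cum[i - 1]) if i else 0)


def _apply_insertions(chrom: str, insertions: list[tuple[int, str]]) -> str:
    """Insert strings at (ascending, distinct) original positions."""
    segments: list[str] = []
    prev = 0
    for pos, ins in sorted(insertions):
        segments.append(chrom[prev:pos])
        segments.append(ins)
        prev = pos
    segments.append(chrom[prev:])
    return "".join(segments)


def _apply_deletions(chrom: str, intervals: list[tuple[int, int]]) -> str:
    segments: list[str] = []
    prev = 0
    for s, e in sorted(intervals):
        segments.append(chrom[prev:s])
        prev = e
    segments.append(chrom[prev:])
    return "".join(segments)


# ---------------------------------------------------------------------------
# site selection
# ---------------------------------------------------------------------------

class _SiteSampler:
    """Weighted, spacing-constrained, TSD-class-matched insertion site draws."""

    def __init__(
        self,
        rng: np.random.Generator,
        chroms: dict[str, str],
        weights: dict[str, np.ndarray],
        cfg: SimulationConfig,
        forbidden: dict[str, list[tuple[int, int]]],
    ):
        self.rng = rng
        self.chroms = chroms
        self.cfg = cfg
        self.names = list(chroms)
        self.cum = {c: np.cumsum(weights[c]) for c in self.names}
        self.totals = np.array([self.cum[c][-1] for c in self.names])
        self.chosen: dict[str, list[int]] = {c: [] for c in self.names}
        self.forbidden = forbidden

    def _ok(self, chrom: str, site: int, spacing: int | None = None, ignore_forbidden: bool = False) -> bool:
        spacing = spacing if spacing is not None else self.cfg.min_spacing
        sites = self.chosen[chrom]
        i = bisect.bisect_left(sites, site)
        for j in (i - 1, i):
            if 0 <= j < len(sites) and abs(sites[j] - site) < spacing:
                return False
        if not ignore_forbidden:
            for s, e in self.forbidden.get(chrom, []):
                if s - self.cfg.min_spacing // 2 <= site < e + self.cfg.min_spacing // 2:
                    return False
        return True

    def _class_pattern(self) -> tuple[bool, ...]:
        return tuple(self.rng.random(3) < self.cfg.tsd_at_bias)

    def _match_forward(self, chrom: str, start: int, pattern: tuple[bool, ...], span: int = 400) -> int | None:
        seq = self.chroms[chrom]
        stop = min(start + span, len(seq) - 1_000)
        for p in range(start, stop):
            trimer = seq[p : p + 3]
            if all((c in "AT") == w for c, w in zip(trimer, pattern)):
                if self._ok(chrom, p):
                    return p
        return None

    def draw(
        self,
        chrom: str | None = None,
        interval: tuple[int, int] | None = None,
        max_tries: int = 400,
    ) -> tuple[str, int, str]:
        """Returns (chrom, site, tsd) or raises if packing is infeasible."""
        for _ in range(max_tries):
            pattern = self._class_pattern()
            if chrom is None:
                ci = int(self.rng.choice(len(self.names), p=self.totals / self.totals.sum()))
                c = self.names[ci]
                u = self.rng.random() * self.cum[c][-1]
                pos = int(np.searchsorted(self.cum[c], u))
            else:
                c = chrom
                lo, hi = interval
                if hi - lo < 60:
                    continue
                pos = int(self.rng.integers(lo, hi - 3))
            if interval is not None:
                site = None
                seq = self.chroms[c]
                for p in range(pos, min(pos + 400, interval[1] - 3)):
                    if all((ch in "AT") == w for ch, w in zip(seq[p : p + 3], pattern)) and self._ok(
                        c, p, spacing=min(self.cfg.min_spacing, 450), ignore_forbidden=True
                    ):
                        site = p
                        break
            else:
                site = self._match_forward(c, pos, pattern)
            if site is not None:
                bisect.insort(self.chosen[c], site)
                return c, site, self.chroms[c][site : site + 3]
        raise RuntimeError(
            "could not place an insertion site: too many elements for the sequence length/spacing"
        )


def _draw_in_gene(sampler: "_SiteSampler", rng: np.random.Generator, gene: "_Gene", feature: str):
    """Insertion site inside a (re-drawn per attempt) intron or exon of a gene."""
    for _ in range(30):
        if feature == "intron":
            ivs = gene.introns
            which = int(rng.integers(len(ivs)))
            lo, hi = ivs[which]
            ordinal = gene.intron_ordinal(which)
        else:
            which = 1 if len(gene.exons) > 2 else 0  # internal exon: safely inside the CDS
            lo, hi = gene.exons[which]
            ordinal = gene.exon_ordinal(which)
        try:
            c, site, tsd = sampler.draw(chrom=gene.chrom, interval=(lo + 25, hi - 28), max_tries=40)
            return c, site, tsd, ordinal
        except RuntimeError:
            continue
    raise RuntimeError(
        f"could not place an insertion site: too many elements for gene {gene.gene_id}"
    )


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass
class _Gene:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]  # plus-strand order

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)]

    def intron_ordinal(self, index_plus: int) -> int:
        """Transcript-orientation ordinal (1-based) of plus-order intron index."""
        n = len(self.exons) - 1
        return index_plus + 1 if self.strand == "+" else n - index_plus

    def exon_ordinal(self, index_plus: int) -> int:
        n = len(self.exons)
        return index_plus + 1 if self.strand == "+" else n - index_plus


def _place_genes(
    rng: np.random.Generator, chroms: dict[str, str], cfg: SimulationConfig
) -> list[_Gene]:
    genes: list[_Gene] = []
    names = list(chroms)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in names}
    for gi in range(cfg.n_genes):
        for _ in range(200):
            c = names[int(rng.integers(len(names)))]
            length = len(chroms[c])
            n_exons = int(rng.integers(3, 6))
            exon_lens = rng.integers(150, 351, size=n_exons)
            intron_lens = rng.integers(900, 1401, size=n_exons - 1)
            span = int(exon_lens.sum() + intron_lens.sum())
            # arms only: outside centromere and telomeres
            tl = int(length * cfg.telomere_fraction)
            cs = int(length * (0.5 - cfg.centromere_fraction / 2))
            ce = int(length * (0.5 + cfg.centromere_fraction / 2))
            windows = [(tl + 2_000, cs - span - 2_000), (ce + 2_000, length - tl - span - 2_000)]
            lo, hi = windows[int(rng.integers(2))]
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            end = start + span
            if any(s - 3_000 < end and start < e + 3_000 for s, e in occupied[c]):
                continue
            exons = []
            pos = start
            for i in range(n_exons):
                exons.append((pos, pos + int(exon_lens[i])))
                pos += int(exon_lens[i])
                if i < n_exons - 1:
                    pos += int(intron_lens[i])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(_Gene(f"gene{gi + 1:03d}", c, start, end, strand, exons))
            occupied[c].append((start, end))
            break
        else:
            raise RuntimeError("could not place gene models")
    return genes


def _gene_features(genes: list[_Gene], shifters: dict[str, CoordinateShifter]) -> list[dict]:
    """GFF3 feature dicts (gene/mRNA/exon/CDS/UTR) with shifted coordinates."""
    feats: list[dict] = []
    for g in genes:
        sh = shifters[g.chrom]
        exons = [(sh.map_start(s), sh.map_end(e)) for s, e in g.exons]
        gs, ge = exons[0][0], exons[-1][1]
        mrna_id = f"{g.gene_id}.1"
        feats.append(dict(chrom=g.chrom, type="gene", start=gs, end=ge, strand=g.strand,
                          attributes={"ID": g.gene_id}))
        feats.append(dict(chrom=g.chrom, type="mRNA", start=gs, end=ge, strand=g.strand,
                          attributes={"ID": mrna_id, "Parent": g.gene_id}))
        # UTRs in transcript orientation: 60 bp 5' in the first exon, 80 bp 3' in the last
        if g.strand == "+":
            utr5 = (exons[0][0], exons[0][0] + 60)
            utr3 = (exons[-1][1] - 80, exons[-1][1])
        else:
            utr5 = (exons[-1][1] - 60, exons[-1][1])
            utr3 = (exons[0][0], exons[0][0] + 80)
        for i, (s, e) in enumerate(exons):
            feats.append(dict(chrom=g.chrom, type="exon", start=s, end=e, strand=g.strand,
                              attributes={"ID": f"{mrna_id}.exon{i + 1}", "Parent": mrna_id}))
            cds_s, cds_e = s, e
            # carve UTRs out of the terminal exons
            if utr5[0] >= s and utr5[1] <= e:
                if g.strand == "+":
                    cds_s = max(cds_s, utr5[1])
                else:
                    cds_e = min(cds_e, utr5[0])
            if utr3[0] >= s and utr3[1] <= e:
                if g.strand == "+":
                    cds_e = min(cds_e, utr3[0])
                else:
                    cds_s = max(cds_s, utr3[1])
            if cds_e > cds_s:
                feats.append(dict(chrom=g.chrom, type="CDS", start=cds_s, end=cds_e, strand=g.strand,
                                  attributes={"ID": f"{mrna_id}.cds", "Parent": mrna_id}))
        for utr, utype in ((utr5, "five_prime_UTR"), (utr3, "three_prime_UTR")):
            feats.append(dict(chrom=g.chrom, type=utype, start=utr[0], end=utr[1], strand=g.strand,
                              attributes={"ID": f"{mrna_id}.{utype}", "Parent": mrna_id}))
    feats.sort(key=lambda f: (f["chrom"], f["start"], f["type"] != "gene"))
    return feats


# ---------------------------------------------------------------------------
# the simulator proper
# ---------------------------------------------------------------------------

@dataclass
class _Planted:
    """Internal: one insertion decision before coordinates are final."""

    element_id: str
    kind: str  # shared | truncated | spec_a | spec_b
    subfamily: str
    seq: str  # as inserted on the plus strand
    strand: str
    chrom: str
    site: int  # ancestral coordinate
    tsd: str | None
    complete: bool
    gene_id: str = ""
    gene_feature: str = ""
    gene_ordinal: int = 0


def _make_copies(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    ancestors: dict[str, str],
) -> list[tuple[str, str]]:
    """(subfamily, copy sequence) for all shared complete elements."""
    out = []
    for sf, anc in ancestors.items():
        for _ in range(cfg.elements_per_subfamily):
            copy = _fix_termini(mutate_sequence(anc, cfg.copy_divergence, rng, cfg.ts_tv_ratio))
            out.append((sf, copy))
    return out


def simulate_pair(cfg: SimulationConfig) -> SimResult:
    """Simulate a diverged genome pair with planted elements and ground truth."""
    rng = np.random.default_rng(cfg.seed)
    names = [f"chr{i + 1:02d}" for i in range(cfg.n_chromosomes)]
    chroms: dict[str, str] = {}
    islands: dict[str, np.ndarray] = {}
    for c in names:
        chroms[c], islands[c] = _random_chromosome(rng, cfg.chrom_length, cfg)
    weights = {c: _site_weights(len(chroms[c]), islands[c], cfg) for c in names}

    genes = _place_genes(rng, chroms, cfg)
    forbidden = {c: [] for c in names}
    for g in genes:
        forbidden[g.chrom].append((g.start, g.end))

    # --- element sequences -------------------------------------------------
    e_lo, e_hi = cfg.element_length_range
    t_lo, t_hi = cfg.tir_length_range
    elen = int(rng.integers(e_lo, e_hi + 1))
    tlen = int(rng.integers(t_lo, min(t_hi, (elen - 10) // 2) + 1))
    consensus = build_element(rng, elen, tlen, cfg.background_gc)
    ancestors: dict[str, str] = {}
    for i in range(cfg.n_subfamilies):
        sf = f"SF{i + 1}"
        mutated = _mutate_class_preserving(consensus, cfg.subfamily_divergence, rng)
        ancestors[sf] = _restructure(mutated, tlen)
    library = {f"{cfg.family_name}_{sf}": seq for sf, seq in ancestors.items()}

    shared = _make_copies(rng, cfg, ancestors)
    sf_cycle = list(ancestors)

    # --- plan insertions (all sites in ancestral coordinates) --------------
    sampler = _SiteSampler(rng, chroms, weights, cfg, forbidden)
    planted: list[_Planted] = []
    counter = 0

    def next_id(prefix: str) -> str:
        nonlocal counter
        counter += 1
        return f"{prefix}{counter:05d}"

    # genic shared elements first (restricted placement); gene 0 gets two
    genic_plan: list[tuple[int, str]] = []
    gene_assign = [0, 0] + list(range(1, max(1, cfg.n_genic_intron - 1)))
    for k in range(cfg.n_genic_intron):
        genic_plan.append((gene_assign[k % len(gene_assign)] % len(genes), "intron"))
    for k in range(cfg.n_genic_exon):
        genic_plan.append(((cfg.n_genic_intron + k + 1) % len(genes), "exon"))

    shared_iter = iter(shared)
    for gene_idx, feature in genic_plan:
        g = genes[gene_idx]
        sf, seq = next(shared_iter)
        c, site, tsd, ordinal = _draw_in_gene(sampler, rng, g, feature)
        strand = "+" if rng.random() < 0.5 else "-"
        planted.append(_Planted(next_id("el"), "shared", sf, seq if strand == "+" else reverse_complement(seq),
                                strand, c, site, tsd, True, g.gene_id, feature, ordinal))

    for sf, seq in shared_iter:
        c, site, tsd = sampler.draw()
        strand = "+" if rng.random() < 0.5 else "-"
        planted.append(_Planted(next_id("el"), "shared", sf, seq if strand == "+" else reverse_complement(seq),
                                strand, c, site, tsd, True))

    f_lo, f_hi = cfg.truncated_length_range
    for i in range(cfg.n_truncated):
        sf = sf_cycle[i % len(sf_cycle)]
        copy = _fix_termini(mutate_sequence(ancestors[sf], cfg.copy_divergence, rng, cfg.ts_tv_ratio))
        flen = int(rng.integers(f_lo, min(f_hi, len(copy) - 10) + 1))
        frag = copy[:flen] if rng.random() < 0.5 else copy[-flen:]
        c, site, _ = sampler.draw()
        strand = "+" if rng.random() < 0.5 else "-"
        planted.append(_Planted(next_id("tr"), "truncated", sf, frag if strand == "+" else reverse_complement(frag),
                                strand, c, site, None, False))

    n_exc_from_b = int(round(cfg.precise_excision_fraction * cfg.n_polymorphic_a))
    n_exc_from_a = int(round(cfg.precise_excision_fraction * cfg.n_polymorphic_b))
    spec_counts = {"spec_a": cfg.n_polymorphic_a - n_exc_from_b, "spec_b": cfg.n_polymorphic_b - n_exc_from_a}
    genic_spec_done = 0
    for kind, n in spec_counts.items():
        for i in range(n):
            sf = sf_cycle[int(rng.integers(len(sf_cycle)))]
            seq = _fix_termini(mutate_sequence(ancestors[sf], cfg.specific_divergence, rng, cfg.ts_tv_ratio))
            strand = "+" if rng.random() < 0.5 else "-"
            if kind == "spec_a" and genic_spec_done < cfg.n_genic_polymorphic and cfg.n_genes:
                g = genes[(genic_spec_done + 3) % len(genes)]
                c, site, tsd, ordinal = _draw_in_gene(sampler, rng, g, "intron")
                planted.append(_Planted(next_id("pa"), kind, sf, seq if strand == "+" else reverse_complement(seq),
                                        strand, c, site, tsd, True, g.gene_id, "intron", ordinal))
                genic_spec_done += 1
                continue
            c, site, tsd = sampler.draw()
            prefix = "pa" if kind == "spec_a" else "pb"
            planted.append(_Planted(next_id(prefix), kind, sf, seq if strand == "+" else reverse_complement(seq),
                                    strand, c, site, tsd, True))

    # elements excised from one branch: planted ancestrally, removed later
    excise_from_a: list[_Planted] = []
    excise_from_b: list[_Planted] = []
    for target_list, n, prefix in ((excise_from_a, n_exc_from_a, "pb"), (excise_from_b, n_exc_from_b, "pa")):
        for _ in range(n):
            sf = sf_cycle[int(rng.integers(len(sf_cycle)))]
            seq = _fix_termini(mutate_sequence(ancestors[sf], cfg.specific_divergence, rng, cfg.ts_tv_ratio))
            c, site, tsd = sampler.draw()
            strand = "+" if rng.random() < 0.5 else "-"
            rec = _Planted(next_id(prefix), "shared", sf, seq if strand == "+" else reverse_complement(seq),
                           strand, c, site, tsd, True)
            target_list.append(rec)
            planted.append(rec)

    # --- build the ancestral genome with shared + truncated insertions -----
    ancestral_records = [p for p in planted if p.kind in ("shared", "truncated")]
    spec_records = {"spec_a": [p for p in planted if p.kind == "spec_a"],
                    "spec_b": [p for p in planted if p.kind == "spec_b"]}

    anc_chroms: dict[str, str] = {}
    anc_coords: dict[str, tuple[int, int]] = {}  # element_id -> (start, end) in ancestral-with-elements coords
    shifters: dict[str, CoordinateShifter] = {}
    for c in names:
        recs = sorted((p for p in ancestral_records if p.chrom == c), key=lambda p: p.site)
        insertions = []
        events = []
        for p in recs:
            if p.tsd is not None:
                ins_pos = p.site + 3
                ins_str = p.seq + chroms[c][p.site : p.site + 3]
            else:
                ins_pos = p.site
                ins_str = p.seq
            insertions.append((ins_pos, ins_str))
            events.append((ins_pos, len(ins_str)))
        anc_chroms[c] = _apply_insertions(chroms[c], insertions)
        shifters[c] = CoordinateShifter(events)
        offset = 0
        for p, (ins_pos, ins_str) in zip(recs, insertions):
            start = ins_pos + offset
            anc_coords[p.element_id] = (start, start + len(p.seq))
            offset += len(ins_str)

    # --- evolve the two branches -------------------------------------------
    p_sub = cfg.substitution_rate * cfg.split_time
    protected: dict[str, np.ndarray] = {}
    for c in names:
        mask = np.zeros(len(anc_chroms[c]), dtype=bool)
        if cfg.protect_motifs:
            for p in ancestral_records:
                if p.chrom != c or not p.complete:
                    continue
                s, e = anc_coords[p.element_id]
                mask[s - 3 : s + 5] = True
                mask[e - 5 : e + 3] = True
            for kind in ("spec_a", "spec_b"):
                for p in spec_records[kind]:
                    if p.chrom != c:
                        continue
                    s_site = shifters[c].map_start(p.site)
                    mask[s_site : s_site + 3] = True
        protected[c] = mask

    branch: dict[str, dict[str, str]] = {}
    for g in ("A", "B"):
        gen = {}
        for c in names:
            enc = _encode(anc_chroms[c])
            gen[c] = _decode(_substitute(enc, p_sub, rng, cfg.ts_tv_ratio, protected[c]))
        branch[g] = gen

    # --- branch-specific events --------------------------------------------
    truth_rows: list[dict] = []
    genome_out: dict[str, dict[str, str]] = {}
    branch_shifters: dict[str, dict[str, CoordinateShifter]] = {}
    excisions = {"A": excise_from_a, "B": excise_from_b}
    for g, kind in (("A", "spec_a"), ("B", "spec_b")):
        gen = branch[g]
        exc_ids = {p.element_id for p in excisions[g]}
        del_events: dict[str, list[tuple[int, int]]] = {c: [] for c in names}
        for p in excisions[g]:
            s, e = anc_coords[p.element_id]
            del_events[p.chrom].append((s, e + 3))  # element + one TSD copy
        gen2 = {}
        post_del_shift: dict[str, CoordinateShifter] = {}
        for c in names:
            gen2[c] = _apply_deletions(gen[c], del_events[c])
            post_del_shift[c] = CoordinateShifter([(s, -(e - s)) for s, e in del_events[c]])
        # branch-specific insertions at mapped ancestral sites
        ins_by_chrom: dict[str, list[tuple[int, str, _Planted]]] = {c: [] for c in names}
        for p in spec_records[kind]:
            site_b = post_del_shift[p.chrom].map_start(shifters[p.chrom].map_start(p.site))
            tsd_now = gen2[p.chrom][site_b : site_b + 3]
            ins_by_chrom[p.chrom].append((site_b, p.seq + tsd_now, p))
        final = {}
        fshift: dict[str, CoordinateShifter] = {}
        spec_coords: dict[str, tuple[int, int]] = {}
        for c in names:
            triples = sorted(ins_by_chrom[c])
            final[c] = _apply_insertions(gen2[c], [(pos + 3, s) for pos, s, _ in triples])
            fshift[c] = CoordinateShifter([(pos + 3, len(s)) for pos, s, _ in triples])
            offset = 0
            for pos, s, p in triples:
                start = pos + 3 + offset
                spec_coords[p.element_id] = (start, start + len(p.seq))
                offset += len(s)
        genome_out[g] = final
        branch_shifters[g] = {
            c: _compose_shifters(shifters[c], post_del_shift[c], fshift[c]) for c in names
        }

        # truth rows for this genome
        for p in ancestral_records:
            if p.element_id in exc_ids:
                continue
            s, e = anc_coords[p.element_id]
            c = p.chrom
            s2 = fshift[c].map_start(post_del_shift[c].map_start(s))
            e2 = fshift[c].map_end(post_del_shift[c].map_end(e))
            is_shared = p.kind == "shared" and p.element_id not in {
                q.element_id for q in excisions["A"] + excisions["B"]
            }
            truth_rows.append(dict(
                element_id=f"{g}_{p.element_id}", genome=g, chrom=c, start=s2, end=e2,
                strand=p.strand, subfamily=p.subfamily, complete=p.complete,
                tsd=p.tsd or "", shared=is_shared,
                ortholog_id=p.element_id if is_shared else "",
                origin="excision" if (p.kind == "shared" and not is_shared) else p.kind,
                gene_id=p.gene_id, gene_feature=p.gene_feature, gene_ordinal=p.gene_ordinal,
                length=len(p.seq),
            ))
        for p in spec_records[kind]:
            s, e = spec_coords[p.element_id]
            truth_rows.append(dict(
                element_id=f"{g}_{p.element_id}", genome=g, chrom=p.chrom, start=s, end=e,
                strand=p.strand, subfamily=p.subfamily, complete=p.complete,
                tsd=p.tsd or "", shared=False, ortholog_id="", origin="specific",
                gene_id=p.gene_id, gene_feature=p.gene_feature, gene_ordinal=p.gene_ordinal,
                length=len(p.seq),
            ))

    truth = pd.DataFrame(truth_rows).sort_values(["genome", "chrom", "start"]).reset_index(drop=True)

    genes_out = {}
    regions_out = {}
    for g in ("A", "B"):
        genes_out[g] = _gene_features(genes, branch_shifters[g])
        regions_out[g] = {
            c: [
                (branch_shifters[g][c].map_start(s), branch_shifters[g][c].map_end(e), label)
                for s, e, label in _region_table(len(chroms[c]), cfg)
            ]
            for c in names
        }

    return SimResult(
        genome_a=genome_out["A"],
        genome_b=genome_out["B"],
        truth=truth,
        genes_a=genes_out["A"],
        genes_b=genes_out["B"],
        library=library,
        regions_a=regions_out["A"],
        regions_b=regions_out["B"],
        config=cfg,
    )


def _compose_shifters(*stages: CoordinateShifter):
    class _Composed:
        def map_start(self, p: int) -> int:
            for st in stages:
                p = st.map_start(p)
            return p

        def map_end(self, p: int) -> int:
            for st in stages:
                p = st.map_end(p)
            return p

    return _Composed()


def config_to_dict(cfg: SimulationConfig) -> dict:
    return asdict(cfg)
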