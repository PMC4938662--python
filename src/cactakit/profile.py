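"""Insertion-site nucleotide bias: context extraction, position frequency
matrix (PFM), and GC summaries.

The PFM covers the 3-bp target site duplication (counted once — it flanks
both sides of the element) plus ``flank`` bp on each side, labeled
-200..-1, TSD1..TSD3, +1..+200 for the default full window (403 columns),
or the 23-column logo window (-10..-1, TSD1..3, +1..+10) for export to
sequence-logo tools.  Contexts are orientation-normalized to the element
strand by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discovery import TEElement
from .seqcore import reverse_complement

logger = logging.getLogger(__name__)

_BASE_ORDER = "ACGT"
_ENC = {b: i for i, b in enumerate(_BASE_ORDER)}


@dataclass
class PositionFrequencyMatrix:
    labels: list[str]
    counts: np.ndarray  # (positions, 4) A C G T
    n_elements: int
    flank: int

    @property
    def fractions(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.counts / totals, 0.0)

    @property
    def gc_per_position(self) -> np.ndarray:
        f = self.fractions
        return f[:, 1] + f[:, 2]

    def tsd_slice(self) -> slice:
        return slice(self.flank, self.flank + 3)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(_BASE_ORDER))
        df.insert(0, "position", self.labels)
        frac = self.fractions
        for i, b in enumerate(_BASE_ORDER):
            df[f"f{b}"] = frac[:, i]
        df["gc"] = self.gc_per_position
        return df


def extract_site_context(
    elements: list[TEElement],
    genome: dict[str, str],
    flank: int = 200,
    orient: bool = True,
) -> tuple[list[tuple[str, str]], int]:
    """Per-element insertion-site context strings.

    Each context is upstream-flank + one TSD copy + downstream-flank in the
    element's own orientation (when ``orient``), with the TSD copies
    themselves excluded from the flanks.  Elements closer than ``flank`` bp
    (plus the TSD) to a contig edge are dropped and counted; elements
    without a TSD are skipped with a warning.

    Returns (list of (element_id, context), n_dropped_at_edges).
    """
    contexts: list[tuple[str, str]] = []
    dropped = 0
    for el in elements:
        if not el.tsd:
            logger.warning("element %s has no TSD; skipped from site profile", el.element_id)
            continue
        seq = genome[el.chrom]
        if el.start - 3 - flank < 0 or el.end + 3 + flank > len(seq):
            dropped += 1
            continue
        up = seq[el.start - 3 - flank : el.start - 3]
        tsd = seq[el.start - 3 : el.start]
        down = seq[el.end + 3 : el.end + 3 + flank]
        if orient and el.strand == "-":
            context = reverse_complement(down) + reverse_complement(tsd) + reverse_complement(up)
        else:
            context = up + tsd + down
        contexts.append((el.element_id, context))
    return contexts, dropped


def position_labels(flank: int) -> list[str]:
    return (
        [str(-i) for i in range(flank, 0, -1)]
        + ["TSD1", "TSD2", "TSD3"]
        + [f"+{i}" for i in range(1, flank + 1)]
    )


def build_pfm(
    contexts: list[tuple[str, str]], window: str = "full", flank: int = 200
) -> PositionFrequencyMatrix:
    """Per-position base counts over contexts.

    ``window="full"`` keeps all 2*flank+3 positions; ``window="logo"``
    slices the 10+3+10 central window.  N observations are excluded per
    position (not per element).
    """
    if not contexts:
        raise ValueError("need at least one context")
    width = 2 * flank + 3
    if window == "logo":
        lo, hi = flank - 10, flank + 13
        eff_flank = 10
    elif window == "full":
        lo, hi = 0, width
        eff_flank = flank
    else:
        raise ValueError(f"unknown window {window!r}")
    counts = np.zeros((hi - lo, 4), dtype=np.int64)
    for _, ctx in contexts:
        if len(ctx) != width:
            raise ValueError("context length does not match flank")
        for j, base in enumerate(ctx[lo:hi]):
            i = _ENC.get(base)
            if i is not None:
                counts[j, i] += 1
    return PositionFrequencyMatrix(
        labels=position_labels(eff_flank), counts=counts, n_elements=len(contexts), flank=eff_flank
    )


@dataclass
class SiteBiasReport:
    tsd_gc: list[float]          # per TSD position
    tsd_gc_mean: float
    tsd_w_fraction: float        # A/T fraction over TSD positions
    flank_gc_mean: float         # mean over flank positions
    genome_gc: float
    biased: bool                 # TSD GC < flank GC < genome GC

    def as_dict(self) -> dict:
        return {
            "tsd_gc_positions": self.tsd_gc,
            "tsd_gc_mean": self.tsd_gc_mean,
            "tsd_w_fraction": self.tsd_w_fraction,
            "flank_gc_mean": self.flank_gc_mean,
            "genome_gc": self.genome_gc,
            "biased": self.biased,
        }


def site_bias_report(pfm: PositionFrequencyMatrix, genome_gc: float) -> SiteBiasReport:
    """GC summaries of the insertion-site window vs. the genome background."""
    gc = pfm.gc_per_position
    tsd = pfm.tsd_slice()
    tsd_gc = [float(x) for x in gc[tsd]]
    flank_mask = np.ones(gc.size, dtype=bool)
    flank_mask[tsd] = False
    flank_gc = float(gc[flank_mask].mean())
    tsd_gc_mean = float(np.mean(tsd_gc))
    return SiteBiasReport(
        tsd_gc=tsd_gc,
        tsd_gc_mean=tsd_gc_mean,
        tsd_w_fraction=1.0 - tsd_gc_mean,
        flank_gc_mean=flank_gc,
        genome_gc=genome_gc,
        biased=tsd_gc_mean < flank_gc < genome_gc,
    )
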