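"""Chromosomal density of elements: windowed counts, per-chromosome density,
and centromere-vs-arm comparison.

Windows tile each chromosome (default 100 kb, last window partial); an
element is assigned to the window containing its start.  The region
comparison is a Welch (unequal-variance) two-sample t-test on window counts
inside vs. outside the supplied intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .discovery import TEElement


@dataclass
class DensityTrack:
    window_size: int
    windows: pd.DataFrame  # chrom, start, end, count, region
    per_chrom_density: dict[str, float]  # elements per Mb

    def counts(self, chrom: str) -> np.ndarray:
        return self.windows.loc[self.windows.chrom == chrom, "count"].to_numpy()


def window_counts(
    elements: list[TEElement],
    genome: dict[str, str],
    window_size: int = 100_000,
    centromeres: list[tuple[str, int, int]] | None = None,
) -> DensityTrack:
    """Windowed element counts along every chromosome.

    ``centromeres`` (chrom, start, end) intervals label windows whose
    midpoint falls inside an interval as "centromeric"; all others are
    "arm".  An element beyond its chromosome end is corrupt input and
    raises.
    """
    rows = []
    n_by_chrom: dict[str, int] = {c: 0 for c in genome}
    for el in elements:
        L = len(genome[el.chrom])
        if el.start >= L or el.end > L:
            raise ValueError(f"element {el.element_id} lies beyond the end of {el.chrom}")
        n_by_chrom[el.chrom] += 1
    for chrom, seq in genome.items():
        L = len(seq)
        starts = [el.start for el in elements if el.chrom == chrom]
        counts = np.histogram(starts, bins=np.append(np.arange(0, L, window_size), L))[0]
        w_starts = np.arange(0, L, window_size)
        w_ends = np.minimum(w_starts + window_size, L)
        regions = np.array(["arm"] * len(w_starts), dtype=object)
        if centromeres:
            mids = (w_starts + w_ends) / 2
            for c, s, e in centromeres:
                if c == chrom:
                    regions[(mids >= s) & (mids < e)] = "centromeric"
        for ws, we, cnt, reg in zip(w_starts, w_ends, counts, regions):
            rows.append(dict(chrom=chrom, start=int(ws), end=int(we), count=int(cnt), region=reg))
    df = pd.DataFrame(rows)
    density = {
        chrom: n_by_chrom[chrom] / (len(genome[chrom]) / 1e6) for chrom in genome
    }
    # conservation invariant: window counts sum to the element count per chromosome
    for chrom in genome:
        assert int(df.loc[df.chrom == chrom, "count"].sum()) == n_by_chrom[chrom]
    return DensityTrack(window_size=window_size, windows=df, per_chrom_density=density)


@dataclass
class RegionComparison:
    mean_inside: float
    mean_outside: float
    ratio: float
    t_statistic: float
    p_value: float
    n_inside: int
    n_outside: int
    test: str = "Welch two-sample t-test on window counts"


def region_compare(track: DensityTrack) -> RegionComparison:
    """Welch t-test of window counts: centromeric vs. arm windows."""
    df = track.windows
    inside = df.loc[df.region == "centromeric", "count"].to_numpy(float)
    outside = df.loc[df.region == "arm", "count"].to_numpy(float)
    for name, grp in (("centromeric", inside), ("arm", outside)):
        if grp.size < 2:
            raise ValueError(f"region {name!r} has fewer than 2 windows")
    if inside.std() == 0 and outside.std() == 0 and inside.mean() == outside.mean():
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(inside, outside, equal_var=False)
    mean_in, mean_out = float(inside.mean()), float(outside.mean())
    return RegionComparison(
        mean_inside=mean_in,
        mean_outside=mean_out,
        ratio=mean_in / mean_out if mean_out else float("nan"),
        t_statistic=float(t),
        p_value=float(p),
        n_inside=int(inside.size),
        n_outside=int(outside.size),
    )
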