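"""Breakpoint detection and recombination-event counting.

A breakpoint is a transition between consecutive non-NA calls with different
parental origins; NA runs are skipped, so a change of origin across missing
markers counts once.  The event position is taken as the midpoint of the
flanking informative markers.  Counts mix meiotic crossovers with any other
origin of a genotype transition (e.g. loss of heterozygosity): detection is
agnostic to the mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import NA, GenomeMap, GenotypeMatrix, Interval


@dataclass(frozen=True)
class Breakpoint:
    strain: str
    chrom: str
    left: int  # position of the last informative marker before the change
    right: int  # position of the first informative marker after the change

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.left + self.right)


@dataclass
class RecombinationSummary:
    per_strain: pd.Series  # events per strain
    mean: float
    min: int
    max: int


def detect_breakpoints(
    calls: np.ndarray, positions: np.ndarray, strain: str = "", chrom: str = ""
) -> list[Breakpoint]:
    """Breakpoints of one strain's call vector over one position-sorted
    chromosome."""
    calls = np.asarray(calls)
    positions = np.asarray(positions)
    informative = calls != NA
    idx = np.flatnonzero(informative)
    if len(idx) < 2:
        return []
    vals = calls[idx]
    change = np.flatnonzero(vals[:-1] != vals[1:])
    return [
        Breakpoint(strain, chrom, int(positions[idx[k]]), int(positions[idx[k + 1]]))
        for k in change
    ]


def all_breakpoints(population: GenotypeMatrix) -> list[Breakpoint]:
    out = []
    marker_df = population.markers.df
    for chrom in marker_df["chrom"].unique():
        cidx = population.markers.chrom_index(chrom)
        positions = marker_df["pos"].to_numpy()[cidx]
        for i, strain in enumerate(population.strains):
            out.extend(
                detect_breakpoints(population.calls[i, cidx], positions, strain, chrom)
            )
    return out


def count_events(population: GenotypeMatrix) -> RecombinationSummary:
    """Per-strain totals over chromosomes and population summary statistics."""
    counts = {s: 0 for s in population.strains}
    for bp in all_breakpoints(population):
        counts[bp.strain] += 1
    per_strain = pd.Series(counts, dtype=int)
    if len(per_strain) == 0:
        return RecombinationSummary(per_strain, float("nan"), 0, 0)
    return RecombinationSummary(
        per_strain=per_strain,
        mean=float(per_strain.mean()),
        min=int(per_strain.min()),
        max=int(per_strain.max()),
    )


def region_recombination(population: GenotypeMatrix, interval: Interval) -> float:
    """Breakpoint midpoints falling in ``interval``, per Mb per strain."""
    if interval.length <= 0:
        raise ValueError("zero-length region")
    n = population.n_strains
    if n == 0:
        return 0.0
    hits = sum(
        1
        for bp in all_breakpoints(population)
        if bp.chrom == interval.chrom and interval.start <= bp.midpoint <= interval.end
    )
    return hits / (interval.length / 1e6) / n


def tetrad_segregation_check(tetrad: GenotypeMatrix) -> np.ndarray:
    """Per-marker check that four sibling spores are consistent with 2:2
    segregation: no allele observed in more than two of the four spores."""
    if tetrad.n_strains != 4:
        raise ValueError(f"expected exactly 4 strains, got {tetrad.n_strains}")
    n1 = (tetrad.calls == 1).sum(axis=0)
    n2 = (tetrad.calls == 2).sum(axis=0)
    return (n1 <= 2) & (n2 <= 2)
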