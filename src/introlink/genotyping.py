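"""Parental-origin assignment from read counts, marker filtering, and
pseudomarker collapsing.

The assignment rule is deliberately strict: a cell is called only when read
depth exceeds ``min_coverage`` (strictly), every read carries the same base,
and that base matches one of the two parental alleles; otherwise the cell is
NA.  Marker filtering then removes non-coding markers (optionally), markers
with too many NA cells, and markers with distorted segregation.  Finally the
retained markers are collapsed onto an evenly spaced pseudomarker grid by
majority vote within a window, which cuts scan dimensionality while
preserving breakpoints in a low-recombination genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import NA, P1, P2, GenomeMap, GenotypeMatrix, MarkerSet
from .simulate import AlleleCounts


@dataclass
class GenotypingRules:
    """Cell-level and marker-level retention rules.

    ``min_coverage`` is a strict lower bound (more than 2x reads, i.e. at
    least 3).  ``balance_window`` is the P1-frequency interval inside which a
    marker is kept; ``balance_mode="keep_unbalanced"`` inverts the filter to
    retain only distorted markers (exposed for comparison because balance
    clauses are sometimes stated with the opposite polarity; not the
    default).
    """

    min_coverage: int = 2
    max_na_fraction: float = 0.30
    balance_window: tuple[float, float] = (0.30, 0.70)
    balance_mode: str = "remove_unbalanced"
    coding_only: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.max_na_fraction <= 1:
            raise ValueError("max_na_fraction outside [0, 1]")
        lo, hi = self.balance_window
        if not (0 <= lo <= hi <= 1):
            raise ValueError("balance_window must be within [0, 1]")
        if self.balance_mode not in ("remove_unbalanced", "keep_unbalanced"):
            raise ValueError(f"unknown balance_mode {self.balance_mode!r}")


@dataclass
class PseudomarkerGrid:
    """Evenly spaced pseudomarkers: one every ``spacing`` bp starting at
    spacing/2, each summarizing real markers within +-``window`` bp."""

    spacing: int = 3000
    window: int = 4000

    def __post_init__(self) -> None:
        if self.spacing <= 0 or self.window <= 0:
            raise ValueError("spacing and window must be > 0")

    def positions(self, chrom_length: int) -> np.ndarray:
        first = self.spacing // 2
        return np.arange(first, chrom_length + 1, self.spacing)


def assign_allelic_origin(
    counts: AlleleCounts,
    markers: MarkerSet | None = None,
    rules: GenotypingRules | None = None,
) -> GenotypeMatrix:
    """Call P1/P2/NA per cell from base counts.

    A cell is P1 iff total reads > ``min_coverage`` and every read carries
    the parent-1 base (allele frequency exactly 1); symmetrically for P2.
    Any mixture, any third base, or insufficient depth gives NA.
    """
    rules = rules or GenotypingRules()
    if markers is not None and markers is not counts.markers and not (markers == counts.markers):
        raise ValueError("counts reference a different marker set")
    total = counts.total
    deep = total > rules.min_coverage
    pure_p1 = deep & (counts.n_p1 == total)
    pure_p2 = deep & (counts.n_p2 == total)
    calls = np.where(pure_p1, P1, np.where(pure_p2, P2, NA)).astype(np.int8)
    return GenotypeMatrix(
        strains=list(counts.strains), markers=counts.markers, calls=calls
    )


def filter_markers(
    genotypes: GenotypeMatrix,
    rules: GenotypingRules | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply marker-level retention rules.

    Returns the filtered matrix and a report with one row per removed marker
    (columns ``chrom``, ``pos``, ``reason``).  Reasons are assigned in rule
    order — non_coding, na_fraction, segregation_distortion — so the report
    categories partition the removed set.
    """
    rules = rules or GenotypingRules()
    calls = genotypes.calls
    n = genotypes.n_strains
    na_frac = (calls == NA).mean(axis=0) if n else np.zeros(genotypes.n_markers)
    called = (calls != NA).sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(called > 0, (calls == P1).sum(axis=0) / np.maximum(called, 1), np.nan)

    coding = genotypes.markers.df["coding"].to_numpy(dtype=bool)
    lo, hi = rules.balance_window
    balanced = (freq >= lo) & (freq <= hi)
    # markers with no called cells cannot demonstrate balance
    balanced &= called > 0
    if rules.balance_mode == "keep_unbalanced":
        balance_ok = ~balanced
    else:
        balance_ok = balanced

    keep = np.ones(genotypes.n_markers, dtype=bool)
    reasons = np.full(genotypes.n_markers, "", dtype=object)
    if rules.coding_only:
        drop = ~coding
        reasons[drop & keep] = "non_coding"
        keep &= ~drop
    drop = na_frac >= rules.max_na_fraction
    reasons[drop & keep] = "na_fraction"
    keep &= ~drop
    drop = ~balance_ok
    reasons[drop & keep] = "segregation_distortion"
    keep &= ~drop

    report = genotypes.markers.df.loc[~keep, ["chrom", "pos"]].copy()
    report["reason"] = reasons[~keep]
    return genotypes.subset_markers(keep), report.reset_index(drop=True)


def collapse_pseudomarkers(
    genotypes: GenotypeMatrix,
    genome: GenomeMap,
    grid: PseudomarkerGrid | None = None,
    tie_break: str = "na",
) -> GenotypeMatrix:
    """Collapse marker calls onto the pseudomarker grid by majority vote.

    Per strain and pseudomarker, the call is the predominant non-NA call
    among markers within +-``window`` bp; ties and empty windows give NA
    (``tie_break="nearest"`` resolves ties by the nearest informative
    marker instead).
    """
    grid = grid or PseudomarkerGrid()
    if tie_break not in ("na", "nearest"):
        raise ValueError(f"unknown tie_break {tie_break!r}")
    s = genotypes.n_strains
    out_cols = []
    rows = []
    for chrom, length in genome.chromosomes:
        idx = genotypes.markers.chrom_index(chrom)
        positions = genotypes.markers.df["pos"].to_numpy()[idx]
        calls = genotypes.calls[:, idx]
        # prefix sums over the marker axis for O(1) window counts
        c1 = np.concatenate(
            [np.zeros((s, 1), dtype=np.int32), np.cumsum(calls == P1, axis=1)], axis=1
        )
        c2 = np.concatenate(
            [np.zeros((s, 1), dtype=np.int32), np.cumsum(calls == P2, axis=1)], axis=1
        )
        for p in grid.positions(length):
            lo = np.searchsorted(positions, p - grid.window, side="left")
            hi = np.searchsorted(positions, p + grid.window, side="right")
            n1 = c1[:, hi] - c1[:, lo]
            n2 = c2[:, hi] - c2[:, lo]
            col = np.where(n1 > n2, P1, np.where(n2 > n1, P2, NA)).astype(np.int8)
            if tie_break == "nearest":
                tied = (n1 == n2) & (n1 > 0)
                for i in np.flatnonzero(tied):
                    window_idx = np.arange(lo, hi)
                    informative = window_idx[calls[i, lo:hi] != NA]
                    j = informative[np.argmin(np.abs(positions[informative] - p))]
                    col[i] = calls[i, j]
            out_cols.append(col)
            rows.append((chrom, int(p)))
    pseudo_markers = MarkerSet(
        pd.DataFrame(
            {
                "chrom": [c for c, _ in rows],
                "pos": [p for _, p in rows],
                "p1_allele": "A",
                "p2_allele": "C",
                "coding": True,
            }
        )
    )
    calls = (
        np.stack(out_cols, axis=1) if out_cols else np.empty((s, 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        strains=list(genotypes.strains),
        markers=pseudo_markers,
        calls=calls,
        mating_types=genotypes.mating_types.copy(),
    )
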