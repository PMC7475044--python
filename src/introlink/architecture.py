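"""QTL-architecture summaries: local/distant classification, hotspot
detection, regional densities and the diversity vs local-eQTL-density
correlation.

"Local" is a positional proxy for cis regulation: an eQTL is local when its
target gene's midpoint falls inside the peak's support interval or within a
configurable buffer of the peak (default 50 kb, reflecting the broad support
intervals of a low-recombination cross).  The nonrecombining introgression is
treated as a single locus throughout: a gene inside it whose peak is also
inside it is local by definition, and the whole region forms one hotspot bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeMap, Interval
from .linkage import QTLCall


@dataclass
class HotspotBin:
    interval: Interval
    observed: int
    expected: float
    p_value: float
    significant: bool  # after Bonferroni correction over bins


@dataclass
class DensityPoint:
    label: str
    diversity: float  # mutations per kb (or %)
    local_eqtl_per_mb: float


def _gene_coords(genes: pd.DataFrame) -> dict[str, tuple[str, int]]:
    return {
        g["gene"]: (g["chrom"], int((g["start"] + g["end"]) // 2))
        for _, g in genes.iterrows()
    }


def classify_local_distant(
    calls: list[QTLCall],
    genes: pd.DataFrame,
    genome: GenomeMap | None = None,
    buffer_bp: int = 50_000,
) -> list[QTLCall]:
    """Label each eQTL call local or distant (in place; list returned).

    Local iff the target gene's midpoint lies within the support interval or
    within ``buffer_bp`` of the peak on the same chromosome.  Genes inside a
    nonrecombining interval with a peak inside the same interval are local,
    positions within the region being unidentifiable.
    """
    coords = _gene_coords(genes)
    for call in calls:
        if call.gene is None or call.gene not in coords:
            raise ValueError(f"call without gene coordinates: {call.gene!r}")
        chrom, mid = coords[call.gene]
        if chrom != call.chrom:
            call.label = "distant"
            continue
        if genome is not None:
            cold = [
                iv
                for iv in genome.cold_intervals(chrom)
                if iv.contains(chrom, call.peak_pos)
            ]
            if cold and cold[0].contains(chrom, mid):
                call.label = "local"
                continue
        local = call.support.contains(chrom, mid) or abs(mid - call.peak_pos) <= buffer_bp
        call.label = "local" if local else "distant"
    return calls


def _genome_bins(genome: GenomeMap, bin_size: int) -> list[Interval]:
    """Tile the genome in ``bin_size`` bins; each nonrecombining interval is
    a single bin and is excluded from the regular tiling."""
    bins: list[Interval] = []
    for chrom, _length in genome.chromosomes:
        for seg_start, seg_end in genome.recombinable_segments(chrom):
            start = seg_start
            while start <= seg_end:
                end = min(start + bin_size - 1, seg_end)
                bins.append(Interval(chrom, start, end))
                start = end + 1
        bins.extend(genome.cold_intervals(chrom))
    return bins


def detect_hotspots(
    calls: list[QTLCall],
    genome: GenomeMap,
    bin_size: int = 50_000,
    alpha: float = 0.05,
    distant_only: bool = False,
) -> list[HotspotBin]:
    """Poisson-excess hotspot bins, Bonferroni-corrected, merged when
    adjacent.

    The genome is tiled into ``bin_size`` bins (the nonrecombining region
    forming one bin of its own); each call's peak falls in one bin.  The
    expected count per bin is total calls x bin length / genome length, and
    significance is the Poisson upper tail, corrected over the number of
    bins.  For eQTL, pass ``distant_only=True`` — local calls cluster where
    genes are and carry no hotspot signal.  The test is this module's own
    formalization of hotspot description; treat boundaries as descriptive.
    """
    if not calls:
        raise ValueError("need at least one call")
    use = [c for c in calls if not distant_only or c.label == "distant"]
    bins = _genome_bins(genome, bin_size)
    counts = np.zeros(len(bins), dtype=int)
    for call in use:
        for b, iv in enumerate(bins):
            if iv.contains(call.chrom, call.peak_pos):
                counts[b] += 1
                break
    total_len = genome.total_length
    total = counts.sum()
    results = []
    for b, iv in enumerate(bins):
        expected = total * iv.length / total_len
        p = float(stats.poisson.sf(counts[b] - 1, expected)) if counts[b] > 0 else 1.0
        results.append(
            HotspotBin(
                interval=iv,
                observed=int(counts[b]),
                expected=float(expected),
                p_value=p,
                significant=bool(p * len(bins) < alpha and counts[b] > 1),
            )
        )
    return _merge_adjacent(results)


def _merge_adjacent(bins: list[HotspotBin]) -> list[HotspotBin]:
    """Merge runs of adjacent significant bins on the same chromosome into
    single hotspot bins (counts summed, smallest p kept)."""
    order = sorted(bins, key=lambda b: (b.interval.chrom, b.interval.start))
    out: list[HotspotBin] = []
    for b in order:
        prev = out[-1] if out else None
        if (
            prev is not None
            and prev.significant
            and b.significant
            and prev.interval.chrom == b.interval.chrom
            and prev.interval.end + 1 == b.interval.start
        ):
            out[-1] = HotspotBin(
                interval=Interval(
                    prev.interval.chrom, prev.interval.start, b.interval.end
                ),
                observed=prev.observed + b.observed,
                expected=prev.expected + b.expected,
                p_value=min(prev.p_value, b.p_value),
                significant=True,
            )
        else:
            out.append(b)
    return out


def significant_hotspots(bins: list[HotspotBin]) -> list[HotspotBin]:
    return [b for b in bins if b.significant]


def regional_density(
    calls: list[QTLCall],
    genes: pd.DataFrame,
    regions: list[Interval],
) -> pd.DataFrame:
    """Local-call density per region: calls whose target gene midpoint lies
    in the region, divided by region length in Mb.  Regions must be
    non-overlapping."""
    for a in regions:
        if a.length <= 0:
            raise ValueError("zero-length region")
    for i, a in enumerate(regions):
        for b in regions[i + 1 :]:
            if a.chrom == b.chrom and a.start <= b.end and b.start <= a.end:
                raise ValueError("overlapping regions")
    coords = _gene_coords(genes)
    rows = []
    for iv in regions:
        n = sum(
            1
            for c in calls
            if c.gene in coords and iv.contains(*coords[c.gene])
        )
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "n_calls": n,
                "per_mb": n / (iv.length / 1e6),
            }
        )
    return pd.DataFrame(rows)


def diversity_density_correlation(
    points: list[DensityPoint],
) -> dict[str, float]:
    """Pearson correlation between genetic diversity and local-eQTL density
    over regions/species, with the least-squares line and two-sided t-test."""
    if len(points) < 3:
        raise ValueError("need >= 3 points")
    x = np.array([p.diversity for p in points], dtype=float)
    y = np.array([p.local_eqtl_per_mb for p in points], dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one coordinate")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return {
        "r": float(r),
        "r2": float(r**2),
        "p_value": float(p),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
    }


def read_bed_regions(path, genome: GenomeMap | None = None) -> list[Interval]:
    """Read regions from a BED file (0-based half-open), converting to the
    package's 1-based inclusive convention."""
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split()[:3]
            regions.append(Interval(chrom, int(start) + 1, int(end)))
    if genome is not None:
        for iv in regions:
            if iv.chrom not in genome.chromosome_names or iv.end > genome.length(iv.chrom):
                raise ValueError(f"BED region outside genome: {iv}")
    return regions
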