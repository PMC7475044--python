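"""Genome description, marker sets, genotype matrices and their on-disk formats.

Coordinates are 1-based and intervals are inclusive on both ends throughout the
package.  Parental origin is abstracted to the labels ``P1``/``P2`` at the
matrix level (encoded internally as ``int8`` 1/2, with 0 for missing);
nucleotide identity is kept only on the marker table, where the read-level
observation model needs it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: integer codes used in every genotype call array
NA, P1, P2 = 0, 1, 2

CALL_TO_TOKEN = {NA: "NA", P1: "P1", P2: "P2"}
TOKEN_TO_CALL = {"NA": NA, "P1": P1, "P2": P2}


class GenomeError(ValueError):
    """Raised when a genome description violates its invariants."""


@dataclass(frozen=True)
class Interval:
    """A 1-based, both-ends-inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise GenomeError(
                f"interval {self.chrom}:{self.start}-{self.end}: start > end"
            )
        if self.start < 1:
            raise GenomeError(
                f"interval {self.chrom}:{self.start}-{self.end}: start < 1"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def in_region(chrom: str, pos: int, interval: Interval) -> bool:
    """True iff (chrom, pos) lies inside ``interval`` (inclusive ends)."""
    return interval.contains(chrom, pos)


@dataclass
class GenomeMap:
    """Chromosome structure, nonrecombining intervals, MAT locus and crossover rate.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    nonrecombining
        Intervals in which meiotic crossovers never occur (the introgressed
        region in the default genome).  Non-overlapping within a chromosome.
    mat_locus
        ``(chromosome, position)`` of the mating-type determinant.
    crossover_rate
        Expected crossovers per Mb of recombinable sequence per meiosis
        (counted over the four-chromatid bundle, not per spore).
    """

    chromosomes: list[tuple[str, int]]
    nonrecombining: list[Interval] = field(default_factory=list)
    mat_locus: tuple[str, int] | None = None
    crossover_rate: float = 4.1

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise GenomeError(f"duplicate chromosome names in {names}")
        for name, length in self.chromosomes:
            if length <= 0:
                raise GenomeError(f"chromosome {name}: length {length} <= 0")
        lengths = dict(self.chromosomes)
        by_chrom: dict[str, list[Interval]] = {}
        for iv in self.nonrecombining:
            if iv.chrom not in lengths:
                raise GenomeError(
                    f"nonrecombining interval on undeclared chromosome {iv.chrom!r}"
                )
            if iv.end > lengths[iv.chrom]:
                raise GenomeError(
                    f"nonrecombining interval {iv.chrom}:{iv.start}-{iv.end} "
                    f"exceeds chromosome length {lengths[iv.chrom]}"
                )
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            ivs = sorted(ivs, key=lambda i: i.start)
            for a, b in zip(ivs, ivs[1:]):
                if b.start <= a.end:
                    raise GenomeError(
                        f"overlapping nonrecombining intervals on {chrom}"
                    )
        if self.mat_locus is not None:
            chrom, pos = self.mat_locus
            if chrom not in lengths:
                raise GenomeError(f"mat_locus on undeclared chromosome {chrom!r}")
            if not 1 <= pos <= lengths[chrom]:
                raise GenomeError(f"mat_locus position {pos} outside {chrom}")
        if self.crossover_rate < 0:
            raise GenomeError(f"crossover_rate {self.crossover_rate} < 0")

    # -- queries ------------------------------------------------------------

    @property
    def chromosome_names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    def length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def cold_intervals(self, chrom: str) -> list[Interval]:
        return sorted(
            (iv for iv in self.nonrecombining if iv.chrom == chrom),
            key=lambda i: i.start,
        )

    def is_cold(self, chrom: str, pos: int) -> bool:
        return any(iv.contains(chrom, pos) for iv in self.nonrecombining)

    def recombinable_segments(self, chrom: str) -> list[tuple[int, int]]:
        """Maximal intervals of ``chrom`` outside all nonrecombining intervals."""
        segments = []
        cursor = 1
        for iv in self.cold_intervals(chrom):
            if iv.start > cursor:
                segments.append((cursor, iv.start - 1))
            cursor = iv.end + 1
        length = self.length(chrom)
        if cursor <= length:
            segments.append((cursor, length))
        return segments

    def recombinable_length(self, chrom: str) -> int:
        return sum(e - s + 1 for s, e in self.recombinable_segments(chrom))

    @property
    def total_recombinable_length(self) -> int:
        return sum(self.recombinable_length(c) for c in self.chromosome_names)


def default_genome(crossover_rate: float = 4.1) -> GenomeMap:
    """An 8-chromosome budding-yeast-like genome (~11.3 Mb) with a 1-Mb
    nonrecombining introgressed interval on the left arm of chromosome C
    carrying the MAT locus.

    The crossover rate default of 4.1 crossovers per recombinable Mb per
    meiosis yields ~14.7 detectable recombination events per spore.  A
    crossover is carried by two of the four chromatids, and a junction
    between chromatids that locally carry the same parental allele (e.g. in
    three-strand double crossovers) leaves no genotype trace, so the
    detectable mean is about 72% of rate x recombinable-Mb / 2.  The
    resulting map is that of a recombination-poor species several-fold below
    *S. cerevisiae*.
    """
    chromosomes = [
        ("A", 1_050_000),
        ("B", 1_300_000),
        ("C", 2_100_000),
        ("D", 1_600_000),
        ("E", 2_200_000),
        ("F", 1_500_000),
        ("G", 1_100_000),
        ("H", 450_000),
    ]
    return GenomeMap(
        chromosomes=chromosomes,
        nonrecombining=[Interval("C", 1, 1_000_000)],
        mat_locus=("C", 530_000),
        crossover_rate=crossover_rate,
    )


def load_genome(path: str | Path) -> GenomeMap:
    """Read a genome description from a YAML config file.

    Expected keys: ``chromosomes`` (list of ``{name, length}``),
    ``nonrecombining`` (list of ``{chrom, start, end}``), ``mat_locus``
    (``{chrom, position}``) and ``crossover_rate``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "chromosomes" not in raw:
        raise GenomeError(f"{path}: malformed genome config (no 'chromosomes' key)")
    try:
        chromosomes = [(str(c["name"]), int(c["length"])) for c in raw["chromosomes"]]
    except (KeyError, TypeError) as exc:
        raise GenomeError(f"{path}: malformed chromosome entry: {exc}") from exc
    nonrec = [
        Interval(str(iv["chrom"]), int(iv["start"]), int(iv["end"]))
        for iv in raw.get("nonrecombining", [])
    ]
    mat = raw.get("mat_locus")
    mat_locus = (str(mat["chrom"]), int(mat["position"])) if mat else None
    return GenomeMap(
        chromosomes=chromosomes,
        nonrecombining=nonrec,
        mat_locus=mat_locus,
        crossover_rate=float(raw.get("crossover_rate", 4.1)),
    )


def save_genome(genome: GenomeMap, path: str | Path) -> None:
    doc = {
        "chromosomes": [{"name": n, "length": l} for n, l in genome.chromosomes],
        "nonrecombining": [
            {"chrom": iv.chrom, "start": iv.start, "end": iv.end}
            for iv in genome.nonrecombining
        ],
        "crossover_rate": genome.crossover_rate,
    }
    if genome.mat_locus is not None:
        doc["mat_locus"] = {
            "chrom": genome.mat_locus[0],
            "position": genome.mat_locus[1],
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Markers
# ---------------------------------------------------------------------------


class MarkerSet:
    """Biallelic markers separating the two parents.

    Backed by a DataFrame with columns ``chrom``, ``pos``, ``p1_allele``,
    ``p2_allele``, ``coding``.  Positions are strictly increasing within a
    chromosome and the parental alleles differ at every marker.
    """

    COLUMNS = ["chrom", "pos", "p1_allele", "p2_allele", "coding"]

    def __init__(self, df: pd.DataFrame):
        df = df.reset_index(drop=True)
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise GenomeError(f"marker table missing columns {missing}")
        for chrom, grp in df.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise GenomeError(
                    f"marker positions not strictly increasing on {chrom}"
                )
        if (df["p1_allele"] == df["p2_allele"]).any():
            raise GenomeError("parental alleles identical at some marker")
        self.df = df[self.COLUMNS].copy()

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, MarkerSet) and self.df.equals(other.df)

    @property
    def ids(self) -> list[str]:
        return [f"{c}:{p}" for c, p in zip(self.df["chrom"], self.df["pos"])]

    def chrom_index(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.df["chrom"] == chrom).to_numpy())

    def positions(self, chrom: str) -> np.ndarray:
        return self.df.loc[self.df["chrom"] == chrom, "pos"].to_numpy()

    def subset(self, mask: np.ndarray) -> "MarkerSet":
        return MarkerSet(self.df.loc[np.asarray(mask)])

    def in_interval_mask(self, interval: Interval) -> np.ndarray:
        c = (self.df["chrom"] == interval.chrom).to_numpy()
        p = self.df["pos"].to_numpy()
        return c & (p >= interval.start) & (p <= interval.end)

    # -- IO -----------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "MarkerSet":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        df["coding"] = df["coding"].astype(bool)
        return cls(df)

    @classmethod
    def from_vcf(cls, path: str | Path, parent1: str, parent2: str) -> "MarkerSet":
        """Extract markers from a VCF: biallelic SNPs where the two named
        samples are homozygous for different alleles.  Everything else is
        skipped with a logged count."""
        from cyvcf2 import VCF  # optional dependency

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        try:
            i1, i2 = samples.index(parent1), samples.index(parent2)
        except ValueError as exc:
            raise GenomeError(f"parent sample missing from VCF: {exc}") from exc
        rows, skipped = [], 0
        for var in vcf:
            if not var.is_snp or len(var.ALT) != 1:
                skipped += 1
                continue
            g1, g2 = var.genotypes[i1], var.genotypes[i2]
            a1 = {g1[0], g1[1]} if len(g1) > 2 else {g1[0]}
            a2 = {g2[0], g2[1]} if len(g2) > 2 else {g2[0]}
            if len(a1) != 1 or len(a2) != 1 or a1 == a2 or -1 in a1 | a2:
                skipped += 1
                continue
            alleles = [var.REF] + var.ALT
            rows.append(
                {
                    "chrom": var.CHROM,
                    "pos": var.POS,
                    "p1_allele": alleles[a1.pop()],
                    "p2_allele": alleles[a2.pop()],
                    "coding": True,
                }
            )
        logger.info("from_vcf: kept %d markers, skipped %d records", len(rows), skipped)
        return cls(pd.DataFrame(rows))


def default_markers(
    genome: GenomeMap,
    density_per_kb: float = 7.0,
    coding_fraction: float = 0.72,
    seed: int | np.random.Generator = 0,
) -> MarkerSet:
    """Random marker set at a given density (the emulated cross differs at
    ~7 SNPs/kb, i.e. 0.7% divergence)."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    frames = []
    for chrom, length in genome.chromosomes:
        n = int(round(length / 1000 * density_per_kb))
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=n, replace=False))
        a1 = rng.integers(0, 4, size=n)
        a2 = (a1 + rng.integers(1, 4, size=n)) % 4
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "p1_allele": bases[a1],
                    "p2_allele": bases[a2],
                    "coding": rng.random(n) < coding_fraction,
                }
            )
        )
    return MarkerSet(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------


class GenotypeTableError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Strains x markers parental-origin calls.

    ``calls`` is ``int8`` with values in {0 (NA), 1 (P1), 2 (P2)};
    ``mating_types`` holds one of ``"a"``, ``"alpha"``, ``"unknown"`` per
    strain.
    """

    strains: list[str]
    markers: MarkerSet
    calls: np.ndarray
    mating_types: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.strains), len(self.markers)):
            raise GenotypeTableError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.strains)} strains x {len(self.markers)} markers"
            )
        if self.calls.size and (self.calls.min() < 0 or self.calls.max() > 2):
            raise GenotypeTableError("calls contain codes outside {0,1,2}")
        if self.mating_types is None:
            self.mating_types = np.array(["unknown"] * len(self.strains))
        else:
            self.mating_types = np.asarray(self.mating_types, dtype=object)
            if len(self.mating_types) != len(self.strains):
                raise GenotypeTableError("mating_types length mismatch")

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def chrom_calls(self, chrom: str) -> np.ndarray:
        return self.calls[:, self.markers.chrom_index(chrom)]

    def subset_markers(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            strains=list(self.strains),
            markers=self.markers.subset(mask),
            calls=self.calls[:, mask],
            mating_types=self.mating_types.copy(),
        )

    def subset_strains(self, idx: list[int]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            strains=[self.strains[i] for i in idx],
            markers=self.markers,
            calls=self.calls[idx],
            mating_types=self.mating_types[idx],
        )


def write_genotype_table(gm: GenotypeMatrix, path: str | Path) -> None:
    """TSV with a ``strain`` column followed by one ``chrom:pos`` column per
    marker, cells in {P1, P2, NA}."""
    tokens = np.array(["NA", "P1", "P2"])
    with open(path, "w") as fh:
        fh.write("strain\t" + "\t".join(gm.markers.ids) + "\n")
        for i, strain in enumerate(gm.strains):
            fh.write(strain + "\t" + "\t".join(tokens[gm.calls[i]]) + "\n")


def read_genotype_table(
    path: str | Path, markers: MarkerSet | None = None
) -> GenotypeMatrix:
    """Read a genotype TSV written by :func:`write_genotype_table`.

    If ``markers`` is given, its ``chrom:pos`` ids must match the header and
    its allele/coding annotation is attached; otherwise a minimal marker table
    is reconstructed from the header.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "strain":
            raise GenotypeTableError(f"{path}: first header field must be 'strain'")
        ids = header[1:]
        strains, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(ids) + 1:
                raise GenotypeTableError(
                    f"{path}:{lineno}: ragged row ({len(fields)} fields, "
                    f"expected {len(ids) + 1})"
                )
            strains.append(fields[0])
            row = np.empty(len(ids), dtype=np.int8)
            for j, tok in enumerate(fields[1:]):
                try:
                    row[j] = TOKEN_TO_CALL[tok]
                except KeyError:
                    raise GenotypeTableError(
                        f"{path}:{lineno}: unknown call token {tok!r} in "
                        f"column {ids[j]}"
                    ) from None
            rows.append(row)
    if markers is None:
        chroms, poss = zip(*(mid.rsplit(":", 1) for mid in ids)) if ids else ((), ())
        markers = MarkerSet(
            pd.DataFrame(
                {
                    "chrom": list(chroms),
                    "pos": [int(p) for p in poss],
                    "p1_allele": "A",
                    "p2_allele": "C",
                    "coding": True,
                }
            )
        )
    elif markers.ids != ids:
        raise GenotypeTableError(f"{path}: marker ids do not match supplied MarkerSet")
    calls = np.vstack(rows) if rows else np.empty((0, len(ids)), dtype=np.int8)
    return GenotypeMatrix(strains=strains, markers=markers, calls=calls)
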