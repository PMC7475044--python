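"""Generative models for the cross: tetrad meiosis with a nonrecombining
introgression, F1/F2 population designs, fitness traits with additive QTL,
expression counts with local/distant eQTL and hotspots, and read-level marker
observations.

The meiosis simulator does four-chromatid bookkeeping: each crossover is a
reciprocal exchange between two non-sister chromatids, so 2:2 segregation at
every heterozygous marker is exact by construction rather than approximate.
Crossover counts per chromosome are Poisson (no interference, no obligate
crossover — the emulated species is recombination-poor, with spores carrying
as few as 3 events over 8 chromosomes) and positions are uniform over the
recombinable portion of the chromosome, so the nonrecombining introgression
never receives a crossover.  The MAT allele travels with the chromatid that
carries it, which makes mating type perfectly linked to the introgression
haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import NA, P1, P2, GenomeMap, GenotypeMatrix, Interval, MarkerSet

_NON_SISTER_PAIRS = [(0, 2), (0, 3), (1, 2), (1, 3)]


@dataclass
class CrossoverModel:
    """Poisson crossover model without interference.

    ``rate`` is crossovers per Mb of recombinable sequence per meiosis over
    the whole four-chromatid bundle; a spore shows a breakpoint for a given
    crossover with probability 1/2 (it is visible in two of four chromatids).
    ``loh_rate`` optionally adds pre-meiotic loss-of-heterozygosity tracts to
    the parental diploid (apparent recombination from return-to-growth);
    off by default because it breaks exact 2:2 segregation where applied.
    """

    rate: float | None = None  # None -> use genome.crossover_rate
    loh_rate: float = 0.0
    loh_tract_bp: int = 20_000

    def __post_init__(self) -> None:
        if self.rate is not None and self.rate < 0:
            raise ValueError(f"crossover rate {self.rate} < 0")
        if self.loh_rate < 0:
            raise ValueError("loh_rate < 0")


@dataclass
class ObservationModel:
    """Read-level observation model for marker genotyping.

    Reads per cell are Poisson(``coverage_mean``); each read reports the true
    parental base with probability 1 - ``error_rate``, the other parental
    base with probability ``error_rate``/3, and a third base otherwise.
    """

    coverage_mean: float = 5.0
    error_rate: float = 0.005

    def __post_init__(self) -> None:
        if self.coverage_mean < 0:
            raise ValueError("coverage_mean < 0")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")


@dataclass
class TetradGenotypes:
    """The four spores of one meiosis."""

    spore_calls: np.ndarray  # 4 x n_markers, int8 in {1, 2}
    crossovers: dict[str, list[float]]  # chrom -> crossover positions (bp)
    mating_types: list[str]  # four entries in {"a", "alpha"}


@dataclass
class SimulationTruth:
    """Ground truth of a simulated dataset, sufficient for recovery tests."""

    seed: int | None = None
    crossovers: dict[str, dict[str, list[float]]] = field(default_factory=dict)
    qtl_spec: pd.DataFrame | None = None
    eqtl_spec: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Meiosis
# ---------------------------------------------------------------------------


def _draw_crossover_positions(
    genome: GenomeMap, chrom: str, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Poisson number of crossovers placed uniformly on the recombinable
    portion of ``chrom``; returns sorted bp positions (floats)."""
    segments = genome.recombinable_segments(chrom)
    seg_lengths = np.array([e - s + 1 for s, e in segments], dtype=float)
    total = seg_lengths.sum()
    if total <= 0 or rate <= 0:
        return np.empty(0)
    n = rng.poisson(rate * total / 1e6)
    if n == 0:
        return np.empty(0)
    u = rng.uniform(0.0, total, size=n)
    cum = np.concatenate([[0.0], np.cumsum(seg_lengths)])
    seg_idx = np.searchsorted(cum, u, side="right") - 1
    starts = np.array([s for s, _ in segments], dtype=float)
    return np.sort(starts[seg_idx] + (u - cum[seg_idx]))


def _apply_loh(
    h1: np.ndarray,
    h2: np.ndarray,
    positions: np.ndarray,
    genome: GenomeMap,
    chrom: str,
    model: CrossoverModel,
    rng: np.random.Generator,
) -> None:
    """Homogenize random tracts of the parental diploid in place."""
    events = _draw_crossover_positions(genome, chrom, model.loh_rate, rng)
    for p in events:
        lo, hi = p, p + model.loh_tract_bp
        mask = (positions > lo) & (positions <= hi)
        donor, recipient = (h1, h2) if rng.random() < 0.5 else (h2, h1)
        recipient[mask] = donor[mask]


def simulate_tetrad(
    genome: GenomeMap,
    markers: MarkerSet,
    parent1: np.ndarray | None = None,
    parent2: np.ndarray | None = None,
    model: CrossoverModel | None = None,
    seed: int | np.random.Generator = 0,
    parent_mat: tuple[int, int] = (P1, P2),
) -> TetradGenotypes:
    """Simulate one meiosis of the diploid formed by two haploid parents.

    ``parent1``/``parent2`` are int8 haplotype vectors over ``markers`` with
    values in {1, 2} (default: the pure parental haplotypes).  The parents
    must carry different MAT alleles (``parent_mat``); the MAT allele is
    tracked as a locus of its own so mating types segregate 2:2 and stay
    linked to the haplotype of the interval that contains the locus.
    """
    rng = _rng(seed)
    model = model or CrossoverModel()
    rate = genome.crossover_rate if model.rate is None else model.rate
    if rate < 0:
        raise ValueError("crossover rate < 0")
    m = len(markers)
    h1 = np.full(m, P1, dtype=np.int8) if parent1 is None else np.asarray(parent1, dtype=np.int8).copy()
    h2 = np.full(m, P2, dtype=np.int8) if parent2 is None else np.asarray(parent2, dtype=np.int8).copy()
    if h1.shape != (m,) or h2.shape != (m,):
        raise ValueError("parent haplotypes must cover every marker")
    if genome.mat_locus is None:
        raise ValueError("genome has no MAT locus")
    if parent_mat[0] == parent_mat[1]:
        raise ValueError("parents are identical at MAT")
    mat_chrom, mat_pos = genome.mat_locus

    spore_calls = np.empty((4, m), dtype=np.int8)
    crossovers: dict[str, list[float]] = {}
    mat_alleles = None
    for chrom, _length in genome.chromosomes:
        idx = markers.chrom_index(chrom)
        positions = markers.df["pos"].to_numpy()[idx].astype(float)
        c1, c2 = h1[idx].copy(), h2[idx].copy()
        if model.loh_rate > 0:
            _apply_loh(c1, c2, positions, genome, chrom, model, rng)
        chromatids = np.stack([c1, c1.copy(), c2, c2.copy()])
        if chrom == mat_chrom:
            mats = np.array(
                [parent_mat[0], parent_mat[0], parent_mat[1], parent_mat[1]],
                dtype=np.int8,
            )
        co_positions = _draw_crossover_positions(genome, chrom, rate, rng)
        pair_idx = rng.integers(0, 4, size=len(co_positions))
        for p, k in zip(co_positions, pair_idx):
            a, b = _NON_SISTER_PAIRS[k]
            j = np.searchsorted(positions, p, side="right")
            tmp = chromatids[a, j:].copy()
            chromatids[a, j:] = chromatids[b, j:]
            chromatids[b, j:] = tmp
            if chrom == mat_chrom and mat_pos > p:
                mats[a], mats[b] = mats[b], mats[a]
        # independent assortment: homolog centromere pairs (0,1) and (2,3)
        # segregate to a random spore pair at meiosis I, sisters split in
        # random order at meiosis II -- drawn independently per chromosome
        pair_a, pair_b = [0, 1], [2, 3]
        rng.shuffle(pair_a)
        rng.shuffle(pair_b)
        if rng.random() < 0.5:
            assignment = pair_a + pair_b  # chromatid index per spore slot
        else:
            assignment = pair_b + pair_a
        spore_calls[:, idx] = chromatids[assignment]
        crossovers[chrom] = list(co_positions)
        if chrom == mat_chrom:
            mat_alleles = mats[assignment]
    mating_types = ["a" if a == P1 else "alpha" for a in mat_alleles]
    return TetradGenotypes(spore_calls, crossovers, mating_types)


# ---------------------------------------------------------------------------
# Population designs
# ---------------------------------------------------------------------------


def generate_f1_population(
    genome: GenomeMap,
    markers: MarkerSet,
    n_tetrads: int = 45,
    keep: str | Sequence[tuple[int, int]] = "all",
    model: CrossoverModel | None = None,
    seed: int = 0,
) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Simulate ``n_tetrads`` full tetrads of the parental cross.

    ``keep`` is ``"all"`` (4 spores per tetrad; 45 tetrads give the
    180-segregant design) or a list of ``(tetrad, spore)`` index pairs.
    """
    if n_tetrads < 1:
        raise ValueError("n_tetrads must be >= 1")
    rng = _rng(seed)
    strains, rows, mats = [], [], []
    truth = SimulationTruth(seed=seed if isinstance(seed, int) else None)
    wanted = None if keep == "all" else {tuple(k) for k in keep}
    for t in range(n_tetrads):
        tetrad = simulate_tetrad(genome, markers, model=model, seed=rng)
        for s in range(4):
            if wanted is not None and (t, s) not in wanted:
                continue
            name = f"F1_T{t:03d}_S{s}"
            strains.append(name)
            rows.append(tetrad.spore_calls[s])
            mats.append(tetrad.mating_types[s])
            truth.crossovers[name] = {
                c: list(p) for c, p in tetrad.crossovers.items()
            }
    gm = GenotypeMatrix(
        strains=strains,
        markers=markers,
        calls=np.vstack(rows),
        mating_types=np.array(mats, dtype=object),
    )
    return gm, truth


def _population_balance(
    gm: GenotypeMatrix, genome: GenomeMap, band: tuple[float, float]
) -> int:
    """Number of markers outside the nonrecombining intervals whose P1
    frequency falls outside ``band``."""
    cold = np.zeros(gm.n_markers, dtype=bool)
    for iv in genome.nonrecombining:
        cold |= gm.markers.in_interval_mask(iv)
    freq = (gm.calls == P1).mean(axis=0)
    out = (freq < band[0]) | (freq > band[1])
    return int((out & ~cold).sum())


def generate_f2_population(
    f1: GenotypeMatrix,
    genome: GenomeMap,
    n_crosses: int = 50,
    model: CrossoverModel | None = None,
    seed: int = 0,
    balance_band: tuple[float, float] = (0.4, 0.6),
    max_resample: int = 20,
) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Cross random MATa x MATalpha F1 pairs and keep one spore per tetrad.

    Crossovers in tracts where the hybrid is homozygous leave no genotype
    trace, so the detectable F2 event count exceeds the F1 count without
    doubling it.  After sampling, the P1 allele frequency outside the
    introgression is checked against ``balance_band``; the population is
    resampled up to ``max_resample`` times and the attempt with the fewest
    out-of-band markers is kept (recorded in the truth object).
    """
    a_idx = np.flatnonzero(f1.mating_types == "a")
    alpha_idx = np.flatnonzero(f1.mating_types == "alpha")
    if len(a_idx) == 0 or len(alpha_idx) == 0:
        raise ValueError("F1 population lacks one of the mating types")
    rng = _rng(seed)
    best = None
    for attempt in range(max_resample):
        strains, rows, mats = [], [], []
        truth = SimulationTruth(seed=seed if isinstance(seed, int) else None)
        parents = []
        for i in range(n_crosses):
            pa = int(rng.choice(a_idx))
            pb = int(rng.choice(alpha_idx))
            tetrad = simulate_tetrad(
                genome,
                f1.markers,
                parent1=f1.calls[pa],
                parent2=f1.calls[pb],
                model=model,
                seed=rng,
                parent_mat=(P1, P2),
            )
            s = int(rng.integers(0, 4))
            name = f"F2_{i:03d}"
            strains.append(name)
            rows.append(tetrad.spore_calls[s])
            mats.append(tetrad.mating_types[s])
            truth.crossovers[name] = {
                c: list(p) for c, p in tetrad.crossovers.items()
            }
            parents.append((f1.strains[pa], f1.strains[pb]))
        gm = GenotypeMatrix(
            strains=strains,
            markers=f1.markers,
            calls=np.vstack(rows),
            mating_types=np.array(mats, dtype=object),
        )
        n_out = _population_balance(gm, genome, balance_band)
        truth.meta["parent_pairs"] = parents
        truth.meta["balance_out_of_band_markers"] = n_out
        truth.meta["balance_attempts"] = attempt + 1
        if best is None or n_out < best[0]:
            best = (n_out, gm, truth)
        if n_out == 0:
            break
    _, gm, truth = best
    return gm, truth


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def make_qtl_spec(rows: Sequence[tuple[str, str, int, float]]) -> pd.DataFrame:
    """Build a QTL specification from (trait, chrom, pos, beta) tuples."""
    return pd.DataFrame(rows, columns=["trait", "chrom", "pos", "beta"])


def _nearest_marker_indicator(
    genotypes: GenotypeMatrix, chrom: str, pos: int, genome: GenomeMap | None
) -> np.ndarray:
    """P1-indicator (0/1, NaN for NA) at the marker nearest to (chrom, pos)."""
    if genome is not None:
        if chrom not in genome.chromosome_names:
            raise ValueError(f"causal locus on undeclared chromosome {chrom!r}")
        if not 1 <= pos <= genome.length(chrom):
            raise ValueError(f"causal locus {chrom}:{pos} outside chromosome")
    idx = genotypes.markers.chrom_index(chrom)
    if len(idx) == 0:
        raise ValueError(f"no markers on chromosome {chrom!r}")
    positions = genotypes.markers.df["pos"].to_numpy()[idx]
    j = idx[np.argmin(np.abs(positions - pos))]
    calls = genotypes.calls[:, j].astype(float)
    x = np.where(calls == P1, 1.0, np.where(calls == P2, 0.0, np.nan))
    return x


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    spec: pd.DataFrame | None = None,
    traits: Sequence[str] | None = None,
    mu: float = 1.0,
    noise_sd: float = 0.1,
    n_parent_replicates: int = 4,
    genome: GenomeMap | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Additive-QTL traits: y = mu + sum_i beta_i x_i + Normal(0, noise_sd^2),
    with x_i the P1 indicator at the marker nearest each causal locus.

    Returns a long-format phenotype table with columns ``strain``,
    ``strain_class`` (segregant / parent1 / parent2 / hybrid), ``replicate``
    and one column per trait.  Parental and hybrid replicate blocks share the
    segregant noise so broad-sense heritability is estimable; parent1 carries
    x = 1, parent2 x = 0 and the hybrid x = 0.5 at every causal locus.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd < 0")
    rng = _rng(seed)
    if spec is None:
        spec = make_qtl_spec([])
    trait_names = list(traits) if traits is not None else []
    for t in spec["trait"]:
        if t not in trait_names:
            trait_names.append(t)
    if not trait_names:
        trait_names = ["trait_0"]

    n = genotypes.n_strains
    blocks = [("segregant", genotypes.strains, 1)]
    for cls in ("parent1", "parent2", "hybrid"):
        blocks.append((cls, [cls], n_parent_replicates))
    records = []
    for cls, names, n_rep in blocks:
        for name in names:
            for r in range(n_rep):
                records.append({"strain": name, "strain_class": cls, "replicate": r})
    table = pd.DataFrame(records)

    class_x = {"parent1": 1.0, "parent2": 0.0, "hybrid": 0.5}
    trait_cols = {}
    for trait in trait_names:
        effects = spec[spec["trait"] == trait]
        y_seg = np.full(n, mu)
        for _, row in effects.iterrows():
            x = _nearest_marker_indicator(genotypes, row["chrom"], int(row["pos"]), genome)
            y_seg = y_seg + row["beta"] * np.nan_to_num(x, nan=0.5)
        values = np.empty(len(table))
        seg_mask = (table["strain_class"] == "segregant").to_numpy()
        strain_pos = {s: i for i, s in enumerate(genotypes.strains)}
        values[seg_mask] = y_seg[[strain_pos[s] for s in table.loc[seg_mask, "strain"]]]
        for cls in ("parent1", "parent2", "hybrid"):
            m = (table["strain_class"] == cls).to_numpy()
            values[m] = mu + effects["beta"].sum() * class_x[cls]
        values = values + rng.normal(0.0, noise_sd, size=len(values))
        trait_cols[trait] = values
    table = pd.concat([table, pd.DataFrame(trait_cols, index=table.index)], axis=1)

    truth = SimulationTruth(
        seed=seed if isinstance(seed, int) else None,
        qtl_spec=spec.copy(),
        meta={"mu": mu, "noise_sd": noise_sd, "traits": trait_names},
    )
    return table, truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def default_genes(
    genome: GenomeMap,
    n_genes: int = 1000,
    gene_length: int = 1300,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Gene table with uniform placement; ``introgressed`` flags genes whose
    midpoint lies in a nonrecombining interval."""
    rng = _rng(seed)
    lengths = np.array([l for _, l in genome.chromosomes], dtype=float)
    probs = lengths / lengths.sum()
    chrom_idx = rng.choice(len(lengths), size=n_genes, p=probs)
    names = genome.chromosome_names
    rows = []
    for g, ci in enumerate(chrom_idx):
        chrom = names[ci]
        start = int(rng.integers(1, max(2, genome.length(chrom) - gene_length)))
        end = min(start + gene_length - 1, genome.length(chrom))
        mid = (start + end) // 2
        rows.append(
            {
                "gene": f"G{g:05d}",
                "chrom": chrom,
                "start": start,
                "end": end,
                "introgressed": genome.is_cold(chrom, mid),
            }
        )
    return pd.DataFrame(rows)


def make_eqtl_spec(
    genes: pd.DataFrame,
    markers: MarkerSet,
    n_local: int = 0,
    n_distant: int = 0,
    hotspots: Sequence[tuple[str, int, int]] = (),
    effect_size: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Random eQTL specification.

    ``n_local`` genes get an effect at their own midpoint; ``n_distant`` get
    one at a random marker on another chromosome; each ``(chrom, pos,
    n_genes)`` hotspot routes distant effects for ``n_genes`` random genes
    through the shared locus.  Effect signs are random; magnitudes are
    ``effect_size`` log2 units.  Columns: gene, chrom, pos, beta, kind.
    """
    rng = _rng(seed)
    rows = []
    order = rng.permutation(len(genes))
    take = iter(order)
    for _ in range(n_local):
        g = genes.iloc[next(take)]
        rows.append(
            {
                "gene": g["gene"],
                "chrom": g["chrom"],
                "pos": int((g["start"] + g["end"]) // 2),
                "beta": effect_size * rng.choice([-1.0, 1.0]),
                "kind": "local",
            }
        )
    marker_df = markers.df
    for _ in range(n_distant):
        g = genes.iloc[next(take)]
        other = marker_df[marker_df["chrom"] != g["chrom"]]
        j = int(rng.integers(0, len(other)))
        rows.append(
            {
                "gene": g["gene"],
                "chrom": other.iloc[j]["chrom"],
                "pos": int(other.iloc[j]["pos"]),
                "beta": effect_size * rng.choice([-1.0, 1.0]),
                "kind": "distant",
            }
        )
    for chrom, pos, n_hot in hotspots:
        for _ in range(n_hot):
            g = genes.iloc[next(take)]
            rows.append(
                {
                    "gene": g["gene"],
                    "chrom": chrom,
                    "pos": int(pos),
                    "beta": effect_size * rng.choice([-1.0, 1.0]),
                    "kind": "hotspot",
                }
            )
    return pd.DataFrame(rows, columns=["gene", "chrom", "pos", "beta", "kind"])


def simulate_expression(
    genotypes: GenotypeMatrix,
    genes: pd.DataFrame,
    spec: pd.DataFrame | None = None,
    baseline_log2: np.ndarray | None = None,
    dispersion: float = 0.05,
    gc_bias_factor: float = 1.0,
    library_sizes: np.ndarray | None = None,
    genome: GenomeMap | None = None,
    seed: int | np.random.Generator = 0,
):
    """Negative-binomial expression counts with planted eQTL.

    mean_{g,s} = library_size_s * 2^(baseline_g + sum of allele effects)
                 * gc_bias_factor (for introgressed genes).

    Returns ``(ExpressionMatrix, SimulationTruth)``; the count matrix is
    genes x strains.  ``dispersion`` is the NB alpha (var = mu + alpha mu^2).
    """
    from .quantgen import ExpressionMatrix

    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = _rng(seed)
    n_genes, n_strains = len(genes), genotypes.n_strains
    if genome is not None:
        for _, g in genes.iterrows():
            if g["chrom"] not in genome.chromosome_names or g["end"] > genome.length(g["chrom"]):
                raise ValueError(f"gene {g['gene']} outside genome")
    if baseline_log2 is None:
        baseline_log2 = rng.normal(7.0, 1.5, size=n_genes)
    baseline_log2 = np.asarray(baseline_log2, dtype=float)
    if library_sizes is None:
        library_sizes = np.exp(rng.normal(0.0, 0.15, size=n_strains))
    library_sizes = np.asarray(library_sizes, dtype=float)
    if np.any(library_sizes <= 0):
        raise ValueError("library sizes must be > 0")

    log2_mu = np.tile(baseline_log2[:, None], (1, n_strains))
    if spec is not None and len(spec):
        gene_row = {g: i for i, g in enumerate(genes["gene"])}
        for _, row in spec.iterrows():
            gi = gene_row[row["gene"]]
            x = _nearest_marker_indicator(genotypes, row["chrom"], int(row["pos"]), genome)
            log2_mu[gi] += row["beta"] * np.nan_to_num(x, nan=0.5)
    mu = library_sizes[None, :] * np.power(2.0, log2_mu)
    intro = genes["introgressed"].to_numpy(dtype=bool)
    # scalar: constant quantification bias on the introgressed set;
    # per-strain array: sample-varying bias (what split normalization removes)
    gc = np.broadcast_to(np.asarray(gc_bias_factor, dtype=float), (n_strains,))
    mu[intro] *= gc[None, :]

    size = 1.0 / dispersion
    counts = rng.negative_binomial(size, size / (size + mu))
    em = ExpressionMatrix(
        counts=pd.DataFrame(counts, index=list(genes["gene"]), columns=genotypes.strains),
        genes=genes.reset_index(drop=True),
        library_sizes=pd.Series(library_sizes, index=genotypes.strains),
    )
    truth = SimulationTruth(
        seed=seed if isinstance(seed, int) else None,
        eqtl_spec=None if spec is None else spec.copy(),
        meta={
            "baseline_log2": baseline_log2,
            "dispersion": dispersion,
            "gc_bias_factor": gc_bias_factor,
        },
    )
    return em, truth


def simulate_expression_replicates(
    genes: pd.DataFrame,
    baseline_log2: np.ndarray,
    n_replicates: int = 24,
    dispersion: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Pure-noise replicate profiles (genes x replicates) of a reference
    strain, emulating the external replicate dataset used to estimate the
    expression noise variance for heritability."""
    rng = _rng(seed)
    mu = np.power(2.0, np.asarray(baseline_log2, dtype=float))[:, None]
    mu = np.tile(mu, (1, n_replicates))
    size = 1.0 / dispersion
    counts = rng.negative_binomial(size, size / (size + mu))
    return pd.DataFrame(
        counts,
        index=list(genes["gene"]),
        columns=[f"rep_{i:02d}" for i in range(n_replicates)],
    )


# ---------------------------------------------------------------------------
# Read-level observations
# ---------------------------------------------------------------------------


@dataclass
class AlleleCounts:
    """Per strain x marker read counts by base class."""

    strains: list[str]
    markers: MarkerSet
    n_p1: np.ndarray
    n_p2: np.ndarray
    n_other: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.n_p1 + self.n_p2 + self.n_other

    def to_tsv(self, path) -> None:
        ids = self.markers.ids
        with open(path, "w") as fh:
            fh.write("strain\t" + "\t".join(ids) + "\n")
            for i, strain in enumerate(self.strains):
                cells = [
                    f"{a},{b},{c}"
                    for a, b, c in zip(self.n_p1[i], self.n_p2[i], self.n_other[i])
                ]
                fh.write(strain + "\t" + "\t".join(cells) + "\n")

    @classmethod
    def read_tsv(cls, path, markers: MarkerSet) -> "AlleleCounts":
        strains, rows = [], []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[1:] != markers.ids:
                raise ValueError(f"{path}: marker ids do not match MarkerSet")
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                strains.append(fields[0])
                rows.append(
                    [[int(x) for x in cell.split(",")] for cell in fields[1:]]
                )
        arr = np.asarray(rows, dtype=np.int32)
        return cls(strains, markers, arr[:, :, 0], arr[:, :, 1], arr[:, :, 2])


def simulate_observations(
    genotypes: GenotypeMatrix,
    model: ObservationModel | None = None,
    seed: int | np.random.Generator = 0,
) -> AlleleCounts:
    """Poisson read depth with per-read base errors at every marker cell.

    A read from a true-P1 cell reports the P1 base with probability 1 - e,
    the P2 base with probability e/3 and one of the two remaining bases
    otherwise (and symmetrically for true-P2 cells).
    """
    model = model or ObservationModel()
    rng = _rng(seed)
    shape = genotypes.calls.shape
    reads = rng.poisson(model.coverage_mean, size=shape)
    e = model.error_rate
    n_err = rng.binomial(reads, e) if e > 0 else np.zeros(shape, dtype=int)
    n_cross = rng.binomial(n_err, 1.0 / 3.0) if e > 0 else n_err
    n_true = reads - n_err
    n_other = n_err - n_cross
    is_p1 = genotypes.calls == P1
    n_p1 = np.where(is_p1, n_true, n_cross)
    n_p2 = np.where(is_p1, n_cross, n_true)
    # NA truth cells (if any) contribute no reads
    na = genotypes.calls == NA
    n_p1[na] = 0
    n_p2[na] = 0
    n_other[na] = 0
    return AlleleCounts(
        strains=list(genotypes.strains),
        markers=genotypes.markers,
        n_p1=n_p1.astype(np.int32),
        n_p2=n_p2.astype(np.int32),
        n_other=n_other.astype(np.int32),
    )
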