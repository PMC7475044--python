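"""Haley-Knott regression LOD scans, permutation significance, eQTL FDR and
QTL calling.

At each locus the phenotype is regressed on the conditional probability that
the strain carries the parent-1 allele given its observed flanking markers
(computed with Haldane map distances, so missing pseudomarker calls are
handled without imputation).  The LOD score is

    LOD = (n/2) * log10(RSS0 / RSS1),

with RSS0 from the intercept-only fit, and the fraction of variance explained
by a peak follows the identity 1 - 10^(-2 LOD / n) = 1 - RSS1/RSS0.

Per-trait significance thresholds come from permutations of the trait values
against fixed genotypes: with 1,000 permutations at alpha = 0.05 the
threshold is the 50th-largest genome-wide maximum LOD, i.e. the LOD at which
a QTL is found in only 50 of the 1,000 permutations.  The eQTL FDR instead
permutes strain labels of the whole expression matrix jointly (preserving
gene-gene correlation) and estimates FDR(t) as the mean false-eQTL count
across permutations divided by the observed eQTL count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import NA, P1, P2, GenomeMap, GenotypeMatrix, Interval

logger = logging.getLogger(__name__)


@dataclass
class GenotypeProbabilities:
    """P(allele = P1 | observed flanking markers) per strain x locus."""

    strains: list[str]
    loci: pd.DataFrame  # columns chrom, pos
    p: np.ndarray  # n_strains x n_loci, float64 in [0, 1]
    eps: float

    def chrom_index(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.loci["chrom"] == chrom).to_numpy())

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.loci["chrom"]))


@dataclass
class ScanResult:
    trait: str
    loci: pd.DataFrame
    lod: np.ndarray
    n: int
    threshold: float | None = None


@dataclass
class QTLCall:
    trait: str
    chrom: str
    peak_pos: int
    peak_lod: float
    threshold: float
    support: Interval
    var_explained: float
    gene: str | None = None
    label: str | None = None  # local / distant, set by the architecture stage


def haldane_r(d_bp: np.ndarray, cm_per_kb: float) -> np.ndarray:
    """Haldane recombination fraction for a physical distance in bp."""
    d_morgan = cm_per_kb * np.asarray(d_bp, dtype=float) / 1000.0 / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * d_morgan))


def genotype_probabilities(
    genotypes: GenotypeMatrix,
    genome: GenomeMap,
    cm_per_kb: float = 0.12,
    eps: float = 0.001,
) -> GenotypeProbabilities:
    """Conditional P1 probabilities at every marker of ``genotypes``.

    Observed loci get p = 1 - eps (P1) or eps (P2).  A missing locus is
    conditioned on its nearest non-NA flanking markers through the two-locus
    Markov chain with Haldane recombination fractions; at chromosome ends a
    single flank is used, and a chromosome with no informative marker gets
    p = 0.5 everywhere (logged).
    """
    n, _ = genotypes.calls.shape
    p = np.full(genotypes.calls.shape, 0.5)
    marker_df = genotypes.markers.df
    for chrom in genome.chromosome_names:
        cidx = genotypes.markers.chrom_index(chrom)
        if len(cidx) == 0:
            continue
        pos = marker_df["pos"].to_numpy()[cidx].astype(float)
        calls = genotypes.calls[:, cidx]
        block = np.full(calls.shape, 0.5)
        for i in range(n):
            obs = np.flatnonzero(calls[i] != NA)
            if len(obs) == 0:
                logger.debug(
                    "strain %s: no informative marker on %s; p = 0.5",
                    genotypes.strains[i],
                    chrom,
                )
                continue
            is_p1 = calls[i, obs] == P1
            block[i, obs] = np.where(is_p1, 1.0 - eps, eps)
            miss = np.flatnonzero(calls[i] == NA)
            if len(miss) == 0:
                continue
            right_rank = np.searchsorted(obs, miss, side="left")
            has_left = right_rank > 0
            has_right = right_rank < len(obs)
            left_idx = obs[np.clip(right_rank - 1, 0, None)]
            right_idx = obs[np.clip(right_rank, None, len(obs) - 1)]
            rl = haldane_r(pos[miss] - pos[left_idx], cm_per_kb)
            rr = haldane_r(pos[right_idx] - pos[miss], cm_per_kb)
            lp1 = calls[i, left_idx] == P1
            rp1 = calls[i, right_idx] == P1
            # P(locus = P1 | flank states), two-locus Markov chain
            a1 = np.where(lp1, 1.0 - rl, rl)  # left flank -> P1 here
            a2 = np.where(lp1, rl, 1.0 - rl)  # left flank -> P2 here
            b1 = np.where(rp1, 1.0 - rr, rr)  # P1 here -> right flank
            b2 = np.where(rp1, rr, 1.0 - rr)
            both = has_left & has_right
            prob = np.full(len(miss), 0.5)
            prob[both] = (a1 * b1 / (a1 * b1 + a2 * b2))[both]
            only_left = has_left & ~has_right
            prob[only_left] = a1[only_left]
            only_right = has_right & ~has_left
            prob[only_right] = b1[only_right]
            block[i, miss] = prob
        p[:, cidx] = block
    loci = marker_df[["chrom", "pos"]].reset_index(drop=True)
    return GenotypeProbabilities(
        strains=list(genotypes.strains), loci=loci, p=p, eps=eps
    )


# ---------------------------------------------------------------------------
# LOD computation
# ---------------------------------------------------------------------------


def lod_matrix(p: np.ndarray, y: np.ndarray) -> np.ndarray:
    """LOD scores for every locus x trait pair.

    ``p``: n x L genotype probabilities; ``y``: n x T complete trait values.
    Returns L x T.  Loci with (numerically) constant p score LOD 0.
    """
    n = p.shape[0]
    pc = p - p.mean(axis=0)
    yc = y - y.mean(axis=0)
    ssp = np.einsum("nl,nl->l", pc, pc)
    ssy = np.einsum("nt,nt->t", yc, yc)
    num = pc.T @ yc  # L x T
    informative = ssp > 1e-12
    rss1 = ssy[None, :] - np.where(
        informative[:, None], num**2 / np.where(informative, ssp, 1.0)[:, None], 0.0
    )
    rss1 = np.maximum(rss1, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = (n / 2.0) * (np.log10(np.maximum(ssy[None, :], 1e-300)) - np.log10(rss1))
    lod[~informative, :] = 0.0
    lod[:, ssy <= 0] = 0.0
    return np.maximum(lod, 0.0)


def _align_trait(probs: GenotypeProbabilities, values: pd.Series | np.ndarray):
    if isinstance(values, pd.Series):
        values = values.reindex(probs.strains)
        y = values.to_numpy(dtype=float)
    else:
        y = np.asarray(values, dtype=float)
        if len(y) != len(probs.strains):
            raise ValueError("trait vector length does not match strains")
    keep = ~np.isnan(y)
    return y[keep], probs.p[keep]


def hk_scan(
    probs: GenotypeProbabilities,
    values: pd.Series | np.ndarray,
    trait: str = "",
) -> ScanResult:
    """Single-trait Haley-Knott scan; strains with missing trait values are
    dropped scan-wide."""
    y, p = _align_trait(probs, values)
    if len(y) < 3:
        raise ValueError("need >= 3 strains with non-missing trait values")
    lod = lod_matrix(p, y[:, None])[:, 0]
    return ScanResult(trait=trait, loci=probs.loci, lod=lod, n=len(y))


def permutation_threshold(
    probs: GenotypeProbabilities,
    values: pd.Series | np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    return_null: bool = False,
):
    """Genome-wide max-LOD permutation threshold for one trait.

    The trait is permuted across strains with genotypes fixed; the threshold
    is the k-th largest of the ``n_perm`` null maxima with
    k = floor(alpha * n_perm) — the LOD at which a QTL is detected in only k
    permutations.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y, p = _align_trait(probs, values)
    n = len(y)
    perm = np.argsort(rng.random((n_perm, n)), axis=1)
    yperm = y[perm].T  # n x n_perm
    # The genome-wide max LOD is a monotone function of the max regression
    # sum of squares, because RSS0 is invariant under permutation; computing
    # the LOD only at the per-permutation maximum avoids a full L x n_perm
    # log evaluation.
    pc = p - p.mean(axis=0)
    yc = yperm - yperm.mean(axis=0)
    ssp = np.einsum("nl,nl->l", pc, pc)
    ssy = np.einsum("nt,nt->t", yc, yc)
    inv_ssp = np.where(ssp > 1e-12, 1.0 / np.maximum(ssp, 1e-12), 0.0)
    num = pc.T @ yc
    np.square(num, out=num)
    num *= inv_ssp[:, None]
    best = num.max(axis=0)
    rss1 = np.maximum(ssy - best, 1e-300)
    with np.errstate(divide="ignore"):
        null_max = np.maximum(
            (n / 2.0) * (np.log10(np.maximum(ssy, 1e-300)) - np.log10(rss1)), 0.0
        )
    k = max(1, int(np.floor(alpha * n_perm)))
    threshold = float(np.sort(null_max)[n_perm - k])
    if return_null:
        return threshold, null_max
    return threshold


# ---------------------------------------------------------------------------
# QTL calling
# ---------------------------------------------------------------------------


def variance_explained(lod: float, n: int) -> float:
    return 1.0 - 10.0 ** (-2.0 * lod / n)


def _cold_interval_at(genome: GenomeMap | None, chrom: str, pos: int):
    if genome is None:
        return None
    for iv in genome.cold_intervals(chrom):
        if iv.contains(chrom, pos):
            return iv
    return None


def call_qtl(
    scan: ScanResult,
    threshold: float,
    genome: GenomeMap | None = None,
    drop: float = 1.5,
    valley: float = 2.0,
) -> list[QTLCall]:
    """Call peaks with LOD >= threshold.

    Per chromosome, the maximum-LOD locus is called first; further peaks are
    accepted only if separated from every accepted peak by a valley at least
    ``valley`` LOD units below both.  The support interval is the maximal
    contiguous run with LOD >= peak - ``drop``.  A peak inside a
    nonrecombining interval is reported at the interval midpoint with the
    support forced to the whole interval, since positions within it are
    unidentifiable.
    """
    calls: list[QTLCall] = []
    loci = scan.loci
    for chrom in dict.fromkeys(loci["chrom"]):
        cidx = np.flatnonzero((loci["chrom"] == chrom).to_numpy())
        lod = scan.lod[cidx]
        pos = loci["pos"].to_numpy()[cidx]
        accepted: list[int] = []
        for j in np.argsort(lod)[::-1]:
            if lod[j] < threshold:
                break
            ok = True
            for k in accepted:
                lo, hi = (j, k) if j < k else (k, j)
                vmin = lod[lo : hi + 1].min()
                if not (vmin <= lod[j] - valley and vmin <= lod[k] - valley):
                    ok = False
                    break
            if ok:
                accepted.append(int(j))
        for j in sorted(accepted, key=lambda j: pos[j]):
            lo = j
            while lo > 0 and lod[lo - 1] >= lod[j] - drop:
                lo -= 1
            hi = j
            while hi < len(lod) - 1 and lod[hi + 1] >= lod[j] - drop:
                hi += 1
            peak_pos = int(pos[j])
            support = Interval(chrom, int(pos[lo]), int(pos[hi]))
            cold = _cold_interval_at(genome, chrom, peak_pos)
            if cold is not None:
                peak_pos = (cold.start + cold.end) // 2
                support = cold
            calls.append(
                QTLCall(
                    trait=scan.trait,
                    chrom=chrom,
                    peak_pos=peak_pos,
                    peak_lod=float(lod[j]),
                    threshold=float(threshold),
                    support=support,
                    var_explained=variance_explained(float(lod[j]), scan.n),
                )
            )
    return calls


def scan_traits(
    probs: GenotypeProbabilities,
    traits: pd.DataFrame,
    n_perm: int = 1000,
    alpha: float = 0.05,
    genome: GenomeMap | None = None,
    seed: int = 0,
    drop: float = 1.5,
) -> tuple[list[QTLCall], dict[str, ScanResult]]:
    """Scan every column of a strains x traits table with per-trait
    permutation thresholds; returns all calls plus the per-trait scans."""
    rng = np.random.default_rng(seed)
    calls, scans = [], {}
    for trait in traits.columns:
        values = traits[trait]
        if values.notna().sum() < 3:
            continue
        scan = hk_scan(probs, values, trait=trait)
        scan.threshold = permutation_threshold(
            probs, values, n_perm=n_perm, alpha=alpha, seed=rng
        )
        scans[trait] = scan
        calls.extend(call_qtl(scan, scan.threshold, genome=genome, drop=drop))
    return calls, scans


# ---------------------------------------------------------------------------
# eQTL
# ---------------------------------------------------------------------------


def eqtl_scan_all(
    probs: GenotypeProbabilities, expression: pd.DataFrame
) -> tuple[list[str], np.ndarray]:
    """Haley-Knott scans for every gene (rows of ``expression``; columns are
    strains).  Vectorized across genes sharing the design matrix; returns the
    gene list and the genes x loci LOD matrix in input gene order."""
    expr = expression[probs.strains]
    y = expr.to_numpy(dtype=float).T  # n x G
    if np.isnan(y).any():
        raise ValueError("expression matrix must be complete")
    lod = lod_matrix(probs.p, y).T  # G x L
    return list(expr.index), lod


def chromosome_max_lod(
    probs: GenotypeProbabilities, lod: np.ndarray
) -> tuple[list[str], np.ndarray]:
    """Reduce a genes x loci LOD matrix to genes x chromosomes maxima."""
    chroms = probs.chromosomes
    out = np.empty((lod.shape[0], len(chroms)))
    for c, chrom in enumerate(chroms):
        out[:, c] = lod[:, probs.chrom_index(chrom)].max(axis=1)
    return chroms, out


def _chrom_boundaries(probs: GenotypeProbabilities) -> np.ndarray:
    """Start offsets of each chromosome's contiguous locus block."""
    chroms = probs.loci["chrom"].to_numpy()
    starts = [0] + [i for i in range(1, len(chroms)) if chroms[i] != chroms[i - 1]]
    return np.asarray(starts, dtype=np.intp)


def _chrom_max_lod_fast(probs: GenotypeProbabilities, y: np.ndarray) -> np.ndarray:
    """Genes x chromosomes max LOD, computed from the per-chromosome maximum
    regression sum of squares (the LOD transform is monotone per gene since
    RSS0 is locus-independent)."""
    pc = probs.p - probs.p.mean(axis=0)
    ssp = np.einsum("nl,nl->l", pc, pc)
    inv_ssp = np.where(ssp > 1e-12, 1.0 / np.maximum(ssp, 1e-12), 0.0)
    yc = y - y.mean(axis=0)
    ssy = np.einsum("ng,ng->g", yc, yc)
    num = pc.T @ yc  # L x G
    np.square(num, out=num)
    num *= inv_ssp[:, None]
    best = np.maximum.reduceat(num, _chrom_boundaries(probs), axis=0)  # C x G
    n = y.shape[0]
    rss1 = np.maximum(ssy[None, :] - best, 1e-300)
    with np.errstate(divide="ignore"):
        lod = (n / 2.0) * (np.log10(np.maximum(ssy[None, :], 1e-300)) - np.log10(rss1))
    lod[:, ssy <= 0] = 0.0
    return np.maximum(lod, 0.0).T


@dataclass
class FDRCurve:
    table: pd.DataFrame  # threshold, observed, mean_false, fdr
    chosen_threshold: float | None
    nominal: float


def eqtl_fdr(
    probs: GenotypeProbabilities,
    expression: pd.DataFrame,
    threshold_grid: np.ndarray | list[float],
    n_perm: int = 100,
    nominal: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> FDRCurve:
    """Permutation FDR for genome-wide eQTL detection.

    Each permutation shuffles the strain labels of the entire expression
    matrix jointly against the fixed genotypes, preserving gene-gene
    correlation.  An eQTL is counted per (gene, chromosome) whose maximum LOD
    clears the threshold; FDR(t) = mean false count / observed count.  The
    chosen threshold is the smallest grid value with FDR <= ``nominal``
    (None when no grid point qualifies).
    """
    grid = np.sort(np.asarray(list(threshold_grid), dtype=float))
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    expr = expression[probs.strains]
    y = expr.to_numpy(dtype=float).T
    if np.isnan(y).any():
        raise ValueError("expression matrix must be complete")
    n = y.shape[0]
    cmax = _chrom_max_lod_fast(probs, y)
    observed = (cmax[:, :, None] >= grid[None, None, :]).sum(axis=(0, 1))

    false_sum = np.zeros(grid.size)
    for _ in range(n_perm):
        cmaxp = _chrom_max_lod_fast(probs, y[rng.permutation(n)])
        false_sum += (cmaxp[:, :, None] >= grid[None, None, :]).sum(axis=(0, 1))
    mean_false = false_sum / n_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(observed > 0, mean_false / np.maximum(observed, 1), np.nan)
    table = pd.DataFrame(
        {
            "threshold": grid,
            "observed": observed,
            "mean_false": mean_false,
            "fdr": fdr,
        }
    )
    ok = np.flatnonzero((observed > 0) & (fdr <= nominal))
    chosen = float(grid[ok[0]]) if len(ok) else None
    return FDRCurve(table=table, chosen_threshold=chosen, nominal=nominal)


def call_eqtl(
    probs: GenotypeProbabilities,
    expression: pd.DataFrame,
    threshold: float,
    genome: GenomeMap | None = None,
    drop: float = 1.5,
) -> list[QTLCall]:
    """Final eQTL calls at a fixed LOD threshold, with support intervals and
    the within-chromosome multiple-peak rule applied per gene."""
    genes, lod = eqtl_scan_all(probs, expression)
    n = len(probs.strains)
    calls = []
    for gi, gene in enumerate(genes):
        if lod[gi].max() < threshold:
            continue
        scan = ScanResult(trait=gene, loci=probs.loci, lod=lod[gi], n=n)
        for call in call_qtl(scan, threshold, genome=genome, drop=drop):
            call.gene = gene
            calls.append(call)
    return calls
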