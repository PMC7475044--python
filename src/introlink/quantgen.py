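"""Fitness quantification, expression normalization, broad-sense heritability
and a thin principal-component projection utility.

Broad-sense heritability is the plug-in estimator
``H^2 = 1 - sigma^2_noise / sigma^2_total`` where the noise variance is the
mean of within-replicate-group variances (parental strains and hybrid for
fitness; an external replicate profile set for expression) and the total
variance is taken across segregants.  Sampling noise can push the raw value
outside [0, 1]; the estimate is clipped and the raw value retained.

Count normalization is median-of-ratios: per-sample size factors are the
median across genes of the ratio between a sample's count and the gene's
geometric mean over samples.  Because the introgressed gene set has a
different base composition (higher GC) it can carry a systematic
quantification bias, so its size factors are computed separately by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """Raw gene counts (genes x strains) with gene coordinates and flags."""

    counts: pd.DataFrame
    genes: pd.DataFrame  # columns: gene, chrom, start, end, introgressed
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if list(self.counts.index) != list(self.genes["gene"]):
            raise ValueError("counts index does not match gene table")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")


@dataclass
class HeritabilityEstimate:
    trait: str
    total_variance: float
    noise_variance: float
    h2: float  # clipped to [0, 1]
    h2_raw: float
    flagged: bool = False  # True when total variance is ~0 (H^2 undefined)


# ---------------------------------------------------------------------------
# Fitness
# ---------------------------------------------------------------------------


def fitness_ratio(
    test: pd.DataFrame, reference: pd.DataFrame, raw_reference: bool = False
) -> pd.Series:
    """Per-strain mean of replicate-paired colony-size ratios.

    ``test`` and ``reference`` are strain x replicate colony sizes with
    matching shape.  A missing or zero reference colony makes that replicate's
    ratio NA; a strain with no valid replicate gets NA.  With
    ``raw_reference`` the raw test sizes are averaged instead (used for the
    reference condition itself, which has no meaningful ratio).
    """
    if not test.index.equals(reference.index) or test.shape != reference.shape:
        raise ValueError("test and reference replicate structures differ")
    if raw_reference:
        return test.mean(axis=1, skipna=True)
    ref = reference.where(reference > 0)
    ratios = test / ref
    return ratios.mean(axis=1, skipna=True)


# ---------------------------------------------------------------------------
# Expression normalization
# ---------------------------------------------------------------------------


def _median_of_ratios(counts: np.ndarray) -> np.ndarray:
    """Size factors for a genes x samples count block."""
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene with positive counts in every sample")
    logc = np.log(counts[positive].astype(float))
    log_gm = logc.mean(axis=1, keepdims=True)
    return np.exp(np.median(logc - log_gm, axis=0))


def size_factors(em: ExpressionMatrix, split_introgression: bool = True) -> pd.DataFrame:
    """Median-of-ratios size factors per strain; one row per gene set when
    the introgressed set is normalized separately."""
    counts = em.counts.to_numpy()
    intro = em.genes["introgressed"].to_numpy(dtype=bool)
    rows = {}
    if split_introgression and intro.any() and (~intro).any():
        rows["non_introgressed"] = _median_of_ratios(counts[~intro])
        rows["introgressed"] = _median_of_ratios(counts[intro])
    else:
        rows["all"] = _median_of_ratios(counts)
    return pd.DataFrame(rows, index=em.counts.columns).T


def normalize_counts(
    em: ExpressionMatrix,
    min_count: int = 32,
    split_introgression: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter low-expressed genes, normalize, and return log2 values.

    Genes whose count is below ``min_count`` in every sample are removed.
    Size factors are computed by median-of-ratios, separately for the
    introgressed and non-introgressed gene sets when ``split_introgression``.
    Returns ``(log2(normalized count + 1) DataFrame, size-factor DataFrame)``.
    """
    expressed = (em.counts >= min_count).any(axis=1)
    kept = ExpressionMatrix(
        counts=em.counts.loc[expressed],
        genes=em.genes.loc[expressed.to_numpy()].reset_index(drop=True),
        library_sizes=em.library_sizes,
    )
    sf = size_factors(kept, split_introgression=split_introgression)
    counts = kept.counts.to_numpy(dtype=float)
    intro = kept.genes["introgressed"].to_numpy(dtype=bool)
    norm = np.empty_like(counts)
    if set(sf.index) == {"non_introgressed", "introgressed"}:
        norm[~intro] = counts[~intro] / sf.loc["non_introgressed"].to_numpy()
        norm[intro] = counts[intro] / sf.loc["introgressed"].to_numpy()
    else:
        norm = counts / sf.loc["all"].to_numpy()
    log2 = pd.DataFrame(
        np.log2(norm + 1.0), index=kept.counts.index, columns=kept.counts.columns
    )
    return log2, sf


# ---------------------------------------------------------------------------
# Heritability
# ---------------------------------------------------------------------------


def broad_sense_heritability(
    segregant_values: pd.Series | np.ndarray,
    replicate_groups: list[np.ndarray] | list[pd.Series],
    trait: str = "",
) -> HeritabilityEstimate:
    """H^2 = 1 - mean(within-group variance) / total segregant variance.

    ``replicate_groups`` are the replicate value vectors used for the noise
    estimate (each with >= 2 observations).  Variances are unbiased (ddof=1).
    """
    seg = np.asarray(segregant_values, dtype=float)
    seg = seg[~np.isnan(seg)]
    if len(seg) < 3:
        raise ValueError("need >= 3 segregant values")
    groups = [np.asarray(g, dtype=float) for g in replicate_groups]
    groups = [g[~np.isnan(g)] for g in groups]
    if not groups or any(len(g) < 2 for g in groups):
        raise ValueError("each replicate group needs >= 2 observations")
    noise = float(np.mean([np.var(g, ddof=1) for g in groups]))
    total = float(np.var(seg, ddof=1))
    if total <= 0:
        return HeritabilityEstimate(trait, total, noise, float("nan"), float("nan"), True)
    raw = 1.0 - noise / total
    return HeritabilityEstimate(trait, total, noise, float(np.clip(raw, 0.0, 1.0)), raw)


def segregant_trait_matrix(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Strain x trait matrix of segregant replicate means, the one-value-per-
    strain form the linkage scan consumes."""
    meta = {"strain", "strain_class", "replicate"}
    traits = [c for c in phenotypes.columns if c not in meta]
    seg = phenotypes[phenotypes["strain_class"] == "segregant"]
    return seg.groupby("strain", sort=False)[traits].mean()


def fitness_heritability(
    phenotypes: pd.DataFrame, traits: list[str] | None = None
) -> pd.DataFrame:
    """Apply :func:`broad_sense_heritability` to a long-format phenotype table
    (columns ``strain``, ``strain_class``, ``replicate`` + one per trait),
    using parent1/parent2/hybrid replicate blocks as the noise groups and
    per-strain segregant means as the population values."""
    meta = {"strain", "strain_class", "replicate"}
    if traits is None:
        traits = [c for c in phenotypes.columns if c not in meta]
    rows = []
    for trait in traits:
        seg = (
            phenotypes[phenotypes["strain_class"] == "segregant"]
            .groupby("strain")[trait]
            .mean()
        )
        groups = [
            phenotypes.loc[phenotypes["strain_class"] == cls, trait].to_numpy()
            for cls in ("parent1", "parent2", "hybrid")
            if (phenotypes["strain_class"] == cls).any()
        ]
        est = broad_sense_heritability(seg, groups, trait)
        rows.append(
            {
                "trait": trait,
                "h2": est.h2,
                "h2_raw": est.h2_raw,
                "total_variance": est.total_variance,
                "noise_variance": est.noise_variance,
                "flagged": est.flagged,
            }
        )
    return pd.DataFrame(rows)


def expression_heritability(
    log2_expression: pd.DataFrame, log2_replicates: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene H^2 with the noise variance taken from an external replicate
    profile set (genes x replicates, same normalization and log2 scale)."""
    common = log2_expression.index.intersection(log2_replicates.index)
    rows = []
    for gene in common:
        est = broad_sense_heritability(
            log2_expression.loc[gene].to_numpy(),
            [log2_replicates.loc[gene].to_numpy()],
            trait=gene,
        )
        rows.append(
            {
                "gene": gene,
                "h2": est.h2,
                "h2_raw": est.h2_raw,
                "total_variance": est.total_variance,
                "noise_variance": est.noise_variance,
                "flagged": est.flagged,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------


def trait_projection(
    matrix: pd.DataFrame, n_components: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of a strains x traits matrix.

    Missing values are mean-imputed per trait; columns are centered and
    standardized (zero-variance columns dropped).  Returns the component
    coordinates (strains x components) and the explained-variance fractions.
    """
    from sklearn.decomposition import PCA

    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 strains")
    x = matrix.to_numpy(dtype=float)
    col_mean = np.nanmean(x, axis=0)
    nan_idx = np.where(np.isnan(x))
    x[nan_idx] = np.take(col_mean, nan_idx[1])
    sd = x.std(axis=0)
    keep = sd > 0
    x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    k = min(x.shape) if n_components is None else min(n_components, *x.shape)
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(x)
    frame = pd.DataFrame(
        coords, index=matrix.index, columns=[f"PC{i+1}" for i in range(k)]
    )
    return frame, pca.explained_variance_ratio_
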