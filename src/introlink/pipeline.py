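"""One-config orchestration of the full analysis on simulated data:
simulate -> genotype -> recombination/quantitative genetics -> linkage ->
architecture, with per-stage derived seeds, TSV outputs and a hashed
manifest for reproducibility checks.

The fitness arm mirrors an F1 full-tetrad design (scan on pseudomarker
genotypes, per-trait permutation thresholds); the expression arm mirrors an
F2 one-spore-per-tetrad design genotyped from read-level observations, with
median-of-ratios normalization and a permutation FDR threshold.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import architecture as arch
from . import genotyping, linkage, quantgen, recombination, simulate
from .genome import (
    GenomeMap,
    Interval,
    default_genome,
    default_markers,
    load_genome,
    save_genome,
    write_genotype_table,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


DEFAULT_CONFIG = {
    "seed": 0,
    "genome": "default",
    "simulate": {
        "marker_density_per_kb": 0.5,
        "n_tetrads": 45,
        "n_f2": 50,
        "n_traits": 4,
        "qtl_per_trait": 1,
        "qtl_effect": 0.4,
        "noise_sd": 0.1,
        "n_parent_replicates": 4,
        "n_genes": 400,
        "n_local_eqtl": 40,
        "n_distant_eqtl": 20,
        "hotspot_genes": 40,
        "eqtl_effect": 1.0,
        "dispersion": 0.05,
        "gc_bias_factor": 1.0,
        "coverage_mean": 6.0,
        "error_rate": 0.002,
    },
    "genotyping": {
        "min_coverage": 2,
        "max_na_fraction": 0.30,
        "balance_window": [0.30, 0.70],
        "coding_only": True,
    },
    "pseudomarkers": {"spacing": 3000, "window": 4000},
    "linkage": {"n_perm": 200, "alpha": 0.05, "cm_per_kb": 0.12, "eps": 0.001},
    "eqtl": {"n_perm": 25, "grid_start": 2.0, "grid_stop": 8.0, "grid_step": 0.25,
             "nominal_fdr": 0.05},
    "architecture": {"bin_size": 50000, "buffer_bp": 50000},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict)
    return _merge(DEFAULT_CONFIG, user)


def validate_config(config: dict) -> None:
    if "out_dir" not in config:
        raise PipelineError("validate", "config missing 'out_dir'")
    if not isinstance(config.get("seed"), int):
        raise PipelineError("validate", "'seed' must be an integer")
    genome = config.get("genome", "default")
    if genome != "default" and not Path(genome).exists():
        raise PipelineError("validate", f"genome config not found: {genome}")


def _stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed so stages can be rerun in isolation."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _calls_to_frame(calls: list[linkage.QTLCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trait": c.trait,
                "gene": c.gene,
                "chrom": c.chrom,
                "peak_bp": c.peak_pos,
                "lod": round(c.peak_lod, 6),
                "threshold": round(c.threshold, 6),
                "ci_lo": c.support.start,
                "ci_hi": c.support.end,
                "var_explained": round(c.var_explained, 6),
                "label": c.label,
            }
            for c in calls
        ]
    )


def run_pipeline(config) -> dict:
    """Run every stage in dependency order; returns the output manifest.

    On stage failure a ``FAILED`` marker naming the stage is written to the
    output directory and :class:`PipelineError` is raised; outputs of earlier
    stages are retained.
    """
    config = load_config(config)
    validate_config(config)
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config["seed"]
    outputs: list[Path] = []
    stage = "validate"
    try:
        # -- genome ---------------------------------------------------------
        stage = "genome"
        genome = (
            default_genome() if config["genome"] == "default" else load_genome(config["genome"])
        )
        save_genome(genome, out_dir / "genome.yaml")
        outputs.append(out_dir / "genome.yaml")

        # -- simulate -------------------------------------------------------
        stage = "simulate"
        sim = config["simulate"]
        markers = default_markers(
            genome, sim["marker_density_per_kb"], seed=_stage_seed(seed, "markers")
        )
        f1, f1_truth = simulate.generate_f1_population(
            genome, markers, n_tetrads=sim["n_tetrads"], seed=_stage_seed(seed, "f1")
        )
        f2, f2_truth = simulate.generate_f2_population(
            f1, genome, n_crosses=sim["n_f2"], seed=_stage_seed(seed, "f2")
        )
        rng = np.random.default_rng(_stage_seed(seed, "specs"))
        marker_df = markers.df
        qtl_rows = []
        for t in range(sim["n_traits"]):
            for _ in range(sim["qtl_per_trait"]):
                j = int(rng.integers(0, len(marker_df)))
                qtl_rows.append(
                    (f"trait_{t}", marker_df.iloc[j]["chrom"],
                     int(marker_df.iloc[j]["pos"]), sim["qtl_effect"])
                )
        qtl_spec = simulate.make_qtl_spec(qtl_rows)
        phenotypes, pheno_truth = simulate.simulate_phenotypes(
            f1, qtl_spec, noise_sd=sim["noise_sd"],
            n_parent_replicates=sim["n_parent_replicates"],
            genome=genome, seed=_stage_seed(seed, "phenotypes"),
        )
        genes = simulate.default_genes(
            genome, n_genes=sim["n_genes"], seed=_stage_seed(seed, "genes")
        )
        cold = genome.nonrecombining[0] if genome.nonrecombining else None
        hotspots = []
        if sim["hotspot_genes"] and cold is not None:
            hotspots.append((cold.chrom, (cold.start + cold.end) // 2, sim["hotspot_genes"] // 2))
            other = [c for c in genome.chromosome_names if c != cold.chrom][0]
            hotspots.append((other, genome.length(other) // 2, sim["hotspot_genes"] - sim["hotspot_genes"] // 2))
        eqtl_spec = simulate.make_eqtl_spec(
            genes, markers, n_local=sim["n_local_eqtl"], n_distant=sim["n_distant_eqtl"],
            hotspots=hotspots, effect_size=sim["eqtl_effect"],
            seed=_stage_seed(seed, "eqtl_spec"),
        )
        expr, expr_truth = simulate.simulate_expression(
            f2, genes, eqtl_spec, dispersion=sim["dispersion"],
            gc_bias_factor=sim["gc_bias_factor"], genome=genome,
            seed=_stage_seed(seed, "expression"),
        )
        obs = simulate.simulate_observations(
            f2,
            simulate.ObservationModel(sim["coverage_mean"], sim["error_rate"]),
            seed=_stage_seed(seed, "observations"),
        )
        write_genotype_table(f1, out_dir / "f1_genotypes.tsv")
        phenotypes.to_csv(out_dir / "phenotypes.tsv", sep="\t", index=False)
        expr.counts.to_csv(out_dir / "expression_counts.tsv", sep="\t")
        genes.to_csv(out_dir / "genes.tsv", sep="\t", index=False)
        obs.to_tsv(out_dir / "allele_counts.tsv")
        truth_doc = {
            "qtl_spec": qtl_spec.to_dict(orient="records"),
            "eqtl_spec": eqtl_spec.to_dict(orient="records"),
            "f2_balance": f2_truth.meta.get("balance_out_of_band_markers"),
        }
        (out_dir / "truth.json").write_text(json.dumps(truth_doc, indent=1, sort_keys=True))
        outputs += [
            out_dir / n
            for n in ("f1_genotypes.tsv", "phenotypes.tsv", "expression_counts.tsv",
                      "genes.tsv", "allele_counts.tsv", "truth.json")
        ]

        # -- genotype (F2 from read counts) ---------------------------------
        stage = "genotype"
        geno_cfg = config["genotyping"]
        rules = genotyping.GenotypingRules(
            min_coverage=geno_cfg["min_coverage"],
            max_na_fraction=geno_cfg["max_na_fraction"],
            balance_window=tuple(geno_cfg["balance_window"]),
            coding_only=geno_cfg["coding_only"],
        )
        f2_called = genotyping.assign_allelic_origin(obs, rules=rules)
        f2_filtered, report = genotyping.filter_markers(f2_called, rules)
        report.to_csv(out_dir / "filter_report.tsv", sep="\t", index=False)
        grid = genotyping.PseudomarkerGrid(**config["pseudomarkers"])
        f2_pseudo = genotyping.collapse_pseudomarkers(f2_filtered, genome, grid)
        f1_pseudo = genotyping.collapse_pseudomarkers(f1, genome, grid)
        write_genotype_table(f2_pseudo, out_dir / "f2_pseudomarkers.tsv")
        write_genotype_table(f1_pseudo, out_dir / "f1_pseudomarkers.tsv")
        outputs += [
            out_dir / n
            for n in ("filter_report.tsv", "f2_pseudomarkers.tsv", "f1_pseudomarkers.tsv")
        ]

        # -- recombination --------------------------------------------------
        stage = "recombination"
        summary_rows = []
        for label, pop in (("F1", f1), ("F2", f2_filtered)):
            s = recombination.count_events(pop)
            summary_rows.append(
                {"population": label, "mean_events": round(s.mean, 4),
                 "min": s.min, "max": s.max, "n_strains": len(s.per_strain)}
            )
        if cold is not None:
            for label, pop in (("F1", f1), ("F2", f2_filtered)):
                summary_rows.append(
                    {"population": f"{label}_introgression_per_mb",
                     "mean_events": recombination.region_recombination(pop, cold),
                     "min": 0, "max": 0, "n_strains": pop.n_strains}
                )
        pd.DataFrame(summary_rows).to_csv(out_dir / "recombination.tsv", sep="\t", index=False)
        outputs.append(out_dir / "recombination.tsv")

        # -- quantgen -------------------------------------------------------
        stage = "quantgen"
        h2 = quantgen.fitness_heritability(phenotypes)
        h2.to_csv(out_dir / "heritability.tsv", sep="\t", index=False)
        log2_expr, sf = quantgen.normalize_counts(
            quantgen.ExpressionMatrix(expr.counts, genes, expr.library_sizes),
            min_count=32, split_introgression=True,
        )
        sf.to_csv(out_dir / "size_factors.tsv", sep="\t")
        outputs += [out_dir / "heritability.tsv", out_dir / "size_factors.tsv"]

        # -- linkage --------------------------------------------------------
        stage = "linkage"
        link_cfg = config["linkage"]
        probs_f1 = linkage.genotype_probabilities(
            f1_pseudo, genome, cm_per_kb=link_cfg["cm_per_kb"], eps=link_cfg["eps"]
        )
        trait_matrix = quantgen.segregant_trait_matrix(phenotypes)
        qtl_calls, _ = linkage.scan_traits(
            probs_f1, trait_matrix, n_perm=link_cfg["n_perm"], alpha=link_cfg["alpha"],
            genome=genome, seed=_stage_seed(seed, "qtl_perms"),
        )
        _calls_to_frame(qtl_calls).to_csv(out_dir / "qtl.tsv", sep="\t", index=False)

        eqtl_cfg = config["eqtl"]
        probs_f2 = linkage.genotype_probabilities(
            f2_pseudo, genome, cm_per_kb=link_cfg["cm_per_kb"], eps=link_cfg["eps"]
        )
        grid_vals = np.arange(
            eqtl_cfg["grid_start"], eqtl_cfg["grid_stop"] + 1e-9, eqtl_cfg["grid_step"]
        )
        fdr = linkage.eqtl_fdr(
            probs_f2, log2_expr, grid_vals, n_perm=eqtl_cfg["n_perm"],
            nominal=eqtl_cfg["nominal_fdr"], seed=_stage_seed(seed, "eqtl_perms"),
        )
        fdr.table.round(6).to_csv(out_dir / "fdr_curve.tsv", sep="\t", index=False)
        eqtl_threshold = (
            fdr.chosen_threshold if fdr.chosen_threshold is not None else float(grid_vals[-1])
        )
        eqtl_calls = linkage.call_eqtl(probs_f2, log2_expr, eqtl_threshold, genome=genome)
        outputs += [out_dir / "qtl.tsv", out_dir / "fdr_curve.tsv"]

        # -- architecture ---------------------------------------------------
        stage = "architecture"
        arch_cfg = config["architecture"]
        gene_table = genes[genes["gene"].isin(log2_expr.index)].reset_index(drop=True)
        eqtl_calls = arch.classify_local_distant(
            eqtl_calls, gene_table, genome=genome, buffer_bp=arch_cfg["buffer_bp"]
        )
        _calls_to_frame(eqtl_calls).to_csv(out_dir / "eqtl.tsv", sep="\t", index=False)
        outputs.append(out_dir / "eqtl.tsv")
        hotspot_rows = []
        if eqtl_calls:
            for b in arch.detect_hotspots(
                eqtl_calls, genome, bin_size=arch_cfg["bin_size"], distant_only=True
            ):
                if b.significant:
                    hotspot_rows.append(
                        {"chrom": b.interval.chrom, "start": b.interval.start,
                         "end": b.interval.end, "observed": b.observed,
                         "expected": round(b.expected, 6), "p_value": b.p_value}
                    )
        pd.DataFrame(
            hotspot_rows, columns=["chrom", "start", "end", "observed", "expected", "p_value"]
        ).to_csv(out_dir / "hotspots.tsv", sep="\t", index=False)
        outputs.append(out_dir / "hotspots.tsv")
        if cold is not None and eqtl_calls:
            rest = [
                Interval(c, 1, genome.length(c))
                for c in genome.chromosome_names
                if c != cold.chrom
            ] + [Interval(cold.chrom, cold.end + 1, genome.length(cold.chrom))]
            local_calls = [c for c in eqtl_calls if c.label == "local"]
            dens_intro = arch.regional_density(local_calls, gene_table, [cold])
            dens_rest = arch.regional_density(local_calls, gene_table, rest)
            dens = pd.concat(
                [dens_intro.assign(region="introgression"),
                 dens_rest.assign(region="rest")]
            )
            dens.round(6).to_csv(out_dir / "local_density.tsv", sep="\t", index=False)
            outputs.append(out_dir / "local_density.tsv")

        # -- manifest -------------------------------------------------------
        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": seed,
            "config": {k: v for k, v in config.items() if k != "out_dir"},
            "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return manifest
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage failures are reported uniformly
        (out_dir / "FAILED").write_text(f"{stage}: {exc}\n")
        raise PipelineError(stage, str(exc)) from exc
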