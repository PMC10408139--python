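"""End-to-end orchestration of the signature analysis.

Stage order mirrors the analysis itself: differential expression per
sex x genotype contrast -> signature extraction -> cross-species
translation -> summed z-score projection onto the reference and
clinical cohorts -> correlation/clustering -> preranked enrichment and
cross-contrast discordance. Every stochastic stage is driven by the
single config seed, and re-running an identical config reproduces every
numeric output byte-for-byte (the manifest carries no timestamps).

By default every input is synthesized by :mod:`oxsig.simulate`; real
count matrices, expression cohorts, clinical tables, ortholog maps and
GMT collections can be swapped in through the config paths, and an
externally produced DEG table can replace the built-in test via
:func:`import_deg_table`.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as oio
from . import __version__
from .diffexpr import (
    cpm_normalize,
    differential_expression,
    extract_signature,
    signature_overlaps,
)
from .enrichment import (
    GeneSetCollection,
    discordant_pathways,
    gsea_preranked,
    nes_matrix,
    rank_genes,
    read_gmt,
    write_gmt,
)
from .orthologs import (
    load_ortholog_map,
    translate_matrix,
    translate_signature,
    write_ortholog_map,
)
from .scoring import score_signatures
from .signature import GeneSignature, write_signatures
from .simulate import (
    SEXES,
    GENOTYPES,
    ContrastEffects,
    MouseDesign,
    PlantedEffects,
    mouse_gene_symbols,
    simulate_clinical_cohort,
    simulate_mouse_counts,
    simulate_ortholog_map,
    simulate_reference_cohort,
)
from .stats import clinical_correlation, cluster_signatures, inter_signature_correlation

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "import_deg_table",
           "default_planted_effects"]

logger = logging.getLogger(__name__)

import_deg_table = oio.read_deg_table


class ConfigError(ValueError):
    """Raised when a pipeline config fails validation."""


@dataclass
class PipelineConfig:
    """Declarative configuration of a full pipeline run.

    Any input left at its default is synthesized; a ``*_path`` field
    switches that stage to loading from disk. Thresholds default to the
    study's conventions: FDR <= 0.05 with fold change >= 1.5x for
    differential expression, FDR < 0.25 for enrichment.
    """

    outdir: str
    seed: int
    # mouse counts
    counts_path: str | None = None
    metadata_path: str | None = None
    n_genes: int = 2000
    n_per_group: int = 6
    dispersion: float = 0.05
    planted_lfc: float = 2.0
    # thresholds
    fdr_max: float = 0.05
    min_fold: float = 1.5
    gsea_fdr_max: float = 0.25
    n_perm: int = 1000
    # reference cohort (healthy lung stand-in)
    reference_path: str | None = None
    n_reference_samples: int = 578
    # clinical cohort
    clinical_expr_path: str | None = None
    clinical_table_path: str | None = None
    severity_counts: tuple = (43, 40, 13, 15)
    delta: float = 0.5
    # ortholog map
    ortholog_path: str | None = None
    frac_one_to_one: float = 0.90
    frac_one_to_many: float = 0.05
    frac_missing: float = 0.05
    # gene sets
    gmt_path: str | None = None
    n_random_sets: int = 25
    random_set_size: int = 40

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is required")
        for name in ("fdr_max", "gsea_fdr_max", "n_perm"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.min_fold <= 1:
            raise ConfigError("min_fold must exceed 1")
        needs_orthologs = self.reference_path or self.clinical_expr_path
        if needs_orthologs and not self.ortholog_path:
            raise ConfigError(
                "an ortholog map (ortholog_path) is required when human "
                "expression matrices are supplied for scoring"
            )
        if (self.counts_path is None) != (self.metadata_path is None):
            raise ConfigError("counts_path and metadata_path must be given together")
        if (self.clinical_expr_path is None) != (self.clinical_table_path is None):
            raise ConfigError(
                "clinical_expr_path and clinical_table_path must be given together"
            )
        for name in ("counts_path", "metadata_path", "reference_path",
                     "clinical_expr_path", "clinical_table_path",
                     "ortholog_path", "gmt_path"):
            value = getattr(self, name)
            if value and not Path(value).exists():
                raise ConfigError(f"{name} does not exist: {value}")

    def echo(self) -> dict:
        return {k: v for k, v in dataclasses.asdict(self).items()}


def default_planted_effects(
    n_genes: int, lfc: float = 2.0, dispersion: float = 0.05
) -> PlantedEffects:
    """Planted per-contrast effects for the default synthetic study.

    The KO female contrast carries by far the largest response (the
    pattern the study design probes), and the two female contrasts share
    36 up- and 8 down-regulated genes so the overlap table is nontrivial.
    """
    genes = mouse_gene_symbols(n_genes)
    if n_genes < 600:
        raise ValueError("default planted effects need n_genes >= 600")

    def block(a, b):
        return {g: lfc for g in genes[a:b]}

    contrasts = {
        ("F", "KO"): ContrastEffects(up=block(0, 150), down=block(150, 250)),
        ("F", "WT"): ContrastEffects(
            up={**block(114, 150), **block(250, 274)},    # 36 shared with F_KO up
            down={**block(242, 250), **block(274, 306)},  # 8 shared with F_KO down
        ),
        ("M", "KO"): ContrastEffects(up=block(306, 386), down=block(386, 446)),
        ("M", "WT"): ContrastEffects(up=block(446, 496), down=block(496, 526)),
    }
    return PlantedEffects(contrasts=contrasts, dispersion=dispersion)


def _contrast_name(sex: str, genotype: str) -> str:
    return f"{sex}_{genotype}"


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write all artifacts under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)
    results: dict = {}

    # --- stage 1: counts -------------------------------------------------
    logger.info("stage counts")
    try:
        if config.counts_path:
            counts = oio.read_matrix(config.counts_path)
            metadata = oio.read_metadata(config.metadata_path)
            truth = None
        else:
            effects = default_planted_effects(
                config.n_genes, lfc=config.planted_lfc, dispersion=config.dispersion
            )
            design = MouseDesign(n_per_group=config.n_per_group, n_genes=config.n_genes)
            counts, metadata, truth = simulate_mouse_counts(design, effects, seed=seed)
            oio.write_matrix(counts, outdir / "counts.tsv")
            oio.write_metadata(metadata, outdir / "sample_metadata.csv")
            truth.write(outdir / "counts_truth.txt")
    except Exception as exc:
        raise RuntimeError(f"stage 'counts' failed: {exc}") from exc
    results["counts"] = counts
    results["metadata"] = metadata

    # --- stage 2: differential expression --------------------------------
    logger.info("stage differential expression")
    try:
        expr = cpm_normalize(counts)
        deg_tables = {}
        for sex, genotype in itertools.product(SEXES, GENOTYPES):
            name = _contrast_name(sex, genotype)
            mask = (metadata["sex"] == sex) & (metadata["genotype"] == genotype)
            sub = metadata.loc[mask]
            cols = sub["sample_id"].tolist()
            deg = differential_expression(
                expr[cols],
                sub["treatment"].to_numpy(),
                baseline="room_air",
                treatment="hyperoxia",
                contrast=name,
            )
            deg_tables[name] = deg
            oio.write_deg_table(deg, outdir / f"deg_{name}.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage 'differential_expression' failed: {exc}") from exc
    results["deg_tables"] = deg_tables

    # --- stage 3: signatures ---------------------------------------------
    logger.info("stage signatures")
    try:
        signatures = [
            extract_signature(deg, fdr_max=config.fdr_max, min_fold=config.min_fold,
                              name=name)
            for name, deg in deg_tables.items()
        ]
        write_signatures(signatures, outdir / "signatures.tsv")
        overlaps = signature_overlaps(signatures)
        overlaps.to_csv(outdir / "signature_overlaps.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'signatures' failed: {exc}") from exc
    results["signatures"] = signatures
    results["overlaps"] = overlaps

    # --- stage 4: ortholog map -------------------------------------------
    logger.info("stage orthologs")
    try:
        if config.ortholog_path:
            omap = load_ortholog_map(config.ortholog_path, direction="mouse->human")
        else:
            omap = simulate_ortholog_map(
                list(counts.index),
                frac_one_to_one=config.frac_one_to_one,
                frac_one_to_many=config.frac_one_to_many,
                frac_missing=config.frac_missing,
                seed=seed + 1,
            )
            write_ortholog_map(omap, outdir / "ortholog_map.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage 'orthologs' failed: {exc}") from exc
    results["ortholog_map"] = omap

    # --- stage 5: reference cohort scoring --------------------------------
    logger.info("stage reference scoring")
    try:
        if config.reference_path:
            reference = oio.read_matrix(config.reference_path)
        else:
            human_symbols = [s.upper() for s in counts.index]
            reference = simulate_reference_cohort(
                n_samples=config.n_reference_samples,
                n_genes=len(human_symbols),
                seed=seed + 2,
                symbols=human_symbols,
            )
            oio.write_matrix(reference, outdir / "reference_expression.tsv")
        ref_mouse, ref_report = translate_matrix(reference, omap.inverted())
        ref_scores = score_signatures(ref_mouse, signatures)
        oio.write_matrix(ref_scores.scores, outdir / "scores_reference.tsv")
        ref_corr = inter_signature_correlation(ref_scores)
        oio.write_matrix(ref_corr.r, outdir / "reference_correlation_r.tsv")
        oio.write_matrix(ref_corr.p, outdir / "reference_correlation_p.tsv")
        clustering = cluster_signatures(ref_corr)
        (outdir / "reference_cluster_order.txt").write_text(
            "\n".join(clustering.order) + "\n"
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'reference_scoring' failed: {exc}") from exc
    results["reference_scores"] = ref_scores
    results["reference_correlation"] = ref_corr
    results["reference_clustering"] = clustering

    # --- stage 6: clinical cohort ----------------------------------------
    logger.info("stage clinical")
    try:
        if config.clinical_expr_path:
            clin_expr = oio.read_matrix(config.clinical_expr_path)
            clinical = oio.read_clinical(config.clinical_table_path)
        else:
            planted_sig = max(signatures, key=len)
            human_sig, _ = translate_signature(planted_sig, omap)
            human_symbols = [s.upper() for s in counts.index]
            # expansion targets outside the cohort's universe cannot be planted
            universe = frozenset(human_symbols)
            human_sig = GeneSignature(
                name=human_sig.name,
                up=human_sig.up & universe,
                down=human_sig.down & universe,
                provenance=human_sig.provenance,
            )
            clin_expr, clinical, clin_truth = simulate_clinical_cohort(
                severity_counts=config.severity_counts,
                delta=config.delta,
                signature=human_sig,
                n_genes=len(human_symbols),
                seed=seed + 3,
                symbols=human_symbols,
            )
            oio.write_matrix(clin_expr, outdir / "clinical_expression.tsv")
            oio.write_clinical(clinical, outdir / "clinical_table.csv")
            clin_truth.write(outdir / "clinical_truth.txt")
        clin_mouse, _ = translate_matrix(clin_expr, omap.inverted())
        clin_scores = score_signatures(clin_mouse, signatures)
        oio.write_matrix(clin_scores.scores, outdir / "scores_clinical.tsv")
        clin_report = clinical_correlation(clin_scores, clinical)
        clin_report.to_csv(
            outdir / "clinical_correlation.tsv", sep="\t", index=False,
            float_format=oio.FLOAT_FORMAT,
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'clinical' failed: {exc}") from exc
    results["clinical_scores"] = clin_scores
    results["clinical_correlation"] = clin_report

    # --- stage 7: enrichment ----------------------------------------------
    logger.info("stage enrichment")
    try:
        if config.gmt_path:
            collection = read_gmt(config.gmt_path)
        else:
            collection = _simulated_gene_sets(counts.index, config, seed + 4)
            write_gmt(collection, outdir / "gene_sets.gmt")
        gsea_results = {}
        for i, (name, deg) in enumerate(sorted(deg_tables.items())):
            ranked = rank_genes(deg)
            table = gsea_preranked(
                ranked, collection, seed=seed + 10 + i, n_perm=config.n_perm
            )
            gsea_results[name] = table
            table.to_csv(outdir / f"gsea_{name}.tsv", sep="\t",
                         float_format=oio.FLOAT_FORMAT)
        nes = nes_matrix(gsea_results, fdr_max=config.gsea_fdr_max)
        oio.write_matrix(nes, outdir / "nes_matrix.tsv")
        if not nes.empty:
            discord = discordant_pathways(nes, "F_KO", "F_WT")
            discord.to_csv(outdir / "discordant_pathways.tsv", sep="\t",
                           float_format=oio.FLOAT_FORMAT)
            results["discordant"] = discord
            nes_corr = nes.fillna(0.0).corr()
            nes_cluster = cluster_signatures(nes_corr)
            (outdir / "nes_cluster_order.txt").write_text(
                "\n".join(nes_cluster.order) + "\n"
            )
            results["nes_clustering"] = nes_cluster
    except Exception as exc:
        raise RuntimeError(f"stage 'enrichment' failed: {exc}") from exc
    results["gsea"] = gsea_results
    results["nes_matrix"] = nes

    # --- manifest ----------------------------------------------------------
    manifest = {"oxsig_version": __version__, "config": config.echo()}
    oio.write_manifest(manifest, outdir / "manifest.txt")
    results["outdir"] = outdir
    return results


def _simulated_gene_sets(symbols, config: PipelineConfig, seed: int) -> GeneSetCollection:
    """Planted pathways (one per contrast's planted up-block) + random sets."""
    symbols = list(symbols)
    effects = default_planted_effects(config.n_genes, lfc=config.planted_lfc)
    sets = {}
    descriptions = {}
    for (sex, genotype), eff in sorted(effects.contrasts.items()):
        name = f"PLANTED_{_contrast_name(sex, genotype)}_UP"
        members = sorted(eff.up)[:30]
        sets[name] = frozenset(members)
        descriptions[name] = f"first planted up-genes of {_contrast_name(sex, genotype)}"
    rng = np.random.default_rng(seed)
    for i in range(config.n_random_sets):
        members = rng.choice(symbols, size=config.random_set_size, replace=False)
        name = f"RANDOM_{i + 1:03d}"
        sets[name] = frozenset(members.tolist())
        descriptions[name] = "random control set"
    return GeneSetCollection(sets=sets, descriptions=descriptions)
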