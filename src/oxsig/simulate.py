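"""Synthetic data generators for the hyperoxia signature pipeline.

Every downstream stage (differential expression, cross-species scoring,
clinical correlation, enrichment) is exercised on data produced here, so
the generators emulate the statistical structure the analysis assumes:

* mouse lung RNA-seq counts under a 2 x 2 x 2 factorial design
  (sex x genotype x treatment) with negative-binomial noise and planted
  per-contrast log2 fold changes;
* a large healthy reference expression cohort (log scale, heterogeneous
  per-gene means/variances, low-rank shared covariance) standing in for
  adult lung transcriptomes;
* a clinical cohort with ordinal BPD severity (default composition
  43 no / 40 mild / 13 moderate / 15 severe, n = 111), gestational age
  and birth weight negatively correlated with severity, oxygen need at
  28 days, and an additive planted shift of signature genes along
  severity;
* Biomart-style ortholog symbol maps with a configurable mixture of
  1:1, 1:many and missing mappings.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .orthologs import OrthologMap
from .signature import GeneSignature

__all__ = [
    "SEXES",
    "GENOTYPES",
    "TREATMENTS",
    "MouseDesign",
    "ContrastEffects",
    "PlantedEffects",
    "ClinicalSimConfig",
    "SimulationTruth",
    "mouse_gene_symbols",
    "human_gene_symbols",
    "simulate_mouse_counts",
    "simulate_reference_cohort",
    "simulate_clinical_cohort",
    "simulate_ortholog_map",
]

SEXES = ("F", "M")
GENOTYPES = ("WT", "KO")
TREATMENTS = ("room_air", "hyperoxia")

_TREATMENT_TAG = {"room_air": "RA", "hyperoxia": "HYX"}


def mouse_gene_symbols(n_genes: int) -> list:
    """Synthetic gene symbols following the mouse convention (capitalized)."""
    return [f"Sim{i:05d}" for i in range(n_genes)]


def human_gene_symbols(n_genes: int) -> list:
    """Synthetic gene symbols following the human convention (upper case)."""
    return [s.upper() for s in mouse_gene_symbols(n_genes)]


@dataclass(frozen=True)
class MouseDesign:
    """2 x 2 x 2 factorial design: sex x genotype x treatment.

    ``n_per_group`` replicates occupy each of the 8 design cells.
    """

    n_per_group: int
    n_genes: int

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError(f"n_per_group must be >= 2, got {self.n_per_group}")
        if self.n_genes < 10:
            raise ValueError(f"n_genes must be >= 10, got {self.n_genes}")

    @property
    def cells(self):
        return list(itertools.product(SEXES, GENOTYPES, TREATMENTS))


@dataclass(frozen=True)
class ContrastEffects:
    """Planted effects for one hyperoxia-vs-room-air contrast.

    ``up`` and ``down`` map gene symbol -> |log2 fold change| (> 0); up
    genes are raised and down genes lowered in the hyperoxia samples of
    the targeted sex x genotype cell only.
    """

    up: Mapping
    down: Mapping

    def __post_init__(self):
        object.__setattr__(self, "up", dict(self.up))
        object.__setattr__(self, "down", dict(self.down))
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ValueError(f"up/down overlap within a contrast: {sorted(overlap)[:5]}")
        for gene, lfc in itertools.chain(self.up.items(), self.down.items()):
            if not lfc > 0:
                raise ValueError(f"planted |log2FC| must be > 0 (gene {gene}: {lfc})")

    @property
    def genes(self):
        return set(self.up) | set(self.down)


@dataclass(frozen=True)
class PlantedEffects:
    """Per-contrast planted effects plus the count-noise model parameters.

    The negative binomial is parameterized mean/dispersion:
    Var = mu + dispersion * mu^2. Baseline per-gene log2 means are drawn
    uniformly over ``baseline_log2_mean_range`` (wide by default so
    library-size normalization is exercised nontrivially).
    """

    contrasts: Mapping = field(default_factory=dict)
    baseline_log2_mean_range: tuple = (2.0, 12.0)
    dispersion: float = 0.05

    def __post_init__(self):
        object.__setattr__(self, "contrasts", dict(self.contrasts))
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for key in self.contrasts:
            sex, genotype = key
            if sex not in SEXES or genotype not in GENOTYPES:
                raise ValueError(f"unknown contrast cell {key!r}")

    @property
    def genes(self):
        out = set()
        for eff in self.contrasts.values():
            out |= eff.genes
        return out


@dataclass(frozen=True)
class SimulationTruth:
    """Everything needed to recompute expectations in recovery tests."""

    seed: int
    planted: PlantedEffects | None = None
    delta: float | None = None
    signature_name: str | None = None

    def to_keyvalues(self) -> list:
        kv = [("seed", str(self.seed))]
        if self.delta is not None:
            kv.append(("delta", repr(self.delta)))
        if self.signature_name is not None:
            kv.append(("signature", self.signature_name))
        if self.planted is not None:
            kv.append(("dispersion", repr(self.planted.dispersion)))
            lo, hi = self.planted.baseline_log2_mean_range
            kv.append(("baseline_log2_mean_range", f"{lo!r},{hi!r}"))
            for (sex, genotype), eff in sorted(self.planted.contrasts.items()):
                for gene, lfc in sorted(eff.up.items()):
                    kv.append((f"planted.{sex}_{genotype}.up.{gene}", repr(lfc)))
                for gene, lfc in sorted(eff.down.items()):
                    kv.append((f"planted.{sex}_{genotype}.down.{gene}", repr(lfc)))
        return kv

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for key, value in self.to_keyvalues():
                fh.write(f"{key}={value}\n")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with Var = mu + dispersion * mu^2 (Poisson if 0)."""
    if dispersion == 0:
        return rng.poisson(mu)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mu)
    return rng.negative_binomial(size_param, p)


def simulate_mouse_counts(
    design: MouseDesign, effects: PlantedEffects, seed: int
) -> tuple:
    """Simulate the factorial mouse lung RNA-seq count matrix.

    Returns ``(counts, metadata, truth)``: a gene x sample integer
    DataFrame, a sample metadata DataFrame (sample_id, sex, genotype,
    treatment), and the :class:`SimulationTruth`.
    """
    symbols = mouse_gene_symbols(design.n_genes)
    universe = set(symbols)
    unknown = effects.genes - universe
    if unknown:
        raise ValueError(f"planted genes outside the gene universe: {sorted(unknown)[:5]}")

    rng = np.random.default_rng(seed)
    lo, hi = effects.baseline_log2_mean_range
    base_log2 = rng.uniform(lo, hi, size=design.n_genes)
    gene_index = {g: i for i, g in enumerate(symbols)}

    columns = {}
    meta_rows = []
    for sex, genotype, treatment in design.cells:
        log2_mu = base_log2.copy()
        if treatment == "hyperoxia" and (sex, genotype) in effects.contrasts:
            eff = effects.contrasts[(sex, genotype)]
            for gene, lfc in sorted(eff.up.items()):
                log2_mu[gene_index[gene]] += lfc
            for gene, lfc in sorted(eff.down.items()):
                log2_mu[gene_index[gene]] -= lfc
        mu = 2.0 ** log2_mu
        for rep in range(design.n_per_group):
            sample_id = f"{sex}_{genotype}_{_TREATMENT_TAG[treatment]}_{rep + 1}"
            columns[sample_id] = _nb_draw(rng, mu, effects.dispersion)
            meta_rows.append((sample_id, sex, genotype, treatment))

    counts = pd.DataFrame(columns, index=symbols)
    counts.index.name = "gene"
    metadata = pd.DataFrame(meta_rows, columns=["sample_id", "sex", "genotype", "treatment"])
    truth = SimulationTruth(seed=seed, planted=effects)
    return counts, metadata, truth


def simulate_reference_cohort(
    n_samples: int,
    n_genes: int,
    seed: int,
    n_factors: int = 5,
    symbols: Sequence | None = None,
) -> pd.DataFrame:
    """Simulate a healthy reference expression cohort on the log scale.

    Per-gene means and variances are heterogeneous and a low-rank shared
    component induces correlated variation across genes, so distinct gene
    sets can show correlated summed z-scores — the property the reference
    cohort is used to expose.
    """
    if n_samples < 3:
        raise ValueError(f"n_samples must be >= 3, got {n_samples}")
    if symbols is None:
        symbols = human_gene_symbols(n_genes)
    elif len(symbols) != n_genes:
        raise ValueError("len(symbols) != n_genes")
    rng = np.random.default_rng(seed)
    means = rng.uniform(2.0, 12.0, size=n_genes)
    sds = rng.uniform(0.3, 1.5, size=n_genes)
    loadings = rng.normal(0.0, 0.4, size=(n_genes, n_factors))
    factors = rng.normal(0.0, 1.0, size=(n_factors, n_samples))
    noise = rng.normal(0.0, 1.0, size=(n_genes, n_samples))
    values = means[:, None] + loadings @ factors + sds[:, None] * noise
    expr = pd.DataFrame(
        values, index=list(symbols), columns=[f"REF{i + 1:04d}" for i in range(n_samples)]
    )
    expr.index.name = "gene"
    return expr


@dataclass(frozen=True)
class ClinicalSimConfig:
    """Covariate model for the synthetic clinical cohort.

    Slopes and noise SDs are set so gestational age and birth weight
    correlate about -0.5 with ordinal severity under the default
    43/40/13/15 composition (sd(severity) ~ 1.02): the noise SD solves
    r = -slope*sd_sev / sqrt(slope^2 sd_sev^2 + sd_noise^2) = -0.5.
    """

    gestational_age_base: float = 29.0   # weeks at severity 0
    gestational_age_slope: float = 1.5   # weeks lost per severity level
    gestational_age_noise_sd: float = 2.66
    birth_weight_base: float = 1250.0    # grams at severity 0
    birth_weight_slope: float = 150.0    # grams lost per severity level
    birth_weight_noise_sd: float = 266.0
    oxygen_28d_prob: tuple = (0.10, 0.85, 0.95, 1.0)  # P(oxygen at 28d) by severity


def simulate_clinical_cohort(
    severity_counts: Sequence,
    delta: float,
    signature: GeneSignature,
    n_genes: int,
    seed: int,
    symbols: Sequence | None = None,
    config: ClinicalSimConfig = ClinicalSimConfig(),
) -> tuple:
    """Simulate an expression cohort with ordinal BPD severity.

    Up-signature genes are shifted by ``+delta * severity`` per-gene SDs
    and down-signature genes by ``-delta * severity``; severity levels are
    0 (no BPD), 1 (mild), 2 (moderate), 3 (severe). Sexes alternate within
    severity strata; gestational age and birth weight decline with
    severity per ``config``.

    Returns ``(expr, clinical, truth)`` with ``expr`` a gene x sample
    log-scale DataFrame and ``clinical`` indexed like the expression
    columns with columns sample_id, sex, gestational_age_weeks,
    birth_weight_g, bpd_severity, oxygen_28d.
    """
    severity_counts = [int(c) for c in severity_counts]
    if len(severity_counts) != 4 or min(severity_counts) < 0:
        raise ValueError("severity_counts must be 4 nonnegative integers")
    n_samples = sum(severity_counts)
    if n_samples < 4:
        raise ValueError(f"severity_counts must sum to >= 4, got {n_samples}")

    if symbols is None:
        symbols = human_gene_symbols(n_genes)
    elif len(symbols) != n_genes:
        raise ValueError("len(symbols) != n_genes")
    universe = set(symbols)
    missing = signature.genes - universe
    if missing:
        raise ValueError(
            f"signature genes outside the gene universe: {sorted(missing)[:5]}"
        )

    rng = np.random.default_rng(seed)
    severity = np.repeat(np.arange(4), severity_counts)
    sex = []
    for level, count in enumerate(severity_counts):
        sex.extend(["F", "M"][(i % 2)] for i in range(count))
    sex = np.array(sex)

    means = rng.uniform(4.0, 12.0, size=n_genes)
    sds = rng.uniform(0.5, 2.0, size=n_genes)
    values = means[:, None] + sds[:, None] * rng.normal(0.0, 1.0, size=(n_genes, n_samples))

    gene_index = {g: i for i, g in enumerate(symbols)}
    for gene in sorted(signature.up):
        i = gene_index[gene]
        values[i] += delta * sds[i] * severity
    for gene in sorted(signature.down):
        i = gene_index[gene]
        values[i] -= delta * sds[i] * severity

    sample_ids = [f"BPD{i + 1:03d}" for i in range(n_samples)]
    expr = pd.DataFrame(values, index=list(symbols), columns=sample_ids)
    expr.index.name = "gene"

    cfg = config
    ga = (
        cfg.gestational_age_base
        - cfg.gestational_age_slope * severity
        + rng.normal(0.0, cfg.gestational_age_noise_sd, size=n_samples)
    )
    bw = (
        cfg.birth_weight_base
        - cfg.birth_weight_slope * severity
        + rng.normal(0.0, cfg.birth_weight_noise_sd, size=n_samples)
    )
    ga = np.clip(ga, 22.0, None)
    bw = np.clip(bw, 300.0, None)
    oxy_p = np.array(cfg.oxygen_28d_prob)[severity]
    oxygen = (rng.random(n_samples) < oxy_p).astype(int)

    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "sex": sex,
            "gestational_age_weeks": ga,
            "birth_weight_g": bw,
            "bpd_severity": severity,
            "oxygen_28d": oxygen,
        }
    )
    truth = SimulationTruth(seed=seed, delta=delta, signature_name=signature.name)
    return expr, clinical, truth


def simulate_ortholog_map(
    symbols: Sequence,
    frac_one_to_one: float = 1.0,
    frac_one_to_many: float = 0.0,
    frac_missing: float = 0.0,
    seed: int = 0,
) -> OrthologMap:
    """Simulate a Biomart-style ortholog map from mouse to human symbols.

    Each source symbol is independently assigned 1:1 (target is the
    upper-cased symbol), 1:many (two upper-cased targets), or missing.
    Any probability mass left over from the three fractions falls to 1:1.
    Unmapped sources are reported on the returned map.
    """
    fracs = (frac_one_to_one, frac_one_to_many, frac_missing)
    if min(fracs) < 0:
        raise ValueError("fractions must be nonnegative")
    total = sum(fracs)
    if total > 1 + 1e-12:
        raise ValueError(f"fractions sum to {total} > 1")
    p_one = frac_one_to_one + (1.0 - total)  # remainder defaults to 1:1

    rng = np.random.default_rng(seed)
    cats = rng.choice(3, size=len(symbols), p=[p_one, frac_one_to_many, frac_missing])
    pairs = []
    unmapped = []
    for sym, cat in zip(symbols, cats):
        if cat == 0:
            pairs.append((sym, sym.upper()))
        elif cat == 1:
            pairs.append((sym, sym.upper()))
            pairs.append((sym, sym.upper() + "B"))
        else:
            unmapped.append(sym)
    return OrthologMap(
        pairs=tuple(pairs),
        direction="mouse->human",
        unmapped_sources=tuple(unmapped),
    )
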