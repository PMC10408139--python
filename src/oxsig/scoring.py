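"""Summed z-score signature scoring.

The central statistic: each gene's expression is standardized across all
samples of a cohort (sample SD, n-1 denominator), and a sample's score
for a signature is the sum of its z-scores over the signature's
up-regulated genes minus the sum over the down-regulated genes.

The score is a plain sum, not rescaled by signature size: downstream
Pearson correlations are scale-invariant, so size normalization would
not change any reported r. Genes missing from the matrix are skipped and
counted in a coverage report (non-conserved orthologs vanish the same
way); zero-variance genes have undefined z and contribute exactly 0,
the unique value preserving the up/down antisymmetry of the score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .signature import GeneSignature

__all__ = ["ZMatrix", "ScoreMatrix", "SignatureCoverage", "zscore_matrix",
           "summed_zscore", "score_signatures"]


@dataclass(frozen=True)
class ZMatrix:
    """Per-gene standardized expression; flagged genes had zero variance."""

    values: pd.DataFrame
    flagged: frozenset = frozenset()


@dataclass(frozen=True)
class SignatureCoverage:
    """How much of a signature was found in the scored matrix."""

    n_up_found: int
    n_up_total: int
    n_down_found: int
    n_down_total: int
    missing: tuple = ()

    @property
    def n_found(self) -> int:
        return self.n_up_found + self.n_down_found

    @property
    def fraction(self) -> float:
        total = self.n_up_total + self.n_down_total
        return self.n_found / total if total else 0.0


@dataclass(frozen=True)
class ScoreMatrix:
    """Signature x sample summed z-scores with per-signature coverage."""

    scores: pd.DataFrame
    coverage: Mapping = field(default_factory=dict)


def zscore_matrix(expr: pd.DataFrame) -> ZMatrix:
    """Standardize each gene row across samples.

    z_gs = (x_gs - mean_g) / sd_g with the sample SD (n-1 denominator).
    Zero-variance rows are set to all-zero and flagged. Requires at least
    two samples.
    """
    if expr.shape[1] < 2:
        raise ValueError("z-scoring requires >= 2 samples")
    values = expr.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("expression matrix contains missing values")
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    # constancy by range, not sd == 0: the mean of a constant row need
    # not be representable, leaving sd at a few ulp instead of zero
    constant = np.ptp(values, axis=1) == 0
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (values - mean) / sd_safe
    z[constant] = 0.0
    flagged = frozenset(expr.index[constant])
    zdf = pd.DataFrame(z, index=expr.index, columns=expr.columns)
    return ZMatrix(values=zdf, flagged=flagged)


def summed_zscore(z: ZMatrix, sig: GeneSignature) -> tuple:
    """Summed z-score of one signature for every sample.

    score_s = sum_{g in up & matrix} z_gs - sum_{g in down & matrix} z_gs.

    Returns ``(scores, coverage)`` where ``scores`` is a Series over
    samples. Raises if none of the signature's genes are present.
    """
    index = z.values.index
    present = set(index)
    up = sorted(sig.up & present)
    down = sorted(sig.down & present)
    if not up and not down:
        raise ValueError(
            f"signature {sig.name!r}: no signature genes present in the matrix"
        )
    arr = z.values.to_numpy()
    loc = {g: i for i, g in enumerate(index)}
    score = np.zeros(arr.shape[1])
    if up:
        score += arr[[loc[g] for g in up]].sum(axis=0)
    if down:
        score -= arr[[loc[g] for g in down]].sum(axis=0)
    coverage = SignatureCoverage(
        n_up_found=len(up),
        n_up_total=len(sig.up),
        n_down_found=len(down),
        n_down_total=len(sig.down),
        missing=tuple(sorted(sig.genes - present)),
    )
    return pd.Series(score, index=z.values.columns, name=sig.name), coverage


def score_signatures(expr: pd.DataFrame, sigs: Iterable[GeneSignature]) -> ScoreMatrix:
    """Score several signatures on one cohort with a shared z-matrix pass.

    A signature with zero coverage is dropped with a warning rather than
    failing the batch; at least one signature must survive.
    """
    sigs = list(sigs)
    if not sigs:
        raise ValueError("no signatures given")
    z = zscore_matrix(expr)
    rows = {}
    coverage = {}
    for sig in sigs:
        try:
            scores, cov = summed_zscore(z, sig)
        except ValueError:
            warnings.warn(
                f"signature {sig.name!r} has zero coverage on this matrix; dropped",
                stacklevel=2,
            )
            continue
        rows[sig.name] = scores
        coverage[sig.name] = cov
    if not rows:
        raise ValueError("no signature had any gene present in the matrix")
    scores = pd.DataFrame(rows).T
    scores.index.name = "signature"
    return ScoreMatrix(scores=scores, coverage=coverage)
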