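"""Correlation and clustering of signature scores.

Two uses: (1) pairwise Pearson correlation between signature scores over
a large reference cohort, with average-linkage hierarchical clustering
on 1 - r distance; (2) correlation of signature scores with clinical
variables (gestational age, birth weight, ordinal BPD severity, oxygen
need at 28 days), overall and stratified by sex.

Pearson p-values come from the exact t reference distribution
(t = r sqrt((n-2)/(1-r^2)) on n-2 df), matching scipy.stats.pearsonr.
Constant inputs yield a distinguished not-computable result rather than
r = 0. No multiple-testing correction is applied across clinical report
cells by default (raw r and p are reported); BH across cells is an
option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .diffexpr import bh_adjust
from .scoring import ScoreMatrix

__all__ = [
    "CorrResult",
    "CorrelationMatrix",
    "SignatureClustering",
    "pearson",
    "inter_signature_correlation",
    "cluster_signatures",
    "clinical_correlation",
    "DEFAULT_CLINICAL_VARIABLES",
]

DEFAULT_CLINICAL_VARIABLES = (
    "gestational_age_weeks",
    "birth_weight_g",
    "bpd_severity",
    "oxygen_28d",
)


@dataclass(frozen=True)
class CorrResult:
    r: float
    p: float
    n: int
    computable: bool = True


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise Pearson r (symmetric, unit diagonal) with p-values."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: int


@dataclass(frozen=True)
class SignatureClustering:
    """Leaf order and scipy linkage matrix of an average-linkage tree."""

    order: tuple
    linkage: np.ndarray


def pearson(x, y) -> CorrResult:
    """Pearson correlation with a two-sided t-distribution p-value.

    A constant input vector makes the correlation undefined; the result
    is flagged not-computable (r and p NaN) rather than reported as 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and the same length")
    n = x.size
    if n < 3:
        raise ValueError(f"pearson requires n >= 3, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrResult(r=float("nan"), p=float("nan"), n=n, computable=False)
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    # snap exact linear dependence (|r|=1 up to rounding) to +-1, p=0
    if 1.0 - abs(r) < 1e-12:
        return CorrResult(r=float(np.sign(r)), p=0.0, n=n)
    return CorrResult(r=r, p=float(res.pvalue), n=n)


def inter_signature_correlation(scores) -> CorrelationMatrix:
    """All pairwise Pearson correlations between signature score rows.

    Symmetry is enforced exactly (each pair computed once and mirrored).
    A constant score row leaves its correlations not-computable (NaN).
    """
    if isinstance(scores, ScoreMatrix):
        scores = scores.scores
    if scores.shape[0] < 2:
        raise ValueError("need >= 2 signatures")
    n = scores.shape[1]
    if n < 3:
        raise ValueError("need >= 3 samples")
    names = list(scores.index)
    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    p = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    arr = scores.to_numpy(dtype=float)
    for i in range(len(names)):
        if np.ptp(arr[i]) == 0:
            r.iloc[i, i] = np.nan
            p.iloc[i, i] = np.nan
        for j in range(i + 1, len(names)):
            res = pearson(arr[i], arr[j])
            r.iloc[i, j] = r.iloc[j, i] = res.r
            p.iloc[i, j] = p.iloc[j, i] = res.p
    return CorrelationMatrix(r=r, p=p, n=n)


def cluster_signatures(corr) -> SignatureClustering:
    """Average-linkage agglomerative clustering at distance 1 - r.

    Accepts a :class:`CorrelationMatrix` or a plain square r (or NES
    correlation) DataFrame. Rows are pre-sorted lexicographically by
    label so that equal-distance merges resolve in label order,
    making the leaf ordering deterministic.
    """
    rdf = corr.r if isinstance(corr, CorrelationMatrix) else corr
    if rdf.isna().to_numpy().any():
        raise ValueError(
            "correlation matrix contains not-computable entries; drop the "
            "offending rows before clustering"
        )
    labels = sorted(rdf.index)
    rdf = rdf.loc[labels, labels]
    if len(labels) == 1:
        return SignatureClustering(order=tuple(labels), linkage=np.empty((0, 4)))
    dist = 1.0 - rdf.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    linkage = hierarchy.average(squareform(dist, checks=False))
    order = tuple(labels[i] for i in hierarchy.leaves_list(linkage))
    return SignatureClustering(order=order, linkage=linkage)


def _strata(clinical: pd.DataFrame, stratify_by) -> list:
    strata = [("all", np.ones(len(clinical), dtype=bool))]
    for col in stratify_by:
        if col not in clinical.columns:
            raise ValueError(f"stratification column {col!r} not in clinical table")
    if len(stratify_by) >= 1:
        col = stratify_by[0]
        for level in sorted(clinical[col].unique()):
            strata.append((f"{col}={level}", (clinical[col] == level).to_numpy()))
    if len(stratify_by) == 2:
        c1, c2 = stratify_by
        for l1 in sorted(clinical[c1].unique()):
            for l2 in sorted(clinical[c2].unique()):
                mask = ((clinical[c1] == l1) & (clinical[c2] == l2)).to_numpy()
                strata.append((f"{c1}={l1},{c2}={l2}", mask))
    return strata


def clinical_correlation(
    scores,
    clinical: pd.DataFrame,
    variables: Sequence | None = None,
    stratify_by: Sequence = ("sex",),
    bh: bool = False,
) -> pd.DataFrame:
    """Correlate signature scores with clinical variables, by stratum.

    ``clinical`` must carry a ``sample_id`` column (or index) aligned
    with the score columns. Ordinal severity is used as coded (0-3);
    binary variables as 0/1. Default variables: gestational age, birth
    weight, BPD severity, oxygen at 28 days. Strata: all samples, each
    level of the stratification column(s), and their cross when two are
    given. Cells with fewer than 3 samples are reported not-computable.

    Returns a long DataFrame: signature, variable, stratum, n, r, p,
    computable (plus q when ``bh=True``).
    """
    if isinstance(scores, ScoreMatrix):
        scores = scores.scores
    clinical = clinical.copy()
    if "sample_id" in clinical.columns:
        clinical = clinical.set_index("sample_id")
    score_ids = list(scores.columns)
    clin_ids = list(clinical.index)
    if set(score_ids) != set(clin_ids):
        only_scores = sorted(set(score_ids) - set(clin_ids))
        only_clin = sorted(set(clin_ids) - set(score_ids))
        raise ValueError(
            f"sample ids misaligned between scores and clinical table; "
            f"scores-only: {only_scores[:5]}, clinical-only: {only_clin[:5]}"
        )
    clinical = clinical.loc[score_ids]
    if variables is None:
        variables = [v for v in DEFAULT_CLINICAL_VARIABLES if v in clinical.columns]
    for var in variables:
        if var not in clinical.columns:
            raise ValueError(f"clinical variable {var!r} not present")
        if not np.issubdtype(clinical[var].dtype, np.number):
            raise ValueError(f"clinical variable {var!r} is not numeric")
    if len(stratify_by) > 2:
        raise ValueError("at most two stratification columns supported")

    rows = []
    for stratum, mask in _strata(clinical, list(stratify_by)):
        n_strat = int(mask.sum())
        for sig_name in scores.index:
            svec = scores.loc[sig_name].to_numpy(dtype=float)[mask]
            for var in variables:
                cvec = clinical[var].to_numpy(dtype=float)[mask]
                if n_strat < 3:
                    res = CorrResult(float("nan"), float("nan"), n_strat, False)
                else:
                    res = pearson(svec, cvec)
                rows.append(
                    (sig_name, var, stratum, res.n, res.r, res.p, res.computable)
                )
    out = pd.DataFrame(
        rows, columns=["signature", "variable", "stratum", "n", "r", "p", "computable"]
    )
    if bh:
        ok = out["computable"].to_numpy()
        q = np.full(len(out), np.nan)
        if ok.any():
            q[ok] = bh_adjust(out.loc[ok, "p"].to_numpy())
        out["q"] = q
    return out
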