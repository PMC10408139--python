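"""Differential expression and signature extraction.

Counts are normalized to log2 counts-per-million, each hyperoxia vs
room-air contrast is tested gene-by-gene with Welch's t on the log2
scale, p-values are Benjamini-Hochberg adjusted per contrast, and
signatures are thresholded at FDR <= 0.05 with fold change >= 1.5x
(|log2FC| >= log2 1.5, boundaries inclusive).

The t-test is a deliberately simple, self-contained producer of the DEG
table; externally computed tables (e.g. from a negative-binomial GLM)
can be imported through :func:`oxsig.pipeline.import_deg_table` and feed
the identical downstream signature machinery.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .signature import GeneSignature

__all__ = [
    "cpm_normalize",
    "differential_expression",
    "bh_adjust",
    "extract_signature",
    "signature_overlaps",
]

CPM_PSEUDOCOUNT = 0.5
LIBRARY_PSEUDOCOUNT = 1.0


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """log2 counts-per-million: log2((count + 0.5) / (libsize + 1) * 1e6).

    ``counts`` is a gene x sample nonnegative integer matrix; the library
    size is the raw column sum. Pseudocounts are fixed so outputs are
    bit-reproducible.
    """
    values = counts.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("count matrix contains missing values")
    if (values < 0).any():
        raise ValueError("count matrix contains negative values")
    libsize = values.sum(axis=0)
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        bad = [str(counts.columns[i]) for i in zero]
        raise ValueError(f"all-zero sample column(s): {bad}")
    cpm = (values + CPM_PSEUDOCOUNT) / (libsize + LIBRARY_PSEUDOCOUNT)[None, :] * 1e6
    return pd.DataFrame(np.log2(cpm), index=counts.index, columns=counts.columns)


def differential_expression(
    expr: pd.DataFrame,
    labels: Sequence,
    baseline: str,
    treatment: str,
    contrast: str | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-gene two-group comparison on log-scale expression.

    log2FC is mean(treatment) - mean(baseline); the p-value is a
    two-sided t-test, pooled-variance by default (the two treatment arms
    share one noise model, and at the small group sizes typical here the
    Welch-Satterthwaite approximation is measurably conservative);
    ``equal_var=False`` selects Welch's test instead. Degenerate genes
    (zero variance in both groups) get p = 1 when the means are equal
    and p = 0 otherwise, and are flagged in the ``degenerate`` column.
    q-values are BH-adjusted within this contrast.

    Returns a DataFrame indexed by gene with columns log2_fold_change,
    p_value, q_value, degenerate; the contrast label is stored in
    ``df.attrs["contrast"]``.
    """
    labels = np.asarray(labels)
    if len(labels) != expr.shape[1]:
        raise ValueError("labels length does not match number of samples")
    mask_base = labels == baseline
    mask_trt = labels == treatment
    if mask_base.sum() < 2 or mask_trt.sum() < 2:
        raise ValueError(
            f"each group needs >= 2 samples (got {int(mask_base.sum())} "
            f"{baseline!r}, {int(mask_trt.sum())} {treatment!r})"
        )

    a = expr.to_numpy(dtype=float)[:, mask_trt]
    b = expr.to_numpy(dtype=float)[:, mask_base]
    lfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
        pvals = np.asarray(res.pvalue, dtype=float)

    # range-based constancy check: exact even for constants whose mean
    # is not representable (e.g. 4.2), where var underflows to ~1e-32
    degenerate = (np.ptp(a, axis=1) == 0) & (np.ptp(b, axis=1) == 0)
    # exact separation: no within-group noise at all
    pvals[degenerate & (lfc != 0)] = 0.0
    pvals[degenerate & (lfc == 0)] = 1.0
    pvals = np.clip(pvals, 0.0, 1.0)

    out = pd.DataFrame(
        {
            "log2_fold_change": lfc,
            "p_value": pvals,
            "q_value": bh_adjust(pvals),
            "degenerate": degenerate,
        },
        index=expr.index,
    )
    out.attrs["contrast"] = contrast or f"{treatment}_vs_{baseline}"
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    Sort ascending, q_(i) = min_{j >= i} p_(j) * m / j, clip to 1,
    return in the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def extract_signature(
    deg: pd.DataFrame,
    fdr_max: float = 0.05,
    min_fold: float = 1.5,
    name: str | None = None,
) -> GeneSignature:
    """Threshold a DEG table into a signature.

    up = {q <= fdr_max and log2FC >= log2(min_fold)};
    down = {q <= fdr_max and log2FC <= -log2(min_fold)}. Both boundaries
    inclusive; thresholds are recorded in the signature's provenance.
    """
    if fdr_max <= 0:
        raise ValueError("fdr_max must be positive")
    if min_fold <= 1:
        raise ValueError("min_fold must exceed 1")
    lfc_min = np.log2(min_fold)
    sig_mask = deg["q_value"] <= fdr_max
    up = frozenset(deg.index[sig_mask & (deg["log2_fold_change"] >= lfc_min)])
    down = frozenset(deg.index[sig_mask & (deg["log2_fold_change"] <= -lfc_min)])
    name = name or deg.attrs.get("contrast", "signature")
    return GeneSignature(
        name=name,
        up=up,
        down=down,
        provenance={"fdr_max": fdr_max, "min_fold": min_fold},
    )


def signature_overlaps(signatures: Iterable[GeneSignature]) -> pd.DataFrame:
    """Upset-style intersection counts across signatures.

    For every subset of >= 2 signatures, the number of genes up in all
    and down in all; for every ordered pair, the number of genes up in
    the first and down in the second (opposite direction).

    Returns a DataFrame with columns kind ('shared_up' / 'shared_down' /
    'opposite'), signatures (tuple of names; ordered pair for
    'opposite'), and count.
    """
    sigs = list(signatures)
    if len(sigs) < 2:
        raise ValueError("need at least 2 signatures")
    names = [s.name for s in sigs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate signature names: {names}")

    rows = []
    for size in range(2, len(sigs) + 1):
        for combo in itertools.combinations(sigs, size):
            combo_names = tuple(s.name for s in combo)
            shared_up = frozenset.intersection(*[s.up for s in combo])
            shared_down = frozenset.intersection(*[s.down for s in combo])
            rows.append(("shared_up", combo_names, len(shared_up)))
            rows.append(("shared_down", combo_names, len(shared_down)))
    for a, b in itertools.permutations(sigs, 2):
        rows.append(("opposite", (a.name, b.name), len(a.up & b.down)))
    return pd.DataFrame(rows, columns=["kind", "signatures", "count"])
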