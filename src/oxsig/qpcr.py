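"""qRT-PCR relative quantification by the 2^-ddCt method.

Target Ct values are normalized to the arithmetic mean of the
housekeeping-gene Cts of the same sample (equivalent to the geometric
mean of housekeeping expression levels), then referenced to the mean
delta-Ct of the reference group within the same sex stratum — fold
changes are always relative to room-air animals of the respective sex.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ddct_fold_change"]


def ddct_fold_change(
    ct: pd.DataFrame,
    target: str,
    housekeeping: Sequence,
    reference_group: str,
    group_col: str = "group",
    sex_col: str = "sex",
) -> pd.DataFrame:
    """Per-sample 2^-ddCt fold changes with sex-specific baselines.

    ``ct`` holds one row per sample with Ct columns for ``target`` and
    each housekeeping gene, plus group and sex labels.

    dCt_s  = Ct_target,s - mean(housekeeping Cts of sample s)
    ddCt_s = dCt_s - mean(dCt over reference-group samples of same sex)
    fold_s = 2^(-ddCt_s)

    Returns the input annotated with dct, ddct and fold columns.
    """
    housekeeping = list(housekeeping)
    if not housekeeping:
        raise ValueError("need at least one housekeeping gene")
    for col in [target, *housekeeping, group_col, sex_col]:
        if col not in ct.columns:
            raise ValueError(f"column {col!r} missing from Ct table")
    ct_values = ct[[target, *housekeeping]].to_numpy(dtype=float)
    if np.isnan(ct_values).any():
        raise ValueError("Ct table contains missing values")
    if (ct_values <= 0).any():
        raise ValueError("Ct values must be positive")

    out = ct.copy()
    out["dct"] = ct[target].to_numpy(dtype=float) - ct[housekeeping].to_numpy(
        dtype=float
    ).mean(axis=1)

    ddct = np.empty(len(out))
    for sex in sorted(out[sex_col].unique()):
        in_sex = out[sex_col] == sex
        ref = in_sex & (out[group_col] == reference_group)
        if not ref.any():
            raise ValueError(
                f"no {reference_group!r} reference samples in sex stratum {sex!r}"
            )
        baseline = out.loc[ref, "dct"].mean()
        ddct[in_sex.to_numpy()] = out.loc[in_sex, "dct"].to_numpy() - baseline
    out["ddct"] = ddct
    out["fold"] = 2.0 ** (-out["ddct"])
    return out
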