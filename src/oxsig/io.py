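"""Plain-text readers and writers for the pipeline's artifacts.

Counts and expression matrices are tab-delimited gene-by-sample text
(first column the gene symbol); metadata and clinical tables are CSV;
result tables are tab-delimited with headers; the run manifest and
simulation-truth sidecars are key=value text.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_metadata",
    "write_metadata",
    "read_clinical",
    "write_clinical",
    "read_deg_table",
    "write_deg_table",
    "write_manifest",
    "read_manifest",
]

FLOAT_FORMAT = "%.10g"

_CLINICAL_COLUMNS = [
    "sample_id",
    "sex",
    "gestational_age_weeks",
    "birth_weight_g",
    "bpd_severity",
    "oxygen_28d",
]

_DEG_ALIASES = {
    "gene": {"gene", "gene_symbol", "symbol"},
    "log2_fold_change": {"log2_fold_change", "log2fc", "logfc", "log2foldchange"},
    "p_value": {"p_value", "p", "pvalue", "pval"},
    "q_value": {"q_value", "q", "qvalue", "fdr", "adj_p", "padj"},
}


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene symbols {dups[:5]}")
    df.index.name = "gene"
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df = df.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    missing = {"sample_id", "sex", "genotype", "treatment"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    return df


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    missing = set(_CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing clinical columns {sorted(missing)}")
    return df


def write_clinical(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_deg_table(path, recompute_q: bool = False) -> pd.DataFrame:
    """Read an externally produced DEG table (header-mapped columns).

    Accepts tab- or comma-delimited text with columns recognizable as
    gene / log2 fold change / p / q (q optional when ``recompute_q``).
    """
    from .diffexpr import bh_adjust

    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    raw = pd.read_csv(path, sep=sep)
    lower = {c.lower().strip(): c for c in raw.columns}
    resolved = {}
    for canonical, aliases in _DEG_ALIASES.items():
        found = [lower[a] for a in aliases if a in lower]
        if found:
            resolved[canonical] = found[0]
    for required in ("gene", "log2_fold_change", "p_value"):
        if required not in resolved:
            raise ValueError(f"{path}: missing required column {required!r}")
    if "q_value" not in resolved and not recompute_q:
        raise ValueError(
            f"{path}: missing required column 'q_value' (pass recompute_q=True "
            f"to derive it from p-values)"
        )

    out = pd.DataFrame(
        {
            "log2_fold_change": raw[resolved["log2_fold_change"]].astype(float).to_numpy(),
            "p_value": raw[resolved["p_value"]].astype(float).to_numpy(),
        },
        index=raw[resolved["gene"]].astype(str),
    )
    out.index.name = "gene"
    if out.index.duplicated().any():
        raise ValueError(f"{path}: duplicate gene symbols")
    p = out["p_value"].to_numpy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError(f"{path}: p-values must lie in [0, 1]")
    if recompute_q or "q_value" not in resolved:
        out["q_value"] = bh_adjust(p)
    else:
        q = raw[resolved["q_value"]].astype(float).to_numpy()
        if np.isnan(q).any() or (q < 0).any() or (q > 1).any():
            raise ValueError(f"{path}: q-values must lie in [0, 1]")
        out["q_value"] = q
    out["degenerate"] = False
    return out


def write_deg_table(deg: pd.DataFrame, path) -> None:
    deg.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def write_manifest(entries, path) -> None:
    """Write key=value lines; nested mappings are flattened with dots."""

    def _flatten(prefix, obj, out):
        if isinstance(obj, dict):
            for key, value in obj.items():
                _flatten(f"{prefix}{key}.", value, out)
        else:
            out.append((prefix.rstrip("."), obj))

    flat = []
    _flatten("", dict(entries), flat)
    with open(path, "w") as fh:
        for key, value in flat:
            fh.write(f"{key}={value}\n")


def read_manifest(path) -> dict:
    out = {}
    with open(Path(path)) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            key, _, value = line.partition("=")
            out[key] = value
    return out
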