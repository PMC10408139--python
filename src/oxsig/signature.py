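"""Gene signatures: named up/down gene-symbol sets.

A signature is the unit projected across species and scored on human
cohorts: the genes up- and down-regulated by hyperoxia in one
sex x genotype group, together with the thresholds that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = ["GeneSignature", "read_signatures", "write_signatures"]


@dataclass(frozen=True)
class GeneSignature:
    """A named pair of disjoint up-/down-regulated gene-symbol sets.

    Parameters
    ----------
    name
        Label of the contrast that produced the signature, e.g. ``"F_KO"``.
    up, down
        Disjoint sets of gene symbols. ``up`` genes add their z-scores to a
        sample's summed z-score; ``down`` genes subtract theirs.
    provenance
        Free-form record of how the signature was derived (thresholds,
        source contrast, translation report).
    """

    name: str
    up: frozenset
    down: frozenset
    provenance: Mapping = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "up", frozenset(self.up))
        object.__setattr__(self, "down", frozenset(self.down))
        overlap = self.up & self.down
        if overlap:
            raise ValueError(
                f"signature {self.name!r}: up and down sets overlap: "
                f"{sorted(overlap)[:5]}"
            )

    @property
    def genes(self) -> frozenset:
        return self.up | self.down

    def __len__(self) -> int:
        return len(self.up) + len(self.down)

    def swapped(self) -> "GeneSignature":
        """Return the signature with up and down sets exchanged."""
        return GeneSignature(
            name=f"{self.name}_swapped",
            up=self.down,
            down=self.up,
            provenance=dict(self.provenance, swapped_from=self.name),
        )


def write_signatures(signatures: Iterable[GeneSignature], path) -> None:
    """Write signatures as tab-delimited text: signature, direction, gene."""
    rows = []
    for sig in signatures:
        for gene in sorted(sig.up):
            rows.append((sig.name, "up", gene))
        for gene in sorted(sig.down):
            rows.append((sig.name, "down", gene))
    df = pd.DataFrame(rows, columns=["signature", "direction", "gene"])
    df.to_csv(path, sep="\t", index=False)


def read_signatures(path) -> list:
    """Read signatures written by :func:`write_signatures`."""
    df = pd.read_csv(Path(path), sep="\t")
    missing = {"signature", "direction", "gene"} - set(df.columns)
    if missing:
        raise ValueError(f"signature file {path}: missing columns {sorted(missing)}")
    out = []
    for name, grp in df.groupby("signature", sort=False):
        up = frozenset(grp.loc[grp["direction"] == "up", "gene"])
        down = frozenset(grp.loc[grp["direction"] == "down", "gene"])
        out.append(GeneSignature(name=str(name), up=up, down=down))
    return out
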