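"""Cross-species gene-symbol translation.

Mouse-derived signatures are scored on human expression cohorts after
projecting gene symbols through an ortholog map (a Biomart-style
two-column table). The pipeline's default orientation translates the
HUMAN expression matrix into MOUSE symbol space and scores it with
untouched mouse signatures; the opposite orientation (translating the
signatures) is equivalent under a 1:1 map and is also provided.

Matching is case-sensitive: mouse and human conventions differ by case,
and silent case-folding would mask direction errors.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .signature import GeneSignature

__all__ = [
    "OrthologMap",
    "TranslationReport",
    "load_ortholog_map",
    "write_ortholog_map",
    "translate_matrix",
    "translate_signature",
]

logger = logging.getLogger(__name__)

_HEADER_WORDS = {"source", "target", "symbol", "gene", "source_symbol", "target_symbol"}


@dataclass(frozen=True)
class OrthologMap:
    """A set of (source_symbol, target_symbol) pairs with a direction label."""

    pairs: tuple
    direction: str = "unspecified"
    unmapped_sources: tuple = ()

    def __post_init__(self):
        seen = set()
        for pair in self.pairs:
            src, tgt = pair
            if not src or not tgt:
                raise ValueError(f"empty symbol in ortholog pair {pair!r}")
            if pair in seen:
                raise ValueError(f"duplicate ortholog pair {pair!r}")
            seen.add(pair)

    def source_to_targets(self) -> "OrderedDict":
        """Mapping source -> list of targets, in pair order."""
        out = OrderedDict()
        for src, tgt in self.pairs:
            out.setdefault(src, []).append(tgt)
        return out

    def inverted(self) -> "OrthologMap":
        """Swap source and target (e.g. mouse->human becomes human->mouse)."""
        if "->" in self.direction:
            a, b = self.direction.split("->", 1)
            direction = f"{b}->{a}"
        else:
            direction = f"inverse of {self.direction}"
        return OrthologMap(
            pairs=tuple((tgt, src) for src, tgt in self.pairs), direction=direction
        )

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class TranslationReport:
    """Accounting of a symbol-space translation."""

    n_translated: int
    n_dropped_unmapped: int
    n_collapsed_many_to_one: int
    n_expanded_one_to_many: int
    dropped: tuple = ()
    collapsed: tuple = ()
    expanded: tuple = ()
    conflicts: tuple = ()

    def __post_init__(self):
        if self.n_dropped_unmapped != len(self.dropped):
            raise ValueError("n_dropped_unmapped does not match dropped list")
        if self.n_collapsed_many_to_one != len(self.collapsed):
            raise ValueError("n_collapsed_many_to_one does not match collapsed list")
        if self.n_expanded_one_to_many != len(self.expanded):
            raise ValueError("n_expanded_one_to_many does not match expanded list")


def _looks_like_header(fields) -> bool:
    return all(f.strip().lower() in _HEADER_WORDS for f in fields)


def load_ortholog_map(path, direction: str = "unspecified") -> OrthologMap:
    """Load a two-column tab-delimited ortholog table (optional header).

    Duplicate pairs are deduplicated with a logged count; a line with a
    field count other than two is rejected with its line number.
    """
    path = Path(path)
    pairs = []
    seen = set()
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-delimited fields, got {len(fields)}"
                )
            if lineno == 1 and _looks_like_header(fields):
                continue
            pair = (fields[0].strip(), fields[1].strip())
            if pair in seen:
                n_dup += 1
                continue
            seen.add(pair)
            pairs.append(pair)
    if n_dup:
        logger.info("deduplicated %d repeated ortholog pairs in %s", n_dup, path)
    return OrthologMap(pairs=tuple(pairs), direction=direction)


def write_ortholog_map(omap: OrthologMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("source_symbol\ttarget_symbol\n")
        for src, tgt in omap.pairs:
            fh.write(f"{src}\t{tgt}\n")


def translate_matrix(expr: pd.DataFrame, omap: OrthologMap) -> tuple:
    """Translate the row symbols of a gene x sample matrix.

    Unmapped rows are dropped; several sources collapsing onto one target
    are averaged (arithmetic mean on the log scale); a source with several
    targets has its row duplicated under each. Row order follows the first
    occurrence of each target while scanning the input rows, so a
    bijective map and its inverse round-trip the matrix exactly.
    """
    src2tgt = omap.source_to_targets()
    present = [g for g in expr.index if g in src2tgt]
    if not present:
        raise ValueError(
            f"no matrix symbols found among the map's sources "
            f"(map direction {omap.direction!r}); wrong direction or species?"
        )
    dropped = tuple(g for g in expr.index if g not in src2tgt)

    tgt_sources = OrderedDict()
    for g in present:
        for tgt in src2tgt[g]:
            tgt_sources.setdefault(tgt, []).append(g)

    values = np.empty((len(tgt_sources), expr.shape[1]))
    for i, (tgt, sources) in enumerate(tgt_sources.items()):
        values[i] = expr.loc[sources].to_numpy().mean(axis=0)
    out = pd.DataFrame(values, index=list(tgt_sources), columns=expr.columns)
    out.index.name = expr.index.name

    expanded = tuple(g for g in present if len(src2tgt[g]) > 1)
    collapsed = tuple(t for t, sources in tgt_sources.items() if len(sources) > 1)
    report = TranslationReport(
        n_translated=len(present),
        n_dropped_unmapped=len(dropped),
        n_collapsed_many_to_one=len(collapsed),
        n_expanded_one_to_many=len(expanded),
        dropped=dropped,
        collapsed=collapsed,
        expanded=expanded,
    )
    return out, report


def translate_signature(sig: GeneSignature, omap: OrthologMap) -> tuple:
    """Translate a signature's up/down sets through an ortholog map.

    A gene that lands in both the translated up and down sets (possible
    after 1:many expansion) is removed from both and reported as a
    conflict.
    """
    src2tgt = omap.source_to_targets()
    genes = sig.genes
    present = [g for g in sorted(genes) if g in src2tgt]
    if not present:
        raise ValueError(
            f"no signature symbols found among the map's sources "
            f"(map direction {omap.direction!r}); wrong direction or species?"
        )
    dropped = tuple(g for g in sorted(genes) if g not in src2tgt)

    def _expand(symbols):
        out = {}
        for g in sorted(symbols):
            for tgt in src2tgt.get(g, ()):
                out.setdefault(tgt, []).append(g)
        return out

    up_map = _expand(sig.up)
    down_map = _expand(sig.down)
    conflicts = tuple(sorted(set(up_map) & set(down_map)))
    up = frozenset(t for t in up_map if t not in conflicts)
    down = frozenset(t for t in down_map if t not in conflicts)

    expanded = tuple(g for g in present if len(src2tgt[g]) > 1)
    collapsed = tuple(
        sorted(
            [t for t, s in up_map.items() if len(s) > 1]
            + [t for t, s in down_map.items() if len(s) > 1]
        )
    )
    report = TranslationReport(
        n_translated=len(present),
        n_dropped_unmapped=len(dropped),
        n_collapsed_many_to_one=len(collapsed),
        n_expanded_one_to_many=len(expanded),
        dropped=dropped,
        collapsed=collapsed,
        expanded=expanded,
        conflicts=conflicts,
    )
    translated = GeneSignature(
        name=sig.name,
        up=up,
        down=down,
        provenance=dict(sig.provenance, translation=omap.direction),
    )
    return translated, report
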