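"""Marker filtering, column trimming, and supermatrix concatenation.

The filtering rules mirror standard phylogenomic practice for ribosomal
protein datasets: markers absent from more than half of the genomes (or
with paralogy problems) are discarded, and taxa are admitted into the
concatenate as long as they miss at most a configured number of markers
(11 by default, matching a 47-marker ribosomal protein set).  Missing
marker blocks are filled with the fully ambiguous residue 'X', so the
likelihood stage treats them as no information rather than as gaps opened
by an aligner.

Column trimming is a light-weight stand-in for similarity-matrix trimmers:
a column is dropped when its gap fraction or its Shannon entropy (over
residues, gaps excluded) exceeds a threshold.  Defaults (0.2 gaps,
3.0 bits) are deliberately conservative and overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phylo_core import Alignment, GAP, MISSING, encode
from .synthetic_data import OrthologTable

__all__ = [
    "FilterReport",
    "Supermatrix",
    "filter_markers",
    "trim_columns",
    "concatenate",
    "column_entropy",
]


@dataclass
class FilterReport:
    removed: dict[str, str] = field(default_factory=dict)  # marker id -> reason

    def __str__(self) -> str:
        if not self.removed:
            return "no markers removed"
        return "\n".join(f"{m}\t{r}" for m, r in sorted(self.removed.items()))


def filter_markers(
    table: OrthologTable,
    max_absent_frac: float = 0.5,
    drop_paralogous: bool = True,
    exclude: list[str] | None = None,
) -> tuple[OrthologTable, FilterReport]:
    """Discard markers absent from strictly more than ``max_absent_frac``
    of the taxa, paralog-flagged markers (when ``drop_paralogous``), and
    explicitly excluded markers.  A marker absent from exactly the
    threshold fraction is retained."""
    if not 0 < max_absent_frac <= 1:
        raise ValueError("max_absent_frac must be in (0, 1]")
    exclude = set(exclude or ())
    report = FilterReport()
    kept: dict[str, dict[str, str]] = {}
    for mid in table.marker_ids():
        if mid in exclude:
            report.removed[mid] = "explicitly excluded"
            continue
        if drop_paralogous and mid in table.paralog_flags:
            report.removed[mid] = "paralogous copies"
            continue
        frac = table.absence_fraction(mid)
        if frac > max_absent_frac:
            report.removed[mid] = (
                f"absent from {frac:.0%} of taxa (> {max_absent_frac:.0%})"
            )
            continue
        kept[mid] = table.markers[mid]
    if not kept:
        raise ValueError(
            "no markers survive filtering; raise max_absent_frac or review "
            "the exclusion list"
        )
    flags = table.paralog_flags & set(kept)
    return OrthologTable(kept, flags, taxa=table.taxa), report


def column_entropy(column: np.ndarray) -> float:
    """Shannon entropy (bits) of the residue distribution in one column,
    ignoring gaps and missing characters."""
    residues = column[column < 20]
    if residues.size == 0:
        return 0.0
    counts = np.bincount(residues, minlength=20).astype(float)
    p = counts[counts > 0] / residues.size
    return float(-(p * np.log2(p)).sum())


def trim_columns(
    alignment: Alignment,
    max_gap_frac: float = 0.2,
    max_entropy: float = 3.0,
) -> tuple[Alignment, np.ndarray]:
    """Remove columns whose gap+missing fraction exceeds ``max_gap_frac``
    or whose residue entropy exceeds ``max_entropy`` bits.  Returns the
    trimmed alignment and the indices of the retained columns in the
    original coordinate system."""
    if not 0 <= max_gap_frac <= 1:
        raise ValueError("max_gap_frac must be in [0, 1]")
    if not 0 <= max_entropy <= np.log2(20) + 1e-9:
        raise ValueError("max_entropy must be in [0, log2(20)]")
    mat = alignment.matrix
    gap_frac = (mat >= 20).mean(axis=0)
    keep = np.array(
        [
            gap_frac[j] <= max_gap_frac and column_entropy(mat[:, j]) <= max_entropy
            for j in range(alignment.n_columns)
        ]
    )
    if alignment.n_columns and not keep.any():
        raise ValueError("trimming removed every column; relax the thresholds")
    idx = np.flatnonzero(keep)
    return alignment.select_columns(idx), idx


@dataclass
class Supermatrix:
    """A concatenated alignment with its partition map.

    ``partitions`` maps marker id to a half-open, 0-based column interval
    of the concatenate; intervals tile the full width in canonical
    (lexicographic marker id) order.  ``missing_counts`` records, per
    retained taxon, how many markers it lacked (those blocks are 'X'-
    filled).
    """

    alignment: Alignment
    partitions: dict[str, tuple[int, int]]
    missing_counts: dict[str, int]
    excluded_taxa: dict[str, int] = field(default_factory=dict)

    def partition_text(self) -> str:
        """RAxML-style partition lines, 1-based inclusive coordinates."""
        lines = []
        for mid, (start, stop) in self.partitions.items():
            lines.append(f"LG, {mid} = {start + 1}-{stop}")
        return "\n".join(lines) + "\n"

    def partition_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {"marker": mid, "start": s, "stop": e, "length": e - s}
                for mid, (s, e) in self.partitions.items()
            ]
        )


def concatenate(
    table: OrthologTable,
    max_missing_markers: int = 11,
) -> Supermatrix:
    """Concatenate the markers of ``table`` into a supermatrix.

    Taxa missing strictly more than ``max_missing_markers`` markers are
    excluded (a taxon missing exactly the maximum is retained).  Markers
    are laid out in lexicographic id order; blocks for absent taxa are
    filled with 'X'.
    """
    ids = table.marker_ids()
    if not ids:
        raise ValueError("ortholog table has no markers")
    missing = {t: table.missing_marker_count(t) for t in table.taxa}
    retained = [t for t in table.taxa if missing[t] <= max_missing_markers]
    excluded = {t: missing[t] for t in table.taxa if t not in retained}
    if len(retained) < 4:
        raise ValueError(
            f"only {len(retained)} taxa retained; no tree can be inferred"
        )
    partitions: dict[str, tuple[int, int]] = {}
    blocks = []
    offset = 0
    for mid in ids:
        seqs = table.markers[mid]
        width = table.marker_length(mid)
        block = np.full((len(retained), width), encode(MISSING)[0], dtype=np.uint8)
        for i, taxon in enumerate(retained):
            if taxon in seqs:
                block[i] = encode(seqs[taxon])
        blocks.append(block)
        partitions[mid] = (offset, offset + width)
        offset += width
    aln = Alignment(retained, np.concatenate(blocks, axis=1) if blocks else
                    np.zeros((len(retained), 0), dtype=np.uint8))
    return Supermatrix(
        alignment=aln,
        partitions=partitions,
        missing_counts={t: missing[t] for t in retained},
        excluded_taxa=excluded,
    )
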