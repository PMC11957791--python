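"""Concatenated marker supermatrix construction and tree-annotation export.

The phylogeny of rim-bearing accessions is inferred from seven widely
conserved single-copy markers (AtpD, DhaE, GuaA, GyrB, RecA, RpoB, RpoD),
aligned per marker with an external aligner and concatenated into one
amino-acid supermatrix per accession.  Columns consisting of more than 50%
gaps are deleted before tree inference (also external).  This module owns
the bespoke steps: concatenation with all-gap blocks for missing markers,
gap-column filtering, leaf-name validation against a Newick tree, and
iTOL colour-strip annotation files for the taxonomy and rim-class rings.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

#: Concatenation order of the marker proteins.
DEFAULT_MARKER_ORDER = ["AtpD", "DhaE", "GuaA", "GyrB", "RecA", "RpoB", "RpoD"]

DEFAULT_MAX_GAP_FRACTION = 0.5

#: Stable qualitative palette for annotation rings.
PALETTE = [
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
    "#aec7e8", "#ffbb78", "#98df8a", "#ff9896", "#c5b0d5",
]


@dataclass
class AlignmentMatrix:
    """A protein alignment: per-marker or concatenated.

    ``markers`` records (name, width) blocks in column order; their widths
    sum to the row length.  Gap character is ``-`` ('.' is normalised on
    read).
    """

    markers: list[tuple[str, int]]
    accessions: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.accessions) != len(self.rows):
            raise ValueError("accessions and rows differ in length")
        if len(set(self.accessions)) != len(self.accessions):
            dupes = sorted({a for a in self.accessions if self.accessions.count(a) > 1})
            raise ValueError(f"duplicate accessions in alignment: {dupes}")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError(f"ragged alignment rows: lengths {sorted(widths)}")
        if self.rows and sum(w for _, w in self.markers) != len(self.rows[0]):
            raise ValueError("marker widths do not sum to alignment width")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @classmethod
    def from_fasta(cls, source, marker_name: str) -> "AlignmentMatrix":
        if isinstance(source, str) and source.lstrip().startswith(">"):
            source = io.StringIO(source)
        accessions, rows = [], []
        for rec in SeqIO.parse(source, "fasta"):
            accessions.append(rec.id)
            rows.append(str(rec.seq).upper().replace(".", "-"))
        width = len(rows[0]) if rows else 0
        return cls(markers=[(marker_name, width)], accessions=accessions, rows=rows)

    def to_fasta(self, handle) -> None:
        close = False
        if isinstance(handle, str):
            handle = open(handle, "w")
            close = True
        try:
            for acc, row in zip(self.accessions, self.rows):
                handle.write(f">{acc}\n")
                for i in range(0, len(row), 60):
                    handle.write(row[i : i + 60] + "\n")
        finally:
            if close:
                handle.close()

    def partition_log(self) -> pd.DataFrame:
        """Marker boundaries as 1-based inclusive column ranges."""
        rows, start = [], 1
        for name, w in self.markers:
            rows.append({"marker": name, "start": start, "end": start + w - 1})
            start += w
        return pd.DataFrame(rows, columns=["marker", "start", "end"])


def concatenate_markers(
    per_marker: Sequence[AlignmentMatrix],
    marker_order: Optional[Sequence[str]] = None,
) -> AlignmentMatrix:
    """Concatenate single-marker alignments into one supermatrix.

    The output has one row per accession in the union; an accession missing
    from a marker receives an all-gap block of that marker's width, so no
    accession is dropped for incompleteness.
    """
    if not per_marker:
        raise ValueError("no marker alignments supplied")
    by_name = {}
    for m in per_marker:
        if len(m.markers) != 1:
            raise ValueError("per-marker input must hold exactly one marker each")
        name = m.markers[0][0]
        if name in by_name:
            raise ValueError(f"marker {name!r} supplied twice")
        by_name[name] = m
    order = list(marker_order) if marker_order is not None else sorted(by_name)
    unknown = set(order) - set(by_name)
    if unknown:
        raise ValueError(f"marker_order names not supplied: {sorted(unknown)}")

    accessions = sorted({a for m in per_marker for a in m.accessions})
    parts: dict[str, list[str]] = {a: [] for a in accessions}
    markers = []
    for name in order:
        m = by_name[name]
        width = m.width
        markers.append((name, width))
        lookup = dict(zip(m.accessions, m.rows))
        gap_block = "-" * width
        for a in accessions:
            parts[a].append(lookup.get(a, gap_block))
    return AlignmentMatrix(
        markers=markers,
        accessions=accessions,
        rows=["".join(parts[a]) for a in accessions],
    )


def filter_gap_columns(
    matrix: AlignmentMatrix, max_gap_fraction: float = DEFAULT_MAX_GAP_FRACTION
) -> tuple[AlignmentMatrix, int]:
    """Delete columns whose gap fraction strictly exceeds the threshold.

    A column with gap fraction exactly equal to ``max_gap_fraction`` is
    kept.  Returns the filtered matrix and the number of deleted columns.
    Idempotent, and invariant under row permutation.
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must lie in [0, 1]")
    if not matrix.rows:
        return matrix, 0
    arr = np.array([list(r) for r in matrix.rows])
    gap_frac = (arr == "-").mean(axis=0)
    keep = gap_frac <= max_gap_fraction
    deleted = int((~keep).sum())
    # Per-marker surviving widths keep the partition log meaningful.
    new_markers, col = [], 0
    for name, w in matrix.markers:
        new_markers.append((name, int(keep[col : col + w].sum())))
        col += w
    filtered = AlignmentMatrix(
        markers=new_markers,
        accessions=list(matrix.accessions),
        rows=["".join(r) for r in arr[:, keep]],
    )
    return filtered, deleted


def check_tree_leaves(newick, accessions: Sequence[str]) -> tuple[set, set]:
    """Compare Newick leaf names against an accession set.

    Returns (accessions missing from the tree, tree leaves not in the
    accession set).  ``newick`` may be a path or a Newick string.
    """
    if isinstance(newick, str) and newick.lstrip().startswith("("):
        tree = dendropy.Tree.get(data=newick, schema="newick")
    else:
        tree = dendropy.Tree.get(path=str(newick), schema="newick")
    leaves = {leaf.taxon.label.replace(" ", "_") for leaf in tree.leaf_node_iter()}
    accs = set(accessions)
    return accs - leaves, leaves - accs


def _color_map(categories: Sequence[str]) -> dict[str, str]:
    return {c: PALETTE[i % len(PALETTE)] for i, c in enumerate(sorted(set(categories)))}


def _write_colorstrip(handle, label: str, assignment: dict[str, str]) -> None:
    colors = _color_map(list(assignment.values()))
    categories = sorted(colors)
    handle.write("DATASET_COLORSTRIP\n")
    handle.write("SEPARATOR TAB\n")
    handle.write(f"DATASET_LABEL\t{label}\n")
    handle.write("COLOR\t#000000\n")
    handle.write(f"LEGEND_TITLE\t{label}\n")
    handle.write("LEGEND_SHAPES\t" + "\t".join("1" for _ in categories) + "\n")
    handle.write("LEGEND_COLORS\t" + "\t".join(colors[c] for c in categories) + "\n")
    handle.write("LEGEND_LABELS\t" + "\t".join(categories) + "\n")
    handle.write("DATA\n")
    for acc in sorted(assignment):
        cat = assignment[acc]
        handle.write(f"{acc}\t{colors[cat]}\t{cat}\n")


def write_itol_annotations(
    profiles: pd.DataFrame,
    metas: pd.DataFrame,
    taxogroup_path,
    rimclass_path,
) -> None:
    """Write the two iTOL colour-strip rings: taxogroup and rim class.

    ``profiles`` needs accession + arrangement_class; ``metas`` needs
    accession + taxogroup and must cover every profiled accession.
    """
    if profiles.empty:
        raise ValueError("no profiles to annotate")
    tax = metas.set_index("accession")["taxogroup"].to_dict()
    missing = sorted(set(profiles["accession"]) - set(tax))
    if missing:
        raise ValueError(f"accessions without metadata: {missing}")
    tax_assignment = {acc: tax[acc] for acc in profiles["accession"]}
    class_assignment = dict(zip(profiles["accession"], profiles["arrangement_class"]))
    with open(taxogroup_path, "w") as fh:
        _write_colorstrip(fh, "taxogroup", tax_assignment)
    with open(rimclass_path, "w") as fh:
        _write_colorstrip(fh, "rim_class", class_assignment)
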