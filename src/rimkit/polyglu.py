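"""Census of contiguous poly-glutamate (poly-E) runs in protein sequences.

RimB recognises contiguous glutamate motifs, so the first bioinformatic
question about any proteome is: which proteins carry a run of five or more
consecutive E residues, and does that run reach the extreme C-terminus
(the position where RimK-added tails sit)?  This module finds maximal
E-runs, tabulates them per proteome, and builds the nested rim-bearing /
rim-lacking partition report over genome accessions.

Coordinates are 1-based inclusive throughout, matching the residue
numbering convention used for point mutants (e.g. D31, D139).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

#: Characters that terminate a run without being an error: the unknown
#: residue X, alignment gaps and a stop marker.  Conservative choice -- an
#: ambiguous position never extends a glutamate run.
RUN_BREAKERS = frozenset("X-.*")

_AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")
VALID_CHARS = _AA20 | RUN_BREAKERS

_RUN_RE = re.compile("E+")

RUN_TABLE_COLUMNS = ["accession", "protein_id", "start", "end", "length", "c_terminal"]


@dataclass(frozen=True)
class PolyGluRun:
    """A maximal run of consecutive glutamate residues within one protein."""

    protein_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    length: int
    c_terminal: bool  # run's last residue is the protein's last residue


@dataclass(frozen=True)
class GenomePolyEStats:
    """Per-accession summary of the poly-E census."""

    accession: str
    has_polyE_gene: bool
    has_cterm_polyE_gene: bool
    run_count: int
    gene_count: int  # proteins with >= 1 qualifying run


def find_runs(sequence: str, min_len: int = 5, protein_id: str = "") -> list[PolyGluRun]:
    """Return all maximal runs of E with length >= ``min_len``, left to right.

    Maximal means the residues flanking the run (if any) are not E; runs are
    therefore non-overlapping by construction.  Characters in
    :data:`RUN_BREAKERS` break runs; any other non-amino-acid character is
    rejected.
    """
    if min_len < 1:
        raise ValueError(f"min_len must be >= 1, got {min_len}")
    seq = sequence.upper()
    bad = set(seq) - VALID_CHARS
    if bad:
        raise ValueError(
            f"invalid residue characters {sorted(bad)!r} in sequence"
            + (f" of {protein_id}" if protein_id else "")
        )
    n = len(seq)
    runs = []
    for m in _RUN_RE.finditer(seq):
        length = m.end() - m.start()
        if length >= min_len:
            runs.append(
                PolyGluRun(
                    protein_id=protein_id,
                    start=m.start() + 1,
                    end=m.end(),
                    length=length,
                    c_terminal=(m.end() == n),
                )
            )
    return runs


def _parse_accession(description: str) -> str:
    # headers written by rimkit.synthetic carry "accession=XXX"; absent for
    # third-party FASTA, in which case the column is left blank.
    for token in description.split():
        if token.startswith("accession="):
            return token[len("accession=") :]
    return ""


def scan_fasta(fasta, min_len: int = 5) -> pd.DataFrame:
    """Scan a protein FASTA for poly-E runs; one output row per run.

    ``fasta`` may be a path or an open text handle (or a string of FASTA
    text wrapped by the caller in ``io.StringIO``).  Protein order is
    preserved; proteins without qualifying runs do not appear.
    """
    if isinstance(fasta, str) and fasta.lstrip().startswith(">"):
        fasta = io.StringIO(fasta)
    rows = []
    for record in SeqIO.parse(fasta, "fasta"):
        accession = _parse_accession(record.description)
        for run in find_runs(str(record.seq), min_len=min_len, protein_id=record.id):
            rows.append(
                {
                    "accession": accession,
                    "protein_id": run.protein_id,
                    "start": run.start,
                    "end": run.end,
                    "length": run.length,
                    "c_terminal": run.c_terminal,
                }
            )
    return pd.DataFrame(rows, columns=RUN_TABLE_COLUMNS)


def genome_stats(
    run_table: pd.DataFrame, accessions: Iterable[str]
) -> list[GenomePolyEStats]:
    """Collapse a run table into per-accession presence statistics.

    ``accessions`` must list every accession scanned, including those with
    no runs, so that denominators in the partition report are correct.
    """
    stats = []
    grouped = dict(tuple(run_table.groupby("accession"))) if len(run_table) else {}
    for acc in accessions:
        sub = grouped.get(acc)
        if sub is None or sub.empty:
            stats.append(GenomePolyEStats(acc, False, False, 0, 0))
        else:
            stats.append(
                GenomePolyEStats(
                    accession=acc,
                    has_polyE_gene=True,
                    has_cterm_polyE_gene=bool(sub["c_terminal"].any()),
                    run_count=int(len(sub)),
                    gene_count=int(sub["protein_id"].nunique()),
                )
            )
    return stats


def partition_report(
    stats: Sequence[GenomePolyEStats], profiles: pd.DataFrame
) -> dict:
    """Nested rim-bearing vs rim-lacking poly-E partition over accessions.

    ``profiles`` needs columns ``accession`` and ``arrangement_class``
    (class ``"none"`` = rim-lacking).  Within each branch the percentages
    are conditional: fraction of the branch with at least one poly-E gene,
    and -- of those -- the fraction where a run reaches the extreme
    C-terminus.  Percentages are rounded to one decimal; an empty branch
    reports ``None`` percentages with ``defined=False``.
    """
    stat_accs = {s.accession for s in stats}
    prof_accs = set(profiles["accession"])
    if stat_accs != prof_accs:
        missing = sorted((stat_accs ^ prof_accs))[:10]
        raise ValueError(f"accession sets differ between stats and profiles: {missing}")

    rim_bearing = set(
        profiles.loc[profiles["arrangement_class"] != "none", "accession"]
    )
    report = {}
    for branch, members in (
        ("rim", [s for s in stats if s.accession in rim_bearing]),
        ("no_rim", [s for s in stats if s.accession not in rim_bearing]),
    ):
        total = len(members)
        n_polye = sum(s.has_polyE_gene for s in members)
        n_cterm = sum(s.has_cterm_polyE_gene for s in members)
        report[branch] = {
            "total": total,
            "polyE": n_polye,
            "cterm_polyE": n_cterm,
            "pct_polyE": round(100.0 * n_polye / total, 1) if total else None,
            "pct_cterm": round(100.0 * n_cterm / n_polye, 1) if n_polye else None,
            "defined": total > 0,
        }
    return report
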