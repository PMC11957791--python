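"""Reciprocal-hit presence calls and arrangement classification of rim genes.

Genome accessions are screened for three query proteins -- RimB (the
retropepsin-like protease), RimK (the ATP-Grasp glutamate ligase) and the
RimBK hybrid -- using pre-computed bidirectional protein-search hit tables
in the 12-column tabular dialect.  A query is *present* in an accession
when its top forward hit passes the E-value threshold (<= 1e-9 by default)
and is reciprocal: the subject, searched back against the query proteome,
returns the original query as its top hit.

Presence patterns map deterministically onto arrangement classes
(rimB+rimK, rimK only, rimB only, rimBK only, rimBK+rimB, rimBK+rimK,
Others, none), and rim genes can additionally be flagged for proximity to
annotated mobile genetic elements within a gene-index window.
"""

from __future__ import annotations

import logging
from typing import Callable, Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: 12-column tabular hit format (the de-facto standard for protein searches).
HIT_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]

METADATA_COLUMNS = ["accession", "ref_flag", "n_contigs", "n_cds", "taxogroup"]
GENE_ORDER_COLUMNS = ["accession", "replicon", "gene_index", "protein_id", "mge_flag"]

QUERIES = ("RimB", "RimK", "RimBK")

#: Presence pattern (RimB, RimK, RimBK) -> arrangement class.
CLASS_TABLE = {
    (True, True, False): "rimB+rimK",
    (False, True, False): "rimK only",
    (True, False, False): "rimB only",
    (False, False, True): "rimBK only",
    (True, False, True): "rimBK+rimB",
    (False, True, True): "rimBK+rimK",
    (True, True, True): "Others",
    (False, False, False): "none",
}

DEFAULT_E_MAX = 1e-9
DEFAULT_MGE_WINDOW = 5


def read_hits(source) -> pd.DataFrame:
    """Read a headerless 12-column tab-separated hit table."""
    return pd.read_csv(source, sep="\t", names=HIT_COLUMNS, header=None)


def read_metadata(source) -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t")
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    df["ref_flag"] = df["ref_flag"].astype(bool)
    return df


def read_gene_order(source) -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t")
    missing = set(GENE_ORDER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene-order table missing columns: {sorted(missing)}")
    return df


def subject_accession(sseqid: str) -> str:
    """Default mapping from subject protein id to its genome accession.

    Subject ids follow ``<accession>_<locus>``; the accession itself
    contains no underscore.
    """
    return sseqid.split("_", 1)[0]


def filter_accessions(metas: pd.DataFrame) -> pd.DataFrame:
    """Keep reference/representative assemblies with <= 15 contigs, >= 500 CDSs."""
    keep = metas["ref_flag"] & (metas["n_contigs"] <= 15) & (metas["n_cds"] >= 500)
    return metas.loc[keep].reset_index(drop=True)


def _top_hits(hits: pd.DataFrame, group_cols: Sequence[str]) -> pd.DataFrame:
    """Top hit per group: max bitscore, then min evalue, then sseqid order."""
    ordered = hits.sort_values(
        ["bitscore", "evalue", "sseqid"], ascending=[False, True, True], kind="mergesort"
    )
    return ordered.groupby(list(group_cols), sort=False).head(1)


def assign_presence(
    forward: pd.DataFrame,
    reverse: pd.DataFrame,
    e_max: float = DEFAULT_E_MAX,
    queries: Sequence[str] = QUERIES,
    accession_of: Callable[[str], str] = subject_accession,
    accessions: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Per-accession presence calls for each query protein.

    Returns a frame indexed by accession with boolean columns per query and
    ``<query>_subject`` columns naming the supporting subject protein.
    ``accessions`` optionally lists accessions to report even when they
    have no hits at all.

    Hybrid resolution: when the RimB-query and RimK-query top hits of an
    accession resolve to one and the same subject protein, both passing the
    E-value threshold, and that subject's reverse top hit is one of the rim
    queries, the accession is called RimBK-positive and the separate
    RimB/RimK presences are suppressed (the single gene is a hybrid, not
    two genes).
    """
    fwd = forward.copy()
    fwd["accession"] = fwd["sseqid"].map(accession_of)
    fwd = fwd[fwd["qseqid"].isin(queries)]

    # Reverse top hit per subject protein (the subject acts as the query in
    # the reverse search).
    if len(reverse):
        rev_top = _top_hits(reverse, ["qseqid"]).set_index("qseqid")["sseqid"].to_dict()
    else:
        rev_top = {}

    top = _top_hits(fwd, ["qseqid", "accession"]) if len(fwd) else fwd

    acc_set = set(top["accession"]) if len(top) else set()
    if accessions is not None:
        acc_set |= set(accessions)

    rows = {}
    for acc in sorted(acc_set):
        rows[acc] = {q: False for q in queries}
        rows[acc].update({f"{q}_subject": None for q in queries})

    n_missing_reverse = 0
    tops: dict[tuple[str, str], pd.Series] = {}
    for _, hit in (top.iterrows() if len(top) else []):
        q, acc = hit["qseqid"], hit["accession"]
        tops[(q, acc)] = hit
        if hit["sseqid"] not in rev_top:
            n_missing_reverse += 1
            continue  # no reverse evidence: treated as non-reciprocal
        if hit["evalue"] <= e_max and rev_top[hit["sseqid"]] == q:
            rows[acc][q] = True
            rows[acc][f"{q}_subject"] = hit["sseqid"]
    if n_missing_reverse:
        logger.warning(
            "%d top forward hits had no reverse entry; treated as non-reciprocal",
            n_missing_reverse,
        )

    # Hybrid same-subject resolution.
    for acc in rows:
        tb = tops.get(("RimB", acc))
        tk = tops.get(("RimK", acc))
        if tb is None or tk is None:
            continue
        shared = tb["sseqid"] == tk["sseqid"]
        pass_e = tb["evalue"] <= e_max and tk["evalue"] <= e_max
        family_reciprocal = rev_top.get(tb["sseqid"]) in queries
        if shared and pass_e and family_reciprocal:
            rows[acc]["RimBK"] = True
            rows[acc]["RimBK_subject"] = rows[acc]["RimBK_subject"] or tb["sseqid"]
            rows[acc]["RimB"] = False
            rows[acc]["RimK"] = False
            rows[acc]["RimB_subject"] = None
            rows[acc]["RimK_subject"] = None

    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "accession"
    return out


def classify_profile(present: Mapping[str, bool]) -> str:
    """Deterministic arrangement class from a presence map."""
    key = (
        bool(present.get("RimB", False)),
        bool(present.get("RimK", False)),
        bool(present.get("RimBK", False)),
    )
    return CLASS_TABLE[key]


def build_profiles(
    presence: pd.DataFrame,
    gene_order: Optional[pd.DataFrame] = None,
    mge_window: int = DEFAULT_MGE_WINDOW,
) -> pd.DataFrame:
    """Attach arrangement classes (and optional MGE linkage) to presence calls."""
    prof = presence.copy()
    prof["arrangement_class"] = [
        classify_profile(row) for row in prof[list(QUERIES)].to_dict("records")
    ]
    if gene_order is not None:
        rim_ids = {
            s
            for col in (f"{q}_subject" for q in QUERIES)
            for s in prof[col]
            if isinstance(s, str)
        }
        linked = mge_proximity(gene_order, rim_ids, window=mge_window) if rim_ids else pd.Series(dtype=bool)
        by_acc: dict[str, bool] = {}
        for pid, flag in linked.items():
            by_acc[subject_accession(pid)] = by_acc.get(subject_accession(pid), False) or bool(flag)
        prof["mge_linked"] = [by_acc.get(acc, False) for acc in prof.index]
    else:
        prof["mge_linked"] = False
    return prof.reset_index()


def partition_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Counts and one-decimal percentages per class over rim-bearing accessions."""
    bearing = profiles[profiles["arrangement_class"] != "none"]
    if bearing.empty:
        logger.warning("no rim-bearing accessions; empty partition")
        return pd.DataFrame(columns=["arrangement_class", "count", "percent"])
    counts = bearing["arrangement_class"].value_counts()
    total = int(counts.sum())
    out = pd.DataFrame(
        {
            "arrangement_class": counts.index,
            "count": counts.values,
            "percent": [round(100.0 * c / total, 1) for c in counts.values],
        }
    )
    return out.sort_values("count", ascending=False, kind="mergesort").reset_index(drop=True)


def mge_proximity(
    gene_order: pd.DataFrame,
    rim_protein_ids: Iterable[str],
    window: int = DEFAULT_MGE_WINDOW,
) -> pd.Series:
    """Flag each rim gene lying within ``window`` gene indices of an MGE.

    Distance is measured on the per-replicon gene-index ordinal; strand and
    physical distance are ignored.  A rim protein absent from the table is
    an error.
    """
    rim_ids = set(rim_protein_ids)
    table_ids = set(gene_order["protein_id"])
    missing = sorted(rim_ids - table_ids)
    if missing:
        raise ValueError(f"rim proteins absent from gene-order table: {missing}")

    rim_rows = gene_order[gene_order["protein_id"].isin(rim_ids)]
    mge_rows = gene_order[gene_order["mge_flag"].astype(bool)]
    mge_by_replicon: dict[tuple, list[int]] = {}
    for _, r in mge_rows.iterrows():
        mge_by_replicon.setdefault((r["accession"], r["replicon"]), []).append(
            int(r["gene_index"])
        )

    flags = {}
    for _, r in rim_rows.iterrows():
        indices = mge_by_replicon.get((r["accession"], r["replicon"]), [])
        flags[r["protein_id"]] = any(
            abs(int(r["gene_index"]) - i) <= window for i in indices
        )
    return pd.Series(flags, name="mge_linked")
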