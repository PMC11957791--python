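"""Marker concatenation, gap-column filtering and iTOL annotation export."""

import numpy as np
import pandas as pd
import pytest

from rimkit import supermatrix
from rimkit.supermatrix import AlignmentMatrix, concatenate_markers, filter_gap_columns


def matrix(name, rows_by_acc):
    accs = list(rows_by_acc)
    rows = [rows_by_acc[a] for a in accs]
    return AlignmentMatrix([(name, len(rows[0]))], accs, rows)


def random_alignment(rng, n_rows=None, width=None, name="M"):
    n_rows = n_rows or int(rng.integers(2, 8))
    width = width or int(rng.integers(1, 25))
    chars = np.array(list("ACDE-"))
    rows = ["".join(rng.choice(chars, size=width)) for _ in range(n_rows)]
    return AlignmentMatrix([(name, width)], [f"A{i}" for i in range(n_rows)], rows)


def test_concatenate_widths_and_order():
    m1 = matrix("GyrB", {"A": "MKLMKLMKLM", "B": "MKLMKLMKL-", "C": "MKLMKLMKLV"})
    m2 = matrix("RecA", {"A": "W" * 20, "B": "Y" * 20, "C": "H" * 20})
    cat = concatenate_markers([m1, m2], ["GyrB", "RecA"])
    assert cat.width == 30 and len(cat.rows) == 3
    assert cat.markers == [("GyrB", 10), ("RecA", 20)]
    log = cat.partition_log()
    assert log.to_dict("records") == [
        {"marker": "GyrB", "start": 1, "end": 10},
        {"marker": "RecA", "start": 11, "end": 30},
    ]


def test_missing_marker_becomes_gap_block():
    m1 = matrix("GyrB", {"A": "MKLMKLMKLM"})
    m2 = matrix("RecA", {"A": "W" * 20, "B": "Y" * 20})
    cat = concatenate_markers([m1, m2], ["GyrB", "RecA"])
    row_b = dict(zip(cat.accessions, cat.rows))["B"]
    assert row_b == "-" * 10 + "Y" * 20


def test_concatenate_errors():
    with pytest.raises(ValueError, match="no marker"):
        concatenate_markers([])
    with pytest.raises(ValueError, match="duplicate accessions"):
        AlignmentMatrix([("M", 3)], ["A", "A"], ["MKL", "MKV"])
    m = matrix("GyrB", {"A": "MKL"})
    with pytest.raises(ValueError, match="twice"):
        concatenate_markers([m, m])


@pytest.mark.parametrize("gaps,kept", [(2, True), (3, False)])
def test_gap_column_50_percent_boundary(gaps, kept):
    # four rows; first column carries `gaps` gaps, second column none
    col1 = ["-"] * gaps + ["M"] * (4 - gaps)
    rows = [c + "K" for c in col1]
    m = AlignmentMatrix([("M", 2)], ["A", "B", "C", "D"], rows)
    filtered, deleted = filter_gap_columns(m, 0.5)
    assert (filtered.width == 2) is kept
    assert deleted == (0 if kept else 1)


def test_gap_filter_never_deletes_gapless_columns():
    rng = np.random.default_rng(0)
    for _ in range(20):
        m = random_alignment(rng)
        arr = np.array([list(r) for r in m.rows])
        gapless = int((arr != "-").all(axis=0).sum())
        filtered, _ = filter_gap_columns(m)
        arr2 = np.array([list(r) for r in filtered.rows]) if filtered.rows[0] else None
        kept_gapless = int((arr2 != "-").all(axis=0).sum()) if arr2 is not None else 0
        assert kept_gapless >= gapless  # every gapless column survives


def test_gap_filter_idempotent_and_permutation_invariant():
    rng = np.random.default_rng(1)
    for _ in range(30):
        m = random_alignment(rng)
        once, _ = filter_gap_columns(m)
        twice, deleted_again = filter_gap_columns(once)
        assert twice.rows == once.rows and deleted_again == 0
        perm = rng.permutation(len(m.rows))
        shuffled = AlignmentMatrix(
            list(m.markers),
            [m.accessions[i] for i in perm],
            [m.rows[i] for i in perm],
        )
        filtered_shuffled, _ = filter_gap_columns(shuffled)
        assert dict(zip(filtered_shuffled.accessions, filtered_shuffled.rows)) == {
            a: r for a, r in zip(once.accessions, once.rows)
        }


def test_width_conservation_before_filtering():
    rng = np.random.default_rng(2)
    mats = [random_alignment(rng, name=f"M{i}") for i in range(4)]
    cat = concatenate_markers(mats, [f"M{i}" for i in range(4)])
    assert cat.width == sum(m.width for m in mats)


def test_itol_annotations(tmp_path):
    profiles = pd.DataFrame(
        {
            "accession": ["A1", "A2", "A3"],
            "arrangement_class": ["rimB+rimK", "Others", "rimBK only"],
        }
    )
    metas = pd.DataFrame(
        {
            "accession": ["A1", "A2", "A3"],
            "ref_flag": True,
            "n_contigs": 1,
            "n_cds": 1000,
            "taxogroup": ["Bacilli", "Bacilli", "Flavobacteriia"],
        }
    )
    tax_file = tmp_path / "tax.txt"
    cls_file = tmp_path / "cls.txt"
    supermatrix.write_itol_annotations(profiles, metas, tax_file, cls_file)
    tax_lines = tax_file.read_text().splitlines()
    assert tax_lines[0] == "DATASET_COLORSTRIP"
    data = tax_lines[tax_lines.index("DATA") + 1 :]
    assert len(data) == 3  # one line per accession
    legend = [l for l in tax_lines if l.startswith("LEGEND_LABELS")][0]
    assert legend.split("\t")[1:] == ["Bacilli", "Flavobacteriia"]
    cls_text = cls_file.read_text()
    # 'Others' gets its own colour, distinct from the other classes
    colors = {
        line.split("\t")[1]: line.split("\t")[2]
        for line in cls_text.splitlines()[cls_text.splitlines().index("DATA") + 1 :]
    }
    assert len(set(colors)) == 3


def test_itol_errors(tmp_path):
    metas = pd.DataFrame([{"accession": "A1", "ref_flag": True, "n_contigs": 1,
                           "n_cds": 1000, "taxogroup": "Bacilli"}])
    profiles = pd.DataFrame({"accession": ["A1", "A2"], "arrangement_class": ["none", "none"]})
    with pytest.raises(ValueError, match="A2"):
        supermatrix.write_itol_annotations(profiles, metas, tmp_path / "t", tmp_path / "c")
    empty = profiles.iloc[:0]
    with pytest.raises(ValueError, match="no profiles"):
        supermatrix.write_itol_annotations(empty, metas, tmp_path / "t", tmp_path / "c")


def test_check_tree_leaves():
    missing, extra = supermatrix.check_tree_leaves("((A1,A2),A3);", ["A1", "A2", "A4"])
    assert missing == {"A4"} and extra == {"A3"}
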