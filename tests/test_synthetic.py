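"""Generators: planted truth is recoverable and seeds determine bytes."""

import io

import numpy as np
import pandas as pd
import pytest
from Bio import SeqIO

from rimkit import polyglu, rimclass, synthetic


def test_gen_proteome_terminal_run_construction():
    fasta, truth = synthetic.gen_proteome(1, [(5, "terminal")], 50, seed=1)
    (rec,) = SeqIO.parse(io.StringIO(fasta), "fasta")
    seq = str(rec.seq)
    assert len(seq) == 55 and seq.endswith("EEEEE")
    assert "E" not in seq[:50]
    assert truth.planted_runs == [("P0001", 51, 55)]


def test_gen_proteome_empty_spec_has_no_glutamate():
    fasta, truth = synthetic.gen_proteome(4, [], 80, seed=3)
    seqs = [str(r.seq) for r in SeqIO.parse(io.StringIO(fasta), "fasta")]
    assert len(seqs) == 4 and all("E" not in s for s in seqs)
    assert truth.planted_runs == []


def test_gen_proteome_deterministic():
    a, _ = synthetic.gen_proteome(5, [(6, "internal"), (5, "terminal")], 100, seed=7)
    b, _ = synthetic.gen_proteome(5, [(6, "internal"), (5, "terminal")], 100, seed=7)
    c, _ = synthetic.gen_proteome(5, [(6, "internal"), (5, "terminal")], 100, seed=8)
    assert a == b
    assert a != c


def test_gen_proteome_sizing_errors():
    with pytest.raises(ValueError, match="does not fit"):
        synthetic.gen_proteome(1, [(5, "terminal")], 0, seed=1)
    with pytest.raises(ValueError, match="flanked"):
        synthetic.gen_proteome(1, [(5, "internal")], 1, seed=1)
    with pytest.raises(ValueError):
        synthetic.gen_proteome(1, [(0, "terminal")], 10, seed=1)


def test_gen_proteome_round_trip_many_seeds():
    """Planted runs are exactly recoverable by parsing for 100 seeds."""
    run_spec = [(5, "terminal"), (8, "internal"), (6, "internal")]
    for seed in range(100):
        fasta, truth = synthetic.gen_proteome(3, run_spec, 60, seed=seed)
        table = polyglu.scan_fasta(fasta, min_len=5)
        got = set(zip(table["protein_id"], table["start"], table["end"]))
        assert got == set(truth.planted_runs)


def test_gen_rim_universe_construction():
    uni = synthetic.gen_rim_universe({"rimB+rimK": 3, "none": 2}, 0.0, seed=1)
    assert len(uni.metadata) == 5
    classes = list(uni.truth.planted_profiles.values())
    assert classes.count("rimB+rimK") == 3 and classes.count("none") == 2
    # with no decoys, rim-lacking accessions produce no forward hits
    hit_accs = {rimclass.subject_accession(s) for s in uni.forward["sseqid"]}
    none_accs = {a for a, c in uni.truth.planted_profiles.items() if c == "none"}
    assert hit_accs.isdisjoint(none_accs)


def test_gen_rim_universe_hybrid_routes_to_one_subject():
    uni = synthetic.gen_rim_universe({"rimBK only": 1}, 0.0, seed=2)
    fwd = uni.forward
    b = fwd.loc[fwd["qseqid"] == "RimB", "sseqid"].iloc[0]
    k = fwd.loc[fwd["qseqid"] == "RimK", "sseqid"].iloc[0]
    bk = fwd.loc[fwd["qseqid"] == "RimBK", "sseqid"].iloc[0]
    assert b == k == bk


def test_gen_rim_universe_all_decoys_fail_criterion():
    uni = synthetic.gen_rim_universe({"none": 20}, 1.0, seed=3)
    presence = rimclass.assign_presence(
        uni.forward, uni.reverse, accessions=uni.metadata["accession"]
    )
    assert not presence[list(rimclass.QUERIES)].any().any()


def test_gen_rim_universe_rejects_bad_inputs():
    with pytest.raises(ValueError, match="decoy_rate"):
        synthetic.gen_rim_universe({"none": 1}, 1.5, seed=1)
    with pytest.raises(ValueError, match="unknown"):
        synthetic.gen_rim_universe({"Others": 1}, 0.0, seed=1)


def test_gen_rim_universe_filter_flags_consistent():
    uni = synthetic.gen_rim_universe({"none": 40}, 0.0, seed=4, filter_fail_rate=0.5)
    kept = set(rimclass.filter_accessions(uni.metadata)["accession"])
    for acc, should_pass in uni.truth.filter_pass.items():
        assert (acc in kept) is should_pass
    assert 0 < len(kept) < 40


def test_gen_rim_universe_write_round_trip(tmp_path):
    uni = synthetic.gen_rim_universe({"rimB+rimK": 4, "rimBK only": 2, "none": 2},
                                     0.3, seed=5, mge_fraction=0.5)
    paths = uni.write(tmp_path)
    meta = rimclass.read_metadata(paths["metadata"])
    fwd = rimclass.read_hits(paths["forward"])
    rev = rimclass.read_hits(paths["reverse"])
    go = rimclass.read_gene_order(paths["gene_order"])
    presence = rimclass.assign_presence(fwd, rev, accessions=meta["accession"])
    prof = rimclass.build_profiles(presence, gene_order=go)
    got = dict(zip(prof["accession"], prof["arrangement_class"]))
    assert got == uni.truth.planted_profiles
    pd.testing.assert_frame_equal(meta, uni.metadata)


def test_gen_rim_universe_deterministic():
    mix = {"rimB+rimK": 3, "rimBK+rimK": 2, "none": 2}
    a = synthetic.gen_rim_universe(mix, 0.4, seed=11, mge_fraction=0.3)
    b = synthetic.gen_rim_universe(mix, 0.4, seed=11, mge_fraction=0.3)
    for attr in ("metadata", "forward", "reverse", "gene_order"):
        pd.testing.assert_frame_equal(getattr(a, attr), getattr(b, attr))
    assert a.truth.planted_mge_linked == b.truth.planted_mge_linked


def test_gen_ladder_peaks_counts_and_monomer():
    peaks, truth = synthetic.gen_ladder_peaks(5, 28, adducts=[0], noise_peaks=0,
                                              rel_noise_ppm=0.0, seed=1)
    assert len(peaks) == 24 and truth.planted_ladder.max_n == 28
    single, _ = synthetic.gen_ladder_peaks(1, 1, adducts=[0], rel_noise_ppm=0.0, seed=1)
    assert len(single) == 1
    assert single["mz"].iloc[0] == pytest.approx(148.06043, abs=1e-5)


def test_gen_ladder_peaks_empty_range_is_noise_only():
    peaks, truth = synthetic.gen_ladder_peaks(5, 4, adducts=[0], noise_peaks=100, seed=2)
    assert truth.planted_ladder.max_n is None and len(peaks) == 100


def test_gen_ladder_peaks_deterministic_csv(tmp_path):
    out1, out2 = tmp_path / "a.csv", tmp_path / "b.csv"
    for out in (out1, out2):
        peaks, _ = synthetic.gen_ladder_peaks(5, 20, adducts=[0, 1], noise_peaks=25, seed=6)
        synthetic.write_peaks(peaks, out)
    assert out1.read_bytes() == out2.read_bytes()


def test_gen_ladder_noise_respects_exclusion_zone():
    peaks, _ = synthetic.gen_ladder_peaks(5, 4, adducts=[0], noise_peaks=200, seed=8)
    from rimkit.msladder import polymer_mz
    guard = np.array([polymer_mz(n, na) for na in range(4) for n in range(1, 61)])
    for mz in peaks["mz"]:
        ppm = np.min(np.abs(mz - guard) / guard) * 1e6
        assert ppm > 50.0
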