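"""Synthetic inputs with planted ground truth for every pipeline stage.

Three generators emulate the input formats the pipeline consumes, each
fully determined by a single integer seed and each returning a
:class:`TruthBundle` that records exactly what was planted:

* :func:`gen_proteome` -- protein FASTA with contiguous Glu runs planted at
  known positions on a Glu-free background (uniform over the 19 non-E
  residues, so no accidental runs can arise);
* :func:`gen_rim_universe` -- genome metadata, forward/reverse hit tables
  (12-column tabular dialect) and gene-order tables for a set of
  accessions with known rim-gene arrangements, including decoy hits built
  to fail the presence criterion;
* :func:`gen_ladder_peaks` -- deconvoluted +1 peak lists containing a
  poly-Glu ladder with optional sodium-adduct series and off-ladder noise
  peaks.

The generators emulate formats and planted signals, not realistic sequence
evolution, alignment scores or isotope envelopes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .msladder import polymer_mz
from .rimclass import GENE_ORDER_COLUMNS, HIT_COLUMNS, METADATA_COLUMNS

#: Background alphabet: the 20 standard residues minus glutamate.
NON_E_ALPHABET = np.array(list("ACDFGHIKLMNPQRSTVWY"))

#: Arrangement classes the universe generator can plant.
PLANTABLE_CLASSES = (
    "rimB+rimK",
    "rimK only",
    "rimB only",
    "rimBK only",
    "rimBK+rimB",
    "rimBK+rimK",
    "none",
)

DEFAULT_ACCESSION_FMT = "ACC{:05d}"
PROTEOME_ACCESSION = "SYN001"


@dataclass(frozen=True)
class LadderTruth:
    max_n: Optional[int]
    adduct_counts: tuple
    noise_peak_count: int


@dataclass
class TruthBundle:
    """Machine-readable record of everything a generator planted."""

    seed: int
    planted_runs: list = field(default_factory=list)  # (protein_id, start, end)
    planted_profiles: dict = field(default_factory=dict)  # accession -> class
    planted_ladder: Optional[LadderTruth] = None
    planted_mge_linked: set = field(default_factory=set)  # rim protein ids
    filter_pass: dict = field(default_factory=dict)  # accession -> bool

    def to_json(self) -> str:
        d = asdict(self)
        d["planted_mge_linked"] = sorted(self.planted_mge_linked)
        return json.dumps(d, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# proteomes

def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def gen_proteome(
    n_proteins: int,
    run_spec: Sequence[tuple[int, str]],
    background_len: int,
    seed: int,
) -> tuple[str, TruthBundle]:
    """Proteome FASTA with planted contiguous Glu runs.

    ``run_spec`` lists (run_length, kind) with kind ``"terminal"`` (run
    ends at the final residue) or ``"internal"``; runs are assigned to
    proteins round-robin.  Truth coordinates are 1-based inclusive.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    per_protein: list[list[tuple[int, str]]] = [[] for _ in range(n_proteins)]
    for i, (length, kind) in enumerate(run_spec):
        if length < 1:
            raise ValueError(f"run_length must be >= 1, got {length}")
        if kind not in ("terminal", "internal"):
            raise ValueError(f"run kind must be terminal|internal, got {kind!r}")
        per_protein[i % n_proteins].append((length, kind))

    rng = np.random.default_rng(seed)
    records, truth_runs = [], []
    for p, runs in enumerate(per_protein):
        pid = f"P{p + 1:04d}"
        terminals = [r for r in runs if r[1] == "terminal"]
        internals = [r for r in runs if r[1] == "internal"]
        if len(terminals) > 1:
            raise ValueError(f"{pid}: at most one terminal run per protein")
        if terminals and background_len < 1:
            raise ValueError(
                f"{pid}: terminal run of {terminals[0][0]} does not fit a "
                f"protein with background_len={background_len}"
            )
        if internals and background_len < 2:
            raise ValueError(
                f"{pid}: internal runs need background_len >= 2 to stay "
                f"flanked, got {background_len}"
            )
        bg = "".join(rng.choice(NON_E_ALPHABET, size=background_len))
        if internals:
            points = np.sort(
                rng.choice(background_len - 1, size=len(internals), replace=False) + 1
            )
        else:
            points = np.array([], dtype=int)
        segments, pos, prev = [], 0, 0
        for (length, _), point in zip(internals, points):
            point = int(point)
            segments.append(bg[prev:point])
            pos += point - prev
            truth_runs.append((pid, pos + 1, pos + length))
            segments.append("E" * length)
            pos += length
            prev = point
        segments.append(bg[prev:])
        pos += background_len - prev
        if terminals:
            length = terminals[0][0]
            truth_runs.append((pid, pos + 1, pos + length))
            segments.append("E" * length)
        seq = "".join(segments)
        records.append(f">{pid} accession={PROTEOME_ACCESSION}\n{_wrap(seq)}\n")

    truth = TruthBundle(seed=seed, planted_runs=truth_runs)
    return "".join(records), truth


# ---------------------------------------------------------------------------
# rim universes

#: Arrangement class -> planted hit layout.  Each entry lists
#: (query, subject_slot, reciprocal) where subject slots are symbolic gene
#: roles resolved to concrete proteins per accession; non-reciprocal hits
#: still pass the E-value threshold but their subject's reverse top hit is
#: another rim query.
_CLASS_LAYOUT = {
    "rimB+rimK": [("RimB", "sB", True), ("RimK", "sK", True)],
    "rimB only": [("RimB", "sB", True)],
    "rimK only": [("RimK", "sK", True)],
    "rimBK only": [("RimBK", "sX", True), ("RimB", "sX", False), ("RimK", "sX", False)],
    "rimBK+rimB": [("RimBK", "sX", True), ("RimB", "sB", True), ("RimK", "sX", False)],
    "rimBK+rimK": [("RimBK", "sX", True), ("RimK", "sK", True), ("RimB", "sX", False)],
    "none": [],
}

#: Reverse top-hit target for each subject slot: the single best reverse
#: hit of a hybrid gene is the hybrid query, which makes plain B/K forward
#: hits onto it non-reciprocal.
_SLOT_REVERSE = {"sB": "RimB", "sK": "RimK", "sX": "RimBK"}

_TAXOGROUPS = [
    "Gammaproteobacteria",
    "Alphaproteobacteria",
    "Flavobacteriia",
    "Bacilli",
    "Actinomycetia",
]


@dataclass
class RimUniverse:
    """Generated accession universe: four tables plus planted truth."""

    metadata: pd.DataFrame
    forward: pd.DataFrame
    reverse: pd.DataFrame
    gene_order: pd.DataFrame
    truth: TruthBundle

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "metadata": out / "metadata.tsv",
            "forward": out / "forward_hits.tsv",
            "reverse": out / "reverse_hits.tsv",
            "gene_order": out / "gene_order.tsv",
            "truth": out / "truth.json",
        }
        self.metadata.to_csv(paths["metadata"], sep="\t", index=False)
        self.forward.to_csv(paths["forward"], sep="\t", index=False, header=False)
        self.reverse.to_csv(paths["reverse"], sep="\t", index=False, header=False)
        self.gene_order.to_csv(paths["gene_order"], sep="\t", index=False)
        paths["truth"].write_text(self.truth.to_json())
        return paths


def _hit_row(rng, qseqid, sseqid, evalue, bitscore):
    length = int(rng.integers(150, 450))
    return {
        "qseqid": qseqid,
        "sseqid": sseqid,
        "pident": round(float(rng.uniform(30, 95)), 1),
        "length": length,
        "mismatch": int(rng.integers(5, 120)),
        "gapopen": int(rng.integers(0, 8)),
        "qstart": 1,
        "qend": length,
        "sstart": 1,
        "send": length,
        "evalue": evalue,
        "bitscore": round(bitscore, 1),
    }


def _true_evalue(rng) -> float:
    # exponent in [-50, -9]: always passes the <= 1e-9 criterion
    return float(10.0 ** rng.uniform(-50, -9))


def gen_rim_universe(
    class_mix: dict[str, int],
    decoy_rate: float,
    seed: int,
    *,
    filter_fail_rate: float = 0.0,
    mge_fraction: float = 0.0,
    mge_window: int = 5,
    genes_per_accession: int = 30,
) -> RimUniverse:
    """Accession universe with planted rim-gene arrangements.

    For every accession of a rim-bearing class, forward best hits with
    E <= 1e-9 and matching reciprocal reverse rows are planted; hybrid
    (rimBK) accessions route both the RimB- and RimK-query best hits onto
    the single hybrid gene.  With probability ``decoy_rate`` per accession
    and query, a decoy forward hit is added that fails the presence
    criterion: either its E-value exceeds 1e-9, or it is not reciprocal.
    With probability ``mge_fraction`` a planted rim gene gets a mobile
    genetic element flagged within ``mge_window`` gene indices; truth
    records the realised linkage.  ``filter_fail_rate`` controls the share
    of accessions that violate the assembly-quality metadata filters.
    """
    if not 0.0 <= decoy_rate <= 1.0:
        raise ValueError("decoy_rate must lie in [0, 1]")
    unknown = set(class_mix) - set(PLANTABLE_CLASSES)
    if unknown:
        raise ValueError(f"unknown arrangement classes: {sorted(unknown)}")
    if genes_per_accession < 12:
        raise ValueError("genes_per_accession too small to place genes and decoys")

    rng = np.random.default_rng(seed)
    classes = [c for c, k in class_mix.items() for _ in range(k)]
    rng.shuffle(classes)

    truth = TruthBundle(seed=seed)
    meta_rows, fwd_rows, gene_rows = [], [], []
    reverse_top: dict[str, str] = {}  # subject protein -> its best reverse target
    G = genes_per_accession

    for i, cls in enumerate(classes):
        acc = DEFAULT_ACCESSION_FMT.format(i + 1)
        truth.planted_profiles[acc] = cls

        # --- metadata, honouring the requested filter-failure share
        fails = bool(rng.random() < filter_fail_rate)
        if fails:
            mode = rng.integers(0, 3)
            ref_flag = mode != 0
            n_contigs = int(rng.integers(16, 80)) if mode == 1 else int(rng.integers(1, 16))
            n_cds = int(rng.integers(520, 6000)) if mode != 2 else int(rng.integers(50, 500))
        else:
            ref_flag, n_contigs, n_cds = True, int(rng.integers(1, 16)), int(rng.integers(520, 6000))
        truth.filter_pass[acc] = not fails
        meta_rows.append(
            {
                "accession": acc,
                "ref_flag": ref_flag,
                "n_contigs": n_contigs,
                "n_cds": n_cds,
                "taxogroup": _TAXOGROUPS[int(rng.integers(0, len(_TAXOGROUPS)))],
            }
        )

        # --- rim genes and their hits
        layout = _CLASS_LAYOUT[cls]
        slots = sorted({slot for _, slot, _ in layout})
        slot_index = dict(
            zip(slots, (rng.choice(G, size=len(slots), replace=False) + 1) if slots else [])
        )
        slot_protein = {
            s: f"{acc}_p{slot_index[s]:03d}" for s in slots
        }
        for query, slot, _reciprocal in layout:
            subject = slot_protein[slot]
            fwd_rows.append(
                _hit_row(rng, query, subject, _true_evalue(rng), rng.uniform(300, 500))
            )
            reverse_top.setdefault(subject, _SLOT_REVERSE[slot])

        # --- decoys, built to fail the presence criterion
        rim_indices = set(slot_index.values())
        for query in ("RimB", "RimK", "RimBK"):
            if rng.random() >= decoy_rate:
                continue
            free = [g for g in range(1, G + 1) if g not in rim_indices]
            subject = f"{acc}_p{free[int(rng.integers(0, len(free)))]:03d}"
            if rng.random() < 0.5:  # fails the E-value threshold
                evalue = float(10.0 ** rng.uniform(-8, -3))
                fwd_rows.append(_hit_row(rng, query, subject, evalue, rng.uniform(50, 150)))
                reverse_top.setdefault(subject, query)
            else:  # passes E but is not reciprocal
                fwd_rows.append(
                    _hit_row(rng, query, subject, _true_evalue(rng), rng.uniform(50, 150))
                )
                reverse_top.setdefault(subject, "DecoyRef")

        # --- gene order and MGE planting
        mge_indices: set[int] = set()
        for slot in slots:
            if rng.random() < mge_fraction:
                offsets = [
                    d
                    for d in range(-mge_window, mge_window + 1)
                    if d != 0 and 1 <= slot_index[slot] + d <= G
                    and slot_index[slot] + d not in rim_indices
                ]
                if offsets:
                    mge_indices.add(slot_index[slot] + offsets[int(rng.integers(0, len(offsets)))])
        for g in range(1, G + 1):
            gene_rows.append(
                {
                    "accession": acc,
                    "replicon": "chr1",
                    "gene_index": g,
                    "protein_id": f"{acc}_p{g:03d}",
                    "mge_flag": int(g in mge_indices),
                }
            )
        # realised linkage (an MGE planted for one rim gene can fall inside
        # another rim gene's window)
        for slot in slots:
            if any(abs(slot_index[slot] - m) <= mge_window for m in mge_indices):
                truth.planted_mge_linked.add(slot_protein[slot])

    # --- reverse table: top row per subject, plus occasional lower-scoring
    # secondary rows to exercise top-hit selection
    rev_rows = []
    for subject in sorted(reverse_top):
        rev_rows.append(
            _hit_row(rng, subject, reverse_top[subject], _true_evalue(rng), rng.uniform(300, 500))
        )
        if rng.random() < 0.3:
            rev_rows.append(
                _hit_row(rng, subject, "SecondaryRef", float(10.0 ** rng.uniform(-20, -5)), rng.uniform(40, 120))
            )

    return RimUniverse(
        metadata=pd.DataFrame(meta_rows, columns=METADATA_COLUMNS),
        forward=pd.DataFrame(fwd_rows, columns=HIT_COLUMNS),
        reverse=pd.DataFrame(rev_rows, columns=HIT_COLUMNS),
        gene_order=pd.DataFrame(gene_rows, columns=GENE_ORDER_COLUMNS),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# ladder peak lists

def gen_ladder_peaks(
    n_min: int,
    n_max: int,
    adducts: Sequence[int] = (0,),
    noise_peaks: int = 0,
    rel_noise_ppm: float = 5.0,
    seed: int = 0,
    *,
    noise_exclusion_ppm: float = 50.0,
    mass_mode: str = "monoisotopic",
    base_intensity: float = 1e5,
    decay: float = 0.08,
) -> tuple[pd.DataFrame, TruthBundle]:
    """Deconvoluted +1 peak list containing a planted poly-Glu ladder.

    Ladder peaks sit at the theoretical polymer m/z jittered uniformly
    within ``rel_noise_ppm``; intensities decay exponentially with chain
    length and drop by a constant factor per sodium substitution.  Noise
    peaks are uniform decoys kept at least ``noise_exclusion_ppm`` away
    from every theoretical ladder mass (sodium counts 0-3, chain lengths
    up to 60) so that planted truth stays recoverable.  An empty chain
    range (``n_max < n_min``) plants no ladder; truth ``max_n`` is None.
    """
    if n_min < 1:
        raise ValueError("n_min must be >= 1")
    if any(a < 0 for a in adducts):
        raise ValueError("sodium adduct counts must be >= 0")
    rng = np.random.default_rng(seed)

    mzs, intensities = [], []
    have_ladder = n_max >= n_min
    if have_ladder:
        for a_idx, na in enumerate(adducts):
            for n in range(n_min, n_max + 1):
                theo = polymer_mz(n, na, mass_mode)
                jitter = rng.uniform(-rel_noise_ppm, rel_noise_ppm)
                mzs.append(theo * (1.0 + jitter * 1e-6))
                intensities.append(
                    base_intensity
                    * np.exp(-decay * (n - n_min))
                    * 0.6**a_idx
                    * float(rng.lognormal(0.0, 0.1))
                )

    guard_na = max(3, max(adducts, default=0))
    guard_n = max(60, (n_max + 10) if have_ladder else 60)
    guard = np.array(
        [polymer_mz(n, na, mass_mode) for na in range(guard_na + 1) for n in range(1, guard_n + 1)]
    )
    hi = (polymer_mz(n_max, max(adducts), mass_mode) * 1.15) if (have_ladder and adducts) else 4000.0
    placed = 0
    while placed < noise_peaks:
        mz = float(rng.uniform(120.0, hi))
        if np.min(np.abs(mz - guard) / guard) * 1e6 > noise_exclusion_ppm:
            mzs.append(mz)
            intensities.append(float(rng.uniform(0.005, 0.5)) * base_intensity)
            placed += 1

    peaks = (
        pd.DataFrame({"mz": mzs, "intensity": intensities})
        .sort_values("mz", kind="mergesort")
        .reset_index(drop=True)
    )
    truth = TruthBundle(
        seed=seed,
        planted_ladder=LadderTruth(
            max_n=n_max if have_ladder else None,
            adduct_counts=tuple(adducts),
            noise_peak_count=noise_peaks,
        ),
    )
    return peaks, truth


def write_peaks(peaks: pd.DataFrame, path) -> None:
    peaks.to_csv(path, index=False, float_format="%.6f")
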