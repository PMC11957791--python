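"""Rule-based prediction of RimB cleavability for engineered C-terminal tails.

RimB is a retropepsin-like aspartic endopeptidase whose only recognition
requirement is the glutamate motif itself, not the fold of the carrier
protein.  The empirical rules, derived from a panel of 26 purified RpsF /
RpsI tail variants, are:

* cleavage occurs when six or more contiguous glutamate residues are
  present anywhere in the tail region;
* five contiguous glutamates suffice when the first of them is the
  terminal genetically encoded residue of the protein (and that residue
  is itself a glutamate);
* aspartate never substitutes for glutamate in a run.

The relative *rate* of proteolysis falls roughly with the number of
glutamates available, but the published ordinal classes are not an exact
function of run length, so the predictor layers a per-construct
calibration table (shipped with the package) over a simple run-length
heuristic.  The binary cleavable / non-cleavable call never needs the
calibration.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from importlib import resources
from typing import Mapping, Optional

import pandas as pd

from .polyglu import find_runs

#: Final five genetically encoded residues of unmodified SBW25 RpsF; the
#: all-glutamate reference substrate is this suffix plus ten E residues.
REFERENCE_SUFFIX = "DNADE"

#: Minimum contiguous glutamates for cleavage of a run not anchored at the
#: encoded terminus.
MIN_INTERNAL_RUN = 6

#: Minimum run length when the run contains the encoded terminal residue
#: (which must itself be E).
MIN_BOUNDARY_RUN = 5


class RateClass(IntEnum):
    """Ordinal proteolysis rate relative to the all-glutamate reference."""

    NIL = 0
    VERY_SLOW = 1
    SLOW = 2
    REDUCED = 3  # slightly reduced
    EQUIVALENT = 4


@dataclass(frozen=True)
class TailConstruct:
    """An engineered substrate: encoded C-terminal suffix + added tail.

    ``encoded_suffix`` holds the final genetically encoded residues of the
    carrier protein that are listed for the construct (may be empty when
    the entire motif is an added tail); ``added_tail`` is the engineered
    extension.  The boundary is the last encoded residue.
    """

    name: str
    encoded_suffix: str
    added_tail: str

    def __post_init__(self):
        if not self.added_tail:
            raise ValueError(f"{self.name}: engineered construct needs a non-empty tail")

    @property
    def full_tail(self) -> str:
        return self.encoded_suffix + self.added_tail

    @property
    def boundary_index(self) -> Optional[int]:
        """0-based index of the last encoded residue within ``full_tail``."""
        if not self.encoded_suffix:
            return None
        return len(self.encoded_suffix) - 1


@dataclass(frozen=True)
class EligibleRun:
    longest_run: int
    includes_boundary: bool  # a longest run contains the boundary residue
    boundary_run: int  # length of the E-run through the boundary residue (0 if not E)


@dataclass(frozen=True)
class CleavagePrediction:
    cleavable: bool
    longest_eligible_run: int
    run_includes_boundary: bool
    rate_class: RateClass


def eligible_run(construct: TailConstruct) -> EligibleRun:
    """Longest maximal E-run in the tail region, and its boundary status."""
    runs = find_runs(construct.full_tail, min_len=1, protein_id=construct.name)
    if not runs:
        return EligibleRun(0, False, 0)
    longest = max(r.length for r in runs)
    b = construct.boundary_index
    includes_boundary = False
    boundary_run = 0
    if b is not None:
        pos = b + 1  # find_runs coordinates are 1-based
        for r in runs:
            if r.start <= pos <= r.end:
                boundary_run = r.length
                if r.length == longest:
                    includes_boundary = True
                break
    return EligibleRun(longest, includes_boundary, boundary_run)


def predict_cleavage(
    construct: TailConstruct,
    calibration: Optional[Mapping[str, RateClass]] = None,
    min_internal_run: int = MIN_INTERNAL_RUN,
    min_boundary_run: int = MIN_BOUNDARY_RUN,
    reference_suffix: str = REFERENCE_SUFFIX,
) -> CleavagePrediction:
    """Predict cleavability and ordinal rate class for one construct.

    The prediction depends only on the tail region, never on the carrier
    protein identity.  With ``calibration`` (construct name -> RateClass)
    the published per-construct class overrides the run-length heuristic;
    without it the default heuristic applies:

    * longest run >= 11 on the unmodified reference suffix -> EQUIVALENT
    * longest run >= 8 -> REDUCED
    * longest run >= 6 -> SLOW
    * boundary rule only (run of 5 through the encoded terminal E) -> VERY_SLOW
    * not cleavable -> NIL
    """
    er = eligible_run(construct)
    cleavable = er.longest_run >= min_internal_run or er.boundary_run >= min_boundary_run

    if not cleavable:
        rate = RateClass.NIL
    elif (
        er.longest_run >= 11
        and construct.encoded_suffix == reference_suffix
        and er.includes_boundary
    ):
        rate = RateClass.EQUIVALENT
    elif er.longest_run >= 8:
        rate = RateClass.REDUCED
    elif er.longest_run >= min_internal_run:
        rate = RateClass.SLOW
    else:
        rate = RateClass.VERY_SLOW

    if calibration is not None and construct.name in calibration:
        rate = RateClass(calibration[construct.name])
        cleavable = rate > RateClass.NIL

    return CleavagePrediction(
        cleavable=cleavable,
        longest_eligible_run=er.longest_run,
        run_includes_boundary=er.includes_boundary,
        rate_class=rate,
    )


def load_substrate_table() -> pd.DataFrame:
    """The packaged substrate panel (26 engineered tail constructs)."""
    with resources.files("rimkit.data").joinpath("substrate_table.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", keep_default_na=False, dtype=str)
    return df


def load_calibration() -> dict[str, RateClass]:
    """Observed rate classes of the packaged panel, keyed by construct name."""
    df = load_substrate_table()
    return {r["name"]: RateClass[r["observed_rate"]] for _, r in df.iterrows()}


def constructs_from_frame(df: pd.DataFrame) -> list[TailConstruct]:
    """Build constructs from a frame with name / encoded_suffix / added_tail."""
    return [
        TailConstruct(
            name=str(r["name"]),
            encoded_suffix=str(r.get("encoded_suffix", "") or ""),
            added_tail=str(r["added_tail"]),
        )
        for _, r in df.iterrows()
    ]


def predict_table(
    constructs: pd.DataFrame, calibration: Optional[Mapping[str, RateClass]] = None
) -> pd.DataFrame:
    """Run the predictor over a construct table; returns an augmented frame.

    Adds columns ``cleavable``, ``longest_run``, ``boundary`` and
    ``rate_class`` (enum name).
    """
    out = constructs.copy()
    preds = [predict_cleavage(c, calibration=calibration) for c in constructs_from_frame(constructs)]
    out["cleavable"] = [p.cleavable for p in preds]
    out["longest_run"] = [p.longest_eligible_run for p in preds]
    out["boundary"] = [p.run_includes_boundary for p in preds]
    out["rate_class"] = [p.rate_class.name for p in preds]
    return out
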