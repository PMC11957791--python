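"""Poly-alpha-L-glutamate mass-ladder detection in deconvoluted peak lists.

RimK synthesises free poly-alpha-L-glutamate; electrospray spectra of the
product, deconvoluted to singly charged species, show an arithmetic ladder
of peaks spaced one glutamate residue apart (129 Da nominal), frequently
accompanied by sodium-adduct satellite series in which Na replaces a
proton (+21.98194 Da per substitution).  This module computes theoretical
polymer m/z values and assigns chain lengths to observed peaks.

A linear n-mer of glutamate is n residues plus one water; the singly
protonated ion with k sodium substitutions is therefore

    m/z = n * m_E + m_H2O + m_proton + k * (m_Na - m_H)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

#: Monoisotopic constants (Da): Glu residue C5H7NO3, water, proton charge
#: carrier, and the Na-for-H substitution shift.
MONOISOTOPIC = {
    "residue": 129.04259,
    "water": 18.01056,
    "proton": 1.00728,
    "na_minus_h": 21.98194,
}

#: Average-mass constants (Da) for instruments reporting average masses of
#: long polymers.
AVERAGE = {
    "residue": 129.11550,
    "water": 18.01528,
    "proton": 1.00728,
    "na_minus_h": 21.98183,
}

_MASS_TABLES = {"monoisotopic": MONOISOTOPIC, "average": AVERAGE}

PEAK_COLUMNS = ["mz", "intensity"]


def polymer_mz(
    n: Union[int, np.ndarray],
    sodium_count: int = 0,
    mass_mode: str = "monoisotopic",
):
    """Theoretical singly charged m/z of a poly-Glu n-mer with k sodiums."""
    if np.any(np.asarray(n) < 1):
        raise ValueError("polymer length n must be >= 1")
    if sodium_count < 0:
        raise ValueError("sodium_count must be >= 0")
    t = _MASS_TABLES[mass_mode]
    return n * t["residue"] + t["water"] + t["proton"] + sodium_count * t["na_minus_h"]


@dataclass(frozen=True)
class Assignment:
    """One peak assigned to a polymer chain length within a series."""

    n_residues: int
    sodium_count: int
    observed_mz: float
    theoretical_mz: float
    error_ppm: float
    intensity: float


@dataclass
class LadderSeries:
    """A detected arithmetic polymer series at a fixed sodium count."""

    sodium_count: int
    assignments: list[Assignment] = field(default_factory=list)

    @property
    def max_n(self) -> int:
        return max(a.n_residues for a in self.assignments)

    @property
    def min_n(self) -> int:
        return min(a.n_residues for a in self.assignments)

    @property
    def total_intensity(self) -> float:
        return float(sum(a.intensity for a in self.assignments))

    def to_frame(self, series_id: int = 0) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "series_id": series_id,
                "n": [a.n_residues for a in self.assignments],
                "na": self.sodium_count,
                "obs_mz": [a.observed_mz for a in self.assignments],
                "theo_mz": [a.theoretical_mz for a in self.assignments],
                "ppm": [a.error_ppm for a in self.assignments],
            }
        )


def read_peaks(source) -> pd.DataFrame:
    """Read a peak list CSV with columns mz, intensity."""
    df = pd.read_csv(source)
    missing = set(PEAK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peak list missing columns: {sorted(missing)}")
    return df[PEAK_COLUMNS]


def detect_ladders(
    peaks: pd.DataFrame,
    tol_ppm: float = 20.0,
    n_max_search: int = 60,
    na_max: int = 3,
    min_series_len: int = 3,
    mass_mode: str = "monoisotopic",
) -> list[LadderSeries]:
    """Detect poly-Glu ladder series in a deconvoluted +1 peak list.

    For each sodium count up to ``na_max``, every chain length up to
    ``n_max_search`` is matched to the closest peak within ``tol_ppm``.
    Candidate series then claim peaks greedily -- longest series first,
    total matched intensity as tie-break -- so each peak supports at most
    one series.  Series retaining fewer than ``min_series_len`` assignments
    are discarded.  Assignments may be gapped (missing intermediate chain
    lengths do not split a series).
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if peaks is None or len(peaks) == 0:
        return []
    mz = np.asarray(peaks["mz"], dtype=float)
    inten = np.asarray(peaks["intensity"], dtype=float)
    order = np.argsort(mz)
    mz, inten = mz[order], inten[order]

    candidates: list[LadderSeries] = []
    for na in range(na_max + 1):
        series = LadderSeries(sodium_count=na)
        for n in range(1, n_max_search + 1):
            theo = polymer_mz(n, na, mass_mode)
            i = np.searchsorted(mz, theo)
            best = None
            for j in (i - 1, i):
                if 0 <= j < len(mz):
                    ppm = (mz[j] - theo) / theo * 1e6
                    if abs(ppm) <= tol_ppm and (best is None or abs(ppm) < abs(best[1])):
                        best = (j, ppm)
            if best is not None:
                j, ppm = best
                series.assignments.append(
                    Assignment(
                        n_residues=n,
                        sodium_count=na,
                        observed_mz=float(mz[j]),
                        theoretical_mz=float(theo),
                        error_ppm=float(ppm),
                        intensity=float(inten[j]),
                    )
                )
        if len(series.assignments) >= min_series_len:
            candidates.append(series)

    # Greedy conflict resolution: each peak backs at most one series.
    candidates.sort(key=lambda s: (len(s.assignments), s.total_intensity), reverse=True)
    claimed: set[float] = set()
    accepted: list[LadderSeries] = []
    for series in candidates:
        kept = [a for a in series.assignments if a.observed_mz not in claimed]
        if len(kept) >= min_series_len:
            series.assignments = kept
            claimed.update(a.observed_mz for a in kept)
            accepted.append(series)
    accepted.sort(key=lambda s: s.sodium_count)
    return accepted


def summarize(series_list: Sequence[LadderSeries]) -> dict:
    """Overall summary: longest chain observed across all series."""
    max_n: Optional[int] = max((s.max_n for s in series_list), default=None)
    return {
        "max_n": max_n,
        "n_series": len(series_list),
        "n_assigned_peaks": int(sum(len(s.assignments) for s in series_list)),
    }


def series_table(series_list: Sequence[LadderSeries]) -> pd.DataFrame:
    """Concatenate all series into one tidy assignment table."""
    if not series_list:
        return pd.DataFrame(columns=["series_id", "n", "na", "obs_mz", "theo_mz", "ppm"])
    return pd.concat(
        [s.to_frame(series_id=i) for i, s in enumerate(series_list)],
        ignore_index=True,
    )
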