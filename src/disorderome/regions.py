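"""Disorder-region calling on per-residue tracks.

A track's binary states are decomposed into maximal same-state runs; the
run decomposition drives the three proteome-level metrics used throughout
the pipeline:

* *long disorder* — the protein contains at least one disordered run of
  >= N consecutive residues (N in {30, 50, 80} by convention);
* *completely disordered* — after reclassifying disordered runs shorter
  than five residues as ordered (they are too short to matter and are
  merged into their ordered neighbours), the protein has no ordered run
  >= 30 residues but does have a disordered run >= 30 residues, i.e. no
  stretch long enough to act as a nucleation site for regular structure.

Coordinates are 1-based closed intervals in memory; the BED-like writer
converts to 0-based half-open on disk only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import DisorderTrack

#: Disordered runs shorter than this are reclassified as ordered before
#: the completely-disordered decision.
SHORT_RUN_FILTER = 5

#: Minimum run length for both the "no ordered nucleation site" check and
#: the long-disorder requirement of the completely-disordered decision.
NUCLEATION_LENGTH = 30

DISORDERED = "disordered"
ORDERED = "ordered"


@dataclass(frozen=True)
class DisorderRegion:
    """A maximal same-state run of one protein (1-based closed interval)."""

    protein_id: str
    start: int
    end: int
    state: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"{self.protein_id}: invalid interval [{self.start}, {self.end}]")
        if self.state not in (DISORDERED, ORDERED):
            raise ValueError(f"{self.protein_id}: unknown state {self.state!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def binarize(track: DisorderTrack, cutoff: float = 0.5) -> DisorderTrack:
    """Return a copy of ``track`` with states set to ``score >= cutoff``.

    0.5 is the conventional disorder threshold of score-emitting
    predictors; predictors that emit binary calls natively pass through
    unchanged at the default cutoff.
    """
    if not (0.0 <= cutoff <= 1.0):
        raise ValueError(f"cutoff {cutoff} outside [0, 1]")
    states = (track.scores >= cutoff).astype(np.int8)
    return DisorderTrack(track.protein_id, track.predictor, track.scores.copy(), states)


def _require_states(track: DisorderTrack) -> np.ndarray:
    if track.states is None:
        raise ValueError(
            f"track {track.protein_id!r} has no binary states; apply binarize() first"
        )
    return track.states


def run_decomposition(states: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Decompose a 0/1 state vector into maximal runs.

    Returns ``(starts, ends, values)`` with 1-based closed coordinates.
    """
    s = np.asarray(states, dtype=np.int8)
    if s.size == 0:
        raise ValueError("empty state vector")
    change = np.flatnonzero(np.diff(s))
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [s.size - 1]))
    return starts + 1, ends + 1, s[starts]


def call_runs(track: DisorderTrack) -> list[DisorderRegion]:
    """Return all maximal runs (both states), sorted and tiling the protein."""
    starts, ends, values = run_decomposition(_require_states(track))
    return [
        DisorderRegion(track.protein_id, int(a), int(b), DISORDERED if v else ORDERED)
        for a, b, v in zip(starts, ends, values)
    ]


def _max_run_length(states: np.ndarray, value: int) -> int:
    starts, ends, values = run_decomposition(states)
    lengths = ends - starts + 1
    sel = lengths[values == value]
    return int(sel.max()) if sel.size else 0


def has_long_disorder(track: DisorderTrack, min_len: int = 30) -> bool:
    """True iff some disordered run spans at least ``min_len`` residues."""
    if min_len < 1:
        raise ValueError(f"min_len must be >= 1, got {min_len}")
    return _max_run_length(_require_states(track), 1) >= min_len


def filter_short_disorder(states: np.ndarray, min_run: int = SHORT_RUN_FILTER) -> np.ndarray:
    """Reclassify disordered runs shorter than ``min_run`` as ordered.

    Residues are never removed: the flanking ordered runs simply merge,
    conserving the protein's coordinate system.
    """
    starts, ends, values = run_decomposition(states)
    lengths = ends - starts + 1
    out = np.asarray(states, dtype=np.int8).copy()
    for a, b in zip(starts[(values == 1) & (lengths < min_run)], ends[(values == 1) & (lengths < min_run)]):
        out[a - 1 : b] = 0
    return out


def is_completely_disordered(
    track: DisorderTrack,
    long_len: int = NUCLEATION_LENGTH,
    short_run: int = SHORT_RUN_FILTER,
) -> bool:
    """Apply the three-step completely-disordered decision.

    (1) disordered runs shorter than ``short_run`` become ordered;
    (2) any ordered run >= ``long_len`` disqualifies the protein;
    (3) otherwise the protein qualifies iff a disordered run >= ``long_len``
    remains.
    """
    filtered = filter_short_disorder(_require_states(track), short_run)
    if _max_run_length(filtered, 0) >= long_len:
        return False
    return _max_run_length(filtered, 1) >= long_len


def write_regions_bed(regions: Sequence[DisorderRegion], path: str | Path) -> None:
    """Write regions as BED-like TSV (0-based half-open on disk only)."""
    with open(path, "w") as handle:
        for region in regions:
            handle.write(f"{region.protein_id}\t{region.start - 1}\t{region.end}\t{region.state}\n")
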