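"""HVAL-based homology between two proteomes and disorder-overlap tables.

Two proteins are called related when their pairwise alignment clears the
HSSP curve by a chosen margin.  The curve gives, for each alignment
length L, the percent identity at which homology becomes plausible:

    p(L) = 480 * L^(-0.32 * (1 + exp(-L / 1000)))   for L <= 450
    p(L) = 19.5                                      for L > 450

(values above 100 are clamped).  HVAL is the distance from that curve,
``pide - p(L)``: HVAL = 0 sits on the curve (about 20% identity for
alignments over 250 residues), HVAL = N means N percentage points above
it.  Relations are kept many-to-many — a protein may have several
homologs — deliberately sidestepping the ortholog/paralog distinction.

On top of the homolog map this module computes, per organism, the
percentage of proteins that are related, the percentage that are related
and carry long disorder (with binomial standard errors), and the
disorder-overlap counts between the two sides of each pair together with
the independence expectation for the number of disordered related
proteins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AlignmentRecord, DisorderTrack, ProteinSequence
from .regions import has_long_disorder

#: Alignment length beyond which the HSSP identity threshold plateaus.
_PLATEAU_LENGTH = 450
_PLATEAU_PCT = 19.5

#: HVAL cutoff grid conventionally reported (columns of a relatedness table).
DEFAULT_CUTOFFS = (-20.0, -10.0, 0.0, 10.0, 20.0, 30.0)


def hssp_threshold(aligned_length: int) -> float:
    """Percent identity at which HVAL = 0 for an alignment of this length."""
    if aligned_length < 1:
        raise ValueError(f"aligned_length must be >= 1, got {aligned_length}")
    if aligned_length > _PLATEAU_LENGTH:
        return _PLATEAU_PCT
    L = float(aligned_length)
    value = 480.0 * L ** (-0.32 * (1.0 + math.exp(-L / 1000.0)))
    return min(value, 100.0)


def hval(pide: float, aligned_length: int) -> float:
    """Distance of the percent identity from the HSSP curve."""
    if not (0.0 <= pide <= 100.0):
        raise ValueError(f"pide {pide} outside [0, 100]")
    return pide - hssp_threshold(aligned_length)


@dataclass
class HomologMap:
    """Many-to-many homolog relation between two organisms at one HVAL cutoff."""

    org_a: str
    org_b: str
    cutoff: float
    pairs: list[tuple[str, str, float]]

    def proteins(self) -> set[str]:
        out: set[str] = set()
        for a, b, _ in self.pairs:
            out.add(a)
            out.add(b)
        return out


def build_homolog_map(
    alignments: Iterable[AlignmentRecord],
    cutoff: float,
    org_a: str = "A",
    org_b: str = "B",
) -> HomologMap:
    """Keep every non-self alignment with HVAL >= cutoff as a homolog pair.

    Symmetric duplicates (A-B and B-A rows) and repeated hits of the same
    pair collapse to the single record with the highest HVAL.
    """
    best: dict[frozenset[str], tuple[str, str, float]] = {}
    for rec in alignments:
        if rec.query_id == rec.subject_id:
            continue
        h = hval(rec.pide, rec.aligned_length)
        if h < cutoff:
            continue
        key = frozenset((rec.query_id, rec.subject_id))
        prev = best.get(key)
        if prev is None or h > prev[2]:
            best[key] = (rec.query_id, rec.subject_id, h)
    return HomologMap(org_a, org_b, cutoff, sorted(best.values()))


# ---------------------------------------------------------------------------
# relatedness statistics


@dataclass(frozen=True)
class OrganismRelated:
    """Table-row statistics for one organism at one HVAL cutoff."""

    organism_id: str
    n_total: int
    n_related: int
    n_related_disordered: int
    pct_related: float
    stderr_related: float
    pct_related_disordered: float
    stderr_related_disordered: float


@dataclass(frozen=True)
class RelatedStats:
    cutoff: float
    a: OrganismRelated
    b: OrganismRelated


def _binomial_stderr(p_fraction: float, n: int) -> float:
    return 100.0 * math.sqrt(p_fraction * (1.0 - p_fraction) / n)


def _as_track_dict(tracks: Mapping[str, DisorderTrack] | Sequence[DisorderTrack]) -> dict[str, DisorderTrack]:
    if isinstance(tracks, Mapping):
        return dict(tracks)
    return {t.protein_id: t for t in tracks}


def _related_side(
    organism_id: str,
    members: set[str],
    tracks: dict[str, DisorderTrack],
    disorder_min_len: int,
) -> OrganismRelated:
    n_total = len(tracks)
    for protein in members:
        if protein not in tracks:
            raise ValueError(f"no disorder track for mapped protein {protein!r} of {organism_id}")
    n_related = len(members)
    n_rel_dis = sum(1 for p in members if has_long_disorder(tracks[p], disorder_min_len))
    p_rel = n_related / n_total
    p_dis = n_rel_dis / n_total
    return OrganismRelated(
        organism_id=organism_id,
        n_total=n_total,
        n_related=n_related,
        n_related_disordered=n_rel_dis,
        pct_related=100.0 * p_rel,
        stderr_related=_binomial_stderr(p_rel, n_total),
        pct_related_disordered=100.0 * p_dis,
        stderr_related_disordered=_binomial_stderr(p_dis, n_total),
    )


def _split_members(
    homolog_map: HomologMap,
    tracks_a: dict[str, DisorderTrack],
    tracks_b: dict[str, DisorderTrack],
) -> tuple[set[str], set[str]]:
    """Assign each mapped protein to its organism via track membership."""
    members_a: set[str] = set()
    members_b: set[str] = set()
    for x, y, _ in homolog_map.pairs:
        for protein in (x, y):
            if protein in tracks_a:
                members_a.add(protein)
            elif protein in tracks_b:
                members_b.add(protein)
            else:
                raise ValueError(f"mapped protein {protein!r} is in neither proteome's tracks")
    return members_a, members_b


def related_table(
    homolog_map: HomologMap,
    tracks_a: Mapping[str, DisorderTrack] | Sequence[DisorderTrack],
    tracks_b: Mapping[str, DisorderTrack] | Sequence[DisorderTrack],
    disorder_min_len: int = 30,
) -> RelatedStats:
    """Percentage of each proteome that is related / related + disordered.

    ``related`` counts proteins with at least one homolog pair on the
    other side; ``related + disordered`` additionally requires the
    protein's own track to contain a disordered run of at least
    ``disorder_min_len`` residues.  Standard errors are the binomial
    standard error of each proportion.
    """
    ta, tb = _as_track_dict(tracks_a), _as_track_dict(tracks_b)
    members_a, members_b = _split_members(homolog_map, ta, tb)
    return RelatedStats(
        cutoff=homolog_map.cutoff,
        a=_related_side(homolog_map.org_a, members_a, ta, disorder_min_len),
        b=_related_side(homolog_map.org_b, members_b, tb, disorder_min_len),
    )


@dataclass(frozen=True)
class DisorderOverlap:
    """Disorder status of the two sides of every homolog pair.

    Counts are per pair.  ``expected_disordered_a`` is the number of
    related proteins of organism A expected to carry long disorder if
    relatedness and disorder were independent: the number of related A
    proteins times A's proteome-wide long-disorder fraction.
    """

    disordered_in_a_only: int
    disordered_in_b_only: int
    both: int
    neither: int
    n_pairs: int
    n_related_a: int
    expected_disordered_a: float
    observed_disordered_a: int


def disorder_overlap(
    homolog_map: HomologMap,
    tracks_a: Mapping[str, DisorderTrack] | Sequence[DisorderTrack],
    tracks_b: Mapping[str, DisorderTrack] | Sequence[DisorderTrack],
    disorder_min_len: int = 30,
) -> DisorderOverlap:
    ta, tb = _as_track_dict(tracks_a), _as_track_dict(tracks_b)
    members_a, _ = _split_members(homolog_map, ta, tb)

    counts = {"a_only": 0, "b_only": 0, "both": 0, "neither": 0}
    for x, y, _ in homolog_map.pairs:
        pa, pb = (x, y) if x in ta else (y, x)
        dis_a = has_long_disorder(ta[pa], disorder_min_len)
        dis_b = has_long_disorder(tb[pb], disorder_min_len)
        if dis_a and dis_b:
            counts["both"] += 1
        elif dis_a:
            counts["a_only"] += 1
        elif dis_b:
            counts["b_only"] += 1
        else:
            counts["neither"] += 1

    frac_long_a = (
        sum(1 for t in ta.values() if has_long_disorder(t, disorder_min_len)) / len(ta)
        if ta
        else 0.0
    )
    observed_a = sum(1 for p in members_a if has_long_disorder(ta[p], disorder_min_len))
    return DisorderOverlap(
        disordered_in_a_only=counts["a_only"],
        disordered_in_b_only=counts["b_only"],
        both=counts["both"],
        neither=counts["neither"],
        n_pairs=len(homolog_map.pairs),
        n_related_a=len(members_a),
        expected_disordered_a=len(members_a) * frac_long_a,
        observed_disordered_a=observed_a,
    )


def related_over_cutoffs(
    alignments: Sequence[AlignmentRecord],
    tracks_a: Mapping[str, DisorderTrack] | Sequence[DisorderTrack],
    tracks_b: Mapping[str, DisorderTrack] | Sequence[DisorderTrack],
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    disorder_min_len: int = 30,
    org_a: str = "A",
    org_b: str = "B",
) -> pd.DataFrame:
    """Relatedness table over an HVAL cutoff grid (two rows per cutoff)."""
    rows = []
    for cutoff in cutoffs:
        stats = related_table(
            build_homolog_map(alignments, cutoff, org_a, org_b),
            tracks_a,
            tracks_b,
            disorder_min_len,
        )
        for side in (stats.a, stats.b):
            rows.append(
                {
                    "hval_cutoff": cutoff,
                    "org": side.organism_id,
                    "pct_related": side.pct_related,
                    "stderr_related": side.stderr_related,
                    "pct_related_disordered": side.pct_related_disordered,
                    "stderr_related_disordered": side.stderr_related_disordered,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# small built-in aligner (synthetic-test plumbing, not a BLAST replacement)

_MAX_ALIGNER_LENGTH = 2000


def align_pair(a: ProteinSequence, b: ProteinSequence) -> AlignmentRecord:
    """Locally align two short sequences and summarise the best alignment.

    Smith-Waterman via Biopython's PairwiseAligner (BLOSUM62, gap open
    -11, extend -1).  Exists so synthetic tests can produce
    :class:`AlignmentRecord` inputs without an external search tool;
    refuses sequences longer than 2,000 residues.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    if a.length > _MAX_ALIGNER_LENGTH or b.length > _MAX_ALIGNER_LENGTH:
        raise ValueError(f"built-in aligner is limited to {_MAX_ALIGNER_LENGTH} residues")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    alignment = aligner.align(a.sequence, b.sequence)[0]
    counts = alignment.counts()
    # aligned columns of the local alignment, gap columns included
    aligned_length = counts.identities + counts.mismatches + counts.internal_gaps
    identities = counts.identities
    if aligned_length == 0:
        raise ValueError(f"no local alignment between {a.id} and {b.id}")
    return AlignmentRecord(
        query_id=a.id,
        subject_id=b.id,
        pide=100.0 * identities / aligned_length,
        aligned_length=int(aligned_length),
    )
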