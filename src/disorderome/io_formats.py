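"""Readers and writers for the external formats the pipeline touches.

Everything downstream of this module operates on in-memory domain types:
:class:`ProteinSequence`, :class:`DisorderTrack` and :class:`AlignmentRecord`.
Three on-disk dialects are supported:

* FASTA (via Biopython), with the duplicate rule used throughout the
  pipeline: when two entries share an identifier, the longer sequence wins.
* IUPred-style per-residue score tracks: ``# protein_id`` header lines
  followed by whitespace-delimited ``position residue score`` rows
  (1-based, contiguous positions). A binary-state dialect with 0/1 in the
  score column is accepted as well and additionally fills ``states``.
* BLAST tabular output (outfmt-6-like, 12 tab-separated columns) of which
  only query, subject, percent identity and alignment length are consumed.

Plain-gzip transparency: any path ending in ``.gz`` is opened through
:mod:`gzip` in text mode.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

#: The 20 standard amino-acid letters plus the ambiguity letter X.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class ParseError(ValueError):
    """Raised when an input file violates its dialect contract."""


@dataclass(frozen=True)
class ProteinSequence:
    """A single protein: identifier plus uppercase amino-acid string."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be nonempty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class DisorderTrack:
    """Per-residue disorder scores (and optionally binary states) for one protein.

    ``scores`` holds one real value in [0, 1] per residue, 1-based positions
    implied by array order.  ``states`` (1 = disordered), when present, has
    the same length.  ``predictor`` is a free label naming the method that
    produced the track (e.g. ``"iupred"``, ``"md"``, ``"norsnet"``,
    ``"synthetic"``); it is metadata only and never interpreted.
    """

    protein_id: str
    predictor: str
    scores: np.ndarray
    states: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or self.scores.size == 0:
            raise ValueError(f"track {self.protein_id!r}: scores must be a nonempty 1-D array")
        if np.any((self.scores < 0.0) | (self.scores > 1.0)):
            raise ValueError(f"track {self.protein_id!r}: scores outside [0, 1]")
        if self.states is not None:
            self.states = np.asarray(self.states, dtype=np.int8)
            if self.states.shape != self.scores.shape:
                raise ValueError(f"track {self.protein_id!r}: states/scores length mismatch")
            if np.any((self.states != 0) & (self.states != 1)):
                raise ValueError(f"track {self.protein_id!r}: states must be 0/1")

    @property
    def length(self) -> int:
        return int(self.scores.size)


@dataclass(frozen=True)
class AlignmentRecord:
    """Summary of one pairwise alignment (one BLAST tabular row).

    ``hval`` is the distance of the percent identity from the HSSP curve;
    it is left unset here and populated by the homology module.
    """

    query_id: str
    subject_id: str
    pide: float
    aligned_length: int
    hval: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.pide <= 100.0):
            raise ValueError(f"{self.query_id}-{self.subject_id}: pide {self.pide} outside [0, 100]")
        if self.aligned_length < 1:
            raise ValueError(f"{self.query_id}-{self.subject_id}: aligned_length must be >= 1")


# ---------------------------------------------------------------------------
# helpers


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA


def _validate_fasta_lines(lines: Iterable[str]) -> None:
    """Cheap pre-scan giving line-numbered errors SeqIO would swallow."""
    header_line: int | None = None
    has_residues = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header_line is not None and not has_residues:
                raise ParseError(f"empty sequence for record starting at line {header_line}")
            if len(line.lstrip(">").strip()) == 0:
                raise ParseError(f"malformed header at line {lineno}: missing identifier")
            header_line = lineno
            has_residues = False
        else:
            if header_line is None:
                raise ParseError(f"sequence data before first header at line {lineno}")
            has_residues = True
    if header_line is not None and not has_residues:
        raise ParseError(f"empty sequence for record starting at line {header_line}")


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a FASTA file into :class:`ProteinSequence` records.

    Duplicate identifiers are resolved by keeping the longer sequence
    (ties keep the first occurrence); order of first appearance is
    preserved.  An empty file yields an empty list with a logged warning.
    """
    with _open_text(path) as handle:
        _validate_fasta_lines(handle)
    with _open_text(path) as handle:
        records = [
            ProteinSequence(id=rec.id, sequence=str(rec.seq))
            for rec in SeqIO.parse(handle, "fasta")
        ]
    if not records:
        log.warning("FASTA file %s contains no records", path)
        return []
    return deduplicate(records)


def deduplicate(records: Sequence[ProteinSequence]) -> list[ProteinSequence]:
    """Collapse records sharing an id, keeping the longer sequence.

    Order of first appearance is preserved, and the operation is idempotent
    and independent of which duplicate comes first.
    """
    best: dict[str, ProteinSequence] = {}
    order: list[str] = []
    for rec in records:
        prev = best.get(rec.id)
        if prev is None:
            best[rec.id] = rec
            order.append(rec.id)
        elif rec.length > prev.length:
            best[rec.id] = rec
    return [best[i] for i in order]


def write_fasta(records: Sequence[ProteinSequence], path: str | Path, width: int = 60) -> None:
    seqrecords = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description="") for rec in records
    ]
    with _open_text(path, "wt") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seqrecords)


# ---------------------------------------------------------------------------
# score tracks


def read_score_track(path: str | Path, predictor: str = "unknown") -> list[DisorderTrack]:
    """Read an IUPred-style score-track file.

    The file consists of ``# protein_id`` header lines each followed by
    whitespace-delimited ``position residue score`` rows with contiguous
    1-based positions.  If every score of a track is the literal 0 or 1
    the binary-state dialect is assumed and ``states`` is filled too.
    """
    tracks: list[DisorderTrack] = []
    cur_id: str | None = None
    cur_scores: list[float] = []
    cur_tokens_binary = True
    header_line = 0

    def _flush() -> None:
        nonlocal cur_id, cur_scores, cur_tokens_binary
        if cur_id is None:
            return
        if not cur_scores:
            raise ParseError(f"track {cur_id!r} (header at line {header_line}) has no rows")
        scores = np.asarray(cur_scores, dtype=float)
        states = scores.astype(np.int8) if cur_tokens_binary else None
        tracks.append(DisorderTrack(cur_id, predictor, scores, states))
        cur_id, cur_scores, cur_tokens_binary = None, [], True

    with _open_text(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                _flush()
                cur_id = line.lstrip("#").strip()
                header_line = lineno
                if not cur_id:
                    raise ParseError(f"missing protein id in header at line {lineno}")
                continue
            if cur_id is None:
                raise ParseError(f"data row before first header at line {lineno}")
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"expected 'position residue score' at line {lineno}")
            try:
                pos = int(fields[0])
                score = float(fields[2])
            except ValueError as exc:
                raise ParseError(f"unparsable row at line {lineno}: {line!r}") from exc
            if pos != len(cur_scores) + 1:
                raise ParseError(
                    f"non-contiguous position at line {lineno}: got {pos}, expected {len(cur_scores) + 1}"
                )
            if not (0.0 <= score <= 1.0):
                raise ParseError(f"score out of range at line {lineno}: {score}")
            if fields[2] not in ("0", "1"):
                cur_tokens_binary = False
            cur_scores.append(score)
    _flush()
    return tracks


def write_score_track(
    tracks: Sequence[DisorderTrack],
    path: str | Path,
    sequences: dict[str, ProteinSequence] | None = None,
) -> None:
    """Write tracks in the dialect :func:`read_score_track` consumes.

    Residue letters are taken from ``sequences`` when supplied, else ``X``.
    """
    with _open_text(path, "wt") as handle:
        for track in tracks:
            handle.write(f"# {track.protein_id}\n")
            seq = sequences.get(track.protein_id) if sequences else None
            for i, score in enumerate(track.scores):
                residue = seq.sequence[i] if seq is not None else "X"
                handle.write(f"{i + 1}\t{residue}\t{score:.4f}\n")


# ---------------------------------------------------------------------------
# alignment tables


def read_alignment_table(path: str | Path) -> list[AlignmentRecord]:
    """Read a BLAST tabular (outfmt-6-like) file.

    Only the first four columns (query, subject, percent identity, aligned
    length) are consumed; self-hits are retained here and filtered by the
    homology module.  An empty file yields an empty list.
    """
    records: list[AlignmentRecord] = []
    with _open_text(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(
                    f"expected >= 4 tab-separated columns at line {lineno}, got {len(fields)}"
                )
            try:
                rec = AlignmentRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pide=float(fields[2]),
                    aligned_length=int(fields[3]),
                )
            except ValueError as exc:
                raise ParseError(f"bad alignment row at line {lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_alignment_table(records: Sequence[AlignmentRecord], path: str | Path) -> None:
    """Write records as 12-column BLAST tabular rows (unused columns zeroed)."""
    with _open_text(path, "wt") as handle:
        for rec in records:
            handle.write(
                "\t".join(
                    [
                        rec.query_id,
                        rec.subject_id,
                        f"{rec.pide:.2f}",
                        str(rec.aligned_length),
                        "0",
                        "0",
                        "1",
                        str(rec.aligned_length),
                        "1",
                        str(rec.aligned_length),
                        "0.0",
                        "0",
                    ]
                )
                + "\n"
            )
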