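"""Amino-acid composition of proteomes and hydrophobic-class fractions.

Composition differences between extremophiles and mesophiles are subtle
(e.g. glutamic-acid enrichment in heat-adapted proteomes), so per-letter
frequencies are standardised across a panel as Z-scores, letter by
letter.  For a coarser two-class view, residues are split into
hydrophobic/not under three published per-residue hydrophobicity scales
(Kyte-Doolittle, Eisenberg consensus, Janin); a residue counts as
hydrophobic when its scale value is positive.  The scale tables are
module data and can be swapped to test alternative class definitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ProteinSequence

log = logging.getLogger(__name__)

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

# Kyte & Doolittle (1982) hydropathy.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Eisenberg & Weiss consensus scale (1984).
EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29, "Q": -0.85,
    "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38, "L": 1.06, "K": -1.50,
    "M": 0.64, "F": 1.19, "P": 0.12, "S": -0.18, "T": -0.05, "W": 0.81,
    "Y": 0.26, "V": 1.08,
}

# Janin (1979) buried/accessible transfer scale.
JANIN = {
    "A": 0.3, "R": -1.4, "N": -0.5, "D": -0.6, "C": 0.9, "Q": -0.7, "E": -0.7,
    "G": 0.3, "H": -0.1, "I": 0.7, "L": 0.5, "K": -1.8, "M": 0.4, "F": 0.5,
    "P": -0.3, "S": -0.1, "T": -0.2, "W": 0.3, "Y": -0.4, "V": 0.6,
}

HYDROPHOBICITY_SCALES: dict[str, dict[str, float]] = {
    "kyte_doolittle": KYTE_DOOLITTLE,
    "eisenberg": EISENBERG,
    "janin": JANIN,
}


@dataclass
class CompositionProfile:
    """Per-proteome amino-acid frequencies, Z-scores and hydrophobic fractions."""

    organism_id: str
    freq: dict[str, float]
    z: dict[str, float] = field(default_factory=dict)
    hydrophobic_pct: dict[str, float] = field(default_factory=dict)
    n_excluded: int = 0

    def __post_init__(self) -> None:
        total = sum(self.freq.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.organism_id}: frequencies sum to {total}, not 1")


def _standard_counts(proteome: Sequence[ProteinSequence]) -> tuple[dict[str, int], int]:
    counts = dict.fromkeys(AMINO_ACIDS, 0)
    excluded = 0
    for protein in proteome:
        for letter in protein.sequence:
            if letter in counts:
                counts[letter] += 1
            else:
                excluded += 1
    return counts, excluded


def aa_frequencies(proteome: Sequence[ProteinSequence], organism_id: str = "proteome") -> CompositionProfile:
    """Amino-acid frequencies over a whole proteome.

    Non-standard letters (X, gaps, ambiguity codes) are excluded from both
    numerator and denominator; their tally is logged and kept on the
    profile.
    """
    if not proteome:
        raise ValueError("empty proteome")
    counts, excluded = _standard_counts(proteome)
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"{organism_id}: no standard residues in proteome")
    if excluded:
        log.info("%s: excluded %d non-standard residues from composition", organism_id, excluded)
    return CompositionProfile(
        organism_id=organism_id,
        freq={aa: counts[aa] / total for aa in AMINO_ACIDS},
        n_excluded=excluded,
    )


def composition_zscores(
    profiles: Sequence[CompositionProfile], ddof: int = 1
) -> list[CompositionProfile]:
    """Fill per-letter Z-scores across a panel of profiles (in place).

    A letter with zero spread across the panel gets Z = 0 for every
    profile, with a warning.
    """
    if len(profiles) < 2:
        raise ValueError("composition Z-scores require >= 2 profiles")
    for aa in AMINO_ACIDS:
        values = np.array([p.freq[aa] for p in profiles])
        sd = values.std(ddof=ddof)
        if sd == 0:
            log.warning("zero variance for %s across panel; Z set to 0", aa)
            for p in profiles:
                p.z[aa] = 0.0
            continue
        mean = values.mean()
        for p, v in zip(profiles, values):
            p.z[aa] = float((v - mean) / sd)
    return list(profiles)


def hydrophobic_fraction(
    proteome: Sequence[ProteinSequence], scale: str = "kyte_doolittle"
) -> float:
    """Percent of standard residues in the hydrophobic class of a scale.

    A residue is hydrophobic when its per-residue scale value is > 0.
    """
    if scale not in HYDROPHOBICITY_SCALES:
        raise ValueError(
            f"unknown scale {scale!r}; expected one of {sorted(HYDROPHOBICITY_SCALES)}"
        )
    table = HYDROPHOBICITY_SCALES[scale]
    counts, _ = _standard_counts(proteome)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no standard residues after filtering")
    hydrophobic = sum(n for aa, n in counts.items() if table[aa] > 0)
    return 100.0 * hydrophobic / total


def annotate_hydrophobicity(
    profile: CompositionProfile, proteome: Sequence[ProteinSequence]
) -> CompositionProfile:
    for scale in HYDROPHOBICITY_SCALES:
        profile.hydrophobic_pct[scale] = hydrophobic_fraction(proteome, scale)
    return profile


def composition_to_frame(profiles: Iterable[CompositionProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row: dict[str, object] = {"organism_id": p.organism_id}
        row.update({f"freq_{aa}": p.freq[aa] for aa in AMINO_ACIDS})
        row.update({f"z_{aa}": p.z.get(aa) for aa in AMINO_ACIDS})
        row.update({f"hydrophobic_pct_{s}": p.hydrophobic_pct.get(s) for s in HYDROPHOBICITY_SCALES})
        rows.append(row)
    return pd.DataFrame(rows)


def write_composition_tsv(profiles: Iterable[CompositionProfile], path: str | Path) -> None:
    composition_to_frame(profiles).to_csv(path, sep="\t", index=False)
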