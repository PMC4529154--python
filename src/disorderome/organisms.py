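"""Habitat classification from growth metadata and organism grouping.

Habitat classes follow the standard extremophile definitions: thermophile
(optimal growth 45-80 °C), hyperthermophile (>80 °C), psychrophile
(optimum about 15 °C with a growth maximum near 20 °C and a minimum at or
below 0 °C), psychrotolerant (grows at or close to 0 °C without being
psychrophilic), halophile (optimal growth from 25% NaCl up to
saturation), alkaliphile (optimum above pH 8), mesophile (none of the
above).  Eukaryotes are carried as their own class because their disorder
content is not comparable to prokaryotes.

An organism may satisfy several definitions (e.g. hot springs brines);
every matching label is returned and the primary label is resolved by a
configurable priority, salt before temperature before pH by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

HABITAT_CLASSES = (
    "eukaryote",
    "halophile",
    "hyperthermophile",
    "thermophile",
    "psychrophile",
    "psychrotolerant",
    "alkaliphile",
    "mesophile",
)

#: Primary-label resolution order: salt > temperature > pH.
DEFAULT_PRIORITY = HABITAT_CLASSES

#: Metadata factors usable as grouping keys besides habitat and phylum.
FACTOR_KEYS = ("oxygen_requirement", "metabolism", "energy_source", "cell_shape")


@dataclass(frozen=True)
class GrowthMetadata:
    """Growth-condition optima used to classify an organism's habitat."""

    opt_temp_c: float | None = None
    min_temp_c: float | None = None
    max_temp_c: float | None = None
    nacl_opt_pct: float | None = None
    ph_opt: float | None = None
    is_eukaryote: bool = False

    def __post_init__(self) -> None:
        temps = [self.min_temp_c, self.opt_temp_c, self.max_temp_c]
        known = [t for t in temps if t is not None]
        if known != sorted(known):
            raise ValueError(f"temperature bounds out of order: min/opt/max = {temps}")


def classify_habitat(
    growth: GrowthMetadata,
    priority: Sequence[str] = DEFAULT_PRIORITY,
    psychro_opt_max_c: float = 20.0,
    psychrotolerant_min_max_c: float = 5.0,
) -> tuple[str, list[str]]:
    """Classify growth metadata into a habitat class.

    Returns ``(primary_label, all_matching_labels)``.  ``primary_label``
    is the highest-priority match; when several definitions match, the
    resolution is logged and no matched label is dropped from the list.
    ``psychrotolerant_min_max_c`` encodes "growth at or close to 0 °C".
    """
    g = growth
    if all(
        v is None
        for v in (g.opt_temp_c, g.min_temp_c, g.max_temp_c, g.nacl_opt_pct, g.ph_opt)
    ) and not g.is_eukaryote:
        raise ValueError("cannot classify: no growth fields present")

    matches: list[str] = []
    if g.is_eukaryote:
        matches.append("eukaryote")
    if g.nacl_opt_pct is not None and g.nacl_opt_pct >= 25.0:
        matches.append("halophile")
    if g.opt_temp_c is not None:
        if g.opt_temp_c > 80.0:
            matches.append("hyperthermophile")
        elif g.opt_temp_c >= 45.0:
            matches.append("thermophile")
    is_psychrophile = (
        g.opt_temp_c is not None
        and g.opt_temp_c <= psychro_opt_max_c
        and g.max_temp_c is not None
        and g.max_temp_c <= 20.0
        and g.min_temp_c is not None
        and g.min_temp_c <= 0.0
    )
    if is_psychrophile:
        matches.append("psychrophile")
    elif g.min_temp_c is not None and g.min_temp_c <= psychrotolerant_min_max_c:
        matches.append("psychrotolerant")
    if g.ph_opt is not None and g.ph_opt > 8.0:
        matches.append("alkaliphile")
    if not matches:
        matches.append("mesophile")

    ranked = sorted(matches, key=lambda label: priority.index(label))
    if len(matches) > 1:
        log.info(
            "multiple habitat definitions match (%s); primary resolved to %s",
            ", ".join(matches),
            ranked[0],
        )
    return ranked[0], matches


@dataclass
class OrganismRecord:
    """One organism's habitat, taxonomy, and grouping factors."""

    organism_id: str
    phylum: str | None = None
    taxonomy: tuple[str, ...] = ()
    growth: GrowthMetadata | None = None
    habitat_class: str | None = None
    factors: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.habitat_class is None and self.growth is not None:
            self.habitat_class, _ = classify_habitat(self.growth)

    def group_value(self, key: str) -> str | None:
        if key == "habitat":
            return self.habitat_class
        if key == "phylum":
            return self.phylum
        return self.factors.get(key)


def group_by(
    records: Sequence[OrganismRecord],
    key: str,
    min_size: int = 2,
) -> dict[str, list[str]]:
    """Group organism ids by habitat, phylum, or a metadata factor.

    Records missing the key are dropped with a warning; groups smaller
    than ``min_size`` (default 2, matching the rule that groups with
    fewer than two samples are not compared) are removed.
    """
    if not records:
        raise ValueError("no organism records to group")
    groups: dict[str, list[str]] = {}
    for rec in records:
        value = rec.group_value(key)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            log.warning("organism %s missing grouping key %r; dropped", rec.organism_id, key)
            continue
        groups.setdefault(str(value), []).append(rec.organism_id)
    kept = {label: ids for label, ids in groups.items() if len(ids) >= min_size}
    if not kept:
        raise ValueError(f"no groups of size >= {min_size} for key {key!r}")
    return kept


# ---------------------------------------------------------------------------
# metadata TSV

_METADATA_COLUMNS = [
    "organism_id",
    "phylum",
    "taxonomy",
    "opt_temp_c",
    "min_temp_c",
    "max_temp_c",
    "nacl_opt_pct",
    "ph_opt",
    "is_eukaryote",
    "habitat_class",
    *FACTOR_KEYS,
]


def _opt_float(value: object) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return float(value)  # type: ignore[arg-type]


def read_metadata_tsv(path: str | Path) -> list[OrganismRecord]:
    """Read the organism metadata table (TSV with a header line)."""
    frame = pd.read_csv(path, sep="\t", dtype={"organism_id": str})
    if "organism_id" not in frame.columns:
        raise ValueError(f"{path}: metadata table lacks an organism_id column")
    records = []
    for _, row in frame.iterrows():
        growth_fields = {
            "opt_temp_c": _opt_float(row.get("opt_temp_c")),
            "min_temp_c": _opt_float(row.get("min_temp_c")),
            "max_temp_c": _opt_float(row.get("max_temp_c")),
            "nacl_opt_pct": _opt_float(row.get("nacl_opt_pct")),
            "ph_opt": _opt_float(row.get("ph_opt")),
            "is_eukaryote": bool(row.get("is_eukaryote", False)),
        }
        has_growth = any(v is not None for k, v in growth_fields.items() if k != "is_eukaryote")
        growth = GrowthMetadata(**growth_fields) if has_growth or growth_fields["is_eukaryote"] else None
        taxonomy = row.get("taxonomy")
        habitat = row.get("habitat_class")
        records.append(
            OrganismRecord(
                organism_id=row["organism_id"],
                phylum=None if pd.isna(row.get("phylum")) else str(row.get("phylum")),
                taxonomy=tuple(str(taxonomy).split(";")) if isinstance(taxonomy, str) and taxonomy else (),
                growth=growth,
                habitat_class=None if pd.isna(habitat) else str(habitat),
                factors={
                    k: str(row[k]) for k in FACTOR_KEYS if k in frame.columns and not pd.isna(row[k])
                },
            )
        )
    return records


def to_metadata_frame(records: Sequence[OrganismRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        g = rec.growth or GrowthMetadata(is_eukaryote=False)
        rows.append(
            {
                "organism_id": rec.organism_id,
                "phylum": rec.phylum,
                "taxonomy": ";".join(rec.taxonomy),
                "opt_temp_c": g.opt_temp_c,
                "min_temp_c": g.min_temp_c,
                "max_temp_c": g.max_temp_c,
                "nacl_opt_pct": g.nacl_opt_pct,
                "ph_opt": g.ph_opt,
                "is_eukaryote": g.is_eukaryote,
                "habitat_class": rec.habitat_class,
                **{k: rec.factors.get(k) for k in FACTOR_KEYS},
            }
        )
    return pd.DataFrame(rows, columns=_METADATA_COLUMNS)


def write_metadata_tsv(records: Sequence[OrganismRecord], path: str | Path) -> None:
    to_metadata_frame(records).to_csv(path, sep="\t", index=False)
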