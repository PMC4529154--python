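"""Proteome-level disorder content and Z-scores.

A proteome's raw disorder content is the percentage of its proteins with
at least one long disordered run (%long30/%long50/%long80) or classified
completely disordered.  To compare proteomes scored by different
predictors on one scale, each raw value is standardised against a
background distribution over many proteomes:

    z = (raw - mean_background) / sd_background

Positive Z-scores mean more disorder than the background average, in
units of one background standard deviation.  Background constants for
%long30 over 1,613 complete prokaryotic proteomes ship as defaults (per
predictor); backgrounds for other metrics can be loaded from a YAML
config or recomputed from user profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io_formats import DisorderTrack
from . import regions as _regions

#: Long-disorder length thresholds (residues) reported for every proteome.
LONG_THRESHOLDS = (30, 50, 80)

#: Metric keys used for Z-scores and backgrounds.
METRICS = ("long30", "long50", "long80", "completely")


@dataclass(frozen=True)
class BackgroundStats:
    """Mean and standard deviation of one raw metric over many proteomes."""

    predictor: str
    metric: str
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; expected one of {METRICS}")
        if self.sd <= 0:
            raise ValueError(f"background sd must be > 0, got {self.sd}")


#: %long30 background over 1,613 complete prokaryotic proteomes, per predictor.
DEFAULT_BACKGROUNDS: dict[tuple[str, str], BackgroundStats] = {
    ("md", "long30"): BackgroundStats("md", "long30", 14.6, 4.2),
    ("norsnet", "long30"): BackgroundStats("norsnet", "long30", 2.5, 2.0),
    ("iupred", "long30"): BackgroundStats("iupred", "long30", 7.5, 5.5),
}


@dataclass
class ProteomeDisorderProfile:
    """One organism's raw disorder content plus (optionally) Z-scores.

    ``pct_long`` maps length threshold -> percent of proteins with a long
    disordered run; ``pct_completely`` is the percent classified
    completely disordered; ``z`` maps metric key -> Z-score once a
    background has been applied.
    """

    organism_id: str
    predictor: str
    n_proteins: int
    pct_long: dict[int, float]
    pct_completely: float
    z: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        ordered = [self.pct_long[t] for t in sorted(self.pct_long)]
        if any(b > a + 1e-9 for a, b in zip(ordered, ordered[1:])):
            raise ValueError(
                f"{self.organism_id}: pct_long must be non-increasing in threshold: {self.pct_long}"
            )

    def raw(self, metric: str) -> float:
        """Raw value of a metric key ('long30', 'long50', 'long80', 'completely')."""
        if metric == "completely":
            return self.pct_completely
        if metric.startswith("long"):
            return self.pct_long[int(metric[4:])]
        raise ValueError(f"unknown metric {metric!r}")


def summarize_proteome(
    tracks: Sequence[DisorderTrack],
    organism_id: str,
    predictor: str | None = None,
    thresholds: Sequence[int] = LONG_THRESHOLDS,
    binarize_cutoff: float = 0.5,
) -> ProteomeDisorderProfile:
    """Aggregate per-protein calls into a proteome profile.

    Tracks lacking binary states are binarized at ``binarize_cutoff``.
    Proteins shorter than a threshold can never satisfy it but still count
    in the denominator: the percentages are over *all* proteins.
    """
    if not tracks:
        raise ValueError("summarize_proteome requires at least one track")
    predictors = {t.predictor for t in tracks}
    if predictor is None:
        if len(predictors) > 1:
            raise ValueError(f"tracks mix predictors {sorted(predictors)}; pass predictor=")
        predictor = next(iter(predictors))

    thresholds = tuple(sorted(thresholds))
    n_long = dict.fromkeys(thresholds, 0)
    n_completely = 0
    for track in tracks:
        states = track.states
        if states is None:
            states = (track.scores >= binarize_cutoff).astype(np.int8)
        starts, ends, values = _regions.run_decomposition(states)
        lengths = ends - starts + 1
        dis_lengths = lengths[values == 1]
        dmax = int(dis_lengths.max()) if dis_lengths.size else 0
        for t in thresholds:
            if dmax >= t:
                n_long[t] += 1
        n_completely += _completely_from_runs(starts, ends, values, int(states.size))

    n = len(tracks)
    pct_long = {t: 100.0 * n_long[t] / n for t in thresholds}
    return ProteomeDisorderProfile(
        organism_id=organism_id,
        predictor=predictor,
        n_proteins=n,
        pct_long=pct_long,
        pct_completely=100.0 * n_completely / n,
    )


def _completely_from_runs(
    starts: np.ndarray,
    ends: np.ndarray,
    values: np.ndarray,
    length: int,
    long_len: int = _regions.NUCLEATION_LENGTH,
    short_run: int = _regions.SHORT_RUN_FILTER,
) -> bool:
    """Completely-disordered decision straight from the run decomposition.

    Equivalent to reclassify-then-rescan: the surviving disordered runs
    are those >= ``short_run``; the merged ordered runs are exactly the
    gaps between surviving disordered runs (including both termini).
    """
    lengths = ends - starts + 1
    keep = (values == 1) & (lengths >= short_run)
    ks, ke = starts[keep], ends[keep]
    if ks.size == 0:
        return False
    gaps = np.concatenate(([ks[0] - 1], ks[1:] - ke[:-1] - 1, [length - ke[-1]]))
    if gaps.size and gaps.max() >= long_len:
        return False
    return bool((ke - ks + 1).max() >= long_len)


def zscore(raw: float, background: BackgroundStats) -> float:
    """Standardise a raw percentage against a background distribution."""
    if background.sd <= 0:
        raise ValueError("background sd must be > 0")
    return (raw - background.mean) / background.sd


def apply_backgrounds(
    profile: ProteomeDisorderProfile,
    backgrounds: Mapping[tuple[str, str], BackgroundStats] | None = None,
) -> ProteomeDisorderProfile:
    """Fill ``profile.z`` for every metric with an available background."""
    backgrounds = DEFAULT_BACKGROUNDS if backgrounds is None else backgrounds
    for metric in METRICS:
        bg = backgrounds.get((profile.predictor, metric))
        if bg is not None:
            profile.z[metric] = zscore(profile.raw(metric), bg)
    return profile


def background_from_profiles(
    profiles: Sequence[ProteomeDisorderProfile],
    metric: str,
    ddof: int = 1,
) -> BackgroundStats:
    """Recompute background mean/sd from a user panel of profiles.

    Uses the sample standard deviation (``ddof=1``) by default; pass
    ``ddof=0`` for the population convention.
    """
    if len(profiles) < 2:
        raise ValueError("background requires >= 2 profiles")
    predictors = {p.predictor for p in profiles}
    if len(predictors) > 1:
        raise ValueError(f"profiles mix predictors {sorted(predictors)}")
    values = np.array([p.raw(metric) for p in profiles], dtype=float)
    sd = float(values.std(ddof=ddof))
    if sd <= 0:
        raise ValueError(f"zero variance in metric {metric!r} across profiles")
    return BackgroundStats(next(iter(predictors)), metric, float(values.mean()), sd)


def load_backgrounds(path: str | Path) -> dict[tuple[str, str], BackgroundStats]:
    """Load background constants from YAML: ``predictor: {metric: [mean, sd]}``."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    out: dict[tuple[str, str], BackgroundStats] = {}
    for predictor, metrics in raw.items():
        for metric, (mean, sd) in metrics.items():
            out[(predictor, metric)] = BackgroundStats(predictor, metric, float(mean), float(sd))
    return out


def profiles_to_frame(profiles: Iterable[ProteomeDisorderProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row: dict[str, object] = {
            "organism_id": p.organism_id,
            "predictor": p.predictor,
            "n_proteins": p.n_proteins,
            "pct_long30": p.pct_long.get(30),
            "pct_long50": p.pct_long.get(50),
            "pct_long80": p.pct_long.get(80),
            "pct_completely": p.pct_completely,
        }
        for metric in METRICS:
            row[f"z_{metric}"] = p.z.get(metric)
        rows.append(row)
    return pd.DataFrame(rows)


def write_profiles_tsv(profiles: Iterable[ProteomeDisorderProfile], path: str | Path) -> None:
    profiles_to_frame(profiles).to_csv(path, sep="\t", index=False)
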