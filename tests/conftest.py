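from __future__ import annotations

import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from disorderome import decision_flow, pairwise_wilcoxon, summarize_proteome
from disorderome.io_formats import DisorderTrack
from disorderome.synthetic import GeneratorConfig, generate_habitat_panel

NULL_SIM_SEED = 97531
POWER_SIM_SEED = 86420

#: Simulation scale for the grouped-statistics studies: organisms carry
#: 150 proteins each (length ~N(300, 100^2)); see docs/methods.md.
PANEL_PROTEINS = 150


def make_track(states, protein_id="p", predictor="synthetic") -> DisorderTrack:
    states = np.asarray(states, dtype=np.int8)
    return DisorderTrack(protein_id, predictor, states.astype(float), states)


@pytest.fixture
def track_factory():
    return make_track


def _panel_rep(seed: int, groups):
    cfg = GeneratorConfig(seed=seed, n_proteins=PANEL_PROTEINS)
    panel = generate_habitat_panel(cfg, groups)
    values: dict[str, list[float]] = {}
    for org in panel.organisms:
        prof = summarize_proteome(panel.tracks[org.organism_id], org.organism_id)
        values.setdefault(org.habitat_class, []).append(prof.pct_long[30])
    return values


@dataclass
class FlowSimulation:
    n_reps: int
    n_groups: int
    group_labels: list[str]
    flow_marks: list[dict]            # per rep: {(g1, g2): mark} from the full flow
    ungated_pvalues: list[list[float]]  # per rep: pairwise rank-test p for every pair
    shifted_group: str | None = None


def _run_flow_sim(base_seed: int, groups, n_reps: int, shifted: str | None) -> FlowSimulation:
    flow_marks, ungated = [], []
    for r in range(n_reps):
        values = _panel_rep(base_seed + r, groups)
        result = decision_flow(values)
        flow_marks.append(dict(result.marks))
        ungated.append([p for _, p in pairwise_wilcoxon(values)])
    return FlowSimulation(
        n_reps=n_reps,
        n_groups=len(groups),
        group_labels=[g[0] for g in groups],
        flow_marks=flow_marks,
        ungated_pvalues=ungated,
        shifted_group=shifted,
    )


@pytest.fixture(scope="session")
def null_flow_sim() -> FlowSimulation:
    """1,000 null panels: 5 groups x 6 organisms, no group effects."""
    groups = [(f"g{i}", 6, 0.0) for i in range(5)]
    return _run_flow_sim(NULL_SIM_SEED, groups, 1000, shifted=None)


@pytest.fixture(scope="session")
def power_flow_sim() -> FlowSimulation:
    """500 panels with one group shifted +2 background sd, others null."""
    groups = [("shifted", 6, 2.0)] + [(f"g{i}", 6, 0.0) for i in range(4)]
    return _run_flow_sim(POWER_SIM_SEED, groups, 500, shifted="shifted")
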