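"""Synthetic proteomes with controllable disorder structure.

Disorder along a protein is modelled as a stationary two-state Markov
chain (ordered / disordered) whose stay-probabilities give geometric run
lengths; the chance that a protein of length L contains a disordered run
of >= 30 residues is then a closed-form dynamic program, which lets the
generator *calibrate* the ordered->disordered entry probability so a
proteome hits a requested %long30 in expectation.  Scores are the true
binary states plus sub-threshold uniform noise, so binarizing at 0.5
recovers the truth exactly.  Sequence letters are drawn from an average
proteome composition, optionally with state-dependent multipliers that
enrich disorder-promoting residues inside disordered runs.

Three generators close the loop with the rest of the package:

* :func:`generate_proteome` — one organism (sequences + tracks);
* :func:`generate_habitat_panel` — a labelled panel of organisms with
  additive group effects on %long30, ready for the grouped statistics;
* :func:`generate_homolog_pairs` — two proteomes of copy-with-
  substitution homolog pairs at a target percent identity, with disorder
  placed on either, both, or neither side.

Everything is reproducible from the config seed alone.
"""

from __future__ import annotations

import functools

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .io_formats import AlignmentRecord, DisorderTrack, ProteinSequence
from .organisms import GrowthMetadata, OrganismRecord
from .profiles import BackgroundStats, DEFAULT_BACKGROUNDS

#: Average proteome amino-acid frequencies used as the base composition.
AA_BACKGROUND = {
    "A": 0.078, "R": 0.051, "N": 0.045, "D": 0.054, "C": 0.019, "Q": 0.043,
    "E": 0.063, "G": 0.074, "H": 0.022, "I": 0.051, "L": 0.091, "K": 0.057,
    "M": 0.022, "F": 0.039, "P": 0.052, "S": 0.071, "T": 0.058, "W": 0.013,
    "Y": 0.032, "V": 0.065,
}

#: Multipliers enriching disorder-promoting letters in disordered runs
#: (TOP-IDP-like ordering: P/E/S/Q/K up, aromatics and aliphatics down).
DEFAULT_DISORDER_BIAS = {
    "P": 1.6, "E": 1.5, "S": 1.4, "Q": 1.3, "K": 1.3, "G": 1.2, "A": 1.1,
    "R": 1.1, "D": 1.1, "T": 1.0, "N": 1.0, "H": 0.9, "M": 0.8, "V": 0.7,
    "L": 0.6, "I": 0.5, "F": 0.5, "Y": 0.5, "C": 0.4, "W": 0.4,
}

_LETTERS = np.array(list(AA_BACKGROUND))


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic proteome generator.

    ``p_stay_ordered`` / ``p_stay_disordered`` are the Markov chain's
    stay-probabilities; mean run lengths are ``1/(1-p_stay)``.  When
    ``target_pct_long30`` is set, ``p_stay_ordered`` is ignored and the
    entry probability is calibrated so the expected fraction of proteins
    with a >= 30-residue disordered run matches the target.
    """

    seed: int
    n_proteins: int = 500
    length_mean: float = 300.0
    length_sd: float = 100.0
    min_length: int = 50
    p_stay_ordered: float = 0.995
    p_stay_disordered: float = 0.97
    target_pct_long30: float | None = None
    score_noise: float = 0.3
    composition_bias: dict[str, float] | None = None
    predictor: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        for name in ("p_stay_ordered", "p_stay_disordered"):
            p = getattr(self, name)
            if not (0.0 <= p < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {p}")
        if not (0.0 < self.score_noise < 0.5):
            raise ValueError("score_noise must be in (0, 0.5) to keep binarize(0.5) faithful")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


# ---------------------------------------------------------------------------
# run-length model: closed-form long-run probability and calibration


def long_run_probability(
    lengths: np.ndarray,
    p_enter: float,
    p_stay_disordered: float,
    min_run: int = 30,
) -> np.ndarray:
    """P(a stationary chain of length L contains a disordered run >= min_run).

    Dynamic program over (current state, current disordered run length),
    absorbing once a run reaches ``min_run``; evaluated for every length
    in ``lengths`` from a single pass up to their maximum.
    """
    lengths = np.asarray(lengths, dtype=int)
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    q = 1.0 - p_stay_disordered  # leave-disorder probability
    if p_enter <= 0.0:
        return np.zeros(lengths.shape)
    pi_d = p_enter / (p_enter + q)
    l_max = int(lengths.max())

    absorbed = np.zeros(l_max + 1)
    run = np.zeros(max(min_run - 1, 1))  # run[r-1]: P(in disordered run of length r)
    if min_run == 1:
        # P(no disordered residue in L) = (1 - pi_d) * p_stay_ordered^(L-1)
        p_stay_o = 1.0 - p_enter
        absorbed[1:] = 1.0 - (1.0 - pi_d) * p_stay_o ** np.arange(l_max)
        return absorbed[lengths]
    state_o = 1.0 - pi_d
    run[0] = pi_d
    acc = 0.0
    for t in range(2, l_max + 1):
        new_first = state_o * p_enter
        state_o = state_o * (1.0 - p_enter) + run.sum() * q
        acc += run[-1] * p_stay_disordered
        run[1:] = run[:-1] * p_stay_disordered
        run[0] = new_first
        absorbed[t] = acc
    return absorbed[lengths]


def calibrate_entry_probability(
    target_fraction: float,
    lengths: np.ndarray,
    p_stay_disordered: float,
    min_run: int = 30,
    tol: float = 1e-10,
) -> float:
    """Entry probability whose expected long-run fraction matches the target.

    Bisection on the (monotone) mean long-run probability over the given
    protein lengths.  Raises with the attainable range when the target
    exceeds what the run-length structure allows.
    """
    if not (0.0 <= target_fraction <= 1.0):
        raise ValueError("target fraction must be in [0, 1]")
    hi = 1.0 - 1e-9
    attainable = float(long_run_probability(lengths, hi, p_stay_disordered, min_run).mean())
    if target_fraction > attainable + 1e-12:
        raise ValueError(
            f"target %long{min_run} = {100 * target_fraction:.2f} is not attainable with "
            f"p_stay_disordered = {p_stay_disordered} and these lengths; attainable range "
            f"is [0, {100 * attainable:.2f}]"
        )
    lo = 0.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        value = float(long_run_probability(lengths, mid, p_stay_disordered, min_run).mean())
        if abs(value - target_fraction) < tol:
            return mid
        if value < target_fraction:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# state-chain sampling


def _sample_state_chain(
    rng: np.random.Generator, total: int, p_enter: float, p_leave: float
) -> np.ndarray:
    """Sample ``total`` residues of the stationary two-state chain.

    Run lengths are geometric; the chain is assembled from batches of
    alternating runs.  Because the chain is stationary and Markov,
    chopping it into proteins leaves each piece stationary.
    """
    pi_d = p_enter / (p_enter + p_leave) if (p_enter + p_leave) > 0 else 0.0
    cur = 1 if rng.random() < pi_d else 0
    out = np.empty(total, dtype=np.int8)
    filled = 0
    while filled < total:
        k = 128
        runs = np.empty(2 * k, dtype=np.int64)
        values = np.empty(2 * k, dtype=np.int8)
        if cur == 1:
            runs[0::2] = rng.geometric(p_leave, k) if p_leave > 0 else total
            runs[1::2] = rng.geometric(p_enter, k) if p_enter > 0 else total
            values[0::2], values[1::2] = 1, 0
        else:
            runs[0::2] = rng.geometric(p_enter, k) if p_enter > 0 else total
            runs[1::2] = rng.geometric(p_leave, k) if p_leave > 0 else total
            values[0::2], values[1::2] = 0, 1
        cumulative = np.cumsum(runs)
        need = total - filled
        if cumulative[-1] >= need:
            use = int(np.searchsorted(cumulative, need)) + 1
            segment = np.repeat(values[:use], runs[:use])[:need]
            out[filled:] = segment
            filled = total
        else:
            segment = np.repeat(values, runs)
            out[filled : filled + segment.size] = segment
            filled += segment.size
            # an even number of runs was consumed, so `cur` is unchanged
    return out


def _draw_lengths(rng: np.random.Generator, config: GeneratorConfig) -> np.ndarray:
    lengths = np.rint(rng.normal(config.length_mean, config.length_sd, config.n_proteins))
    return np.maximum(lengths, config.min_length).astype(int)


@functools.lru_cache(maxsize=256)
def _calibrated_entry(
    target_pct: float,
    p_stay_disordered: float,
    length_mean: float,
    length_sd: float,
    min_length: int,
    min_run: int = 30,
) -> float:
    """Entry probability for a target %long, memoized per parameter set.

    Calibration uses a deterministic 64-point quantile grid of the length
    distribution rather than one organism's sampled lengths, so the same
    parameters always yield the same entry probability and repeated
    panel generation pays for the bisection only once.
    """
    from scipy import stats as _st

    quantiles = (np.arange(64) + 0.5) / 64
    grid = np.rint(_st.norm.ppf(quantiles, loc=length_mean, scale=length_sd))
    grid = np.maximum(grid, min_length).astype(int)
    return calibrate_entry_probability(target_pct / 100.0, grid, p_stay_disordered, min_run)


def _scores_from_states(rng: np.random.Generator, states: np.ndarray, noise: float) -> np.ndarray:
    u = rng.uniform(0.0, noise, states.size)
    return np.where(states == 1, 1.0 - u, u)


def _sample_letters(
    rng: np.random.Generator,
    states: np.ndarray,
    bias: dict[str, float] | None,
) -> np.ndarray:
    base = np.array([AA_BACKGROUND[aa] for aa in _LETTERS])
    base = base / base.sum()
    letters = np.empty(states.size, dtype="<U1")
    if bias is None:
        letters[:] = rng.choice(_LETTERS, size=states.size, p=base)
        return letters
    mult = np.array([bias.get(aa, 1.0) for aa in _LETTERS])
    dis = base * mult
    dis = dis / dis.sum()
    n_dis = int(states.sum())
    letters[states == 1] = rng.choice(_LETTERS, size=n_dis, p=dis)
    letters[states == 0] = rng.choice(_LETTERS, size=states.size - n_dis, p=base)
    return letters


def generate_proteome(
    config: GeneratorConfig,
    organism_id: str = "synthetic",
    include_sequences: bool = True,
) -> tuple[list[ProteinSequence], list[DisorderTrack]]:
    """Generate one synthetic proteome (sequences and disorder tracks).

    Tracks carry the true binary states plus noisy scores.  With
    ``include_sequences=False`` the sequence list is empty (tracks alone
    feed the disorder metrics; skipping letters is much faster for
    simulation studies).
    """
    rng = np.random.default_rng(config.seed)
    lengths = _draw_lengths(rng, config)
    if config.target_pct_long30 is not None:
        p_enter = _calibrated_entry(
            config.target_pct_long30,
            config.p_stay_disordered,
            config.length_mean,
            config.length_sd,
            config.min_length,
        )
    else:
        p_enter = 1.0 - config.p_stay_ordered
    p_leave = 1.0 - config.p_stay_disordered

    chain = _sample_state_chain(rng, int(lengths.sum()), p_enter, p_leave)
    scores = _scores_from_states(rng, chain, config.score_noise)
    bounds = np.concatenate(([0], np.cumsum(lengths)))
    letters = _sample_letters(rng, chain, config.composition_bias) if include_sequences else None

    sequences: list[ProteinSequence] = []
    tracks: list[DisorderTrack] = []
    for i in range(config.n_proteins):
        lo, hi = bounds[i], bounds[i + 1]
        protein_id = f"{organism_id}_p{i + 1:05d}"
        tracks.append(
            DisorderTrack(protein_id, config.predictor, scores[lo:hi], chain[lo:hi])
        )
        if letters is not None:
            sequences.append(ProteinSequence(protein_id, "".join(letters[lo:hi])))
    return sequences, tracks


# ---------------------------------------------------------------------------
# habitat panels


@dataclass
class HabitatPanel:
    """A labelled multi-organism panel ready for the grouped statistics."""

    organisms: list[OrganismRecord]
    tracks: dict[str, list[DisorderTrack]]
    sequences: dict[str, list[ProteinSequence]]
    targets: dict[str, float]


#: Representative growth metadata per habitat label, used so panel
#: organisms round-trip through classify_habitat consistently.
_PANEL_GROWTH = {
    "halophile": GrowthMetadata(opt_temp_c=37.0, nacl_opt_pct=27.0),
    "thermophile": GrowthMetadata(opt_temp_c=60.0),
    "hyperthermophile": GrowthMetadata(opt_temp_c=95.0),
    "psychrophile": GrowthMetadata(opt_temp_c=15.0, max_temp_c=19.0, min_temp_c=-1.0),
    "psychrotolerant": GrowthMetadata(opt_temp_c=25.0, min_temp_c=1.0),
    "alkaliphile": GrowthMetadata(opt_temp_c=37.0, ph_opt=9.5),
    "mesophile": GrowthMetadata(opt_temp_c=37.0),
}


def generate_habitat_panel(
    config: GeneratorConfig,
    groups: Sequence[tuple[str, int, float]],
    background: BackgroundStats = DEFAULT_BACKGROUNDS[("md", "long30")],
    include_sequences: bool = False,
) -> HabitatPanel:
    """Generate a panel of organisms with additive group effects on %long30.

    ``groups`` is a list of ``(label, n_organisms, effect)``; every
    organism of a group targets ``baseline + effect * background.sd``
    percent long30, where the baseline is ``config.target_pct_long30``
    or, when unset, the background mean.  Labels that match a habitat
    class get consistent growth metadata; other labels are attached as-is.
    """
    if len(groups) < 2:
        raise ValueError("a habitat panel needs >= 2 groups")
    for label, n_orgs, _ in groups:
        if n_orgs < 1:
            raise ValueError(f"group {label!r} must have >= 1 organism")
    baseline = (
        config.target_pct_long30 if config.target_pct_long30 is not None else background.mean
    )
    seeds = np.random.SeedSequence(config.seed).generate_state(sum(n for _, n, _ in groups))

    organisms: list[OrganismRecord] = []
    tracks: dict[str, list[DisorderTrack]] = {}
    sequences: dict[str, list[ProteinSequence]] = {}
    targets: dict[str, float] = {}
    idx = 0
    for label, n_orgs, effect in groups:
        target = float(np.clip(baseline + effect * background.sd, 0.0, 100.0))
        for j in range(n_orgs):
            organism_id = f"{label}_{j + 1:02d}"
            org_config = replace(
                config,
                seed=int(seeds[idx] % (2**31)),
                target_pct_long30=target,
            )
            seqs, trks = generate_proteome(org_config, organism_id, include_sequences)
            organisms.append(
                OrganismRecord(
                    organism_id=organism_id,
                    phylum=f"phylum_{label}",
                    growth=_PANEL_GROWTH.get(label),
                    habitat_class=label,
                )
            )
            tracks[organism_id] = trks
            sequences[organism_id] = seqs
            targets[organism_id] = target
            idx += 1
    return HabitatPanel(organisms, tracks, sequences, targets)


# ---------------------------------------------------------------------------
# homolog pairs

DisorderPattern = Literal["a_only", "b_only", "both", "neither"]


@dataclass
class HomologPairSet:
    sequences_a: list[ProteinSequence]
    tracks_a: list[DisorderTrack]
    sequences_b: list[ProteinSequence]
    tracks_b: list[DisorderTrack]
    alignments: list[AlignmentRecord]


def _place_disorder(
    rng: np.random.Generator, length: int, run_len: int, disordered: bool
) -> np.ndarray:
    states = np.zeros(length, dtype=np.int8)
    if disordered:
        start = int(rng.integers(0, length - run_len + 1))
        states[start : start + run_len] = 1
    return states


def generate_homolog_pairs(
    config: GeneratorConfig,
    n_pairs: int,
    pide_target: float,
    aligned_length: int,
    disordered_in: DisorderPattern = "a_only",
    disorder_run_len: int = 40,
    n_unrelated_a: int = 0,
    n_unrelated_b: int = 0,
    org_a: str = "A",
    org_b: str = "B",
) -> HomologPairSet:
    """Two proteomes of homolog pairs at a controlled percent identity.

    Each pair is built by copy-with-substitution: protein B is protein A
    with ``round(L * (1 - pide/100))`` positions substituted to a
    different letter, so the realised identity matches the target within
    a point; the emitted alignment records carry the realised identity.
    Long disorder (one run of ``disorder_run_len`` residues) is placed on
    the sides named by ``disordered_in``.  Optional unrelated (fully
    ordered, unaligned) proteins pad either proteome.
    """
    if not (0.0 < pide_target <= 100.0):
        raise ValueError("pide_target must be in (0, 100]")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    needs_disorder = disordered_in in ("a_only", "b_only", "both")
    if disorder_run_len < 30:
        raise ValueError("disorder_run_len must be >= 30 to constitute long disorder")
    if needs_disorder and aligned_length < disorder_run_len:
        raise ValueError(
            f"aligned_length {aligned_length} too short to place a {disorder_run_len}-residue "
            "disordered run"
        )
    rng = np.random.default_rng(config.seed)
    base = np.array([AA_BACKGROUND[aa] for aa in _LETTERS])
    base = base / base.sum()

    n_sub = int(round(aligned_length * (1.0 - pide_target / 100.0)))
    realized_pide = 100.0 * (aligned_length - n_sub) / aligned_length

    seqs_a, tracks_a, seqs_b, tracks_b, alignments = [], [], [], [], []
    for i in range(n_pairs):
        letters_a = rng.choice(_LETTERS, size=aligned_length, p=base)
        letters_b = letters_a.copy()
        if n_sub:
            positions = rng.choice(aligned_length, size=n_sub, replace=False)
            for pos in positions:
                choices = _LETTERS[_LETTERS != letters_b[pos]]
                letters_b[pos] = rng.choice(choices)
        id_a, id_b = f"{org_a}_h{i + 1:04d}", f"{org_b}_h{i + 1:04d}"
        states_a = _place_disorder(
            rng, aligned_length, disorder_run_len, disordered_in in ("a_only", "both")
        )
        states_b = _place_disorder(
            rng, aligned_length, disorder_run_len, disordered_in in ("b_only", "both")
        )
        seqs_a.append(ProteinSequence(id_a, "".join(letters_a)))
        seqs_b.append(ProteinSequence(id_b, "".join(letters_b)))
        tracks_a.append(
            DisorderTrack(id_a, config.predictor, _scores_from_states(rng, states_a, config.score_noise), states_a)
        )
        tracks_b.append(
            DisorderTrack(id_b, config.predictor, _scores_from_states(rng, states_b, config.score_noise), states_b)
        )
        alignments.append(
            AlignmentRecord(id_a, id_b, realized_pide, aligned_length)
        )

    for org, count, seqs, trks in (
        (org_a, n_unrelated_a, seqs_a, tracks_a),
        (org_b, n_unrelated_b, seqs_b, tracks_b),
    ):
        for i in range(count):
            letters = rng.choice(_LETTERS, size=aligned_length, p=base)
            protein_id = f"{org}_u{i + 1:04d}"
            states = np.zeros(aligned_length, dtype=np.int8)
            seqs.append(ProteinSequence(protein_id, "".join(letters)))
            trks.append(
                DisorderTrack(
                    protein_id,
                    config.predictor,
                    _scores_from_states(rng, states, config.score_noise),
                    states,
                )
            )
    return HomologPairSet(seqs_a, tracks_a, seqs_b, tracks_b, alignments)
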