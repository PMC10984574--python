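"""Synthetic ASRT behaviour and coupled multichannel oscillatory recordings.

Ground-truth generators for every downstream stage: alternating-sequence
stimulus streams, a parametric responder with a planted statistical-learning
advantage on high-probability trials, planted connectivity graphs, and
band-limited phase-lagged multichannel signals whose imaginary coherency is
nonzero on planted edges only.

All randomness flows from a single integer seed through documented
``numpy.random.SeedSequence`` splits (sequence, responses, network, signal).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .behavior import StimulusStream, categorize_triplets
from .graphs import ring_lattice_adjacency, random_gnm_adjacency

logger = logging.getLogger(__name__)

__all__ = [
    "AsrtDesign",
    "SubjectParams",
    "PlantedNetwork",
    "SyntheticRecording",
    "GroupSpec",
    "SimulationConfig",
    "generate_asrt_sequence",
    "simulate_responses",
    "generate_planted_network",
    "synthesize_coupled_recording",
    "make_cohort",
    "default_channel_labels",
]

# 60-channel equidistant montage labels (10% system subset)
_MONTAGE_60 = [
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "O2",
]


def default_channel_labels(n_channels: int) -> list[str]:
    if n_channels <= len(_MONTAGE_60):
        return _MONTAGE_60[:n_channels]
    return _MONTAGE_60 + [f"EX{i:02d}" for i in range(n_channels - len(_MONTAGE_60))]


@dataclass(frozen=True)
class AsrtDesign:
    """Structure and timing of the cued ASRT task.

    Each block holds five random practice trials followed by ten
    repetitions of the eight-element alternating sequence (pattern trial,
    random trial, ...), i.e. 85 trials. Stimuli are fixed-paced: 200 ms
    stimulus, a response window of 500 ms, then a 700 ms fixed delay.
    """

    pattern: tuple[int, int, int, int] = (1, 2, 3, 4)
    n_blocks: int = 20
    trials_per_block: int = 85
    practice_trials: int = 5
    sequence_repeats: int = 10
    stimulus_ms: int = 200
    response_window_ms: int = 500
    fixed_delay_ms: int = 700

    def __post_init__(self) -> None:
        if sorted(self.pattern) != [1, 2, 3, 4]:
            raise ValueError(
                f"pattern must be a permutation of (1, 2, 3, 4), got {self.pattern}"
            )
        if self.trials_per_block != self.practice_trials + 8 * self.sequence_repeats:
            raise ValueError(
                "trials_per_block must equal practice_trials + 8 * sequence_repeats"
            )


@dataclass(frozen=True)
class SubjectParams:
    """Parametric responder for one simulated participant.

    ``acc_learning_pp`` is the planted asymptotic accuracy advantage
    (percentage points) on high-probability trials; ``rt_learning_ms`` the
    analogous RT advantage. ``learning_ramp`` is the fraction of the
    asymptote reached per block (1.0 = full effect from the first block).
    Defaults describe a near-ceiling responder typical of the cued task
    variant, where learning is expressed in the 1-2 pp range.
    """

    base_accuracy: float = 0.97
    base_rt_ms: float = 350.0
    acc_learning_pp: float = 2.0
    rt_learning_ms: float = 15.0
    learning_ramp: float = 1.0
    lapse_rate: float = 0.02
    rt_noise_sd_ms: float = 60.0
    group: str = "GTS"
    medicated: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_accuracy <= 1.0:
            raise ValueError("base_accuracy must be in [0, 1]")
        if self.lapse_rate < 0:
            raise ValueError("lapse_rate must be >= 0")
        if self.base_rt_ms <= 0:
            raise ValueError("base_rt_ms must be positive")


@dataclass
class PlantedNetwork:
    """Ground-truth coupling graph realized by the signal generator."""

    adjacency: np.ndarray
    lag_ms: float = 20.0
    band: tuple[float, float] = (4.0, 7.0)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if not np.array_equal(a, a.T) or np.any(np.diag(a) != 0):
            raise ValueError("adjacency must be symmetric with a zero diagonal")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def density(self) -> float:
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2)


@dataclass
class SyntheticRecording:
    """Multichannel recording with event markers.

    ``samples`` is channels x time in arbitrary microvolt-scale units;
    ``events`` is an ordered list of ``(sample_index, code)`` pairs.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    events: list[tuple[int, str]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        idx = [s for s, _ in self.events]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("event sample indices must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


# ---------------------------------------------------------------------------
# Behaviour


def generate_asrt_sequence(design: AsrtDesign, seed=None) -> StimulusStream:
    """Generate the cued ASRT stimulus stream for one participant.

    Each block starts with five random practice trials, then pattern and
    random trials alternate; pattern trial k of a block (cued black) shows
    ``pattern[k % 4]``, random trials (cued red) are drawn uniformly from
    the four directions. Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    seq_trials = 8 * design.sequence_repeats
    blocks, positions, directions, classes = [], [], [], []
    for b in range(1, design.n_blocks + 1):
        practice = rng.integers(1, 5, size=design.practice_trials)
        dirs = np.empty(design.trials_per_block, dtype=int)
        cls = np.empty(design.trials_per_block, dtype=object)
        dirs[: design.practice_trials] = practice
        cls[: design.practice_trials] = "random"
        pat_idx = 0
        for i in range(seq_trials):
            pos = design.practice_trials + i
            if i % 2 == 0:
                dirs[pos] = design.pattern[pat_idx % 4]
                cls[pos] = "pattern"
                pat_idx += 1
            else:
                dirs[pos] = rng.integers(1, 5)
                cls[pos] = "random"
        blocks.append(np.full(design.trials_per_block, b))
        positions.append(np.arange(1, design.trials_per_block + 1))
        directions.append(dirs)
        classes.append(cls)
    trials = pd.DataFrame(
        {
            "block": np.concatenate(blocks),
            "position_in_block": np.concatenate(positions),
            "direction": np.concatenate(directions),
            "trial_class": np.concatenate(classes),
        }
    )
    return StimulusStream(trials=trials, pattern=tuple(design.pattern))


def simulate_responses(
    stream: StimulusStream,
    params: SubjectParams,
    seed=None,
    response_window_ms: float = 500.0,
) -> pd.DataFrame:
    """Simulate responses with a planted high-probability advantage.

    The trial's true triplet probability is computed with the same
    categorizer the analysis uses, so the planted advantage applies to
    high-probability trials of both structures. Correctness is Bernoulli
    with probability ``base_accuracy + ramp * acc_learning_pp/100`` on
    high-probability trials; RT is Gaussian around
    ``base_rt_ms - ramp * rt_learning_ms`` on those trials. Responses
    later than the response window are converted to unresponded trials,
    mirroring the task's 500 ms deadline; lapses occur at ``lapse_rate``.
    """
    if len(stream) == 0:
        raise ValueError("stream must be nonempty")
    rng = np.random.default_rng(seed)
    trials = stream.trials
    labels = categorize_triplets(stream)
    is_high = (labels["probability"].to_numpy() == "high").astype(float)
    block = trials["block"].to_numpy()
    ramp = np.minimum(1.0, params.learning_ramp * block)

    p_correct = params.base_accuracy + ramp * is_high * params.acc_learning_pp / 100.0
    if (p_correct > 1).any() or (p_correct < 0).any():
        warnings.warn(
            "per-trial correctness probabilities clipped to [0, 1]", stacklevel=2
        )
        p_correct = np.clip(p_correct, 0.0, 1.0)

    n = len(trials)
    responded = rng.random(n) >= params.lapse_rate
    correct = rng.random(n) < p_correct
    rt = (
        params.base_rt_ms
        - ramp * is_high * params.rt_learning_ms
        + rng.normal(0.0, params.rt_noise_sd_ms, size=n)
    )
    late = rt >= response_window_ms
    responded &= ~late
    rt = np.clip(rt, 1.0, None)

    out = trials.copy()
    out["responded"] = responded.astype(int)
    out["correct"] = (correct & responded).astype(int)
    out["rt_ms"] = np.where(responded, rt, np.nan)
    return out


# ---------------------------------------------------------------------------
# Networks and signals


def _round_half_even(x: float) -> int:
    return int(round(x))


def generate_planted_network(
    topology: str,
    n_nodes: int = 60,
    density: float = 0.15,
    rewire_p: float = 0.1,
    seed=None,
    lag_ms: float = 20.0,
    band: tuple[float, float] = (4.0, 7.0),
    custom_adjacency: np.ndarray | None = None,
) -> PlantedNetwork:
    """Planted coupling graph of one of the reference topologies.

    The edge count is ``round(density * n(n-1)/2)`` (round-half-even).
    ``ring_lattice`` connects nearest neighbours symmetrically;
    ``watts_strogatz`` rewires each lattice edge with probability
    ``rewire_p`` (edge count preserved); ``erdos_renyi`` places the edges
    uniformly at random; ``custom`` uses ``custom_adjacency`` as is.
    """
    if n_nodes < 4:
        raise ValueError("n_nodes must be >= 4")
    if topology == "custom":
        if custom_adjacency is None:
            raise ValueError("custom topology requires custom_adjacency")
        return PlantedNetwork(custom_adjacency, lag_ms=lag_ms, band=band)
    if not 0.0 < density < 1.0:
        raise ValueError("density must be in (0, 1)")
    rng = np.random.default_rng(seed)
    m = _round_half_even(density * n_nodes * (n_nodes - 1) / 2)
    if 2 * m / n_nodes < 2:
        warnings.warn("mean degree < 2: disconnection likely", stacklevel=2)
    if topology == "ring_lattice":
        adj = ring_lattice_adjacency(n_nodes, m, rng)
    elif topology == "watts_strogatz":
        adj = ring_lattice_adjacency(n_nodes, m, rng)
        adj = _rewire(adj, rewire_p, rng)
    elif topology == "erdos_renyi":
        adj = random_gnm_adjacency(n_nodes, m, rng)
    else:
        raise ValueError(f"unknown topology: {topology!r}")
    return PlantedNetwork(adj, lag_ms=lag_ms, band=band)


def _rewire(adj: np.ndarray, rewire_p: float, rng: np.random.Generator) -> np.ndarray:
    """Watts-Strogatz-style rewiring preserving the edge count."""
    adj = adj.copy()
    n = adj.shape[0]
    edges = np.argwhere(np.triu(adj, k=1) == 1)
    for i, j in edges:
        if rng.random() >= rewire_p:
            continue
        candidates = np.flatnonzero(adj[i] == 0)
        candidates = candidates[candidates != i]
        if len(candidates) == 0:
            continue
        k = rng.choice(candidates)
        adj[i, j] = adj[j, i] = 0
        adj[i, k] = adj[k, i] = 1
    return adj


def _bandlimited_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band`` (Hz)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spec[~mask] = 0.0
    sig = np.fft.irfft(spec, n=n)
    sd = sig.std()
    return sig / sd if sd > 0 else sig


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int], fs: float) -> np.ndarray:
    """Unit-variance 1/f (pink) noise per row."""
    n = shape[1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    spec *= scale
    sig = np.fft.irfft(spec, n=n, axis=1)
    sig /= sig.std(axis=1, keepdims=True)
    return sig


def synthesize_coupled_recording(
    planted: PlantedNetwork,
    n_segments: int = 60,
    segment_ms: float = 2000.0,
    fs: float = 500.0,
    snr: float = 1.0,
    seed=None,
    channel_labels: list[str] | None = None,
    event_code: str = "R0",
    event_offset_ms: float = 0.0,
    coupling_gain: float | str = "balanced",
) -> SyntheticRecording:
    """Multichannel signal whose planted edges carry lagged shared sources.

    Each node emits a band-limited source; for every planted edge one
    endpoint (chosen at random per edge) additionally receives the other
    endpoint's source delayed by ``lag_ms``, so only planted pairs acquire
    a consistent nonzero-lag coupling and hence nonzero imaginary
    coherency. Channels with common driving sources at identical lags add
    only zero-lag (real) coherence, which the imaginary part ignores by
    design. Independent 1/f noise is added per channel at power
    ``signal_power / snr**2``. Segments are statistically independent and
    an event marker is placed in each (at ``event_offset_ms`` past the
    segment start).

    ``coupling_gain`` scales the delayed copies. The default "balanced"
    gain, ``1/sqrt(mean in-degree)``, makes the total coupled power a
    channel receives comparable to its intrinsic source power, so each
    planted edge retains an identifiable share of its receiver's signal
    even in dense graphs.
    """
    if planted.lag_ms == 0:
        raise ValueError("lag_ms must be nonzero (zero lag has no imaginary coherency)")
    if not 0 < planted.band[0] < planted.band[1] < fs / 2:
        raise ValueError("band must lie within (0, fs/2)")
    rng = np.random.default_rng(seed)
    n_ch = planted.n_nodes
    seg_len = int(round(segment_ms / 1000.0 * fs))
    lag = int(round(planted.lag_ms / 1000.0 * fs))
    pad = max(abs(lag), 8)

    # random transmission direction per undirected edge
    edges = np.argwhere(np.triu(planted.adjacency, k=1) == 1)
    senders, receivers = [], []
    for i, j in edges:
        if rng.random() < 0.5:
            senders.append(i); receivers.append(j)
        else:
            senders.append(j); receivers.append(i)
    senders = np.asarray(senders, dtype=int)
    receivers = np.asarray(receivers, dtype=int)
    in_deg = np.bincount(receivers, minlength=n_ch) if len(receivers) else np.zeros(n_ch, int)
    if coupling_gain == "balanced":
        mean_in = max(1.0, planted.n_edges / n_ch)
        gain = 1.0 / np.sqrt(mean_in)
    else:
        gain = float(coupling_gain)

    data = np.empty((n_ch, n_segments * seg_len), dtype=float)
    events = []
    for s in range(n_segments):
        src = np.empty((n_ch, seg_len + pad))
        for ch in range(n_ch):
            src[ch] = _bandlimited_noise(rng, seg_len + pad, fs, planted.band)
        seg = src[:, pad:].copy()
        if lag >= 0:
            delayed = src[:, pad - lag : pad - lag + seg_len]
        else:
            delayed = src[:, pad - lag :][:, :seg_len]
        np.add.at(seg, receivers, gain * delayed[senders])
        sig_power = 1.0 + gain**2 * in_deg.astype(float)
        if np.isfinite(snr):
            noise = _pink_noise(rng, (n_ch, seg_len), fs)
            seg = seg + noise * (np.sqrt(sig_power) / snr)[:, None]
        data[:, s * seg_len : (s + 1) * seg_len] = seg
        events.append((s * seg_len + int(round(event_offset_ms / 1000.0 * fs)), event_code))

    if channel_labels is None:
        channel_labels = default_channel_labels(n_ch)
    prov = {
        "seed": seed if seed is None or isinstance(seed, int) else "derived",
        "n_segments": n_segments,
        "segment_ms": segment_ms,
        "snr": snr,
        "lag_ms": planted.lag_ms,
        "band": list(planted.band),
    }
    return SyntheticRecording(
        samples=data,
        fs=fs,
        channel_labels=channel_labels,
        events=events,
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# Cohort


@dataclass(frozen=True)
class GroupSpec:
    """Per-group distributions of subject parameters and network topology."""

    name: str = "GTS"
    n_subjects: int = 25
    acc_learning_pp_mean: float = 2.0
    acc_learning_pp_sd: float = 0.3
    rt_learning_ms_mean: float = 15.0
    rt_learning_ms_sd: float = 5.0
    base_accuracy_mean: float = 0.97
    base_accuracy_sd: float = 0.005
    base_rt_ms_mean: float = 350.0
    base_rt_ms_sd: float = 30.0
    lapse_rate: float = 0.02
    rt_noise_sd_ms: float = 60.0
    learning_ramp: float = 1.0
    n_medicated: int = 0
    topology: str = "watts_strogatz"
    rewire_p: float = 0.1


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level configuration of the synthetic cohort.

    Defaults emulate the study conditions: 25 participants per group,
    a 20-block cued ASRT task, 60-channel 500 Hz recordings, 60 resting
    segments of 2000 ms per run (120 s), theta-band coupling with a 20 ms
    lag at snr 1, and 15 percent planted edge density. The patient-like
    group carries a larger planted learning effect and a more lattice-like
    planted topology (lower rewiring probability).
    """

    design: AsrtDesign = field(default_factory=AsrtDesign)
    gts: GroupSpec = field(
        default_factory=lambda: GroupSpec(
            name="GTS", acc_learning_pp_mean=2.0, n_medicated=13, rewire_p=0.1
        )
    )
    hc: GroupSpec = field(
        default_factory=lambda: GroupSpec(
            name="HC", acc_learning_pp_mean=0.7, rt_learning_ms_mean=8.0,
            n_medicated=0, rewire_p=0.3
        )
    )
    n_channels: int = 60
    fs: float = 500.0
    resting_segments: int = 60
    segment_ms: float = 2000.0
    density: float = 0.15
    lag_ms: float = 20.0
    band: tuple[float, float] = (4.0, 7.0)
    snr: float = 1.0
    include_eeg: bool = True
    include_task_eeg: bool = False
    seed: int = 0

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class CohortBundle:
    """Simulated cohort: trial records, subject metadata and recordings."""

    behavior: pd.DataFrame
    subjects: pd.DataFrame
    recordings: dict
    planted: dict
    config: SimulationConfig


def _draw_params(spec: GroupSpec, rng: np.random.Generator, medicated: bool) -> SubjectParams:
    return SubjectParams(
        base_accuracy=float(np.clip(rng.normal(spec.base_accuracy_mean, spec.base_accuracy_sd), 0.5, 1.0)),
        base_rt_ms=float(max(50.0, rng.normal(spec.base_rt_ms_mean, spec.base_rt_ms_sd))),
        acc_learning_pp=float(rng.normal(spec.acc_learning_pp_mean, spec.acc_learning_pp_sd)),
        rt_learning_ms=float(rng.normal(spec.rt_learning_ms_mean, spec.rt_learning_ms_sd)),
        learning_ramp=spec.learning_ramp,
        lapse_rate=spec.lapse_rate,
        rt_noise_sd_ms=spec.rt_noise_sd_ms,
        group=spec.name,
        medicated=medicated,
    )


def make_cohort(config: SimulationConfig, out_dir=None) -> CohortBundle:
    """Simulate the full two-group cohort.

    Per subject: an independent stimulus stream, simulated responses, and
    (if ``include_eeg``) pre- and post-task resting recordings realizing
    the group's planted topology. Subjects are matched pairwise across
    groups (GTS subject i <-> HC subject i) for the medication-sensitivity
    rerun. Reproducible under a fixed seed; if ``out_dir`` is given the
    behavioural table and subject metadata are written as CSV and
    recordings in the raw+sidecar format.
    """
    root = np.random.SeedSequence(config.seed)
    behav_frames, subject_rows = [], []
    recordings: dict[str, dict] = {}
    planted: dict[str, PlantedNetwork] = {}

    groups = [config.gts, config.hc]
    for g_idx, spec in enumerate(groups):
        for s_idx in range(spec.n_subjects):
            sid = f"{spec.name}{s_idx + 1:02d}"
            seq_seed, resp_seed, net_seed, sig_seed = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(g_idx, s_idx)
            ).spawn(4)
            param_rng = np.random.default_rng(resp_seed.spawn(1)[0])
            medicated = s_idx < spec.n_medicated
            params = _draw_params(spec, param_rng, medicated)
            stream = generate_asrt_sequence(config.design, seed=seq_seed)
            records = simulate_responses(
                stream, params, seed=resp_seed,
                response_window_ms=config.design.response_window_ms,
            )
            records.insert(0, "subject", sid)
            records.insert(1, "group", spec.name)
            records.insert(2, "medicated", int(medicated))
            behav_frames.append(records)
            subject_rows.append(
                {
                    "subject": sid,
                    "group": spec.name,
                    "medicated": int(medicated),
                    "matched_to": f"{groups[1 - g_idx].name}{s_idx + 1:02d}",
                    "pattern": "".join(map(str, stream.pattern)),
                    **{f"param_{k}": v for k, v in asdict(params).items()
                       if k not in ("group", "medicated")},
                }
            )
            if config.include_eeg:
                net = generate_planted_network(
                    spec.topology,
                    n_nodes=config.n_channels,
                    density=config.density,
                    rewire_p=spec.rewire_p,
                    seed=net_seed,
                    lag_ms=config.lag_ms,
                    band=config.band,
                )
                planted[sid] = net
                rest_seeds = sig_seed.spawn(2)
                recordings[sid] = {
                    cond: synthesize_coupled_recording(
                        net,
                        n_segments=config.resting_segments,
                        segment_ms=config.segment_ms,
                        fs=config.fs,
                        snr=config.snr,
                        seed=rest_seeds[k],
                        channel_labels=default_channel_labels(config.n_channels),
                    )
                    for k, cond in enumerate(("rest_pre", "rest_post"))
                }
                if config.include_task_eeg:
                    recordings[sid]["task"] = _task_recording(
                        net, records, config, sig_seed.spawn(3)[2]
                    )

    behavior = pd.concat(behav_frames, ignore_index=True)
    subjects = pd.DataFrame(subject_rows)
    bundle = CohortBundle(
        behavior=behavior,
        subjects=subjects,
        recordings=recordings,
        planted=planted,
        config=config,
    )
    if out_dir is not None:
        _write_cohort(bundle, out_dir)
    return bundle


def _task_recording(
    net: PlantedNetwork, records: pd.DataFrame, config: SimulationConfig, seed
) -> SyntheticRecording:
    """Stimulus-locked task recording: one 1500 ms segment per trial.

    The stimulus event sits 500 ms into its segment so that the
    -500..1000 ms analysis epoch spans the segment exactly. Event codes:
    S1 high-probability random, S2 low-probability random, S3 pattern.
    """
    rec = synthesize_coupled_recording(
        net,
        n_segments=len(records),
        segment_ms=1500.0,
        fs=config.fs,
        snr=config.snr,
        seed=seed,
        channel_labels=default_channel_labels(config.n_channels),
        event_code="S3",
        event_offset_ms=500.0,
    )
    labels = categorize_triplets(
        StimulusStream(
            trials=records[
                ["block", "position_in_block", "direction", "trial_class"]
            ].reset_index(drop=True),
            pattern=_infer_pattern(records),
        )
    )
    codes = []
    for struct, prob in zip(records["trial_class"], labels["probability"]):
        if struct == "pattern":
            codes.append("S3")
        elif prob == "high":
            codes.append("S1")
        else:
            codes.append("S2")
    rec.events = [(s, c) for (s, _), c in zip(rec.events, codes)]
    return rec


def _infer_pattern(records: pd.DataFrame) -> tuple[int, int, int, int]:
    pat = records.loc[records["trial_class"] == "pattern", "direction"].to_numpy()[:4]
    return tuple(int(x) for x in pat)


def _write_cohort(bundle: CohortBundle, out_dir) -> None:
    from pathlib import Path
    from .io import write_raw_sidecar

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cols = [
        "subject", "group", "medicated", "block", "position_in_block",
        "direction", "trial_class", "responded", "correct", "rt_ms",
    ]
    df = bundle.behavior[cols].rename(columns={"position_in_block": "trial"})
    df.to_csv(out / "behavior.csv", index=False)
    bundle.subjects.to_csv(out / "subjects.csv", index=False)
    for sid, recs in bundle.recordings.items():
        for cond, rec in recs.items():
            write_raw_sidecar(rec, out / f"{sid}_{cond}")
    logger.info("cohort written to %s (config hash %s)", out, bundle.config.hash())
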