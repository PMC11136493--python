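"""Synthetic MEG-like data with known ground truth.

Generates multi-sensor trial epochs at 100 Hz that emulate the structure of a
sensor-level MEG experiment: a localizer session (repeated isolated stimulus
presentations, epoched -0.1..0.5 s) and a retrieval session (cued-recall
trials, epoched 0..1.5 s).  Each of the 10 stimuli has a fixed random spatial
pattern across sensors; trials are that pattern riding on temporally
autocorrelated Gaussian sensor noise.  Retrieval epochs can optionally carry

* ``sequential`` replay: successive item patterns along the forward graph path,
  separated by a configurable state-to-state lag, each convolved with a brief
  half-sine response kernel; or
* ``clustered`` reactivation: all off-screen item patterns injected
  simultaneously, with amplitude graded by directed graph distance.

Every injected event is logged, so recovery can always be tested against
ground truth.  All randomness derives from a single master seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .task_graph import GraphTask, enumerate_triplets, select_distractors

__all__ = [
    "TrialArray",
    "SimulationConfig",
    "ParticipantData",
    "make_stimulus_patterns",
    "generate_localizer_sequence",
    "generate_localizer_trials",
    "generate_retrieval_trials",
    "inject_sequential_replay",
    "inject_clustered_reactivation",
    "simulate_behavior",
    "draw_participant_profiles",
    "simulate_cohort",
]

DT = 0.01  # 100 Hz sampling
LOCALIZER_TIMES = np.round(np.arange(-10, 50) * DT, 10)   # -0.1 .. 0.49 s
RETRIEVAL_TIMES = np.round(np.arange(0, 150) * DT, 10)    # 0 .. 1.49 s


@dataclass
class TrialArray:
    """Epoched multi-sensor time series with per-trial metadata.

    data : (n_trials, n_sensors, n_times) float array, arbitrary units
    times : sample times in seconds relative to epoch onset (step 0.01 s)
    meta : one row per trial (``stimulus`` for localizer epochs;
        ``predecessor, current, successor, chosen, correct, block, phase``
        for learning/retrieval epochs)
    """

    data: np.ndarray
    times: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be trial x sensor x time")
        if self.data.shape[2] != len(self.times):
            raise ValueError("time axis mismatch")
        if self.data.shape[0] != len(self.meta):
            raise ValueError("meta length mismatch")
        steps = np.diff(self.times)
        if len(steps) and not np.allclose(steps, DT, atol=1e-9):
            raise ValueError("sampling step must be exactly 0.01 s")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    def time_index(self, t: float) -> int:
        idx = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[idx] - t) > 1e-6:
            raise ValueError(f"time {t} is not on the sample grid")
        return idx

    def select(self, mask) -> "TrialArray":
        mask = np.asarray(mask)
        return TrialArray(self.data[mask], self.times,
                          self.meta.iloc[mask].reset_index(drop=True))

    # -- HDF5 round trip ---------------------------------------------------
    def to_hdf5(self, h5group) -> None:
        h5group.create_dataset("data", data=self.data)
        h5group.create_dataset("times", data=self.times)
        meta = h5group.create_group("meta")
        for col in self.meta.columns:
            vals = self.meta[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S")
            meta.create_dataset(col, data=vals)
        meta.attrs["columns"] = list(self.meta.columns)

    @classmethod
    def from_hdf5(cls, h5group) -> "TrialArray":
        cols = list(h5group["meta"].attrs["columns"])
        meta = {}
        for col in cols:
            vals = h5group["meta"][col][()]
            if vals.dtype.kind == "S":
                vals = vals.astype(str)
            meta[col] = vals
        return cls(h5group["data"][()], h5group["times"][()], pd.DataFrame(meta))


@dataclass
class SimulationConfig:
    """Study-level parameters of the synthetic cohort.

    Defaults mirror the emulated experiment: 306 sensors, 10 stimulus classes,
    two localizer runs of 25 repetitions per item, 100 Hz epochs, and a
    21-participant cohort.
    """

    n_participants: int = 21
    n_sensors: int = 306
    n_states: int = 10
    localizer_reps: int = 25          # repetitions per item per run
    localizer_runs: int = 2
    noise_sd: float = 1.0
    noise_ar: float = 0.5             # AR(1) coefficient per 10 ms sample
    pattern_amplitude: float = 3.0    # evoked peak amplitude (SNR control)
    pattern_overlap: float = 0.0
    evoked_latency: float = 0.21      # decodability peak (s after onset)
    evoked_width: float = 0.05        # Gaussian sd of the evoked time course (s)
    kernel_ms: float = 40.0           # half-sine replay response kernel (ms)
    replay_mode: str = "none"         # none | sequential | clustered
    replay_lag_ms: float = 50.0
    replay_amplitude: float = 6.0
    replay_path_length: int = 4
    replay_events_per_trial: int = 3
    replay_onset_jitter: float = 0.0  # per-event onset jitter (s)
    cluster_gradient: tuple = (1.0, 0.8, 0.6, 0.4, 0.2)  # amplitude by distance 1..>=5
    cluster_onset: float = 0.24
    n_retrieval_blocks: int = 1
    n_learning_blocks: int = 0
    learning_amplitude_scale: float = 1.0
    accuracy_range: tuple = (0.6, 1.0)
    coupling: float | None = None     # target corr(accuracy, replay amplitude)
    amplitude_cv: float = 0.25        # sd of per-participant amplitude scale
    seed: int = 0

    def __post_init__(self) -> None:
        self.cluster_gradient = tuple(self.cluster_gradient)
        self.accuracy_range = tuple(self.accuracy_range)

    def validate(self) -> None:
        for name in ("n_participants", "n_sensors", "n_states",
                     "localizer_reps", "localizer_runs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.replay_mode not in ("none", "sequential", "clustered"):
            raise ValueError(f"unknown replay_mode: {self.replay_mode!r}")
        if abs(self.replay_lag_ms / 10.0 - round(self.replay_lag_ms / 10.0)) > 1e-9:
            raise ValueError("replay_lag_ms must be a multiple of 10 ms")
        if any(a < 0 for a in self.cluster_gradient):
            raise ValueError("cluster gradient must be non-negative")
        if not 0 <= self.pattern_overlap < 1:
            raise ValueError("pattern_overlap must be in [0, 1)")


@dataclass
class ParticipantData:
    """One simulated participant: data, behavior and injected ground truth."""

    participant: int
    localizer: TrialArray
    retrieval: TrialArray
    events: pd.DataFrame            # injected ground truth (retrieval phase)
    accuracy: float                 # simulated retrieval accuracy
    replay_amplitude: float         # injected per-participant amplitude
    learning: TrialArray | None = None
    learning_events: pd.DataFrame | None = None
    seed: int = 0


# ---------------------------------------------------------------------------
# patterns and noise
# ---------------------------------------------------------------------------

def make_stimulus_patterns(n_sensors: int, n_states: int,
                           rng: np.random.Generator,
                           overlap: float = 0.0) -> np.ndarray:
    """Random unit-norm spatial pattern per state.

    ``overlap`` in [0, 1) mixes a shared component into every pattern so the
    expected pairwise correlation between patterns is about ``overlap``; 0
    yields random directions that are orthogonal in expectation.
    """
    if n_states < 2:
        raise ValueError("need at least 2 states")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    shared = rng.standard_normal(n_sensors)
    shared /= np.linalg.norm(shared)
    pats = rng.standard_normal((n_states, n_sensors))
    pats /= np.linalg.norm(pats, axis=1, keepdims=True)
    pats = np.sqrt(overlap) * shared + np.sqrt(1 - overlap) * pats
    pats /= np.linalg.norm(pats, axis=1, keepdims=True)
    return pats


def _ar_noise(rng: np.random.Generator, shape: tuple, sd: float, ar: float) -> np.ndarray:
    """AR(1) noise along the last (time) axis with stationary sd ``sd``."""
    white = rng.standard_normal(shape)
    if ar == 0:
        return sd * white
    out = lfilter([1.0], [1.0, -ar], white, axis=-1)
    return sd * np.sqrt(1 - ar ** 2) * out


# ---------------------------------------------------------------------------
# localizer
# ---------------------------------------------------------------------------

def generate_localizer_sequence(n_states: int, n_reps: int,
                                rng: np.random.Generator,
                                max_tries: int = 200) -> np.ndarray:
    """Pseudo-random stimulus order with balanced pairwise transitions.

    Each stimulus occurs exactly ``n_reps`` times, no stimulus repeats
    immediately, and every ordered pair of distinct stimuli occurs as a
    transition a number of times balanced to within +/-1 (a randomized
    near-de-Bruijn construction; an exact split is impossible because
    ``n_states * n_reps - 1`` transitions do not divide evenly over the
    ``n_states * (n_states - 1)`` ordered pairs).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    total = n_states * n_reps
    for _ in range(max_tries):
        counts = np.full(n_states, n_reps)
        trans = np.zeros((n_states, n_states), dtype=int)
        seq = np.empty(total, dtype=int)
        seq[0] = rng.integers(n_states)
        counts[seq[0]] -= 1
        ok = True
        for k in range(1, total):
            prev = seq[k - 1]
            cands = np.flatnonzero(counts > 0)
            cands = cands[cands != prev]
            if len(cands) == 0:
                ok = False
                break
            tmin = trans[prev, cands].min()
            best = cands[trans[prev, cands] == tmin]
            cmax = counts[best].max()
            best = best[counts[best] == cmax]
            nxt = int(best[rng.integers(len(best))])
            seq[k] = nxt
            counts[nxt] -= 1
            trans[prev, nxt] += 1
        if not ok:
            continue
        off = trans[~np.eye(n_states, dtype=bool)]
        if off.max() - off.min() <= 1:
            return seq
    raise RuntimeError("could not balance localizer transitions; increase max_tries")


def _evoked_profile(times: np.ndarray, latency: float, width: float) -> np.ndarray:
    prof = np.exp(-0.5 * ((times - latency) / width) ** 2)
    prof[times < 0] = 0.0
    return prof


def generate_localizer_trials(patterns: np.ndarray, order: Sequence[int],
                              cfg: SimulationConfig,
                              rng: np.random.Generator) -> TrialArray:
    """Noise plus each trial's stimulus pattern on a Gaussian amplitude
    time course peaking at ``cfg.evoked_latency`` (epochs -0.1..0.5 s)."""
    order = np.asarray(order, dtype=int)
    if order.max() >= patterns.shape[0]:
        raise ValueError("order references unknown state")
    times = LOCALIZER_TIMES
    n_trials = len(order)
    data = _ar_noise(rng, (n_trials, cfg.n_sensors, len(times)),
                     cfg.noise_sd, cfg.noise_ar)
    prof = cfg.pattern_amplitude * _evoked_profile(times, cfg.evoked_latency,
                                                   cfg.evoked_width)
    data += patterns[order][:, :, None] * prof[None, None, :]
    meta = pd.DataFrame({"stimulus": order})
    return TrialArray(data, times, meta)


# ---------------------------------------------------------------------------
# injections
# ---------------------------------------------------------------------------

def _half_sine_kernel(kernel_ms: float) -> np.ndarray:
    n = max(1, int(round(kernel_ms / 1000.0 / DT)))
    return np.sin(np.pi * (np.arange(n) + 1) / (n + 1))


def inject_sequential_replay(epoch: np.ndarray, patterns: np.ndarray,
                             path: Sequence[int], lag_ms: float,
                             amplitude: float, jitter: float,
                             rng: np.random.Generator,
                             times: np.ndarray = RETRIEVAL_TIMES,
                             t0: float = 0.3,
                             kernel_ms: float = 40.0):
    """Add successive item patterns at onsets t0 + k*lag (k = 0, 1, ...).

    Each event is the item's spatial pattern times a brief half-sine response
    kernel.  Onsets are jittered by +/- ``jitter`` seconds.  Events extending
    past the epoch end are truncated with a warning.  Returns
    ``(epoch, events)`` where events is a list of (state, onset_s, amplitude).
    """
    if abs(lag_ms / 10.0 - round(lag_ms / 10.0)) > 1e-9:
        raise ValueError("lag_ms must be a multiple of 10 ms")
    kernel = _half_sine_kernel(kernel_ms)
    n_t = epoch.shape[-1]
    events = []
    for k, state in enumerate(path):
        onset = t0 + k * lag_ms / 1000.0
        if jitter > 0:
            onset += rng.uniform(-jitter, jitter)
        i0 = int(round((onset - times[0]) / DT))
        if i0 >= n_t:
            warnings.warn(f"replay event for state {state} at {onset:.3f}s "
                          "falls outside the epoch; truncated")
            continue
        seg = kernel[: n_t - i0]
        if len(seg) < len(kernel):
            warnings.warn(f"replay event for state {state} at {onset:.3f}s "
                          "extends past the epoch end; truncated")
        if amplitude != 0 and len(seg):
            epoch[:, i0:i0 + len(seg)] += amplitude * patterns[state][:, None] * seg[None, :]
        events.append((int(state), float(times[0] + i0 * DT), float(amplitude)))
    return epoch, events


def inject_clustered_reactivation(epoch: np.ndarray, patterns: np.ndarray,
                                  g: GraphTask, predecessor: int, current: int,
                                  distance_amplitudes: Mapping[int, float],
                                  t_onset: float,
                                  rng: np.random.Generator | None = None,
                                  times: np.ndarray = RETRIEVAL_TIMES,
                                  kernel_ms: float = 40.0):
    """Add every off-screen item's pattern simultaneously at ``t_onset``,
    scaled by the amplitude assigned to its directed graph distance from the
    current on-screen item.  Distances missing from the map contribute
    nothing.  Returns ``(epoch, events)``."""
    if any(a < 0 for a in distance_amplitudes.values()):
        raise ValueError("amplitudes must be non-negative")
    if not (times[0] <= t_onset <= times[-1]):
        raise ValueError("t_onset outside epoch")
    kernel = _half_sine_kernel(kernel_ms)
    i0 = int(round((t_onset - times[0]) / DT))
    seg = kernel[: epoch.shape[-1] - i0]
    events = []
    for state in g.node_ids:
        if state in (predecessor, current):
            continue
        amp = float(distance_amplitudes.get(int(g.distance[current, state]), 0.0))
        if amp > 0 and len(seg):
            epoch[:, i0:i0 + len(seg)] += amp * patterns[state][:, None] * seg[None, :]
            events.append((int(state), float(times[0] + i0 * DT), amp))
    return epoch, events


# ---------------------------------------------------------------------------
# retrieval / learning trials
# ---------------------------------------------------------------------------

def _forward_path(g: GraphTask, predecessor: int, current: int, length: int) -> list[int]:
    """Triplet-consistent forward path starting at the current item."""
    path = [current]
    a, b = predecessor, current
    while len(path) < length:
        c = g.triplet_successor[(a, b)]
        path.append(c)
        a, b = b, c
    return path


def generate_retrieval_trials(g: GraphTask, patterns: np.ndarray,
                              cfg: SimulationConfig, rng: np.random.Generator,
                              accuracy: float | None = None,
                              amplitude_scale: float = 1.0,
                              phase: str = "retrieval",
                              n_blocks: int | None = None):
    """Cued-recall epochs (0..1.5 s), 12 trials per block (one per edge).

    Each epoch carries the on-screen current item's evoked pattern at cue
    onset plus, depending on ``cfg.replay_mode``, injected sequential replay
    along the forward path or clustered distance-graded reactivation.  The
    simulated choice is correct with probability ``accuracy``.

    Returns ``(TrialArray, events)`` where events is a ground-truth log with
    columns trial/state/onset/amplitude.
    """
    cfg.validate()
    if accuracy is None:
        accuracy = float(np.mean(cfg.accuracy_range))
    n_blocks = cfg.n_retrieval_blocks if n_blocks is None else n_blocks
    times = RETRIEVAL_TIMES
    triplets = enumerate_triplets(g)
    rows, evrows, epochs = [], [], []
    trial = 0
    grad = {d: cfg.cluster_gradient[min(d, len(cfg.cluster_gradient)) - 1]
            for d in range(1, int(g.distance.max()) + 1)}
    for block in range(n_blocks):
        order = rng.permutation(len(triplets))
        for ti in order:
            pred, cur, suc = triplets[ti]
            epoch = _ar_noise(rng, (cfg.n_sensors, len(times)),
                              cfg.noise_sd, cfg.noise_ar)
            prof = (amplitude_scale * cfg.pattern_amplitude
                    * _evoked_profile(times, cfg.evoked_latency, cfg.evoked_width))
            epoch += patterns[cur][:, None] * prof[None, :]
            amp = amplitude_scale * cfg.replay_amplitude
            if cfg.replay_mode == "sequential":
                path = _forward_path(g, pred, cur, cfg.replay_path_length)
                span = (len(path) - 1) * cfg.replay_lag_ms / 1000.0 + cfg.kernel_ms / 1000.0
                hi = max(times[-1] - span, 0.05)
                for _ in range(cfg.replay_events_per_trial):
                    t0 = float(rng.uniform(0.05, hi))
                    _, events = inject_sequential_replay(
                        epoch, patterns, path, cfg.replay_lag_ms, amp,
                        cfg.replay_onset_jitter, rng, times, t0=t0,
                        kernel_ms=cfg.kernel_ms)
                    evrows += [(trial, s, t, a) for s, t, a in events]
            elif cfg.replay_mode == "clustered":
                scaled = {d: amp * a for d, a in grad.items()}
                _, events = inject_clustered_reactivation(
                    epoch, patterns, g, pred, cur, scaled, cfg.cluster_onset,
                    rng, times, kernel_ms=cfg.kernel_ms)
                evrows += [(trial, s, t, a) for s, t, a in events]
            correct = bool(rng.random() < accuracy)
            if correct:
                chosen = suc
            else:
                close, distal = select_distractors(g, (pred, cur, suc), rng)
                chosen = close if rng.random() < 0.5 else distal
            rows.append((pred, cur, suc, chosen, correct, block, phase))
            epochs.append(epoch)
            trial += 1
    meta = pd.DataFrame(rows, columns=["predecessor", "current", "successor",
                                       "chosen", "correct", "block", "phase"])
    events = pd.DataFrame(evrows, columns=["trial", "state", "onset", "amplitude"])
    return TrialArray(np.stack(epochs), times, meta), events


def simulate_behavior(g: GraphTask, n_blocks: int,
                      p_correct: Sequence[float],
                      near_bias: Sequence[float],
                      rng: np.random.Generator):
    """Simulated learning-block choices among {successor, close, distal}.

    ``p_correct[b]`` is the per-block probability of a correct choice;
    ``near_bias[b]`` the probability that an error picks the close (rather
    than distal) distractor.  Returns a list of BehavioralRecord.
    """
    from .task_graph import BehavioralRecord

    records = []
    for block in range(n_blocks):
        for pred, cur, suc in enumerate_triplets(g):
            close, distal = select_distractors(g, (pred, cur, suc), rng)
            if rng.random() < p_correct[block]:
                chosen, correct = suc, True
            else:
                chosen = close if rng.random() < near_bias[block] else distal
                correct = False
            records.append(BehavioralRecord(block, (pred, cur), int(chosen), correct))
    return records


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def draw_participant_profiles(cfg: SimulationConfig, rng: np.random.Generator):
    """Per-participant retrieval accuracy and replay amplitude scale.

    With performance-replay coupling ``c``, the latent Gaussians behind
    accuracy and amplitude are drawn with correlation ``c``, so the expected
    sample correlation between the two equals ``c`` (up to mild clipping).
    Returns ``(accuracies, amplitude_scales)``.
    """
    n = cfg.n_participants
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    c = 0.0 if cfg.coupling is None else float(cfg.coupling)
    if not -1 <= c <= 1:
        raise ValueError("coupling must be in [-1, 1]")
    z2 = c * z1 + np.sqrt(1 - c ** 2) * z2
    lo, hi = cfg.accuracy_range
    mu, sd = (lo + hi) / 2.0, (hi - lo) / 4.0
    acc = np.clip(mu + sd * z1, 0.0, 1.0)
    amp = np.clip(1.0 + cfg.amplitude_cv * z2, 0.05, None)
    return acc, amp


def simulate_cohort(cfg: SimulationConfig, graph: GraphTask | None = None):
    """Simulate a full cohort; reproducible byte-for-byte from ``cfg.seed``.

    Returns ``(graph, [ParticipantData, ...])``.
    """
    cfg.validate()
    if graph is None:
        from .task_graph import build_task_graph
        graph = build_task_graph()
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_participants + 1)
    accs, amps = draw_participant_profiles(cfg, np.random.default_rng(children[0]))
    out = []
    for p, child in enumerate(children[1:]):
        rng = np.random.default_rng(child)
        patterns = make_stimulus_patterns(cfg.n_sensors, cfg.n_states, rng,
                                          cfg.pattern_overlap)
        order = np.concatenate([
            generate_localizer_sequence(cfg.n_states, cfg.localizer_reps, rng)
            for _ in range(cfg.localizer_runs)])
        localizer = generate_localizer_trials(patterns, order, cfg, rng)
        learning = learning_events = None
        if cfg.n_learning_blocks > 0:
            learning, learning_events = generate_retrieval_trials(
                graph, patterns, cfg, rng, accuracy=accs[p],
                amplitude_scale=amps[p] * cfg.learning_amplitude_scale,
                phase="learning", n_blocks=cfg.n_learning_blocks)
        retrieval, events = generate_retrieval_trials(
            graph, patterns, cfg, rng, accuracy=accs[p],
            amplitude_scale=amps[p], phase="retrieval")
        out.append(ParticipantData(
            participant=p, localizer=localizer, retrieval=retrieval,
            events=events, accuracy=float(accs[p]),
            replay_amplitude=float(amps[p] * cfg.replay_amplitude),
            learning=learning, learning_events=learning_events,
            seed=int(child.generate_state(1)[0] % (2 ** 31))))
    return graph, out
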