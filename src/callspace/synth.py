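"""Synthetic flock experiments: frequency-modulated contact calls with ground
truth, dyadic interaction logs, and proximity snapshots.

The generator emulates the structure of a captive vocal-learning experiment:
4-bird single-age-class flocks, one baseline recording block followed by four
post-flock-formation blocks, contact calls whose frequency-modulation contours
drift and converge toward flockmates across blocks, and age-class differences
in call acoustics and social interaction rates.

Call model: a harmonic stack (fundamental plus integer harmonics with 1/k
amplitude decay) rendered under a smoothly interpolated FM contour defined by
anchor frequencies.  Convergence dynamics: each bird's anchor frequencies move
linearly toward the flock-mean prototype by a fixed fraction per block; drift
adds independent Gaussian jitter to anchors each block.

Interaction counts are negative-binomial per dyad per session; proximity
snapshots draw a dyad "close" (distance <= 10 cm) with a per-dyad affinity
probability and mark birds unmeasurable with an absence probability.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.signal import windows

from .io import CallSelection, selections_to_frame, write_selection_table, write_wav

FREQ_FLOOR_HZ = 500.0
FREQ_CEIL_HZ = 8000.0
MIN_CALL_S = 0.05
MAX_CALL_S = 0.4

#: study layout: 1 baseline block + 4 post-flock blocks, 4 audio sessions each
N_BLOCKS = 5
SESSIONS_PER_BLOCK = 4
#: video sampling: 2 sessions per post-flock block (8 total), 11 snapshots each
VIDEO_SESSIONS = 8
SNAPSHOTS_PER_FLOCK = 88
FLOCK_SIZE = 4
DYADS_PER_FLOCK = 6

#: printed interaction totals used to calibrate per-dyad rates
#: (6 flocks x 6 dyads x 8 video sessions per age class)
TABLE_TOTALS = {
    ("young", "affiliative"): 316,
    ("young", "agonistic"): 202,
    ("old", "affiliative"): 116,
    ("old", "agonistic"): 134,
}
_TABLE_CELLS = 6 * DYADS_PER_FLOCK * VIDEO_SESSIONS


def table_calibrated_rates(age_class: str) -> dict[str, float]:
    """Per-dyad per-session expected interaction counts calibrated so that six
    flocks over eight video sessions reproduce the study's printed totals."""
    return {
        kind: TABLE_TOTALS[(age_class, kind)] / _TABLE_CELLS
        for kind in ("affiliative", "agonistic")
    }


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CallPrototype:
    """One contact-call type: an FM contour given by anchor frequencies."""

    contour_anchor_freqs: list[float]
    duration: float
    amplitude: float = 0.8
    harmonics: int = 2

    def __post_init__(self):
        freqs = np.asarray(self.contour_anchor_freqs, dtype=float)
        if freqs.size < 2:
            raise ValueError("contour needs at least 2 anchor frequencies")
        if freqs.min() < FREQ_FLOOR_HZ or freqs.max() > FREQ_CEIL_HZ:
            raise ValueError(
                f"anchor frequencies must lie in [{FREQ_FLOOR_HZ:.0f}, "
                f"{FREQ_CEIL_HZ:.0f}] Hz, got range "
                f"[{freqs.min():.1f}, {freqs.max():.1f}]"
            )
        if not (MIN_CALL_S <= self.duration <= MAX_CALL_S):
            raise ValueError(
                f"duration must be in [{MIN_CALL_S}, {MAX_CALL_S}] s, got {self.duration}"
            )
        self.contour_anchor_freqs = [float(f) for f in freqs]


@dataclass
class IndividualProfile:
    """Generating parameters for one bird."""

    individual_id: str
    age_class: str
    repertoire: list[CallPrototype]
    drift_rate: float = 0.0
    convergence_rate: float = 0.0
    call_rate: float = 25.0  # expected calls per recording session
    #: fraction of call types dropped after the baseline block (repertoire
    #: pruning; at least one type is always kept)
    prune_after_baseline: float = 0.0

    def __post_init__(self):
        if self.drift_rate < 0 or self.convergence_rate < 0:
            raise ValueError("drift_rate and convergence_rate must be >= 0")
        if not (0.0 <= self.prune_after_baseline < 1.0):
            raise ValueError("prune_after_baseline must be in [0, 1)")
        if not self.repertoire:
            raise ValueError("repertoire must be non-empty")


@dataclass
class AgePreset:
    """Relative scalings of call acoustics and social rates by age class.

    ``old`` relative to ``young``: shorter calls, higher frequency, shallower
    frequency modulation, fewer affiliative interactions, and repertoire
    pruning (a fraction of call types dropped after the baseline block, the
    mechanism behind declining repertoire diversity in the older cohort).
    """

    duration_scale: float = 1.0
    freq_scale: float = 1.0
    fm_scale: float = 1.0
    affiliative_scale: float = 1.0
    prune_fraction: float = 0.0


AGE_PRESETS = {
    "young": AgePreset(),
    "old": AgePreset(duration_scale=0.8, freq_scale=1.15, fm_scale=0.6,
                     affiliative_scale=0.5, prune_fraction=0.5),
}


# ---------------------------------------------------------------------------
# call synthesis
# ---------------------------------------------------------------------------

def contour_on_grid(prototype: CallPrototype, n_points: int) -> np.ndarray:
    """Evaluate the smoothly interpolated FM contour on n_points samples."""
    anchors = np.asarray(prototype.contour_anchor_freqs, dtype=float)
    anchor_t = np.linspace(0.0, 1.0, anchors.size)
    t = np.linspace(0.0, 1.0, n_points)
    return PchipInterpolator(anchor_t, anchors)(t)


def synthesize_call(
    prototype: CallPrototype,
    sample_rate: int,
    noise_level: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Render a prototype as a waveform: harmonic stack under the FM contour.

    The instantaneous frequency follows the interpolated anchor contour;
    harmonic k has amplitude 1/k.  Broadband Gaussian noise is added at
    ``noise_level`` relative to the call amplitude (an amplitude-0 prototype
    renders as silence).

    Raises ``ValueError`` when any harmonic exceeds the Nyquist frequency.
    """
    max_f = max(prototype.contour_anchor_freqs) * prototype.harmonics
    if sample_rate < 2 * max_f:
        raise ValueError(
            f"sample rate {sample_rate} Hz cannot represent harmonic at "
            f"{max_f:.1f} Hz (Nyquist violation)"
        )
    n = int(round(prototype.duration * sample_rate))
    if n == 0:
        return np.zeros(0)
    freq = contour_on_grid(prototype, n)
    phase = 2.0 * np.pi * np.cumsum(freq) / sample_rate
    wave = np.zeros(n)
    for k in range(1, prototype.harmonics + 1):
        wave += np.sin(k * phase) / k
    # fade edges to avoid clicks; keep most of the call at full level
    wave *= windows.tukey(n, alpha=0.2)
    peak = np.max(np.abs(wave))
    if peak > 0:
        wave *= prototype.amplitude / peak
    if noise_level > 0 and prototype.amplitude > 0:
        rng = np.random.default_rng(seed)
        wave = wave + rng.normal(0.0, noise_level * prototype.amplitude, n)
    return wave


# ---------------------------------------------------------------------------
# repertoire construction and flock dynamics
# ---------------------------------------------------------------------------

def make_profile(
    individual_id: str,
    age_class: str,
    rng: np.random.Generator,
    n_call_types: int = 3,
    n_anchors: int = 4,
    drift_rate: float = 20.0,
    convergence_rate: float = 0.5,
    call_rate: float = 25.0,
    base_freq_range: tuple[float, float] = (1800.0, 3200.0),
    fm_depth: float = 700.0,
    type_offset_sd: float = 120.0,
    duration_range: tuple[float, float] = (0.12, 0.20),
) -> IndividualProfile:
    """Draw a random individual with an age-preset-scaled repertoire.

    Contact calls are individually distinctive: the bird gets one signature
    base frequency and duration, and its call types are variants around that
    signature (distinct FM shapes, small frequency offsets), so within-bird
    repertoire spread stays well below between-bird separation at baseline.
    """
    preset = AGE_PRESETS[age_class]
    bird_base = rng.uniform(*base_freq_range) * preset.freq_scale
    bird_duration = rng.uniform(*duration_range) * preset.duration_scale
    repertoire = []
    for _ in range(n_call_types):
        base = bird_base + rng.normal(0.0, type_offset_sd)
        shape = rng.normal(0.0, 1.0, n_anchors)
        shape -= shape.mean()
        if np.max(np.abs(shape)) > 0:
            shape /= np.max(np.abs(shape))
        anchors = base + fm_depth * preset.fm_scale * shape
        anchors = np.clip(anchors, FREQ_FLOOR_HZ, FREQ_CEIL_HZ)
        duration = float(
            np.clip(bird_duration * rng.uniform(0.92, 1.08),
                    MIN_CALL_S, MAX_CALL_S)
        )
        repertoire.append(
            CallPrototype(list(anchors), duration, amplitude=0.8, harmonics=2)
        )
    return IndividualProfile(
        individual_id=individual_id,
        age_class=age_class,
        repertoire=repertoire,
        drift_rate=drift_rate,
        convergence_rate=convergence_rate,
        call_rate=call_rate,
        prune_after_baseline=preset.prune_fraction,
    )


def make_flock_profiles(
    individual_ids: list[str],
    age_class: str,
    rng: np.random.Generator,
    **kwargs,
) -> list[IndividualProfile]:
    """Draw a flock of mutually unfamiliar birds.

    Flockmates come from separate source populations, so their signature
    frequencies are stratified across the base range (one stratum per bird,
    in shuffled order) rather than drawn independently — chance signature
    collisions between future flockmates are excluded by design.
    """
    lo, hi = kwargs.pop("base_freq_range", (1800.0, 3200.0))
    n = len(individual_ids)
    edges = np.linspace(lo, hi, n + 1)
    order = rng.permutation(n)
    profiles = []
    for bid, k in zip(individual_ids, order):
        profiles.append(
            make_profile(
                bid, age_class, rng,
                base_freq_range=(float(edges[k]), float(edges[k + 1])),
                **kwargs,
            )
        )
    return profiles


def _repertoire_mean_anchors(profile: IndividualProfile) -> np.ndarray:
    return np.mean(
        [p.contour_anchor_freqs for p in profile.repertoire], axis=0
    )


def _evolve_block(
    prototypes: dict[str, list[CallPrototype]],
    profiles: dict[str, IndividualProfile],
    rng: np.random.Generator,
) -> dict[str, list[CallPrototype]]:
    """One block of contour dynamics: converge toward the flockmate-mean
    contour, then jitter anchors by the drift rate."""
    mean_anchors = {
        bid: np.mean([p.contour_anchor_freqs for p in protos], axis=0)
        for bid, protos in prototypes.items()
    }
    mean_durs = {
        bid: float(np.mean([p.duration for p in protos]))
        for bid, protos in prototypes.items()
    }
    out: dict[str, list[CallPrototype]] = {}
    for bid, protos in prototypes.items():
        prof = profiles[bid]
        target = np.mean([mean_anchors[o] for o in prototypes if o != bid],
                         axis=0)
        # imitation copies the whole call, duration included
        target_dur = float(np.mean([mean_durs[o] for o in prototypes
                                    if o != bid]))
        new = []
        for proto in protos:
            anchors = np.asarray(proto.contour_anchor_freqs)
            anchors = anchors + prof.convergence_rate * (target - anchors)
            if prof.drift_rate > 0:
                anchors = anchors + rng.normal(0.0, prof.drift_rate, anchors.size)
            anchors = np.clip(anchors, FREQ_FLOOR_HZ, FREQ_CEIL_HZ)
            dur = proto.duration + prof.convergence_rate * (
                target_dur - proto.duration
            )
            dur = float(np.clip(dur, MIN_CALL_S, MAX_CALL_S))
            new.append(replace(proto, contour_anchor_freqs=list(anchors),
                               duration=dur))
        out[bid] = new
    return out


def true_contour_distances(
    prototypes_by_block: dict[int, dict[str, list[CallPrototype]]]
) -> pd.DataFrame:
    """Mean RMS anchor distance from each bird's repertoire-mean contour to
    its flockmates' repertoire-mean contours, per block (the planted truth
    the convergence statistic should recover)."""
    rows = []
    for block, protos in sorted(prototypes_by_block.items()):
        means = {
            bid: np.mean([p.contour_anchor_freqs for p in pl], axis=0)
            for bid, pl in protos.items()
        }
        for bid in protos:
            dists = [
                np.sqrt(np.mean((means[bid] - means[o]) ** 2))
                for o in protos
                if o != bid
            ]
            rows.append(
                {"individual": bid, "block": block,
                 "mean_contour_distance": float(np.mean(dists))}
            )
    return pd.DataFrame(rows)


@dataclass
class FlockCallSim:
    """Output of :func:`simulate_flock_calls` for one flock."""

    profiles: list[IndividualProfile]
    #: block -> bird -> evolved prototypes
    prototypes_by_block: dict[int, dict[str, list[CallPrototype]]]
    #: rows (individual, block, call_index, prototype_index, duration)
    calls: pd.DataFrame
    #: rendered call waveforms aligned with ``calls`` rows
    waveforms: list[np.ndarray]
    sample_rate: int
    #: per (individual, block) true mean contour distance to flockmates
    truth: pd.DataFrame


def simulate_flock_calls(
    profiles: list[IndividualProfile],
    blocks: int = N_BLOCKS,
    calls_per_block: int | None = None,
    sample_rate: int = 19000,
    noise_level: float = 0.02,
    seed: int = 0,
) -> FlockCallSim:
    """Simulate contact-call production for one flock across recording blocks.

    Block 1 draws calls from each bird's baseline repertoire; in blocks >= 2
    contours converge toward flockmates and jitter at the drift rate.  The
    returned truth table carries the generating contour distances, which are
    monotonically non-increasing in expectation when convergence_rate > 0 and
    drift_rate = 0.
    """
    if blocks < 2:
        raise ValueError("need at least 2 blocks (baseline + post-flock)")
    rng = np.random.default_rng(seed)
    current = {p.individual_id: copy.deepcopy(p.repertoire) for p in profiles}
    profs = {p.individual_id: p for p in profiles}
    prototypes_by_block = {1: copy.deepcopy(current)}
    # repertoire pruning takes effect once, after the baseline block
    for bid, prof in profs.items():
        if prof.prune_after_baseline > 0:
            n = len(current[bid])
            keep = max(1, n - int(round(prof.prune_after_baseline * n)))
            order = rng.permutation(n)[:keep]
            current[bid] = [current[bid][j] for j in sorted(order)]
    for b in range(2, blocks + 1):
        current = _evolve_block(current, profs, rng)
        prototypes_by_block[b] = copy.deepcopy(current)

    rows, waveforms = [], []
    for b in range(1, blocks + 1):
        for prof in profiles:
            protos = prototypes_by_block[b][prof.individual_id]
            n_calls = (
                calls_per_block
                if calls_per_block is not None
                else rng.poisson(prof.call_rate * SESSIONS_PER_BLOCK)
            )
            for i in range(n_calls):
                j = int(rng.integers(len(protos)))
                call_seed = int(rng.integers(2**31))
                wave = synthesize_call(
                    protos[j], sample_rate, noise_level=noise_level, seed=call_seed
                )
                rows.append(
                    {
                        "individual": prof.individual_id,
                        "age_class": prof.age_class,
                        "block": b,
                        "call_index": i,
                        "prototype_index": j,
                        "duration": protos[j].duration,
                    }
                )
                waveforms.append(wave)
    calls = pd.DataFrame(
        rows,
        columns=["individual", "age_class", "block", "call_index",
                 "prototype_index", "duration"],
    )
    return FlockCallSim(
        profiles=profiles,
        prototypes_by_block=prototypes_by_block,
        calls=calls,
        waveforms=waveforms,
        sample_rate=sample_rate,
        truth=true_contour_distances(prototypes_by_block),
    )


# ---------------------------------------------------------------------------
# social data
# ---------------------------------------------------------------------------

def _dyads(flock: list[str]) -> list[tuple[str, str]]:
    return [(a, b) for i, a in enumerate(flock) for b in flock[i + 1:]]


def _rate_lookup(rates, dyads) -> dict[tuple[str, str], float]:
    if np.isscalar(rates):
        return {d: float(rates) for d in dyads}
    out = {}
    for (a, b), r in rates.items():
        if a == b:
            raise ValueError(f"self-dyad ({a}, {a}) is not allowed")
        key = (a, b) if (a, b) in dyads else (b, a)
        if key not in dyads:
            raise ValueError(f"dyad ({a}, {b}) not in flock")
        out[key] = float(r)
    for d in dyads:
        out.setdefault(d, 0.0)
    return out


def simulate_interactions(
    flock: list[str],
    affiliative_rate,
    agonistic_rate,
    sessions: int = VIDEO_SESSIONS,
    dispersion: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a dyadic interaction event log.

    Rates are per-dyad expected counts per session (scalar, or a dict keyed
    by dyad).  Counts are negative-binomial with the given mean and shape
    ``dispersion`` (variance = m + m^2/dispersion), matching the count model
    the statistics battery fits.  Rows: (session, actor, receiver, type).
    """
    if sessions < 1:
        raise ValueError("sessions must be >= 1")
    rng = np.random.default_rng(seed)
    dyads = _dyads(flock)
    rates = {
        "affiliative": _rate_lookup(affiliative_rate, dyads),
        "agonistic": _rate_lookup(agonistic_rate, dyads),
    }
    rows = []
    for s in range(1, sessions + 1):
        for kind, rate_map in rates.items():
            for (a, b) in dyads:
                m = rate_map[(a, b)]
                if m < 0:
                    raise ValueError("interaction rates must be >= 0")
                if m == 0:
                    continue
                # NB as Poisson-gamma mixture
                lam = rng.gamma(dispersion, m / dispersion)
                count = rng.poisson(lam)
                for _ in range(count):
                    actor, receiver = (a, b) if rng.random() < 0.5 else (b, a)
                    rows.append(
                        {"session": s, "actor": actor, "receiver": receiver,
                         "type": kind}
                    )
    return pd.DataFrame(rows, columns=["session", "actor", "receiver", "type"])


def simulate_proximity(
    flock: list[str],
    affinity,
    snapshots: int = SNAPSHOTS_PER_FLOCK,
    absence_prob: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate proximity snapshots: per snapshot each bird is unmeasurable
    with probability ``absence_prob``; a measurable dyad is in close proximity
    (distance <= 10 cm) with its affinity probability, else farther apart.

    Rows: (snapshot_id, bird_a, bird_b, distance_cm), distance NaN when either
    bird is absent.
    """
    rng = np.random.default_rng(seed)
    dyads = _dyads(flock)
    aff = _rate_lookup(affinity, dyads)
    for d, p in aff.items():
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"affinity for dyad {d} must be in [0, 1]")
    if not (0.0 <= absence_prob <= 1.0):
        raise ValueError("absence_prob must be in [0, 1]")
    rows = []
    for s in range(1, snapshots + 1):
        present = {b: rng.random() >= absence_prob for b in flock}
        for (a, b) in dyads:
            if present[a] and present[b]:
                if rng.random() < aff[(a, b)]:
                    dist = rng.uniform(1.0, 10.0)
                else:
                    dist = rng.uniform(10.5, 80.0)
            else:
                dist = np.nan
            rows.append(
                {"snapshot_id": s, "bird_a": a, "bird_b": b,
                 "distance_cm": dist}
            )
    return pd.DataFrame(rows, columns=["snapshot_id", "bird_a", "bird_b",
                                       "distance_cm"])


# ---------------------------------------------------------------------------
# full experiment assembly
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Layout and rates of one synthetic flock experiment."""

    flocks_per_age: int = 1
    blocks: int = N_BLOCKS
    sessions_per_block: int = SESSIONS_PER_BLOCK
    call_rate: float = 25.0          # expected calls per bird per session
    drift_rate: float = 20.0         # Hz anchor jitter per block
    convergence_rate: float = 0.5    # fraction moved toward flock mean per
                                     # block; imitation of flockmates is
                                     # fast (within about one block)
    noise_level: float = 0.02
    sample_rate: int = 44100
    mean_gap_s: float = 0.5          # exponential inter-call silence
    n_call_types: int = 3
    use_table_rates: bool = True     # calibrate interaction rates to the
                                     # printed study totals
    proximity_affinity: dict = field(
        default_factory=lambda: {"young": 0.30, "old": 0.22}
    )
    absence_prob: float = 0.1


@dataclass
class SyntheticExperiment:
    """One rendered experiment: recordings, ground truth, and social logs."""

    config: ExperimentConfig
    #: rows (flock, individual, age_class, block, session, wav_path, truth_path)
    recordings: pd.DataFrame
    events: pd.DataFrame       # with flock + block columns
    snapshots: pd.DataFrame    # with flock column
    truth: dict                # generating parameters + contour distances


def _render_session(
    waveforms: list[np.ndarray],
    sample_rate: int,
    mean_gap_s: float,
    rng: np.random.Generator,
    recording: str,
) -> tuple[np.ndarray, list[CallSelection]]:
    """Place calls with exponential gaps; truth selections tile call positions
    exactly at sample boundaries."""
    chunks, selections = [], []
    cursor = 0
    for wave in waveforms:
        gap = int(round(rng.exponential(mean_gap_s) * sample_rate)) + 1
        chunks.append(np.zeros(gap))
        start = cursor + gap
        chunks.append(wave)
        selections.append(
            CallSelection(
                recording=recording,
                begin=start / sample_rate,
                end=(start + wave.size) / sample_rate,
                label="call",
            )
        )
        cursor = start + wave.size
    chunks.append(np.zeros(int(round(0.5 * sample_rate))))
    return np.concatenate(chunks) if chunks else np.zeros(0), selections


def simulate_experiment(
    config: ExperimentConfig,
    out_dir: str | Path,
    seed: int = 0,
) -> SyntheticExperiment:
    """Generate and write a full synthetic experiment to ``out_dir``.

    Writes per-bird-per-session WAV files with matching ground-truth selection
    tables, an interaction event log, a proximity snapshot table, and the
    generating truth as JSON.  Bit-reproducible given (config, seed).
    """
    out = Path(out_dir)
    (out / "audio").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    rec_rows, all_events, all_snaps = [], [], []
    truth: dict = {"flocks": {}, "contour_distances": []}
    flock_idx = 0
    for age in ("young", "old"):
        for _ in range(config.flocks_per_age):
            flock_idx += 1
            flock_id = f"F{flock_idx:02d}"
            bird_ids = [f"{flock_id}B{i+1}" for i in range(FLOCK_SIZE)]
            profiles = make_flock_profiles(
                bird_ids,
                age,
                rng,
                n_call_types=config.n_call_types,
                drift_rate=config.drift_rate,
                convergence_rate=config.convergence_rate,
                call_rate=config.call_rate,
            )
            # evolve contours once per flock
            sim = simulate_flock_calls(
                profiles,
                blocks=config.blocks,
                calls_per_block=0,  # sessions rendered below
                sample_rate=config.sample_rate,
                seed=int(rng.integers(2**31)),
            )
            truth["flocks"][flock_id] = {
                "age_class": age,
                "birds": bird_ids,
                "drift_rate": config.drift_rate,
                "convergence_rate": config.convergence_rate,
            }
            td = sim.truth.assign(flock=flock_id)
            truth["contour_distances"].extend(td.to_dict("records"))

            for block in range(1, config.blocks + 1):
                protos = sim.prototypes_by_block[block]
                for prof in profiles:
                    for session in range(1, config.sessions_per_block + 1):
                        n_calls = rng.poisson(config.call_rate)
                        plist = protos[prof.individual_id]
                        waves = []
                        for _ in range(n_calls):
                            j = int(rng.integers(len(plist)))
                            waves.append(
                                synthesize_call(
                                    plist[j],
                                    config.sample_rate,
                                    noise_level=config.noise_level,
                                    seed=int(rng.integers(2**31)),
                                )
                            )
                        stem = f"{prof.individual_id}_b{block}_s{session}"
                        wav_path = out / "audio" / f"{stem}.wav"
                        truth_path = out / "truth" / f"{stem}.txt"
                        session_wave, sels = _render_session(
                            waves, config.sample_rate, config.mean_gap_s,
                            rng, stem,
                        )
                        write_wav(wav_path, session_wave, config.sample_rate)
                        write_selection_table(selections_to_frame(sels), truth_path)
                        rec_rows.append(
                            {
                                "flock": flock_id,
                                "individual": prof.individual_id,
                                "age_class": age,
                                "block": block,
                                "session": session,
                                "n_calls": n_calls,
                                "wav_path": str(wav_path),
                                "truth_path": str(truth_path),
                            }
                        )

            # social data: video covers the 4 post-flock blocks
            if config.use_table_rates:
                rates = table_calibrated_rates(age)
                affil, agon = rates["affiliative"], rates["agonistic"]
            else:
                preset = AGE_PRESETS[age]
                affil = 1.0 * preset.affiliative_scale
                agon = 0.7
            events = simulate_interactions(
                bird_ids, affil, agon,
                sessions=VIDEO_SESSIONS,
                seed=int(rng.integers(2**31)),
            )
            events["flock"] = flock_id
            events["block"] = (events["session"] - 1) // 2 + 1 if len(events) else []
            all_events.append(events)
            snaps = simulate_proximity(
                bird_ids,
                config.proximity_affinity[age],
                snapshots=SNAPSHOTS_PER_FLOCK,
                absence_prob=config.absence_prob,
                seed=int(rng.integers(2**31)),
            )
            snaps["flock"] = flock_id
            all_snaps.append(snaps)

    recordings = pd.DataFrame(rec_rows)
    events = pd.concat(all_events, ignore_index=True) if all_events else pd.DataFrame()
    snapshots = pd.concat(all_snaps, ignore_index=True) if all_snaps else pd.DataFrame()
    recordings.to_csv(out / "recordings.csv", index=False)
    events.to_csv(out / "events.csv", index=False)
    snapshots.to_csv(out / "snapshots.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return SyntheticExperiment(
        config=config,
        recordings=recordings,
        events=events,
        snapshots=snapshots,
        truth=truth,
    )
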