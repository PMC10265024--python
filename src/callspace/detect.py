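"""Energy-based sound-event detection, threshold optimization, and
signal/noise classification.

Detection: bandpass filter -> rectified amplitude envelope smoothed with a
5 ms moving average -> contiguous supra-threshold runs, with the threshold
expressed as a fraction of the envelope maximum (detection is therefore
invariant to uniform gain).  Runs closer than a hold time are merged; runs
outside the duration bounds are discarded.

Optimization evaluates a parameter grid exhaustively against an annotated
fixture; a detection counts as a true positive when it overlaps an annotated
call by at least half the annotation's duration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.ensemble import RandomForestClassifier

from .io import CallSelection

ENVELOPE_SMOOTH_S = 0.005
MATCH_MIN_OVERLAP = 0.5


@dataclass
class DetectorParams:
    """Energy-detector settings: relative amplitude threshold, duration
    bounds (s), bandpass (Hz), and gap-merge hold time (s)."""

    amplitude_threshold: float = 0.1
    min_duration: float = 0.04
    max_duration: float = 0.5
    bandpass: tuple[float, float] = (500.0, 8000.0)
    hold_time: float = 0.02

    def __post_init__(self):
        if not (0.0 < self.amplitude_threshold < 1.0):
            raise ValueError("amplitude_threshold must be in (0, 1)")
        if not (self.min_duration < self.max_duration):
            raise ValueError("min_duration must be < max_duration")
        low, high = self.bandpass
        if not (low < high):
            raise ValueError("bandpass low must be < high")


@dataclass
class DetectionDiagnostics:
    """Standard detection counts and rates against an annotated truth set."""

    true_positives: int
    false_positives: int
    false_negatives: int

    @property
    def recall(self) -> float:
        denom = self.true_positives + self.false_negatives
        return self.true_positives / denom if denom else 0.0

    @property
    def precision(self) -> float:
        denom = self.true_positives + self.false_positives
        return self.true_positives / denom if denom else 0.0

    @property
    def f_score(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def as_dict(self) -> dict:
        return {
            "true_positives": self.true_positives,
            "false_positives": self.false_positives,
            "false_negatives": self.false_negatives,
            "recall": self.recall,
            "precision": self.precision,
            "f_score": self.f_score,
        }


def _bandpass(waveform: np.ndarray, sample_rate: int,
              band: tuple[float, float]) -> np.ndarray:
    low, high = band
    nyq = sample_rate / 2.0
    high = min(high, nyq * 0.99)
    sos = signal.butter(4, [low / nyq, high / nyq], btype="band", output="sos")
    return signal.sosfiltfilt(sos, waveform)


def amplitude_envelope(waveform: np.ndarray, sample_rate: int) -> np.ndarray:
    """Rectified signal smoothed with a 5 ms moving average."""
    win = max(1, int(round(ENVELOPE_SMOOTH_S * sample_rate)))
    kernel = np.ones(win) / win
    return np.convolve(np.abs(waveform), kernel, mode="same")


def energy_detect(
    waveform: np.ndarray,
    sample_rate: int,
    params: DetectorParams,
    recording: str = "",
) -> list[CallSelection]:
    """Detect candidate calls; returns sorted non-overlapping half-open
    [start, end) selections in seconds.  Silence yields an empty list."""
    if waveform.size == 0:
        raise ValueError("waveform is empty")
    if not np.any(waveform):
        return []
    filtered = _bandpass(waveform, sample_rate, params.bandpass)
    env = amplitude_envelope(filtered, sample_rate)
    threshold = params.amplitude_threshold * env.max()
    above = env > threshold
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    run_ends = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))

    hold = params.hold_time * sample_rate
    merged = [[run_starts[0], run_ends[0]]]
    for s, e in zip(run_starts[1:], run_ends[1:]):
        if s - merged[-1][1] < hold:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    out = []
    for s, e in merged:
        dur = (e - s) / sample_rate
        if params.min_duration <= dur <= params.max_duration:
            out.append(
                CallSelection(
                    recording=recording,
                    begin=s / sample_rate,
                    end=e / sample_rate,
                    low_freq=params.bandpass[0],
                    high_freq=params.bandpass[1],
                    label="detection",
                )
            )
    return out


def match_detections(
    detections: list[CallSelection],
    truth: list[CallSelection],
    min_overlap: float = MATCH_MIN_OVERLAP,
) -> DetectionDiagnostics:
    """Score detections against annotations.  A detection matches an
    annotation when their intersection covers >= ``min_overlap`` of the
    annotation's duration."""
    matched_truth = np.zeros(len(truth), dtype=bool)
    matched_det = np.zeros(len(detections), dtype=bool)
    for j, t in enumerate(truth):
        need = min_overlap * t.duration
        for i, d in enumerate(detections):
            ov = min(d.end, t.end) - max(d.begin, t.begin)
            if ov >= need and ov > 0:
                matched_truth[j] = True
                matched_det[i] = True
    tp = int(matched_truth.sum())
    return DetectionDiagnostics(
        true_positives=tp,
        false_positives=int((~matched_det).sum()),
        false_negatives=int((~matched_truth).sum()),
    )


def expand_grid(grid: dict[str, list]) -> list[DetectorParams]:
    """Expand a dict of candidate value lists into DetectorParams points."""
    keys = list(grid)
    points = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        points.append(DetectorParams(**dict(zip(keys, combo))))
    return points


def optimize_detector(
    waveform: np.ndarray,
    sample_rate: int,
    truth: list[CallSelection],
    grid: list[DetectorParams] | dict[str, list],
) -> tuple[DetectorParams, DetectionDiagnostics, pd.DataFrame]:
    """Exhaustive grid search for the detector settings maximizing F-score on
    an annotated fixture.

    Ties are broken by higher recall, then by lower amplitude threshold.
    Returns the winning settings, their diagnostics, and the full grid table.
    """
    if isinstance(grid, dict):
        grid = expand_grid(grid)
    if not grid:
        raise ValueError("parameter grid is empty")
    if not truth:
        raise ValueError("truth selections are empty; cannot optimize")
    rows = []
    results = []
    for params in grid:
        diag = match_detections(
            energy_detect(waveform, sample_rate, params), truth
        )
        results.append((params, diag))
        rows.append({**params.__dict__, **diag.as_dict()})
    best_params, best_diag = max(
        results,
        key=lambda pr: (pr[1].f_score, pr[1].recall, -pr[0].amplitude_threshold),
    )
    return best_params, best_diag, pd.DataFrame(rows)


def classify_selections(
    train_features: np.ndarray | pd.DataFrame,
    train_labels,
    test_features: np.ndarray | pd.DataFrame,
    seed: int = 0,
    n_estimators: int = 200,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Signal/noise filtering with an ensemble-of-trees classifier.

    Returns predicted labels and per-class probabilities (rows sum to 1).
    Raises on a single-class training set.
    """
    labels = np.asarray(train_labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError(
            f"training labels contain a single class {classes.tolist()}; "
            "need both signal and noise examples"
        )
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    clf.fit(np.asarray(train_features), labels)
    proba = clf.predict_proba(np.asarray(test_features))
    pred = clf.classes_[np.argmax(proba, axis=1)]
    return pred, pd.DataFrame(proba, columns=clf.classes_)
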