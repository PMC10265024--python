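"""Audio preprocessing and per-call spectro-temporal feature extraction.

Audio is resampled to 19 kHz and bandpassed to the 0.5-8.0 kHz contact-call
band.  Each call is summarized by a 17-dimensional feature vector computed on
a 150-sample Hann-window spectrogram (50% overlap): duration, statistics of
the time-aggregated magnitude spectrum (mean, SD, quartiles, IQR, skewness,
kurtosis), entropy and flatness measures, and the per-frame dominant-frequency
track (mean, min, max, and a modulation index).

``dom_freq_range`` (max - min of the dominant track) is carried as a derived
convenience column; it is not part of the 17 scaled features because it is an
exact linear combination of two of them.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

TARGET_RATE = 19000
BAND = (500.0, 8000.0)
WINDOW_SAMPLES = 150
OVERLAP = 0.5

#: the 17 features used downstream, in column order
FEATURE_NAMES = [
    "duration",
    "mean_freq",
    "sd_freq",
    "median_freq",
    "q25_freq",
    "q75_freq",
    "iqr_freq",
    "spectral_skewness",
    "spectral_kurtosis",
    "spectral_entropy",
    "temporal_entropy",
    "overall_entropy",
    "spectral_flatness",
    "mean_dom_freq",
    "min_dom_freq",
    "max_dom_freq",
    "modulation_index",
]

#: metadata columns written before the features in a FeatureTable
META_COLUMNS = ["individual", "flock", "age_class", "block"]


def preprocess(waveform: np.ndarray, sample_rate: int) -> tuple[np.ndarray, int]:
    """Anti-aliased resampling to 19 kHz plus zero-phase 0.5-8 kHz bandpass.

    Raises when the input rate is below 16 kHz (the 8 kHz band edge cannot be
    represented).
    """
    if sample_rate < 16000:
        raise ValueError(
            f"sample rate {sample_rate} Hz is too low; need >= 16000 Hz to "
            "represent the 8 kHz band edge"
        )
    if sample_rate != TARGET_RATE:
        frac = Fraction(TARGET_RATE, int(sample_rate))
        waveform = signal.resample_poly(
            waveform, frac.numerator, frac.denominator,
            window=("kaiser", 14.0),
        )
    nyq = TARGET_RATE / 2.0
    sos = signal.butter(
        5, [BAND[0] / nyq, BAND[1] / nyq], btype="band", output="sos"
    )
    return signal.sosfiltfilt(sos, waveform), TARGET_RATE


def _weighted_quantile(freqs: np.ndarray, p: np.ndarray, q: float) -> float:
    cum = np.cumsum(p)
    return float(freqs[np.searchsorted(cum, q)])


def extract_features(
    waveform: np.ndarray,
    sample_rate: int = TARGET_RATE,
    begin: float | None = None,
    end: float | None = None,
) -> dict[str, float]:
    """Compute the per-call feature vector for one selection.

    ``begin``/``end`` (seconds, half-open) cut the selection out of the
    waveform; omitted they cover the whole array.  The selection must span at
    least two analysis windows.
    """
    i0 = 0 if begin is None else int(round(begin * sample_rate))
    i1 = waveform.size if end is None else int(round(end * sample_rate))
    if i0 < 0 or i1 > waveform.size or i1 <= i0:
        raise ValueError("selection lies outside the waveform")
    x = waveform[i0:i1]
    min_samples = 2 * WINDOW_SAMPLES
    if x.size < min_samples:
        raise ValueError(
            f"selection too short for analysis: need >= {min_samples} samples "
            f"({min_samples / sample_rate:.4f} s), got {x.size}"
        )
    duration = x.size / sample_rate

    hop = int(WINDOW_SAMPLES * (1 - OVERLAP))
    freqs, _, spec = signal.stft(
        x,
        fs=sample_rate,
        window="hann",
        nperseg=WINDOW_SAMPLES,
        noverlap=WINDOW_SAMPLES - hop,
        boundary=None,
        padded=False,
    )
    mag = np.abs(spec)  # (freq, frame)
    band_mask = (freqs >= BAND[0]) & (freqs <= BAND[1])
    bf = freqs[band_mask]
    bmag = mag[band_mask]

    # aggregated magnitude spectrum over the call
    agg = bmag.mean(axis=1)
    total = agg.sum()
    if total <= 0:
        p = np.full(bf.size, 1.0 / bf.size)
    else:
        p = agg / total

    mean_freq = float(np.sum(bf * p))
    sd_freq = float(np.sqrt(np.sum((bf - mean_freq) ** 2 * p)))
    median_freq = _weighted_quantile(bf, p, 0.5)
    q25 = _weighted_quantile(bf, p, 0.25)
    q75 = _weighted_quantile(bf, p, 0.75)
    if sd_freq > 0:
        z = (bf - mean_freq) / sd_freq
        skew = float(np.sum(z**3 * p))
        kurt = float(np.sum(z**4 * p))
    else:
        skew, kurt = 0.0, 0.0

    # entropies normalized to [0, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        spec_entropy = float(
            -np.sum(p * np.log(p, where=p > 0, out=np.zeros_like(p)))
            / np.log(p.size)
        )
    frame_energy = (bmag**2).sum(axis=0)
    te_total = frame_energy.sum()
    if te_total > 0 and frame_energy.size > 1:
        pe = frame_energy / te_total
        temp_entropy = float(
            -np.sum(pe * np.log(pe, where=pe > 0, out=np.zeros_like(pe)))
            / np.log(pe.size)
        )
    else:
        temp_entropy = 1.0
    overall_entropy = spec_entropy * temp_entropy

    power = agg**2
    am = power.mean()
    if am > 0:
        gm = np.exp(np.mean(np.log(power + 1e-300)))
        flatness = float(gm / am)
    else:
        flatness = 1.0

    # dominant-frequency track
    dom = bf[np.argmax(bmag, axis=0)]
    mean_dom = float(dom.mean())
    min_dom = float(dom.min())
    max_dom = float(dom.max())
    dom_range = max_dom - min_dom
    if dom_range > 0:
        modulation = float(np.sum(np.abs(np.diff(dom))) / dom_range)
    else:
        modulation = 1.0

    return {
        "duration": duration,
        "mean_freq": mean_freq,
        "sd_freq": sd_freq,
        "median_freq": median_freq,
        "q25_freq": q25,
        "q75_freq": q75,
        "iqr_freq": q75 - q25,
        "spectral_skewness": skew,
        "spectral_kurtosis": kurt,
        "spectral_entropy": spec_entropy,
        "temporal_entropy": temp_entropy,
        "overall_entropy": overall_entropy,
        "spectral_flatness": flatness,
        "mean_dom_freq": mean_dom,
        "min_dom_freq": min_dom,
        "max_dom_freq": max_dom,
        "dom_freq_range": dom_range,
        "modulation_index": modulation,
    }


def feature_table(
    rows: list[dict[str, float]],
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble feature dicts (plus optional per-call metadata) into a
    FeatureTable with metadata columns first."""
    feats = pd.DataFrame(rows)
    if meta is not None:
        meta = meta.reset_index(drop=True)
        feats = pd.concat([meta, feats.reset_index(drop=True)], axis=1)
        cols = [c for c in META_COLUMNS if c in feats.columns]
        other_meta = [c for c in meta.columns if c not in cols]
        feat_cols = [c for c in feats.columns if c not in meta.columns]
        feats = feats[cols + other_meta + feat_cols]
    return feats


def scale_features(
    table: pd.DataFrame,
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Z-scale feature columns to zero mean, unit variance (population SD).

    Scaling constants are recorded in ``result.attrs['scaling']``.  Raises on
    fewer than 2 rows, missing values, or zero-variance columns (all listed).
    """
    cols = columns if columns is not None else [
        c for c in FEATURE_NAMES if c in table.columns
    ]
    if len(table) < 2:
        raise ValueError("need at least 2 rows to scale")
    block = table[cols].to_numpy(dtype=float)
    if np.isnan(block).any():
        raise ValueError("feature table contains missing values")
    means = block.mean(axis=0)
    sds = block.std(axis=0)  # population convention
    dead = [c for c, s in zip(cols, sds) if s == 0]
    if dead:
        raise ValueError(f"zero-variance feature columns: {dead}")
    out = table.copy()
    out[cols] = (block - means) / sds
    out.attrs["scaling"] = {
        c: {"mean": float(m), "sd": float(s)}
        for c, m, s in zip(cols, means, sds)
    }
    return out
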