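"""Spectral and time-domain feature extraction from single-channel EEG.

Pipeline (per recording): zero-phase band-pass filter (1-40 Hz, 4th-order
Butterworth applied forward and reverse), segmentation into non-overlapping
1-second zero-mean epochs, Bartlett averaged periodogram (rectangular window
per epoch, periodograms averaged across epochs), then ten features:

==============  =====================================================
alpha_power     log10 trapezoidal band power around the alpha peak
beta_power      same, beta band
theta_power     same, theta band
alpha_max       log10 of the maximum PSD value in the alpha band
beta_max        same, beta band
theta_max       same, theta band
rms             median over epochs of per-epoch root mean square (uV)
sd              median per-epoch sample SD, n-1 denominator (uV)
skewness        median per-epoch moment skewness g1 = m3 / m2^1.5
mm              median per-epoch peak-to-peak range max - min (uV)
==============  =====================================================

Band power is the trapezoidal integral of the PSD over a window of
``half_width`` Hz (default 1 Hz, one bin at 1-second epochs) on either side
of the band's maximum bin, clipped to the band. Band edges are inclusive on
both sides, so a peak exactly at 8 Hz belongs to both the theta (4-8 Hz) and
alpha (8-13 Hz) bands and yields equal maxima for the two — the behavior
observed in recordings whose dominant rhythm sits on the band boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .datamatrix import DataMatrix

__all__ = [
    "BANDS",
    "FEATURE_COLUMNS",
    "EpochSet",
    "FeatureRow",
    "bandpass_filter",
    "make_epochs",
    "bartlett_psd",
    "band_features",
    "time_features",
    "feature_row",
    "build_feature_matrix",
]

#: EEG frequency bands (Hz), edges inclusive.
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

#: Column order of the assembled feature matrix.
FEATURE_COLUMNS = [
    "alpha_power",
    "beta_power",
    "theta_power",
    "alpha_max",
    "beta_max",
    "theta_max",
    "rms",
    "sd",
    "skewness",
    "mm",
]

_LOG_FLOOR = 1e-300  # keeps log10 finite on an identically-zero PSD bin


@dataclass
class EpochSet:
    """E non-overlapping, zero-mean epochs of L samples each."""

    epochs: np.ndarray  # (E, L)
    fs: float
    subject_id: str = ""
    condition: str = ""
    n_rejected: int = 0
    too_few: bool = False

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def epoch_len(self) -> int:
        return self.epochs.shape[1]


@dataclass
class FeatureRow:
    """The ten features of one recording (one subject in one condition)."""

    alpha_power: float
    beta_power: float
    theta_power: float
    alpha_max: float
    beta_max: float
    theta_max: float
    rms: float
    sd: float
    skewness: float
    mm: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in FEATURE_COLUMNS])


def bandpass_filter(
    x: np.ndarray, fs: float, lo: float = 1.0, hi: float = 40.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-reverse, i.e. filtfilt).

    The effective magnitude response is the square of the single-pass
    response, so the stopband attenuation doubles in dB and the phase is
    exactly zero.
    """
    if fs <= 2 * hi:
        raise ValueError(
            f"sampling rate {fs} Hz too low for a {hi} Hz upper band edge"
        )
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def make_epochs(
    x: np.ndarray,
    fs: float,
    epoch_seconds: float = 1.0,
    max_epochs: int | None = 150,
    min_epochs: int | None = None,
    subject_id: str = "",
    condition: str = "",
    reject_k: float | None = None,
) -> EpochSet:
    """Cut a series into consecutive non-overlapping zero-mean epochs.

    At most ``max_epochs`` surviving epochs are kept, in temporal order. If
    fewer than ``min_epochs`` survive, the set is flagged ``too_few`` (such
    recordings are excluded when the feature matrix is assembled).

    ``reject_k`` enables a simple amplitude-threshold artifact rule: an epoch
    is rejected when any sample deviates from the whole-series mean by more
    than ``k`` times the whole-series SD. This is a crude stand-in for a
    dedicated EEG artifact-rejection method and is labeled as such; it is off
    by default.
    """
    x = np.asarray(x, dtype=float)
    L = int(round(epoch_seconds * fs))
    if x.size < L:
        raise ValueError("series shorter than one epoch")
    E = x.size // L
    ep = x[: E * L].reshape(E, L)
    if reject_k is not None:
        dev = np.abs(ep - x.mean())
        keep = dev.max(axis=1) <= reject_k * x.std()
        n_rejected = int((~keep).sum())
        ep = ep[keep]
    else:
        n_rejected = 0
    if max_epochs is not None:
        ep = ep[:max_epochs]
    ep = ep - ep.mean(axis=1, keepdims=True)
    too_few = min_epochs is not None and ep.shape[0] < min_epochs
    return EpochSet(
        epochs=ep,
        fs=fs,
        subject_id=subject_id,
        condition=condition,
        n_rejected=n_rejected,
        too_few=too_few,
    )


def bartlett_psd(es: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Bartlett averaged periodogram: mean of per-epoch rectangular-window
    periodograms.

    Frequency resolution is ``fs / L`` (1 Hz for 1-second epochs). The
    one-sided density normalization conserves energy exactly:
    ``sum(psd) * fs / L == mean(epochs**2)`` (Parseval), per epoch and hence
    for the average. Averaging E independent epochs shrinks the estimate's
    variance by 1/E without changing its expectation.
    """
    if es.n_epochs < 1:
        raise ValueError("need at least one epoch")
    freqs, pxx = sps.periodogram(
        es.epochs, fs=es.fs, window="boxcar", scaling="density", axis=-1
    )
    return freqs, pxx.mean(axis=0)


def band_features(
    freqs: np.ndarray,
    psd: np.ndarray,
    band: tuple[float, float],
    half_width: float = 1.0,
) -> tuple[float, float]:
    """(log10 band maximum, log10 trapezoidal band power around the peak).

    The maximum is taken over PSD bins with ``lo <= f <= hi`` (edges
    inclusive). The power is the trapezoidal integral over
    ``[f_peak - half_width, f_peak + half_width]`` clipped to the band.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    lo, hi = band
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError(f"band {band} contains no PSD bins")
    fb, pb = freqs[mask], psd[mask]
    peak = int(np.argmax(pb))
    f_peak = fb[peak]
    band_max = math.log10(max(pb[peak], _LOG_FLOOR))
    wmask = (fb >= max(lo, f_peak - half_width)) & (
        fb <= min(hi, f_peak + half_width)
    )
    if wmask.sum() >= 2:
        power = np.trapezoid(pb[wmask], fb[wmask])
    else:  # single-bin window: rectangle of one bin width
        df = freqs[1] - freqs[0] if freqs.size > 1 else 1.0
        power = float(pb[wmask][0]) * df
    return band_max, math.log10(max(power, _LOG_FLOOR))


def time_features(es: EpochSet) -> dict[str, float]:
    """Median over epochs of per-epoch RMS, SD (n-1), skewness (g1), and
    peak-to-peak range (Mm = max - min)."""
    ep = es.epochs
    rms = np.sqrt(np.mean(ep**2, axis=1))
    sd = ep.std(axis=1, ddof=1)
    skew = spstats.skew(ep, axis=1, bias=True)
    mm = ep.max(axis=1) - ep.min(axis=1)
    return {
        "rms": float(np.median(rms)),
        "sd": float(np.median(sd)),
        "skewness": float(np.median(skew)),
        "mm": float(np.median(mm)),
    }


def feature_row(
    es: EpochSet,
    bands: dict[str, tuple[float, float]] | None = None,
    half_width: float = 1.0,
) -> FeatureRow:
    """All ten features of one epoch set."""
    bands = BANDS if bands is None else bands
    freqs, psd = bartlett_psd(es)
    spec: dict[str, float] = {}
    for name in ("alpha", "beta", "theta"):
        bmax, bpow = band_features(freqs, psd, bands[name], half_width)
        spec[f"{name}_max"] = bmax
        spec[f"{name}_power"] = bpow
    t = time_features(es)
    return FeatureRow(**spec, **t)


def build_feature_matrix(
    epoch_sets: list[EpochSet],
    bands: dict[str, tuple[float, float]] | None = None,
    half_width: float = 1.0,
) -> tuple[DataMatrix, list[str]]:
    """Assemble the subjects-by-conditions feature matrix.

    One row per (subject, condition) recording, columns in
    :data:`FEATURE_COLUMNS` order, row ids ``"<subject>_<condition>"``. A
    subject missing any condition, or with a recording flagged ``too_few``,
    is dropped entirely (all conditions of a subject enter together or not at
    all, keeping the condition contrast balanced). Returns the matrix and the
    list of excluded subject ids.
    """
    fs_set = {es.fs for es in epoch_sets}
    if len(fs_set) > 1:
        raise ValueError(f"inconsistent sampling rates: {sorted(fs_set)}")
    conditions = sorted({es.condition for es in epoch_sets})
    by_subject: dict[str, dict[str, EpochSet]] = {}
    for es in epoch_sets:
        by_subject.setdefault(es.subject_id, {})[es.condition] = es
    rows, row_ids, excluded = [], [], []
    for sid in sorted(by_subject):
        recs = by_subject[sid]
        if set(recs) != set(conditions) or any(r.too_few for r in recs.values()):
            excluded.append(sid)
            continue
        for cond in conditions:
            rows.append(feature_row(recs[cond], bands, half_width).as_array())
            row_ids.append(f"{sid}_{cond}")
    if len(rows) < 3:
        raise ValueError("fewer than 3 usable recordings after exclusions")
    X = DataMatrix(
        values=np.vstack(rows),
        row_ids=row_ids,
        col_names=list(FEATURE_COLUMNS),
    )
    return X, excluded
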