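"""Synthetic inputs: latent-factor feature matrices and EEG-like signals.

Two generators make every downstream module testable without access to any
recorded data.

``synth_feature_matrix`` draws a 48 x 10 (by default) matrix from a
latent-factor model ``x_j = w_j f + w2_j g + s_j e_j`` with two exact
duplicate column pairs, emulating the empirical structure of occipital EEG
feature tables: one strong "overall amplitude" factor loading positively on
every variable (all pairwise Spearman correlations positive and large), a
perfect correlation between alpha power and alpha maximum and between RMS
and SD, and — optionally — a weak second factor contrasting the beta and
theta bands. With equal loadings ``w = sqrt(rho)`` the population
correlation matrix is equicorrelated and its leading eigenvalue is
``1 + (p - 1) rho``, which lets a target first-eigenvalue fraction be mapped
to loadings in closed form.

``synth_eeg`` builds band-limited oscillatory signals on a 1/f background:
an alpha rhythm (subject-specific peak frequency in 8-13 Hz, occasionally
exactly at the 8 Hz theta/alpha boundary) whose amplitude is larger with
eyes closed than open (alpha blocking), plus weaker beta and theta rhythms.
A per-subject amplitude scale couples all amplitude-dependent features, and
a small quadratic waveform asymmetry (tied to the same per-subject latent)
gives the positive skewness that couples the skewness feature to the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamatrix import DataMatrix
from .eeg import FEATURE_COLUMNS

__all__ = [
    "SyntheticSpec",
    "synth_feature_matrix",
    "two_factor_spec",
    "EEGSubjectParams",
    "draw_subject_params",
    "synth_eeg",
    "synth_eeg_study",
]

#: column indices of the duplicate pairs: alpha_max copies alpha_power,
#: sd copies rms (Table-order columns).
DEFAULT_DUPLICATE_PAIRS: list[tuple[int, int]] = [(0, 3), (6, 7)]

#: columns carrying the beta-vs-theta contrast of the optional second factor
_BETA_COLS = (1, 4)  # beta_power, beta_max
_THETA_COLS = (2, 5)  # theta_power, theta_max


@dataclass
class SyntheticSpec:
    """Parameters of the latent-factor feature-matrix generator.

    The default target first-eigenvalue fraction of 0.84 reproduces the
    magnitude of the leading correlation eigenvalue typical of strongly
    positively inter-correlated EEG feature sets (~8.4 of a trace of 10).
    """

    n_subjects: int = 24
    conditions: tuple[str, ...] = ("A", "B")
    seed: int = 0
    p: int = 10
    target_first_eigenvalue_fraction: float = 0.84
    factor_loadings: np.ndarray | None = None  # default sqrt(rho) everywhere
    second_factor_loadings: np.ndarray | None = None
    noise_sd: np.ndarray | None = None  # default sqrt(1 - w^2 - w2^2)
    duplicate_pairs: list[tuple[int, int]] = field(
        default_factory=lambda: list(DEFAULT_DUPLICATE_PAIRS)
    )
    condition_effect: float = 0.0  # latent-factor mean shift between conditions
    col_names: list[str] | None = None

    def resolve(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Loadings (w1, w2) and noise SDs implied by the spec; validates
        feasibility."""
        p = self.p
        t = self.target_first_eigenvalue_fraction
        if self.factor_loadings is None:
            if not 1.0 / p < t < 1.0:
                raise ValueError(
                    f"target first-eigenvalue fraction must be in (1/p, 1), got {t}"
                )
            rho = (p * t - 1.0) / (p - 1.0)
            w1 = np.full(p, np.sqrt(rho))
        else:
            w1 = np.asarray(self.factor_loadings, dtype=float)
            if w1.shape != (p,):
                raise ValueError("factor_loadings must have length p")
        w2 = (
            np.zeros(p)
            if self.second_factor_loadings is None
            else np.asarray(self.second_factor_loadings, dtype=float)
        )
        if w2.shape != (p,):
            raise ValueError("second_factor_loadings must have length p")
        if self.noise_sd is None:
            resid = 1.0 - w1**2 - w2**2
            if np.any(resid <= 0):
                raise ValueError(
                    "infeasible loadings: w1^2 + w2^2 >= 1 for some column"
                )
            s = np.sqrt(resid)
        else:
            s = np.asarray(self.noise_sd, dtype=float)
            if s.shape != (p,) or np.any(s < 0):
                raise ValueError("noise_sd must be p nonnegative values")
        return w1, w2, s


def two_factor_spec(seed: int = 0, **kwargs) -> SyntheticSpec:
    """Spec with the weak beta-vs-theta second factor.

    Calibrated so the population eigenvalues mirror an occipital-EEG feature
    table: first factor ~7.8-8.4 (overall amplitude), second factor
    ``4 * 0.185 = 0.74`` concentrated on a contrast between the beta
    (positive) and theta (negative) band columns.
    """
    p = kwargs.pop("p", 10)
    w1 = np.full(p, np.sqrt(0.78))
    w2 = np.zeros(p)
    w2[list(_BETA_COLS)] = np.sqrt(0.185)
    w2[list(_THETA_COLS)] = -np.sqrt(0.185)
    return SyntheticSpec(
        seed=seed,
        p=p,
        factor_loadings=w1,
        second_factor_loadings=w2,
        **kwargs,
    )


def synth_feature_matrix(spec: SyntheticSpec) -> DataMatrix:
    """Draw a feature matrix from the latent-factor model.

    Rows are ordered subject-major (``S01_A, S01_B, S02_A, ...``). Each
    subject has its own random substream (seeded by ``(seed, subject)``), so
    adding subjects never changes existing rows. Duplicate pairs are exact
    copies, hence Spearman rho = 1.00 after any monotone transform.
    """
    w1, w2, s = spec.resolve()
    p = spec.p
    n_cond = len(spec.conditions)
    rows = np.empty((spec.n_subjects * n_cond, p))
    row_ids = []
    shifts = spec.condition_effect * (
        np.arange(n_cond) - (n_cond - 1) / 2.0
    )  # symmetric condition offsets on the latent factor
    for i in range(spec.n_subjects):
        rng = np.random.default_rng([spec.seed, i])
        for c, cond in enumerate(spec.conditions):
            f = rng.normal() + shifts[c]
            g = rng.normal()
            e = rng.normal(size=p)
            rows[i * n_cond + c] = w1 * f + w2 * g + s * e
            row_ids.append(f"S{i + 1:02d}_{cond}")
    for a, b in spec.duplicate_pairs:
        rows[:, b] = rows[:, a]
    names = spec.col_names
    if names is None:
        names = (
            list(FEATURE_COLUMNS)
            if p == len(FEATURE_COLUMNS)
            else [f"v{j + 1}" for j in range(p)]
        )
    return DataMatrix(values=rows, row_ids=row_ids, col_names=names)


@dataclass
class EEGSubjectParams:
    """Per-subject parameters of the EEG signal generator (amplitudes in uV)."""

    peak_freq: float  # alpha peak (Hz); may sit exactly on the 8 Hz boundary
    alpha_amp_closed: float
    alpha_amp_open: float
    beta_freq: float
    beta_amp: float
    theta_freq: float
    theta_amp: float
    background_amp: float
    skew_coef: float  # strength of the quadratic waveform asymmetry


def draw_subject_params(
    seed: int, subject_index: int, boundary_peak_prob: float = 1.0 / 24.0
) -> EEGSubjectParams:
    """Draw one subject's generator parameters from the master seed.

    A shared latent ``u`` scales every amplitude (lognormally) and shifts the
    asymmetry coefficient, so that amplitude, power, and skewness features
    all increase together across subjects.
    """
    rng = np.random.default_rng([seed, subject_index])
    u = rng.normal()
    scale = float(np.exp(0.45 * u))
    peak = 8.0 if rng.random() < boundary_peak_prob else float(rng.uniform(8.0, 13.0))
    return EEGSubjectParams(
        peak_freq=peak,
        alpha_amp_closed=18.0 * scale * float(rng.uniform(0.85, 1.15)),
        alpha_amp_open=7.0 * scale * float(rng.uniform(0.85, 1.15)),
        beta_freq=float(rng.uniform(15.0, 25.0)),
        beta_amp=3.0 * scale * float(rng.uniform(0.8, 1.2)),
        theta_freq=float(rng.uniform(5.0, 7.0)),
        theta_amp=4.0 * scale * float(rng.uniform(0.8, 1.2)),
        background_amp=9.0 * scale,
        skew_coef=float(0.04 + 0.04 * u),
    )


def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance noise with a 1/f power spectrum (power ~ f^-1)."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** -0.5
    x = np.fft.irfft(spec * shaping, n=n)
    return x / x.std()


def synth_eeg(
    params: EEGSubjectParams,
    condition: str,
    fs: float = 400.0,
    duration_s: float = 155.0,
    seed: int = 0,
    subject_index: int = 0,
) -> np.ndarray:
    """One synthetic single-channel recording (uV) for one condition.

    Condition ``"A"`` is eyes closed (full alpha amplitude); any other
    condition uses the attenuated open-eyes alpha amplitude. The alpha
    rhythm's envelope waxes and wanes slowly, as real posterior alpha does.
    Deterministic given (seed, subject_index, condition).
    """
    n = int(round(duration_s * fs))
    rng = np.random.default_rng([seed, subject_index, _condition_key(condition)])
    t = np.arange(n) / fs
    alpha_amp = params.alpha_amp_closed if condition == "A" else params.alpha_amp_open
    envelope = 1.0 + 0.4 * np.sin(2 * np.pi * 0.23 * t + rng.uniform(0, 2 * np.pi))
    x = params.background_amp * _one_over_f_noise(rng, n, fs)
    x = x + alpha_amp * envelope * np.sin(
        2 * np.pi * params.peak_freq * t + rng.uniform(0, 2 * np.pi)
    )
    x = x + params.beta_amp * np.sin(
        2 * np.pi * params.beta_freq * t + rng.uniform(0, 2 * np.pi)
    )
    x = x + params.theta_amp * np.sin(
        2 * np.pi * params.theta_freq * t + rng.uniform(0, 2 * np.pi)
    )
    if params.skew_coef != 0.0:
        sd = x.std()
        x = x + params.skew_coef * (x**2 - np.mean(x**2)) / sd
    return x


def _condition_key(condition: str) -> int:
    # stable small integer per condition label for substream seeding
    return sum(ord(c) for c in condition) % (2**16)


def synth_eeg_study(
    n_subjects: int = 24,
    conditions: tuple[str, ...] = ("A", "B"),
    seed: int = 0,
    fs: float = 400.0,
    duration_s: float = 155.0,
    boundary_peak_prob: float = 1.0 / 24.0,
) -> list[tuple[str, str, np.ndarray]]:
    """All recordings of a study: list of (subject_id, condition, series)."""
    out = []
    for i in range(n_subjects):
        params = draw_subject_params(seed, i, boundary_peak_prob)
        for cond in conditions:
            series = synth_eeg(
                params,
                cond,
                fs=fs,
                duration_s=duration_s,
                seed=seed,
                subject_index=i,
            )
            out.append((f"S{i + 1:02d}", cond, series))
    return out
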