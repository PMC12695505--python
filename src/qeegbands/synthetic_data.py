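"""Seeded synthetic EEG cohort generator.

Each channel is 1/f (pink) background noise plus four band-limited
oscillators realized as spectrally shaped Gaussian noise, so within-band
power has realistic spread. Oscillator amplitudes carry per-subject and
per-visit lognormal variability and configurable multiplicative
(group, band) effects at the second visit. Cognitive scores are linear in
the subject-visit's realized whole-scalp relative alpha (positive
direction for performance scores) and relative delta (negative), plus
Gaussian noise, with configurable missing CANTAB cells.

Everything is reproducible from ``CohortConfig.seed``: each
(subject, visit) recording draws from its own deterministic substream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from qeegbands.eeg_io import EEGRecording, GROUPS, default_montage, write_recording
from qeegbands.spectral import CANONICAL_BANDS, relative_band_power, welch_psd

__all__ = [
    "Oscillator",
    "ScoreModel",
    "CohortConfig",
    "Cohort",
    "generate_recording",
    "generate_cohort",
    "write_cohort",
    "simulate_within_subject_changes",
]


@dataclass(frozen=True)
class Oscillator:
    """A band-limited noise component: Gaussian spectral bump at ``center_hz``."""

    center_hz: float
    bandwidth_hz: float
    amplitude_uv: float  # RMS in microvolts

    def __post_init__(self) -> None:
        if self.amplitude_uv < 0:
            raise ValueError("oscillator amplitude must be non-negative")
        if self.bandwidth_hz <= 0 or self.center_hz <= 0:
            raise ValueError("oscillator centre and bandwidth must be positive")


@dataclass(frozen=True)
class ScoreModel:
    """score = intercept + alpha_coef * rel_alpha + delta_coef * rel_delta + N(0, sd)."""

    intercept: float
    alpha_coef: float
    delta_coef: float
    noise_sd: float


#: Eyes-closed resting defaults: posterior-dominant alpha, pink background.
DEFAULT_OSCILLATORS: Mapping[str, Oscillator] = {
    "delta": Oscillator(2.0, 2.0, 4.0),
    "theta": Oscillator(6.0, 2.0, 3.0),
    "alpha": Oscillator(10.0, 2.0, 6.0),
    "beta": Oscillator(20.0, 6.0, 2.0),
}

#: Performance tests load positively on alpha and negatively on delta;
#: timed/severity scales (TMT, HAM-A/D, reaction time) run the other way.
DEFAULT_SCORE_MODELS: Mapping[str, ScoreModel] = {
    "MoCA": ScoreModel(20.0, 30.0, -15.0, 1.0),
    "Stroop1": ScoreModel(60.0, 80.0, -40.0, 4.0),
    "Stroop2": ScoreModel(50.0, 80.0, -40.0, 4.0),
    "Stroop3": ScoreModel(30.0, 60.0, -30.0, 4.0),
    "DigitSpan": ScoreModel(10.0, 20.0, -10.0, 1.5),
    "PSI": ScoreModel(85.0, 60.0, -30.0, 5.0),
    "TMT": ScoreModel(80.0, -120.0, 60.0, 8.0),
    "HAM_A": ScoreModel(15.0, -25.0, 12.0, 2.0),
    "HAM_D": ScoreModel(14.0, -25.0, 12.0, 2.0),
    "CANTAB_RTI": ScoreModel(420.0, -300.0, 150.0, 20.0),
    "CANTAB_Multitasking": ScoreModel(700.0, -400.0, 200.0, 30.0),
    "CANTAB_OTS": ScoreModel(12.0, 18.0, -9.0, 1.2),
}

CANTAB_TESTS = ("CANTAB_RTI", "CANTAB_Multitasking", "CANTAB_OTS")


@dataclass(frozen=True)
class CohortConfig:
    """Full description of a synthetic cohort.

    ``effects`` maps group -> band -> multiplicative amplitude change at
    visit 2 (1.0 everywhere is the null). ``missingness`` is the number of
    subjects lacking CANTAB data at (visit 1, visit 2).
    """

    group_sizes: tuple[int, int, int] = (16, 15, 19)
    fs: float = 1024.0
    duration_s: float = 60.0
    noise_exponent: float = 1.0
    noise_amplitude_uv: float = 8.0
    oscillators: Mapping[str, Oscillator] = field(default_factory=lambda: dict(DEFAULT_OSCILLATORS))
    effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    score_models: Mapping[str, ScoreModel] = field(default_factory=lambda: dict(DEFAULT_SCORE_MODELS))
    missingness: tuple[int, int] = (2, 1)
    subject_sigma: float = 0.25  # lognormal SD of per-subject band amplitude
    visit_sigma: float = 0.08  # lognormal SD of per-visit amplitude jitter
    channels: tuple[str, ...] | None = None  # default: the 32-channel montage
    seed: int = 20000523

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.group_sizes):
            raise ValueError("every group needs at least 2 subjects")
        if not 0 < self.noise_exponent <= 2:
            raise ValueError("noise exponent must lie in (0, 2]")
        if self.duration_s < 2:
            raise ValueError("recordings must be at least 2 s long")
        for group in self.effects:
            if group not in GROUPS:
                raise ValueError(f"unknown group {group!r} in effects")

    def subjects(self) -> pd.DataFrame:
        """Subject roster: subject_id (S01..), group; fixed ordering."""
        rows = []
        idx = 0
        for group, n in zip(GROUPS, self.group_sizes):
            for _ in range(n):
                idx += 1
                rows.append((f"S{idx:02d}", group))
        return pd.DataFrame(rows, columns=["subject_id", "group"])

    def channel_labels(self) -> tuple[str, ...]:
        return self.channels if self.channels is not None else default_montage().labels


def _subject_index(config: CohortConfig, subject_id: str) -> tuple[int, str]:
    roster = config.subjects()
    match = roster.index[roster["subject_id"] == subject_id]
    if len(match) == 0:
        raise KeyError(f"unknown subject {subject_id!r}")
    i = int(match[0])
    return i, roster.at[i, "group"]


def _pink_noise(rng: np.random.Generator, n_ch: int, n: int, fs: float, beta: float) -> np.ndarray:
    """Unit-RMS 1/f^beta noise per channel via spectral shaping."""
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, 1 / fs)
    weight = np.zeros_like(freqs)
    weight[1:] = freqs[1:] ** (-beta / 2)
    shaped = np.fft.irfft(spec * weight, n=n, axis=1)
    rms = shaped.std(axis=1, keepdims=True)
    return shaped / np.where(rms > 0, rms, 1.0)


def _narrowband_noise(
    rng: np.random.Generator, n_ch: int, n: int, fs: float, center: float, bandwidth: float
) -> np.ndarray:
    """Unit-RMS Gaussian-bump band noise centred at ``center`` Hz."""
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, 1 / fs)
    sigma = bandwidth / 2.0
    weight = np.exp(-0.5 * ((freqs - center) / sigma) ** 2)
    shaped = np.fft.irfft(spec * weight, n=n, axis=1)
    rms = shaped.std(axis=1, keepdims=True)
    return shaped / np.where(rms > 0, rms, 1.0)


def _subject_band_jitter(config: CohortConfig, subject_idx: int) -> dict[str, float]:
    rng = np.random.default_rng((config.seed, 7001, subject_idx))
    return {
        band: float(np.exp(rng.normal(0.0, config.subject_sigma)))
        for band in config.oscillators
    }


def generate_recording(config: CohortConfig, subject_id: str, visit: str) -> EEGRecording:
    """Deterministic synthetic recording for one subject-visit.

    The same (config, subject, visit) always yields identical samples.
    """
    if visit not in ("V1", "V2"):
        raise ValueError(f"visit must be 'V1' or 'V2', got {visit!r}")
    subject_idx, group = _subject_index(config, subject_id)
    visit_idx = 0 if visit == "V1" else 1
    n = int(round(config.duration_s * config.fs))
    labels = config.channel_labels()
    n_ch = len(labels)

    rng = np.random.default_rng((config.seed, subject_idx, visit_idx))
    data = config.noise_amplitude_uv * _pink_noise(rng, n_ch, n, config.fs, config.noise_exponent)
    subject_jitter = _subject_band_jitter(config, subject_idx)
    group_effects = config.effects.get(group, {})
    for band, osc in config.oscillators.items():
        amp = osc.amplitude_uv * subject_jitter[band]
        amp *= float(np.exp(rng.normal(0.0, config.visit_sigma)))
        if visit == "V2":
            amp *= float(group_effects.get(band, 1.0))
        if amp <= 0:
            continue
        data += amp * _narrowband_noise(rng, n_ch, n, config.fs, osc.center_hz, osc.bandwidth_hz)

    return EEGRecording(
        fs=config.fs, channels=list(labels), data=data,
        subject_id=subject_id, group=group, visit=visit,
    )


@dataclass
class Cohort:
    """An in-memory synthetic cohort: recordings plus tabular metadata."""

    config: CohortConfig
    recordings: dict[tuple[str, str], EEGRecording]
    metadata: pd.DataFrame  # subject_id, group, visit
    scores: pd.DataFrame  # subject_id, visit, one column per test


def _realized_whole_scalp_fractions(rec: EEGRecording) -> pd.Series:
    ps = welch_psd(rec)
    rel = relative_band_power(ps, CANONICAL_BANDS)
    return rel.mean(axis=0)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate every subject-visit recording plus metadata and scores.

    Scores are linear in the realized whole-scalp relative alpha and delta
    of the corresponding recording; CANTAB cells are blanked for the
    configured number of subjects at each visit.
    """
    roster = config.subjects()
    if roster["subject_id"].duplicated().any():
        raise ValueError("duplicate subject ids in roster")

    recordings: dict[tuple[str, str], EEGRecording] = {}
    meta_rows, score_rows = [], []
    score_rng = np.random.default_rng((config.seed, 9001))
    for _, row in roster.iterrows():
        for visit in ("V1", "V2"):
            rec = generate_recording(config, row.subject_id, visit)
            recordings[(row.subject_id, visit)] = rec
            meta_rows.append((row.subject_id, row.group, visit))
            fractions = _realized_whole_scalp_fractions(rec)
            scores = {"subject_id": row.subject_id, "visit": visit}
            for test, model in config.score_models.items():
                scores[test] = (
                    model.intercept
                    + model.alpha_coef * fractions["alpha"]
                    + model.delta_coef * fractions["delta"]
                    + model.noise_sd * score_rng.standard_normal()
                )
            score_rows.append(scores)

    metadata = pd.DataFrame(meta_rows, columns=["subject_id", "group", "visit"])
    scores = pd.DataFrame(score_rows)

    cantab_cols = [c for c in CANTAB_TESTS if c in scores.columns]
    n_miss_v1, n_miss_v2 = config.missingness
    subject_order = roster["subject_id"].tolist()
    for visit, n_miss, offset in (("V1", n_miss_v1, 0), ("V2", n_miss_v2, n_miss_v1)):
        for subject in subject_order[offset : offset + n_miss]:
            mask = (scores["subject_id"] == subject) & (scores["visit"] == visit)
            scores.loc[mask, cantab_cols] = np.nan

    return Cohort(config=config, recordings=recordings, metadata=metadata, scores=scores)


def write_cohort(cohort: Cohort, out_dir: str | Path, dialect: str = "matrix") -> dict:
    """Write recordings plus metadata/scores CSVs; returns the file map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rec_dir = out_dir / "recordings"
    rec_dir.mkdir(exist_ok=True)
    suffix = {"matrix": ".csv", "brainvision": ".vhdr", "edf": ".edf"}[dialect]
    paths = {}
    for (subject, visit), rec in sorted(cohort.recordings.items()):
        path = rec_dir / f"{subject}_{visit}{suffix}"
        write_recording(path, rec, dialect=dialect)
        paths[f"{subject}_{visit}"] = str(path)
    meta_path = out_dir / "metadata.csv"
    scores_path = out_dir / "scores.csv"
    cohort.metadata.to_csv(meta_path, index=False)
    cohort.scores.to_csv(scores_path, index=False, float_format="%.10g")
    return {"recordings": paths, "metadata": str(meta_path), "scores": str(scores_path)}


def simulate_within_subject_changes(
    n: int, p_increase: float, rng: np.random.Generator, sd: float = 1.0
) -> np.ndarray:
    """Gaussian within-subject changes with P(change > 0) = ``p_increase``.

    Used to calibrate paired effect-size recovery: the expected paired
    Cliff's delta of such an arm is ``2 * p_increase - 1``.
    """
    if not 0 < p_increase < 1:
        raise ValueError("p_increase must lie strictly between 0 and 1")
    mean = sd * norm.ppf(p_increase)
    return rng.normal(mean, sd, size=n)
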