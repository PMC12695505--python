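"""Welch power spectral densities and relative band powers.

The analysis contract: one-sided Welch PSD with 1 s Hann windows at 50 %
overlap and constant detrending; band powers are trapezoidal integrals of
the density over each band, so a bin sitting exactly on a shared edge
(4, 8, 13 Hz) contributes half its power to each neighbouring band and
the four bands partition 0-30 Hz with no double counting. Relative
powers divide each band by the total 0-30 Hz power per channel, so the
four fractions sum to one by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from qeegbands.eeg_io import EEGRecording, Montage

__all__ = [
    "BandDefinition",
    "CANONICAL_BANDS",
    "PowerSpectrum",
    "band_power",
    "relative_band_power",
    "welch_psd",
    "zone_average",
    "zone_table",
]

SPECTRUM_LO_HZ = 0.0
SPECTRUM_HI_HZ = 30.0


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band ``[lo, hi]`` with half-weight shared edges."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name!r}: lo must be < hi, got [{self.lo}, {self.hi}]")

    def weights(self, freqs: np.ndarray) -> np.ndarray:
        """Trapezoid integration weights: 1 inside, 0.5 on an edge bin."""
        w = np.zeros(freqs.shape)
        w[(freqs > self.lo) & (freqs < self.hi)] = 1.0
        w[np.isclose(freqs, self.lo) | np.isclose(freqs, self.hi)] = 0.5
        return w

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        return self.weights(freqs) > 0


#: delta 0-4, theta 4-8, alpha 8-13, beta 13-30; shared edges split evenly.
CANONICAL_BANDS = (
    BandDefinition("delta", 0.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
)

BAND_NAMES = tuple(b.name for b in CANONICAL_BANDS)


@dataclass
class PowerSpectrum:
    """Per-channel one-sided power density on a uniform frequency grid."""

    freqs: np.ndarray
    power: np.ndarray  # channels x freqs, uV^2/Hz
    channels: list[str]
    window_s: float
    overlap: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.power.ndim != 2 or self.power.shape[1] != self.freqs.size:
            raise ValueError("power must be channels x freqs")
        if len(self.channels) != self.power.shape[0]:
            raise ValueError("one label per power row required")
        if np.any(self.power < 0):
            raise ValueError("power density cannot be negative")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def welch_psd(rec: EEGRecording, window_s: float = 1.0, overlap: float = 0.5) -> PowerSpectrum:
    """Welch PSD with Hann taper and constant per-segment detrending.

    The frequency resolution is ``1 / window_s``. Raises ``ValueError``
    for recordings shorter than one window or an overlap outside [0, 1).
    """
    if not 0 <= overlap < 1:
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    nperseg = int(round(window_s * rec.fs))
    if rec.n_samples < nperseg:
        raise ValueError(
            f"recording of {rec.duration_s:.3f} s is shorter than one {window_s} s window"
        )
    freqs, power = signal.welch(
        rec.data,
        fs=rec.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(nperseg * overlap)),
        detrend="constant",
        scaling="density",
        axis=1,
    )
    return PowerSpectrum(
        freqs=freqs, power=power, channels=list(rec.channels), window_s=window_s, overlap=overlap
    )


def band_power(ps: PowerSpectrum, band: BandDefinition) -> np.ndarray:
    """Absolute band power per channel: trapezoidal sum of ``power * df``.

    Bins on a band edge count half, so adjacent bands sharing an edge
    never double-count a bin.
    """
    weights = band.weights(ps.freqs)
    if not weights.any():
        raise ValueError(f"no frequency bins fall inside band {band.name!r} [{band.lo}, {band.hi}]")
    return ps.power @ weights * ps.df


def relative_band_power(
    ps: PowerSpectrum, bands: tuple[BandDefinition, ...] = CANONICAL_BANDS
) -> pd.DataFrame:
    """Per-channel band fractions of total analysed-spectrum power.

    Returns a DataFrame indexed by channel with one column per band;
    each row sums to 1. Raises if any channel has zero total power.
    """
    absolute = np.column_stack([band_power(ps, band) for band in bands])
    total = absolute.sum(axis=1)
    dead = np.asarray(total <= 0).nonzero()[0]
    if dead.size:
        names = [ps.channels[i] for i in dead]
        raise ValueError(f"zero total power in 0-30 Hz on channel(s) {names}")
    fractions = absolute / total[:, None]
    return pd.DataFrame(fractions, index=pd.Index(ps.channels, name="channel"),
                        columns=[band.name for band in bands])


def zone_average(rel: pd.DataFrame, montage: Montage, zone: str) -> pd.Series:
    """Unweighted mean of per-channel band fractions over a zone's electrodes."""
    members = montage.zone(zone)
    missing = [m for m in members if m not in rel.index]
    if missing:
        raise ValueError(f"zone {zone!r} electrodes absent from recording: {missing}")
    return rel.loc[list(members)].mean(axis=0)


def zone_table(rel: pd.DataFrame, montage: Montage) -> pd.DataFrame:
    """All zone averages as a zones x bands DataFrame."""
    rows = {zone: zone_average(rel, montage, zone) for zone in montage.zone_names}
    out = pd.DataFrame(rows).T
    out.index.name = "zone"
    return out
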