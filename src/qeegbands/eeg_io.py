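"""EEG recording containers, file formats, montage, and preprocessing.

Three interchangeable on-disk dialects are supported:

``matrix``
    Plain text. One header line ``fs,label1,label2,...`` followed by one
    sample per row (comma-separated, channels in header order). Lossless
    for float64 and the default fixture format.
``brainvision``
    The BrainVision triplet: an ASCII ``.vhdr`` header, a binary
    multiplexed ``.eeg`` data file (IEEE float32, little-endian) and a
    ``.vmrk`` marker file. Markers are passed through, not interpreted.
``edf``
    European Data Format (16-bit). Quantized to the per-channel physical
    range, so round-trips are exact only up to the 16-bit step.

Preprocessing implements the fixed analysis contract: polyphase
downsampling, average re-referencing, and a zero-phase 50 Hz IIR notch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import signal

__all__ = [
    "GROUPS",
    "VISITS",
    "EEGRecording",
    "Montage",
    "default_montage",
    "load_montage",
    "read_recording",
    "write_recording",
    "preprocess",
    "read_metadata",
    "read_scores",
]

#: Canonical treatment-arm codes.
GROUPS = ("CRB_rTMS", "CRB_sham", "PLC_sham")
#: Canonical visit codes (baseline, final).
VISITS = ("V1", "V2")

REQUIRED_METADATA_COLUMNS = ("subject_id", "group", "visit")


@dataclass
class EEGRecording:
    """A channels x samples block of EEG in microvolts.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz, strictly positive.
    channels : sequence of str
        Unique channel labels, one per data row.
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    subject_id, group, visit : str or None
        Cohort annotations; ``group``/``visit`` are validated against the
        canonical code lists when present.
    """

    fs: float
    channels: list[str]
    data: np.ndarray
    subject_id: str | None = None
    group: str | None = None
    visit: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        self.channels = [str(c) for c in self.channels]
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel labels for {self.data.shape[0]} data rows"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if self.group is not None and self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.visit is not None and self.visit not in VISITS:
            raise ValueError(f"unknown visit {self.visit!r}; expected one of {VISITS}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class Montage:
    """An electrode set with named scalp-zone groupings.

    ``zones`` maps zone name -> tuple of member labels. ``whole_scalp``
    always denotes the full label set and is added automatically.
    """

    labels: tuple[str, ...]
    zones: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        label_set = set(self.labels)
        if len(label_set) != len(self.labels):
            raise ValueError("montage labels must be unique")
        zones = {name: tuple(members) for name, members in self.zones.items()}
        for name, members in zones.items():
            unknown = [m for m in members if m not in label_set]
            if unknown:
                raise ValueError(f"zone {name!r} references unknown electrodes {unknown}")
        zones["whole_scalp"] = tuple(self.labels)
        object.__setattr__(self, "zones", zones)

    @property
    def zone_names(self) -> tuple[str, ...]:
        return tuple(self.zones)

    def zone(self, name: str) -> tuple[str, ...]:
        try:
            return self.zones[name]
        except KeyError:
            raise KeyError(f"unknown zone {name!r}; known zones: {sorted(self.zones)}") from None


def load_montage(path: str | Path) -> Montage:
    """Load a montage from a YAML file with ``labels`` and ``zones`` keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return Montage(labels=tuple(raw["labels"]), zones={k: tuple(v) for k, v in raw.get("zones", {}).items()})


def default_montage() -> Montage:
    """The packaged 32-channel 10-20 montage with conventional lobe zones."""
    ref = resources.files("qeegbands").joinpath("data/zones.yaml")
    raw = yaml.safe_load(ref.read_text())
    return Montage(labels=tuple(raw["labels"]), zones={k: tuple(v) for k, v in raw["zones"].items()})


def _canonical_label_map() -> dict[str, str]:
    return {label.lower(): label for label in default_montage().labels}


def normalize_labels(labels: Sequence[str]) -> list[str]:
    """Map labels case-insensitively onto canonical 10-20 spellings.

    Unknown labels are kept verbatim with a warning.
    """
    canon = _canonical_label_map()
    out = []
    for label in labels:
        stripped = label.strip()
        if stripped.lower() in canon:
            out.append(canon[stripped.lower()])
        else:
            warnings.warn(f"channel label {label!r} is not a known 10-20 electrode; kept as-is")
            out.append(stripped)
    return out


# ---------------------------------------------------------------------------
# matrix dialect


def _write_matrix(path: Path, rec: EEGRecording) -> None:
    header = ",".join([repr(float(rec.fs))] + rec.channels)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, rec.data.T, fmt="%.17g", delimiter=",")


def _read_matrix(path: Path) -> EEGRecording:
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        fs = float(header[0])
        labels = normalize_labels(header[1:])
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    return EEGRecording(fs=fs, channels=labels, data=data.T)


# ---------------------------------------------------------------------------
# BrainVision triplet


def _write_brainvision(vhdr_path: Path, rec: EEGRecording) -> None:
    stem = vhdr_path.with_suffix("")
    eeg_path, vmrk_path = stem.with_suffix(".eeg"), stem.with_suffix(".vmrk")
    sampling_interval_us = 1e6 / rec.fs
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_path.name}",
        f"MarkerFile={vmrk_path.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={sampling_interval_us!r}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, label in enumerate(rec.channels, start=1):
        lines.append(f"Ch{i}={label},,1,µV")
    vhdr_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    vmrk_path.write_text(
        "Brain Vision Data Exchange Marker File, Version 1.0\n\n"
        "[Common Infos]\nCodepage=UTF-8\n"
        f"DataFile={eeg_path.name}\n\n"
        "[Marker Infos]\nMk1=New Segment,,1,1,0\n",
        encoding="utf-8",
    )
    rec.data.T.astype("<f4").tofile(eeg_path)


def _parse_vhdr(text: str) -> dict:
    sections: dict[str, dict[str, str]] = {}
    current: dict[str, str] | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith((";", "#")):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = sections.setdefault(line[1:-1], {})
        elif "=" in line and current is not None:
            key, _, value = line.partition("=")
            current[key.strip()] = value.strip()
    return sections


def _read_brainvision(vhdr_path: Path) -> EEGRecording:
    sections = _parse_vhdr(vhdr_path.read_text(encoding="utf-8"))
    common = sections.get("Common Infos", {})
    for key, role in (("DataFile", "data"), ("MarkerFile", "marker")):
        member = vhdr_path.parent / common.get(key, "")
        if key not in common or not member.exists():
            raise FileNotFoundError(
                f"BrainVision triplet incomplete: {role} file "
                f"{common.get(key, '<undeclared>')!r} is missing next to {vhdr_path.name}"
            )
    if common.get("DataOrientation", "MULTIPLEXED").upper() != "MULTIPLEXED":
        raise ValueError("only MULTIPLEXED BrainVision data is supported")
    binary_format = sections.get("Binary Infos", {}).get("BinaryFormat", "IEEE_FLOAT_32")
    dtype = {"IEEE_FLOAT_32": "<f4", "INT_16": "<i2", "INT_32": "<i4"}.get(binary_format)
    if dtype is None:
        raise ValueError(f"unsupported BrainVision BinaryFormat {binary_format!r}")
    n_channels = int(common["NumberOfChannels"])
    fs = 1e6 / float(common["SamplingInterval"])
    chan_section = sections.get("Channel Infos", {})
    labels, resolutions = [], []
    for i in range(1, n_channels + 1):
        parts = chan_section.get(f"Ch{i}", f"Ch{i}").split(",")
        labels.append(parts[0])
        resolutions.append(float(parts[2]) if len(parts) > 2 and parts[2] else 1.0)
    raw = np.fromfile(vhdr_path.parent / common["DataFile"], dtype=dtype)
    if raw.size % n_channels:
        raise ValueError("BrainVision data size is not a multiple of the channel count")
    data = raw.reshape(-1, n_channels).T.astype(np.float64)
    data *= np.asarray(resolutions)[:, None]
    return EEGRecording(fs=fs, channels=normalize_labels(labels), data=data)


# ---------------------------------------------------------------------------
# EDF (one data record covering the whole signal; 16-bit quantization)


def _edf_field(value, width: int) -> bytes:
    text = f"{value}"[:width]
    return text.ljust(width).encode("ascii")


def _write_edf(path: Path, rec: EEGRecording) -> None:
    ns = rec.n_channels
    n_samp = rec.n_samples
    record_duration = n_samp / rec.fs
    phys_min = rec.data.min(axis=1)
    phys_max = rec.data.max(axis=1)
    flat = phys_max - phys_min < 1e-12
    phys_min = np.where(flat, phys_min - 1.0, phys_min)
    phys_max = np.where(flat, phys_max + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767

    header = b"".join(
        [
            _edf_field(0, 8),
            _edf_field(rec.subject_id or "X", 80),
            _edf_field("qeegbands", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(256 * (1 + ns), 8),
            _edf_field("", 44),
            _edf_field(1, 8),  # one data record
            _edf_field(f"{record_duration:.6g}", 8),
            _edf_field(ns, 4),
        ]
    )
    header += b"".join(_edf_field(label, 16) for label in rec.channels)
    header += b"".join(_edf_field("", 80) for _ in range(ns))  # transducer
    header += b"".join(_edf_field("uV", 8) for _ in range(ns))
    header += b"".join(_edf_field(f"{v:.8g}"[:8], 8) for v in phys_min)
    header += b"".join(_edf_field(f"{v:.8g}"[:8], 8) for v in phys_max)
    header += b"".join(_edf_field(dig_min, 8) for _ in range(ns))
    header += b"".join(_edf_field(dig_max, 8) for _ in range(ns))
    header += b"".join(_edf_field("", 80) for _ in range(ns))  # prefiltering
    header += b"".join(_edf_field(n_samp, 8) for _ in range(ns))
    header += b"".join(_edf_field("", 32) for _ in range(ns))

    # physical -> digital, sequential per channel within the single record
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint((rec.data - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        digital.tofile(fh)


def _read_edf(path: Path) -> EEGRecording:
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError(f"{path} is not a valid EDF file (truncated header)")
        n_records = int(head[236:244].decode("ascii").strip())
        record_duration = float(head[244:252].decode("ascii").strip())
        ns = int(head[252:256].decode("ascii").strip())
        sig = fh.read(256 * ns)
        # fixed layout offsets (bytes within the per-signal header block):
        # label 16, transducer 80, dimension 8, phys_min 8, phys_max 8,
        # dig_min 8, dig_max 8, prefilter 80, samples_per_record 8, reserved 32
        offsets = {}
        pos = 0
        for name, width in [
            ("label", 16),
            ("transducer", 80),
            ("dimension", 8),
            ("phys_min", 8),
            ("phys_max", 8),
            ("dig_min", 8),
            ("dig_max", 8),
            ("prefilter", 80),
            ("n_samples", 8),
            ("reserved", 32),
        ]:
            offsets[name] = (pos, width)
            pos += width * ns

        def col(name: str) -> list[str]:
            start, width = offsets[name]
            return [
                sig[start + i * width : start + (i + 1) * width].decode("ascii").strip()
                for i in range(ns)
            ]

        labels = col("label")
        phys_min = np.array([float(v) for v in col("phys_min")])
        phys_max = np.array([float(v) for v in col("phys_max")])
        dig_min = np.array([float(v) for v in col("dig_min")])
        dig_max = np.array([float(v) for v in col("dig_max")])
        samples_per_record = np.array([int(v) for v in col("n_samples")])
        raw = np.fromfile(fh, dtype="<i2")

    total_per_record = samples_per_record.sum()
    if raw.size < n_records * total_per_record:
        raise ValueError(f"{path}: EDF data shorter than the header declares")
    raw = raw[: n_records * total_per_record]
    chunks: list[list[np.ndarray]] = [[] for _ in range(ns)]
    pos = 0
    for _ in range(n_records):
        for i in range(ns):
            chunks[i].append(raw[pos : pos + samples_per_record[i]])
            pos += samples_per_record[i]
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    data = np.vstack(
        [np.concatenate(chunks[i]) * scale[i] + phys_min[i] - dig_min[i] * scale[i] for i in range(ns)]
    )
    fs = samples_per_record[0] / record_duration
    return EEGRecording(fs=fs, channels=normalize_labels(labels), data=data)


# ---------------------------------------------------------------------------
# dispatch

_DIALECTS = ("matrix", "brainvision", "edf")


def _infer_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".vhdr":
        return "brainvision"
    if suffix == ".edf":
        return "edf"
    return "matrix"


def read_recording(path: str | Path, dialect: str | None = None) -> EEGRecording:
    """Read an EEG recording; dialect is inferred from the extension if omitted."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such recording: {path}")
    dialect = dialect or _infer_dialect(path)
    if dialect == "matrix":
        return _read_matrix(path)
    if dialect == "brainvision":
        return _read_brainvision(path)
    if dialect == "edf":
        return _read_edf(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")


def write_recording(path: str | Path, rec: EEGRecording, dialect: str | None = None) -> Path:
    """Write ``rec`` to ``path``; returns the primary file written."""
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "matrix":
        _write_matrix(path, rec)
    elif dialect == "brainvision":
        _write_brainvision(path, rec)
    elif dialect == "edf":
        _write_edf(path, rec)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    return path


# ---------------------------------------------------------------------------
# preprocessing


def preprocess(
    rec: EEGRecording,
    target_fs: float = 512.0,
    notch_hz: float | None = 50.0,
    bandpass: tuple[float, float] = (0.5, 40.0),
    apply_bandpass: bool = False,
    notch_quality: float = 30.0,
) -> EEGRecording:
    """Downsample, average-reference and notch-filter a recording.

    Steps, in order: polyphase resampling to ``target_fs`` (no upsampling),
    average re-referencing (the instantaneous cross-channel mean is
    subtracted at every sample), and a zero-phase second-order IIR notch at
    ``notch_hz``. The acquisition band-pass is only re-applied when
    ``apply_bandpass`` is set, for raw inputs.

    Raises
    ------
    ValueError
        If ``target_fs`` exceeds the input rate or fewer than two channels
        are present (the average reference is undefined).
    """
    if target_fs > rec.fs:
        raise ValueError(f"cannot upsample: target {target_fs} Hz > input {rec.fs} Hz")
    if rec.n_channels < 2:
        raise ValueError("average reference requires at least 2 channels")

    data = rec.data
    fs = rec.fs
    if target_fs != fs:
        ratio = Fraction(target_fs / fs).limit_denominator(10000)
        data = signal.resample_poly(data, ratio.numerator, ratio.denominator, axis=1)
        fs = float(target_fs)

    data = data - data.mean(axis=0, keepdims=True)

    if apply_bandpass:
        low, high = bandpass
        if not 0 < low < high < fs / 2:
            raise ValueError(f"band-pass {bandpass} invalid for fs={fs}")
        sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
        data = signal.sosfiltfilt(sos, data, axis=1)

    if notch_hz is not None and notch_hz < fs / 2:
        b, a = signal.iirnotch(notch_hz, Q=notch_quality, fs=fs)
        data = signal.filtfilt(b, a, data, axis=1)

    return replace(rec, fs=fs, data=data)


# ---------------------------------------------------------------------------
# tabular metadata


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the subject metadata CSV (subject_id, group, visit columns)."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata table {path} lacks required columns {missing}")
    bad_groups = set(df["group"]) - set(GROUPS)
    if bad_groups:
        raise ValueError(f"metadata table {path} has unknown groups {sorted(bad_groups)}")
    bad_visits = set(df["visit"]) - set(VISITS)
    if bad_visits:
        raise ValueError(f"metadata table {path} has unknown visits {sorted(bad_visits)}")
    return df


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read the neuropsychological score CSV; missing cells stay NaN."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in ("subject_id", "visit") if c not in df.columns]
    if missing:
        raise ValueError(f"score table {path} lacks required columns {missing}")
    return df
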