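"""On-disk representations of recordings, events, features, and reports.

Every pipeline stage reads and writes only these plain-text formats
(long-format TSV for time series, TSV for tables, JSON sidecars for
metadata), so real data in the documented schema can enter the pipeline at
any stage.  All writers embed a schema version; readers reject unknown
major versions.

Units: concentration-change series are stored as pathlength-scaled
concentration in uM*mm by default (optical density divided by the
differential pathlength factor only); see :mod:`nirsmci.preprocess` for the
unit switch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

SCHEMA_VERSION = "1.0"

#: Closed, case-sensitive set of group labels.
GROUPS = ("healthy", "mci")

#: Prefrontal regions covered by the montage.
REGIONS = ("left_pfc", "right_pfc")

#: Instrument range of the MoCA-K cognitive screening score, points.
MOCA_RANGE = (0, 30)

INTENSITY_COLUMNS = ["time_s", "channel", "wavelength_nm", "intensity"]
EVENT_COLUMNS = [
    "block",
    "encoding_onset_s",
    "encoding_duration_s",
    "recall_onset_s",
    "rest_onset_s",
]
FEATURE_COLUMNS = [
    "subject_id",
    "group",
    "mhbo_left",
    "mhbo_right",
    "mhbo_total",
    "moca_k",
    "vdst_score",
]
HEMO_COLUMNS = ["time_s", "channel", "hbo", "hbr"]

_FLOAT_FMT = "%.17g"  # lossless for float64 round-trips


class SchemaError(ValueError):
    """A file does not conform to the documented on-disk schema."""


def _check_version(version: str, path: Path) -> None:
    major = str(version).split(".")[0]
    if major != SCHEMA_VERSION.split(".")[0]:
        raise SchemaError(
            f"{path}: unsupported schema major version {version!r} "
            f"(reader supports {SCHEMA_VERSION})"
        )


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


def default_region_map(n_channels: int = 8) -> dict[int, str]:
    """First half of the montage on the left PFC, second half on the right."""
    half = n_channels // 2
    return {
        ch: ("left_pfc" if ch <= half else "right_pfc")
        for ch in range(1, n_channels + 1)
    }


@dataclass(frozen=True)
class AcquisitionSpec:
    """Geometry and timing of the continuous-wave fNIRS montage.

    Defaults describe an 8-channel, two-wavelength (760/850 nm) prefrontal
    band sampled at 10 Hz with 3 cm source-detector separation, split into
    4 left-PFC and 4 right-PFC channels.
    """

    sampling_rate: float = 10.0
    wavelengths: tuple[float, float] = (760.0, 850.0)
    n_channels: int = 8
    source_detector_distance: float = 3.0
    channel_region_map: Mapping[int, str] = field(default_factory=default_region_map)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.wavelengths) != 2:
            raise ValueError("exactly two wavelengths are required")
        if self.source_detector_distance <= 0:
            raise ValueError("source_detector_distance must be positive")
        channels = set(range(1, self.n_channels + 1))
        mapped = set(self.channel_region_map)
        if mapped != channels:
            raise ValueError(
                f"channel_region_map must map exactly channels {sorted(channels)}, "
                f"got {sorted(mapped)}"
            )
        bad = {r for r in self.channel_region_map.values() if r not in REGIONS}
        if bad:
            raise ValueError(f"unknown regions in channel_region_map: {sorted(bad)}")

    @property
    def channels(self) -> list[int]:
        return list(range(1, self.n_channels + 1))

    def region_channels(self, region: str) -> list[int]:
        return [ch for ch in self.channels if self.channel_region_map[ch] == region]

    def to_dict(self) -> dict:
        return {
            "sampling_rate": self.sampling_rate,
            "wavelengths": list(self.wavelengths),
            "n_channels": self.n_channels,
            "source_detector_distance": self.source_detector_distance,
            "channel_region_map": {str(k): v for k, v in self.channel_region_map.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AcquisitionSpec":
        required = {
            "sampling_rate",
            "wavelengths",
            "n_channels",
            "source_detector_distance",
            "channel_region_map",
        }
        missing = required - set(d)
        if missing:
            raise SchemaError(f"acquisition spec missing fields: {sorted(missing)}")
        return cls(
            sampling_rate=float(d["sampling_rate"]),
            wavelengths=tuple(float(w) for w in d["wavelengths"]),
            n_channels=int(d["n_channels"]),
            source_detector_distance=float(d["source_detector_distance"]),
            channel_region_map={int(k): v for k, v in d["channel_region_map"].items()},
        )


@dataclass(frozen=True)
class EventTable:
    """Block-design event schedule, seconds from recording start.

    Events are half-open intervals [onset, onset + duration).  One record
    per task block: digit-sequence encoding, verbal recall, inter-block
    rest.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        missing = [c for c in EVENT_COLUMNS if c not in f.columns]
        if missing:
            raise SchemaError(f"event table missing columns: {missing}")
        onsets = f["encoding_onset_s"].to_numpy(float)
        if len(onsets) and not np.all(np.diff(onsets) > 0):
            raise ValueError("encoding onsets must be strictly increasing")
        per_block = np.column_stack(
            [
                onsets,
                f["recall_onset_s"].to_numpy(float),
                f["rest_onset_s"].to_numpy(float),
            ]
        )
        if len(onsets) and not np.all(np.diff(per_block, axis=1) > 0):
            raise ValueError("within each block, encoding < recall < rest onset")

    @property
    def n_blocks(self) -> int:
        return len(self.frame)

    @property
    def encoding_onsets(self) -> np.ndarray:
        return self.frame["encoding_onset_s"].to_numpy(float)

    @property
    def encoding_durations(self) -> np.ndarray:
        return self.frame["encoding_duration_s"].to_numpy(float)

    def __eq__(self, other: object) -> bool:  # pragma: no cover - trivial
        if not isinstance(other, EventTable):
            return NotImplemented
        return self.frame.reset_index(drop=True).equals(other.frame.reset_index(drop=True))


@dataclass
class RawRecording:
    """Per-subject two-wavelength intensity time series plus metadata.

    ``intensity`` is channel x wavelength x time in arbitrary detector
    units and must be strictly positive.
    """

    subject_id: str
    group: str
    acquisition: AcquisitionSpec
    events: EventTable
    intensity: np.ndarray
    moca_k: float
    vdst_score: float
    demographics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, float)
        if self.group not in GROUPS:
            raise ValueError(f"unknown group label {self.group!r}; must be one of {GROUPS}")
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be channel x wavelength x time")
        n_ch, n_wl, _ = self.intensity.shape
        if n_ch != self.acquisition.n_channels or n_wl != 2:
            raise ValueError(
                f"intensity shape {self.intensity.shape} inconsistent with "
                f"{self.acquisition.n_channels} channels x 2 wavelengths"
            )
        if np.isnan(self.intensity).any():
            raise ValueError("intensity contains NaN")
        if not (self.intensity > 0).all():
            raise ValueError("intensity must be strictly positive")
        if not (MOCA_RANGE[0] <= self.moca_k <= MOCA_RANGE[1]):
            raise ValueError(f"moca_k {self.moca_k} outside range {MOCA_RANGE}")
        if self.vdst_score < 0:
            raise ValueError("vdst_score must be non-negative")
        end = self.duration
        ev = self.events.frame
        if len(ev) and (ev["rest_onset_s"] > end).any():
            raise ValueError("events extend past the recording end")

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[2]

    @property
    def duration(self) -> float:
        return self.n_samples / self.acquisition.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.acquisition.sampling_rate


@dataclass
class HemoRecording:
    """Per-channel HbO/HbR concentration-change series with QC flags.

    Channels flagged ``rejected`` carry no values into downstream averages.
    """

    subject_id: str
    group: str
    acquisition: AcquisitionSpec
    events: EventTable
    hbo: np.ndarray
    hbr: np.ndarray
    channel_qc: dict[int, str] = field(default_factory=dict)
    unit: str = "uM*mm"
    moca_k: float = float("nan")
    vdst_score: float = float("nan")

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, float)
        self.hbr = np.asarray(self.hbr, float)
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("hbo and hbr must have the same shape")
        if self.hbo.ndim != 2:
            raise ValueError("hbo must be channel x time")
        if not self.channel_qc:
            self.channel_qc = {ch: "kept" for ch in self.acquisition.channels}
        bad = {v for v in self.channel_qc.values()} - {"kept", "rejected"}
        if bad:
            raise ValueError(f"invalid QC flags: {sorted(bad)}")

    @property
    def kept_channels(self) -> list[int]:
        return [ch for ch in self.acquisition.channels if self.channel_qc[ch] == "kept"]


# ---------------------------------------------------------------------------
# Recording I/O
# ---------------------------------------------------------------------------


def write_recording(rec: RawRecording, path: str | Path) -> list[Path]:
    """Write a raw recording as intensity.tsv + events.tsv + subject.json.

    The intensity table is long-format (time_s, channel, wavelength_nm,
    intensity); reading it back reproduces the recording to float64
    precision.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    acq = rec.acquisition
    times = rec.times
    n_t = rec.n_samples
    frames = []
    for ci, ch in enumerate(acq.channels):
        for wi, wl in enumerate(acq.wavelengths):
            frames.append(
                pd.DataFrame(
                    {
                        "time_s": times,
                        "channel": ch,
                        "wavelength_nm": wl,
                        "intensity": rec.intensity[ci, wi],
                    }
                )
            )
    intensity = pd.concat(frames, ignore_index=True)

    files = []
    p = path / "intensity.tsv"
    intensity.to_csv(p, sep="\t", index=False, float_format=_FLOAT_FMT)
    files.append(p)

    p = path / "events.tsv"
    rec.events.frame[EVENT_COLUMNS].to_csv(p, sep="\t", index=False, float_format=_FLOAT_FMT)
    files.append(p)

    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "subject_id": rec.subject_id,
        "group": rec.group,
        "moca_k": rec.moca_k,
        "vdst_score": rec.vdst_score,
        "demographics": rec.demographics,
        "acquisition": acq.to_dict(),
        "n_samples": n_t,
    }
    p = path / "subject.json"
    p.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    files.append(p)
    return files


def read_recording(path: str | Path) -> RawRecording:
    """Read and validate a recording written by :func:`write_recording`."""
    path = Path(path)
    sidecar_path = path / "subject.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(sidecar_path)
    sidecar = json.loads(sidecar_path.read_text())
    if "schema_version" not in sidecar:
        raise SchemaError(f"{sidecar_path}: missing schema_version")
    _check_version(sidecar["schema_version"], sidecar_path)
    for key in ("subject_id", "group", "moca_k", "vdst_score", "acquisition"):
        if key not in sidecar:
            raise SchemaError(f"{sidecar_path}: missing required field {key!r}")
    acq = AcquisitionSpec.from_dict(sidecar["acquisition"])

    intensity_df = pd.read_csv(path / "intensity.tsv", sep="\t", float_precision="round_trip")
    missing = [c for c in INTENSITY_COLUMNS if c not in intensity_df.columns]
    if missing:
        raise SchemaError(f"intensity.tsv missing columns: {missing}")

    n_t = int(sidecar.get("n_samples", intensity_df["time_s"].nunique()))
    intensity = np.empty((acq.n_channels, 2, n_t))
    intensity.fill(np.nan)
    for ci, ch in enumerate(acq.channels):
        for wi, wl in enumerate(acq.wavelengths):
            sel = intensity_df[
                (intensity_df["channel"] == ch) & (intensity_df["wavelength_nm"] == wl)
            ]
            if len(sel) != n_t:
                raise SchemaError(
                    f"intensity.tsv: channel {ch} wavelength {wl} has {len(sel)} "
                    f"samples, expected {n_t}"
                )
            intensity[ci, wi] = sel.sort_values("time_s")["intensity"].to_numpy()

    events = EventTable(pd.read_csv(path / "events.tsv", sep="\t", float_precision="round_trip"))
    return RawRecording(
        subject_id=str(sidecar["subject_id"]),
        group=sidecar["group"],
        acquisition=acq,
        events=events,
        intensity=intensity,
        moca_k=float(sidecar["moca_k"]),
        vdst_score=float(sidecar["vdst_score"]),
        demographics=sidecar.get("demographics", {}),
    )


def write_hemo(rec: HemoRecording, path: str | Path) -> list[Path]:
    """Write a preprocessed recording as hemo.tsv + hemo.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    times = np.arange(rec.hbo.shape[1]) / rec.acquisition.sampling_rate
    frames = []
    for ci, ch in enumerate(rec.acquisition.channels):
        frames.append(
            pd.DataFrame(
                {"time_s": times, "channel": ch, "hbo": rec.hbo[ci], "hbr": rec.hbr[ci]}
            )
        )
    df = pd.concat(frames, ignore_index=True)
    files = []
    p = path / "hemo.tsv"
    df.to_csv(p, sep="\t", index=False, float_format=_FLOAT_FMT)
    files.append(p)
    p = path / "events.tsv"
    rec.events.frame[EVENT_COLUMNS].to_csv(p, sep="\t", index=False, float_format=_FLOAT_FMT)
    files.append(p)
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "subject_id": rec.subject_id,
        "group": rec.group,
        "moca_k": rec.moca_k,
        "vdst_score": rec.vdst_score,
        "unit": rec.unit,
        "channel_qc": {str(k): v for k, v in rec.channel_qc.items()},
        "acquisition": rec.acquisition.to_dict(),
    }
    p = path / "hemo.json"
    p.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    files.append(p)
    return files


def read_hemo(path: str | Path) -> HemoRecording:
    path = Path(path)
    sidecar = json.loads((path / "hemo.json").read_text())
    _check_version(sidecar.get("schema_version", "?"), path / "hemo.json")
    acq = AcquisitionSpec.from_dict(sidecar["acquisition"])
    df = pd.read_csv(path / "hemo.tsv", sep="\t", float_precision="round_trip")
    n_t = df["time_s"].nunique()
    hbo = np.empty((acq.n_channels, n_t))
    hbr = np.empty((acq.n_channels, n_t))
    for ci, ch in enumerate(acq.channels):
        sel = df[df["channel"] == ch].sort_values("time_s")
        if len(sel) != n_t:
            raise SchemaError(f"hemo.tsv: channel {ch} has {len(sel)} samples, expected {n_t}")
        hbo[ci] = sel["hbo"].to_numpy()
        hbr[ci] = sel["hbr"].to_numpy()
    events = EventTable(pd.read_csv(path / "events.tsv", sep="\t", float_precision="round_trip"))
    return HemoRecording(
        subject_id=str(sidecar["subject_id"]),
        group=sidecar["group"],
        acquisition=acq,
        events=events,
        hbo=hbo,
        hbr=hbr,
        channel_qc={int(k): v for k, v in sidecar["channel_qc"].items()},
        unit=sidecar.get("unit", "uM*mm"),
        moca_k=float(sidecar.get("moca_k", "nan")),
        vdst_score=float(sidecar.get("vdst_score", "nan")),
    )


# ---------------------------------------------------------------------------
# Feature-table I/O
# ---------------------------------------------------------------------------


def validate_feature_table(features: pd.DataFrame) -> pd.DataFrame:
    """Validate the per-subject feature table schema; returns the frame."""
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise SchemaError(f"feature table missing columns: {missing}")
    if features["subject_id"].duplicated().any():
        dup = features.loc[features["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject_id values: {dup}")
    unknown = set(features["group"].unique()) - set(GROUPS)
    if unknown:
        raise ValueError(
            f"unknown group labels {sorted(unknown)}; labels are case-sensitive {GROUPS}"
        )
    if features["group"].isna().any():
        raise ValueError("missing group labels")
    return features


def write_feature_table(features: pd.DataFrame, path: str | Path) -> Path:
    """Write the per-subject feature table as TSV (header-stable)."""
    validate_feature_table(features)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = FEATURE_COLUMNS + [c for c in features.columns if c not in FEATURE_COLUMNS]
    features[cols].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str}, float_precision="round_trip")
    if len(df) == 0 and set(FEATURE_COLUMNS) <= set(df.columns):
        return df
    return validate_feature_table(df)
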