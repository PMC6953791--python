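"""Reading and writing alarm-episode records in PhysioNet/CinC-2015-style layouts.

A record is a WFDB header (``<id>.hea``) plus a signal file, either a
format-16 ``.dat`` (interleaved little-endian int16) or a MATLAB v4 ``.mat``
holding a ``val`` matrix, as distributed for the 2015 challenge.  Only the
subset of WFDB needed for those layouts is supported: single sampling
frequency, format 16, gain/baseline calibration.  Records are fixed at
250 Hz; other rates are rejected rather than resampled.

Channel descriptions are mapped case-insensitively onto the three modality
roles the classifier consumes: lead ``II`` -> ECG_II, ``PLETH``/``PPG`` ->
PPG, ``ABP``/``ART`` -> ABP.  Other channels (e.g. ECG lead V) are parsed and
ignored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .exceptions import SchemaError, UnsupportedRateError

REQUIRED_FS = 250.0

__all__ = [
    "AlarmType",
    "Label",
    "ChannelRole",
    "WaveformRecord",
    "LabelTable",
    "read_record",
    "write_record",
    "load_label_table",
    "load_challenge_answers",
    "quantize_channels",
]


class AlarmType(str, Enum):
    """The five life-threatening arrhythmia alarm types."""

    ASY = "ASY"  # asystole
    EBR = "EBR"  # extreme bradycardia
    ETC = "ETC"  # extreme tachycardia
    VTA = "VTA"  # ventricular tachycardia
    VFB = "VFB"  # ventricular flutter/fibrillation


class Label(str, Enum):
    TRUE_ALARM = "TRUE_ALARM"
    FALSE_ALARM = "FALSE_ALARM"
    UNKNOWN = "UNKNOWN"


class ChannelRole(str, Enum):
    ECG_II = "ECG_II"
    ABP = "ABP"
    PPG = "PPG"


#: header description token -> role (matched upper-cased)
_ROLE_ALIASES = {
    "II": ChannelRole.ECG_II,
    "PLETH": ChannelRole.PPG,
    "PPG": ChannelRole.PPG,
    "ABP": ChannelRole.ABP,
    "ART": ChannelRole.ABP,
}

#: role -> description written into headers
_ROLE_DESCRIPTION = {
    ChannelRole.ECG_II: "II",
    ChannelRole.ABP: "ABP",
    ChannelRole.PPG: "PLETH",
}

# Fixed 12-bit calibration per role (gain in adu per physical unit, baseline
# in adu).  Fixed constants make quantization idempotent, so a written record
# re-reads bit-exactly.
_CALIBRATION = {
    ChannelRole.ECG_II: (200.0, 0),  # mV, +-10.24 mV span
    ChannelRole.ABP: (10.0, -1000),  # mmHg, approx [-104, 304] mmHg span
    ChannelRole.PPG: (1000.0, 0),  # normalised units, +-2.05 span
}
_UNITS = {ChannelRole.ECG_II: "mV", ChannelRole.ABP: "mmHg", ChannelRole.PPG: "NU"}

_ALARM_COMMENT_ALIASES = {
    "ASYSTOLE": AlarmType.ASY,
    "EXTREME BRADYCARDIA": AlarmType.EBR,
    "BRADYCARDIA": AlarmType.EBR,
    "EXTREME TACHYCARDIA": AlarmType.ETC,
    "TACHYCARDIA": AlarmType.ETC,
    "VENTRICULAR TACHYCARDIA": AlarmType.VTA,
    "VENTRICULAR FLUTTER/FIBRILLATION": AlarmType.VFB,
    **{t.value: t for t in AlarmType},
}


@dataclass
class WaveformRecord:
    """One alarm episode: multichannel samples plus alarm metadata.

    ``beat_times`` / ``beat_tags`` / ``meta`` carry generator ground truth and
    are populated only by the synthetic module; records read from disk leave
    them ``None``.
    """

    record_id: str
    fs: float
    channels: dict[ChannelRole, np.ndarray]
    alarm_type: Optional[AlarmType] = None
    label: Label = Label.UNKNOWN
    onset_index: int = 0
    beat_times: Optional[np.ndarray] = None
    beat_tags: Optional[list[str]] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.onset_index == 0 and self.channels:
            self.onset_index = self.n_samples

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    def validate(self) -> None:
        if not self.channels:
            raise SchemaError(f"record {self.record_id!r} has no channels")
        if self.fs != REQUIRED_FS:
            raise UnsupportedRateError(
                f"record {self.record_id!r} sampled at {self.fs} Hz; only "
                f"{REQUIRED_FS:g} Hz records are supported"
            )
        lengths = {role: len(x) for role, x in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise SchemaError(f"channel lengths differ: {lengths}")
        if self.onset_index <= 0:
            raise SchemaError("onset_index must be positive")
        if self.n_samples < self.onset_index:
            raise SchemaError("channels shorter than onset_index")


class LabelTable:
    """Table of (record_id, alarm_type, label) rows with unique record ids."""

    def __init__(self, frame: pd.DataFrame):
        required = {"record_id", "alarm_type", "label"}
        if not required.issubset(frame.columns):
            raise SchemaError(f"label table needs columns {sorted(required)}")
        if frame["record_id"].duplicated().any():
            dups = frame.loc[frame["record_id"].duplicated(), "record_id"].tolist()
            raise SchemaError(f"duplicate record_id(s): {dups}")
        try:
            alarm = frame["alarm_type"].map(lambda s: AlarmType(str(s).strip().upper()))
            label = frame["label"].map(lambda s: Label(str(s).strip().upper()))
        except ValueError as exc:
            raise SchemaError(f"unrecognised token in label table: {exc}") from exc
        self.frame = pd.DataFrame(
            {
                "record_id": frame["record_id"].astype(str),
                "alarm_type": alarm,
                "label": label,
            }
        ).set_index("record_id", drop=False)

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, record_id: str) -> bool:
        return record_id in self.frame.index

    def get(self, record_id: str) -> tuple[AlarmType, Label]:
        row = self.frame.loc[record_id]
        return row["alarm_type"], row["label"]

    def counts(self) -> pd.DataFrame:
        """Records per (alarm_type, label), mirroring the dataset census table."""
        return (
            self.frame.groupby(["alarm_type", "label"], observed=True)
            .size()
            .unstack(fill_value=0)
        )

    def to_csv(self, path) -> None:
        out = self.frame.reset_index(drop=True).copy()
        out["alarm_type"] = out["alarm_type"].map(lambda a: a.value)
        out["label"] = out["label"].map(lambda l: l.value)
        out.to_csv(path, index=False)


def load_label_table(csv_path) -> LabelTable:
    csv_path = Path(csv_path)
    if not csv_path.exists():
        raise FileNotFoundError(csv_path)
    return LabelTable(pd.read_csv(csv_path))


#: leading letter of a Challenge-2015 record name -> alarm type
_CHALLENGE_PREFIX = {
    "a": AlarmType.ASY,
    "b": AlarmType.EBR,
    "t": AlarmType.ETC,
    "v": AlarmType.VTA,
    "f": AlarmType.VFB,
}


def load_challenge_answers(path) -> LabelTable:
    """Adapter for a Challenge-2015 answers file (``record,0|1`` lines).

    The alarm type is recovered from the record-name prefix
    (a/b/t/v/f -> ASY/EBR/ETC/VTA/VFB); 1 means true alarm.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            record_id, flag = (tok.strip() for tok in line.split(","))
        except ValueError as exc:
            raise SchemaError(f"malformed answers line {line!r}") from exc
        alarm = _CHALLENGE_PREFIX.get(record_id[0].lower())
        if alarm is None:
            raise SchemaError(f"cannot infer alarm type of record {record_id!r}")
        if flag not in {"0", "1"}:
            raise SchemaError(f"answers flag must be 0 or 1, got {flag!r}")
        label = Label.TRUE_ALARM if flag == "1" else Label.FALSE_ALARM
        rows.append((record_id, alarm.value, label.value))
    return LabelTable(pd.DataFrame(rows, columns=["record_id", "alarm_type", "label"]))


def resolve_channel_role(description: str) -> Optional[ChannelRole]:
    """Map a header channel description to a modality role (pure function)."""
    return _ROLE_ALIASES.get(description.strip().upper())


_GAIN_RE = re.compile(r"^(?P<gain>-?[\d.eE+]+)?(?:\((?P<baseline>-?\d+)\))?(?:/(?P<units>\S+))?$")


def _parse_gain(token: str) -> tuple[float, int]:
    m = _GAIN_RE.match(token)
    if m is None:
        raise SchemaError(f"cannot parse gain field {token!r}")
    gain = float(m.group("gain")) if m.group("gain") else 200.0
    if gain == 0:
        gain = 200.0  # WFDB convention: 0 means the default gain
    baseline = int(m.group("baseline")) if m.group("baseline") else 0
    return gain, baseline


def read_record(header_path, label_table: Optional[LabelTable] = None) -> WaveformRecord:
    """Read one Challenge-2015-layout record.

    The label (and alarm type) come from ``label_table`` when given; otherwise
    the alarm type is recovered from a header comment line when present and
    the label is :data:`Label.UNKNOWN`.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(header_path)
    lines = [ln.rstrip() for ln in header_path.read_text().splitlines() if ln.strip()]
    comments = [ln.lstrip("#").strip() for ln in lines if ln.startswith("#")]
    body = [ln for ln in lines if not ln.startswith("#")]
    if not body:
        raise SchemaError(f"empty header {header_path}")
    head = body[0].split()
    if len(head) < 4:
        raise SchemaError(f"malformed record line in {header_path}: {body[0]!r}")
    record_id = head[0].split("/")[0]
    n_sig = int(head[1])
    fs = float(head[2].split("/")[0])
    n_samples = int(head[3])
    if fs != REQUIRED_FS:
        raise UnsupportedRateError(
            f"{header_path.name}: {fs:g} Hz is unsupported (records must be 250 Hz)"
        )
    sig_lines = body[1 : 1 + n_sig]
    if len(sig_lines) != n_sig:
        raise SchemaError(f"{header_path}: expected {n_sig} signal lines")

    specs = []  # (filename, fmt, gain, baseline, description)
    for ln in sig_lines:
        tok = ln.split()
        if len(tok) < 3:
            raise SchemaError(f"malformed signal line {ln!r}")
        fmt = tok[1].split("x")[0].split(":")[0].split("+")[0]
        gain, baseline = _parse_gain(tok[2])
        description = " ".join(tok[8:]) if len(tok) > 8 else tok[-1]
        specs.append((tok[0], fmt, gain, baseline, description))

    raw = _read_signal_matrix(header_path.parent, specs, n_sig, n_samples)

    channels: dict[ChannelRole, np.ndarray] = {}
    for idx, (_, _, gain, baseline, description) in enumerate(specs):
        role = resolve_channel_role(description)
        if role is None or role in channels:
            continue
        channels[role] = (raw[idx].astype(np.float64) - baseline) / gain
    if not channels:
        raise SchemaError(
            f"{header_path.name}: no recognised modality channel among "
            f"{[s[4] for s in specs]}"
        )

    alarm_type, label = None, Label.UNKNOWN
    if label_table is not None and record_id in label_table:
        alarm_type, label = label_table.get(record_id)
    else:
        for comment in comments:
            hit = _ALARM_COMMENT_ALIASES.get(comment.strip().upper())
            if hit is not None:
                alarm_type = hit
                break

    rec = WaveformRecord(
        record_id=record_id,
        fs=fs,
        channels=channels,
        alarm_type=alarm_type,
        label=label,
        onset_index=n_samples,  # challenge records end at the alarm trigger
    )
    rec.validate()
    return rec


def _read_signal_matrix(directory: Path, specs, n_sig: int, n_samples: int) -> np.ndarray:
    """Return the (n_sig, n_samples) integer sample matrix."""
    filenames = {s[0] for s in specs}
    if len(filenames) != 1:
        raise SchemaError("multi-file records are not supported")
    filename = next(iter(filenames))
    path = directory / filename
    if not path.exists():
        raise FileNotFoundError(path)
    if filename.endswith(".mat"):
        from scipy.io import loadmat

        mat = loadmat(str(path))
        if "val" not in mat:
            raise SchemaError(f"{filename}: no 'val' matrix")
        raw = np.asarray(mat["val"])
    else:
        fmts = {s[1] for s in specs}
        if fmts != {"16"}:
            raise SchemaError(f"unsupported WFDB format(s) {sorted(fmts)}; only 16")
        flat = np.fromfile(path, dtype="<i2")
        if len(flat) < n_sig * n_samples:
            raise SchemaError(f"{filename}: signal file shorter than header claims")
        raw = flat[: n_sig * n_samples].reshape(n_samples, n_sig).T
    if raw.shape != (n_sig, n_samples):
        raise SchemaError(f"{filename}: shape {raw.shape} != ({n_sig}, {n_samples})")
    return raw


def _to_adc(x: np.ndarray, role: ChannelRole) -> np.ndarray:
    gain, baseline = _CALIBRATION[role]
    return np.clip(np.rint(x * gain + baseline), -32768, 32767).astype(np.int16)


def quantize_channels(channels: Mapping[ChannelRole, np.ndarray]) -> dict[ChannelRole, np.ndarray]:
    """Snap physical samples onto the fixed 12-bit ADC grid used by the writer.

    Idempotent; applying it in the generator makes write -> read an exact
    round trip.
    """
    out = {}
    for role, x in channels.items():
        gain, baseline = _CALIBRATION[role]
        out[role] = (_to_adc(np.asarray(x, dtype=np.float64), role).astype(np.float64) - baseline) / gain
    return out


def write_record(record: WaveformRecord, directory) -> tuple[Path, Path]:
    """Write ``<id>.hea`` + format-16 ``<id>.dat`` readable by :func:`read_record`.

    Deterministic: the same record always produces byte-identical files.
    """
    record.validate()
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    roles = sorted(record.channels, key=lambda r: r.value)
    n = record.n_samples
    adc = np.stack([_to_adc(np.asarray(record.channels[r], np.float64), r) for r in roles])

    dat_path = directory / f"{record.record_id}.dat"
    hea_path = directory / f"{record.record_id}.hea"
    adc.T.astype("<i2").tofile(dat_path)

    lines = [f"{record.record_id} {len(roles)} {record.fs:g} {n}"]
    for role in roles:
        gain, baseline = _CALIBRATION[role]
        lines.append(
            f"{record.record_id}.dat 16 {gain:g}({baseline})/{_UNITS[role]} "
            f"12 0 0 0 0 {_ROLE_DESCRIPTION[role]}"
        )
    if record.alarm_type is not None:
        lines.append(f"#{record.alarm_type.value}")
    hea_path.write_text("\n".join(lines) + "\n")
    return hea_path, dat_path
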