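"""Trial-log and session-manifest I/O plus the shared domain vocabulary.

A *trial* is one 30 s balance exercise recorded by a body-worn smartphone
accelerometer; a *calibration* recording is the same device resting on a level
surface with one axis vertical.  Trial logs are plain CSV streams of
timestamped triaxial samples in m/s²; a session manifest (YAML or JSON) ties
trial files to participant, exercise condition, leg and body location, and
lists the six static calibration files per device.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "CONDITIONS",
    "DIFFICULTY_ORDER",
    "CONDITION_NAMES",
    "LEGS",
    "BODY_LOCATIONS",
    "DIRECTIONS",
    "STANDARD_GRAVITY",
    "TriaxialSample",
    "Recording",
    "TrialEntry",
    "SessionManifest",
    "Session",
    "ParseError",
    "SessionValidationError",
    "read_trial_csv",
    "write_trial_csv",
    "load_session",
    "load_study",
    "expected_cells",
]

#: Exercise conditions in the order they are tested.
CONDITIONS: tuple[str, ...] = (
    "DL", "FT", "TAN", "SLS", "SLSE", "FDL", "FSLS", "FSLSE",
)

#: The same conditions ordered from least to most difficult (clinical consensus
#: order; also the device's difficulty ranking at every body location).
DIFFICULTY_ORDER: tuple[str, ...] = (
    "DL", "FT", "FDL", "TAN", "SLS", "SLSE", "FSLS", "FSLSE",
)

CONDITION_NAMES: dict[str, str] = {
    "DL": "double leg stance on ground, feet apart",
    "FT": "double leg stance on ground, feet together",
    "TAN": "tandem (one foot in front of the other)",
    "SLS": "single leg stance on ground",
    "SLSE": "single leg stance on ground, eyes closed",
    "FDL": "double leg stance on foam, feet apart",
    "FSLS": "single leg stance on foam",
    "FSLSE": "single leg stance on foam, eyes closed",
}

LEGS: tuple[str, ...] = ("left", "right")
BODY_LOCATIONS: tuple[str, ...] = ("ankle", "knee", "torso")

#: Signed axis directions used for static calibration.
DIRECTIONS: tuple[str, ...] = ("x+", "x-", "y+", "y-", "z+", "z-")

STANDARD_GRAVITY: float = 9.81  # m/s^2

_CSV_HEADER = ("t_s", "ax_ms2", "ay_ms2", "az_ms2")


class ParseError(ValueError):
    """Raised when a trial log cannot be parsed or violates its invariants."""


class SessionValidationError(ValueError):
    """Raised when a session manifest is inconsistent or incomplete."""


def _normalize_direction(d: str) -> str:
    # tolerate the unicode minus that appears in typeset protocols
    d = d.strip().replace("−", "-").lower()
    if d not in DIRECTIONS:
        raise ValueError(f"unknown calibration direction {d!r}; expected one of {DIRECTIONS}")
    return d


@dataclass(frozen=True)
class TriaxialSample:
    """One timestamped accelerometer reading (device axes, m/s²)."""

    t: float
    ax: float
    ay: float
    az: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.t) or self.t < 0:
            raise ValueError(f"sample time must be finite and non-negative, got {self.t!r}")
        for name in ("ax", "ay", "az"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"sample {name} must be finite, got {getattr(self, name)!r}")

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.ax, self.ay, self.az])


@dataclass
class Recording:
    """An ordered triaxial sample stream for one trial or one calibration pose.

    Calibration recordings carry an ``orientation`` (which signed axis points
    up) and no trial metadata; trial recordings carry condition/leg/location
    metadata and no orientation.  Trial metadata may be left unset on a bare
    recording parsed straight from CSV — the session manifest supplies it —
    but a fully tagged trial is required for session-level analysis.
    """

    device_id: str
    purpose: str  # "trial" | "calibration"
    samples: list[TriaxialSample]
    nominal_rate: float
    orientation: str | None = None
    condition: str | None = None
    leg: str | None = None
    body_location: str | None = None

    def __post_init__(self) -> None:
        if self.purpose not in ("trial", "calibration"):
            raise ValueError(f"purpose must be 'trial' or 'calibration', got {self.purpose!r}")
        if not self.samples:
            raise ValueError("Recording requires at least one sample")
        if not self.nominal_rate > 0:
            raise ValueError(f"nominal_rate must be positive, got {self.nominal_rate!r}")
        times = [s.t for s in self.samples]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("sample timestamps must be strictly increasing")
        if self.purpose == "calibration":
            if self.orientation is None:
                raise ValueError("calibration Recording requires an orientation")
            self.orientation = _normalize_direction(self.orientation)
            if self.condition or self.leg or self.body_location:
                raise ValueError("calibration Recording must not carry trial metadata")
        else:
            if self.orientation is not None:
                raise ValueError("trial Recording must not carry an orientation")
            if self.condition is not None and self.condition not in CONDITIONS:
                raise ValueError(f"unknown condition {self.condition!r}; expected one of {CONDITIONS}")
            if self.leg is not None and self.leg not in LEGS:
                raise ValueError(f"unknown leg {self.leg!r}")
            if self.body_location is not None and self.body_location not in BODY_LOCATIONS:
                raise ValueError(f"unknown body_location {self.body_location!r}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def is_fully_tagged(self) -> bool:
        if self.purpose == "calibration":
            return True
        return None not in (self.condition, self.leg, self.body_location)

    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.samples])

    def as_array(self) -> np.ndarray:
        """Samples as an (n, 3) array of accelerations."""
        return np.array([[s.ax, s.ay, s.az] for s in self.samples])

    def with_samples(self, arr: np.ndarray) -> "Recording":
        """Copy of this recording with axis values replaced (timestamps kept)."""
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (self.n_samples, 3):
            raise ValueError(f"expected shape {(self.n_samples, 3)}, got {arr.shape}")
        t = self.times()
        samples = [TriaxialSample(float(ti), *map(float, row)) for ti, row in zip(t, arr)]
        return replace(self, samples=samples)

    def tagged(self, **meta) -> "Recording":
        return replace(self, **meta)


def read_trial_csv(
    path: str | Path,
    *,
    device_id: str = "unknown",
    nominal_rate: float | None = None,
    units: str = "ms2",
    **metadata,
) -> Recording:
    """Parse a trial log CSV into a Recording.

    The file must carry the header ``t_s,ax_ms2,ay_ms2,az_ms2`` and strictly
    increasing timestamps.  ``units='g'`` multiplies axis values by 9.81 on
    read.  Extra keyword metadata (condition, leg, body_location, purpose,
    orientation) is attached to the returned Recording.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if units not in ("ms2", "g"):
        raise ValueError(f"units must be 'ms2' or 'g', got {units!r}")
    scale = STANDARD_GRAVITY if units == "g" else 1.0

    samples: list[TriaxialSample] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        if tuple(header) != _CSV_HEADER:
            raise ParseError(
                f"{path}: bad header {header!r}; expected {','.join(_CSV_HEADER)}"
            )
        prev_t = -math.inf
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 4:
                raise ParseError(f"{path}: row {lineno}: expected 4 fields, got {len(row)}")
            try:
                t, ax, ay, az = (float(v) for v in row)
            except ValueError:
                raise ParseError(f"{path}: row {lineno}: non-numeric cell in {row!r}") from None
            if not t > prev_t:
                raise ParseError(
                    f"{path}: row {lineno}: time {t} not strictly greater than previous {prev_t}"
                )
            prev_t = t
            try:
                samples.append(TriaxialSample(t, ax * scale, ay * scale, az * scale))
            except ValueError as exc:
                raise ParseError(f"{path}: row {lineno}: {exc}") from None
    if not samples:
        raise ParseError(f"{path}: no data rows")

    if nominal_rate is None:
        t = np.array([s.t for s in samples])
        nominal_rate = float((len(t) - 1) / (t[-1] - t[0])) if len(t) > 1 else 1.0
    purpose = metadata.pop("purpose", "trial")
    return Recording(
        device_id=device_id,
        purpose=purpose,
        samples=samples,
        nominal_rate=nominal_rate,
        **metadata,
    )


def write_trial_csv(rec: Recording, path: str | Path) -> Path:
    """Write a Recording to CSV with full float precision (round-trip safe)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        for s in rec.samples:
            writer.writerow([repr(s.t), repr(s.ax), repr(s.ay), repr(s.az)])
    return path


@dataclass(frozen=True)
class TrialEntry:
    """One manifest line: a trial file and the cell it belongs to."""

    path: Path
    device_id: str
    condition: str
    leg: str
    body_location: str

    @property
    def cell(self) -> tuple[str, str, str]:
        return (self.condition, self.leg, self.body_location)


@dataclass
class SessionManifest:
    """Declarative description of one participant's session on disk."""

    participant_id: str
    sex: str
    trials: list[TrialEntry]
    calibration_files: dict[str, dict[str, Path]]  # device -> direction -> path
    nominal_rate: float = 15.0

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise SessionValidationError(f"sex must be 'male' or 'female', got {self.sex!r}")


@dataclass
class Session:
    """A loaded, validated session: manifest plus parsed recordings."""

    manifest: SessionManifest
    trials: dict[tuple[str, str, str], Recording]
    calibrations: dict[str, dict[str, Recording]]  # device -> direction -> Recording

    @property
    def participant_id(self) -> str:
        return self.manifest.participant_id

    @property
    def sex(self) -> str:
        return self.manifest.sex

    def present_cells(self) -> list[tuple[str, str, str]]:
        return sorted(self.trials)

    def missing_cells(self) -> list[tuple[str, str, str]]:
        return [c for c in expected_cells() if c not in self.trials]

    @property
    def is_complete(self) -> bool:
        return not self.missing_cells()


def expected_cells() -> list[tuple[str, str, str]]:
    """The 48 analysis cells of a full session (8 conditions × 2 legs × 3 locations)."""
    return [
        (cond, leg, loc)
        for cond in CONDITIONS
        for leg in LEGS
        for loc in BODY_LOCATIONS
    ]


def _parse_manifest_doc(doc: Mapping, base: Path) -> SessionManifest:
    try:
        participant_id = str(doc["participant_id"])
        sex = str(doc["sex"])
        trials_raw = doc["trials"]
        devices_raw = doc["devices"]
    except KeyError as exc:
        raise SessionValidationError(f"manifest missing required key {exc}") from None
    nominal_rate = float(doc.get("nominal_rate", 15.0))

    trials = []
    for entry in trials_raw:
        try:
            trials.append(
                TrialEntry(
                    path=base / entry["file"],
                    device_id=str(entry["device"]),
                    condition=str(entry["condition"]),
                    leg=str(entry["leg"]),
                    body_location=str(entry["body_location"]),
                )
            )
        except KeyError as exc:
            raise SessionValidationError(f"trial entry {entry!r} missing key {exc}") from None

    calibration_files: dict[str, dict[str, Path]] = {}
    for device_id, dev in devices_raw.items():
        calib = dev.get("calibration", {})
        calibration_files[str(device_id)] = {
            _normalize_direction(d): base / p for d, p in calib.items()
        }
    return SessionManifest(
        participant_id=participant_id,
        sex=sex,
        trials=trials,
        calibration_files=calibration_files,
        nominal_rate=nominal_rate,
    )


def _load_one_session(m: SessionManifest) -> Session:
    problems: list[str] = []

    seen: dict[tuple[str, str, str], Path] = {}
    for entry in m.trials:
        if entry.cell in seen:
            problems.append(
                f"duplicate cell {entry.cell}: {seen[entry.cell]} and {entry.path}"
            )
        seen[entry.cell] = entry.path

    for device_id, calib in m.calibration_files.items():
        missing = [d for d in DIRECTIONS if d not in calib]
        if missing:
            problems.append(
                f"device {device_id}: missing calibration orientation(s) {', '.join(missing)}"
            )

    for entry in m.trials:
        if not entry.path.exists():
            problems.append(f"trial file not found: {entry.path}")
    for device_id, calib in m.calibration_files.items():
        for d, p in calib.items():
            if not p.exists():
                problems.append(f"calibration file not found ({device_id} {d}): {p}")

    if problems:
        raise SessionValidationError(
            f"session {m.participant_id}: " + "; ".join(problems)
        )

    trials = {
        entry.cell: read_trial_csv(
            entry.path,
            device_id=entry.device_id,
            nominal_rate=m.nominal_rate,
            condition=entry.condition,
            leg=entry.leg,
            body_location=entry.body_location,
        )
        for entry in m.trials
    }
    calibrations = {
        device_id: {
            d: read_trial_csv(
                p, device_id=device_id, purpose="calibration", orientation=d,
                nominal_rate=m.nominal_rate,
            )
            for d, p in calib.items()
        }
        for device_id, calib in m.calibration_files.items()
    }
    return Session(manifest=m, trials=trials, calibrations=calibrations)


def _read_manifest_file(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_session(manifest_path: str | Path, participant_id: str | None = None) -> Session:
    """Load and validate a single participant's session.

    The manifest may describe one participant directly or carry a
    ``participants`` list, in which case ``participant_id`` selects the entry
    (required when more than one is present).
    """
    doc = _read_manifest_file(manifest_path)
    base = Path(manifest_path).parent
    if "participants" in doc:
        entries = doc["participants"]
        if participant_id is not None:
            entries = [e for e in entries if str(e.get("participant_id")) == participant_id]
            if not entries:
                raise SessionValidationError(f"participant {participant_id!r} not in manifest")
        if len(entries) != 1:
            raise SessionValidationError(
                "manifest lists multiple participants; pass participant_id or use load_study"
            )
        doc = entries[0]
    return _load_one_session(_parse_manifest_doc(doc, base))


def load_study(manifest_path: str | Path) -> list[Session]:
    """Load every participant session from a multi-participant manifest."""
    doc = _read_manifest_file(manifest_path)
    base = Path(manifest_path).parent
    entries = doc["participants"] if "participants" in doc else [doc]
    return [_load_one_session(_parse_manifest_doc(e, base)) for e in entries]
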