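"""Static-bias calibration of a triaxial accelerometer.

A motionless, level accelerometer should read exactly ±g along its vertical
axis.  Consumer sensors show a direction-dependent static bias, so each of the
six signed directions (x±, y±, z±) gets its own multiplicative correction
factor C = g / |mean reading with that direction vertical|.  Correction is
sign-dispatched: a positive raw x value is multiplied by Cx+, a negative one
by Cx−, leaving the sign intact.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .sensor_io import DIRECTIONS, STANDARD_GRAVITY, Recording

__all__ = [
    "CorrectionFactors",
    "direction_mean",
    "derive_correction_factors",
    "apply_correction",
]

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass
class CorrectionFactors:
    """Six per-direction static-bias multipliers for one device."""

    device_id: str
    c: dict[str, float]
    g_ref: float = STANDARD_GRAVITY

    def __post_init__(self) -> None:
        missing = [d for d in DIRECTIONS if d not in self.c]
        if missing:
            raise ValueError(f"missing correction factor(s) for {missing}")
        for d, v in self.c.items():
            if d not in DIRECTIONS:
                raise ValueError(f"unknown direction {d!r}")
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"correction factor {d} must be finite and positive, got {v!r}")
        # a working sensor is at most a factor ~2 off nominal gain
        suspicious = {d: v for d, v in self.c.items() if not 0.5 <= v <= 2.0}
        if suspicious:
            warnings.warn(
                f"device {self.device_id}: correction factor(s) outside [0.5, 2.0]: {suspicious}",
                stacklevel=2,
            )

    @classmethod
    def identity(cls, device_id: str = "ideal") -> "CorrectionFactors":
        return cls(device_id=device_id, c={d: 1.0 for d in DIRECTIONS})

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {"device_id": self.device_id, "g_ref": self.g_ref, "factors": self.c}
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CorrectionFactors":
        p = Path(source)
        text = p.read_text(encoding="utf-8") if p.exists() else str(source)
        doc = json.loads(text)
        return cls(device_id=doc["device_id"], c=dict(doc["factors"]),
                   g_ref=float(doc.get("g_ref", STANDARD_GRAVITY)))


def direction_mean(rec: Recording, axis: str) -> float:
    """Mean acceleration along the vertical axis of a calibration recording.

    The sign is preserved: a ``+`` orientation gives roughly +9.81 m/s², a
    ``-`` orientation roughly −9.81 m/s².  A magnitude below 1 m/s² almost
    certainly means the wrong axis was vertical, and triggers a warning.
    """
    if rec.purpose != "calibration":
        raise ValueError("direction_mean requires a calibration Recording")
    if axis not in _AXIS_INDEX:
        raise ValueError(f"axis must be one of x, y, z, got {axis!r}")
    assert rec.orientation is not None
    if rec.orientation[0] != axis:
        raise ValueError(
            f"recording orientation {rec.orientation!r} does not match requested axis {axis!r}"
        )
    mean = float(rec.as_array()[:, _AXIS_INDEX[axis]].mean())
    if abs(mean) < 1.0:
        warnings.warn(
            f"device {rec.device_id}, orientation {rec.orientation}: mean |{mean:.3f}| < 1 m/s² "
            "— orientation likely wrong",
            stacklevel=2,
        )
    return mean


def derive_correction_factors(
    recordings: Mapping[str, Recording] | list[Recording],
    device_id: str | None = None,
) -> CorrectionFactors:
    """Estimate the six correction factors from one recording per direction.

    Each factor is reference gravity divided by the magnitude of the mean
    vertical-axis reading: C_dir = 9.81 / |mean|.  Factors are kept positive
    for both signs so that correction is sign-preserving.
    """
    if not isinstance(recordings, Mapping):
        recs: dict[str, Recording] = {}
        for r in recordings:
            if r.orientation is None:
                raise ValueError("calibration Recording without orientation")
            if r.orientation in recs:
                raise ValueError(f"duplicate calibration recording for {r.orientation}")
            recs[r.orientation] = r
    else:
        recs = dict(recordings)

    missing = [d for d in DIRECTIONS if d not in recs]
    if missing:
        raise ValueError(f"missing calibration recording(s) for direction(s) {missing}")

    if device_id is None:
        device_id = recs["x+"].device_id

    c: dict[str, float] = {}
    for d in DIRECTIONS:
        mean = direction_mean(recs[d], d[0])
        if mean == 0.0:
            raise ValueError(f"degenerate sensor: zero mean reading in direction {d}")
        c[d] = STANDARD_GRAVITY / abs(mean)
    return CorrectionFactors(device_id=device_id, c=c)


def apply_correction(rec: Recording, cf: CorrectionFactors) -> Recording:
    """Multiply every sample's axis values by the factor matching axis and sign.

    Positive (and exactly-zero) values use the ``+`` factor, negative values
    the ``-`` factor; timestamps and metadata are untouched.
    """
    if rec.device_id != cf.device_id:
        warnings.warn(
            f"applying factors for device {cf.device_id!r} to recording from {rec.device_id!r}",
            stacklevel=2,
        )
    arr = rec.as_array()
    out = np.empty_like(arr)
    for axis, i in _AXIS_INDEX.items():
        pos = arr[:, i] >= 0
        out[pos, i] = arr[pos, i] * cf.c[f"{axis}+"]
        out[~pos, i] = arr[~pos, i] * cf.c[f"{axis}-"]
    return rec.with_samples(out)
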