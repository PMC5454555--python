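"""Per-trial balance index: mean resultant magnitude and its reciprocal.

Each corrected sample yields a resultant magnitude
R = sqrt(x² + y² + z²); the trial index *mean R* is the average of the
420–450 per-sample magnitudes.  Two variants are provided:

``literal``
    R of the corrected samples as-is.  Gravity dominates, so quiet stance
    gives mean R ≈ 9.81 m/s²; useful for calibration checks.
``deviation``
    The per-trial mean acceleration vector is subtracted from every sample
    before taking magnitudes, leaving the gravity-removed sway magnitude on
    the scale of fractions of a m/s² for easy stances.  This is the variant
    whose reciprocal ranks exercise difficulty.

The reciprocal 1/mean R normalises the right-skewed index distribution;
larger reciprocal values mean steadier (easier) performance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .calibration import CorrectionFactors, apply_correction
from .sensor_io import Recording, Session, TriaxialSample

__all__ = ["TrialMetrics", "resultant_magnitude", "mean_r", "session_metrics"]

VARIANTS = ("literal", "deviation")


@dataclass(frozen=True)
class TrialMetrics:
    """Balance index for one trial cell."""

    mean_r: float
    recip_mean_r: float | None  # None when mean_r == 0 (reciprocal undefined)
    n_samples: int
    variant: str
    condition: str | None = None
    leg: str | None = None
    body_location: str | None = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.mean_r < 0:
            raise ValueError("mean_r cannot be negative")
        if self.recip_mean_r is not None and self.mean_r == 0:
            raise ValueError("recip_mean_r must be unset when mean_r == 0")


def resultant_magnitude(sample: TriaxialSample | np.ndarray) -> float:
    """Euclidean norm of the three (corrected) axis values, in m/s²."""
    if isinstance(sample, TriaxialSample):
        v = sample.vector
    else:
        v = np.asarray(sample, dtype=float)
        if v.shape != (3,):
            raise ValueError(f"expected a 3-vector, got shape {v.shape}")
    return float(np.linalg.norm(v))


def mean_r(rec: Recording, variant: str = "deviation") -> TrialMetrics:
    """Average resultant magnitude of a (corrected) recording.

    With ``variant='deviation'`` the trial-mean acceleration vector (gravity
    plus any constant offset) is removed before computing magnitudes.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    arr = rec.as_array()
    if variant == "deviation":
        arr = arr - arr.mean(axis=0, keepdims=True)
    m = float(np.linalg.norm(arr, axis=1).mean())
    recip = 1.0 / m if m > 0 else None
    return TrialMetrics(
        mean_r=m,
        recip_mean_r=recip,
        n_samples=rec.n_samples,
        variant=variant,
        condition=rec.condition,
        leg=rec.leg,
        body_location=rec.body_location,
    )


def session_metrics(
    sessions: Session | Iterable[Session],
    factors: Mapping[str, CorrectionFactors],
    variant: str = "deviation",
) -> pd.DataFrame:
    """Correct every trial of one or more sessions and tabulate its metrics.

    Returns a long-format DataFrame with one row per trial cell, keyed by
    (participant, condition, leg, body_location).
    """
    if isinstance(sessions, Session):
        sessions = [sessions]
    rows = []
    for session in sessions:
        for cell, rec in sorted(session.trials.items()):
            if rec.device_id not in factors:
                raise KeyError(
                    f"no correction factors for device {rec.device_id!r} "
                    f"(trial {cell}, participant {session.participant_id})"
                )
            corrected = apply_correction(rec, factors[rec.device_id])
            tm = mean_r(corrected, variant=variant)
            rows.append(
                {
                    "participant": session.participant_id,
                    "sex": session.sex,
                    "condition": tm.condition,
                    "leg": tm.leg,
                    "body_location": tm.body_location,
                    "variant": tm.variant,
                    "n_samples": tm.n_samples,
                    "mean_r": tm.mean_r,
                    "recip_mean_r": tm.recip_mean_r,
                }
            )
    return pd.DataFrame(rows)
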