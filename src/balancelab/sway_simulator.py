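"""Synthetic sway-recording generator.

Emulates a body-worn smartphone accelerometer during quiet-stance balance
exercises: a gravity vector at a small fixed tilt from the device's vertical
axis, temporally correlated sway modelled as an AR(1) process in the
horizontal plane, white measurement noise, and a per-direction sensor gain
(the static bias the calibration procedure must undo).  Sway amplitude is
condition- and location-dependent, increasing along the clinical difficulty
order, so the full pipeline (calibrate → correct → mean R → rank) can be
exercised and its ranking recovery measured against known ground truth.

The generator also produces noisy clinical raters: each perceives the true
difficulty scores through independent Gaussian noise and ranks accordingly.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.signal import lfilter

from .concordance import RankingTable
from .sensor_io import (
    BODY_LOCATIONS,
    CONDITIONS,
    DIFFICULTY_ORDER,
    DIRECTIONS,
    LEGS,
    STANDARD_GRAVITY,
    Recording,
    Session,
    SessionManifest,
    TrialEntry,
    TriaxialSample,
    write_trial_csv,
)

__all__ = [
    "SwayParams",
    "default_sigma_table",
    "simulate_static",
    "simulate_trial",
    "simulate_study",
    "simulate_session",
    "simulate_rater",
]

#: Per-location scaling of the knee sway amplitudes.
LOCATION_SCALE = {"knee": 1.0, "torso": 0.7, "ankle": 1.1}

#: Between-participant coefficient of variation of sway amplitude, per
#: location; the ankle is the most idiosyncratic site.
DEFAULT_PARTICIPANT_CV = {"ankle": 0.25, "knee": 0.10, "torso": 0.10}

DEVICE_IDS = {loc: f"phone_{loc}" for loc in BODY_LOCATIONS}


def default_sigma_table() -> dict[tuple[str, str], float]:
    """Sway standard deviation (m/s²) per (condition, body location).

    Knee amplitudes are spaced geometrically from 0.1 (easiest, double-leg
    stance) to 2.0 m/s² (hardest, single-leg on foam eyes closed); torso and
    ankle are scaled copies.
    """
    table: dict[tuple[str, str], float] = {}
    for i, cond in enumerate(DIFFICULTY_ORDER):
        knee = 0.1 * (20.0 ** (i / 7.0))
        for loc, scale in LOCATION_SCALE.items():
            table[(cond, loc)] = knee * scale
    return table


@dataclass
class SwayParams:
    """Simulation parameters; defaults reflect the hardware and protocol assumed
    throughout: 30 s trials at 14–15 Hz, a ~2° mounting tilt, slow correlated
    sway and a few-hundredths-of-a-m/s² sensor noise floor."""

    fs: float = 15.0
    duration: float = 30.0
    tilt_deg: float = 2.0
    sigma: dict[tuple[str, str], float] = field(default_factory=default_sigma_table)
    phi: float = 0.9
    noise_sd: float = 0.03
    gains: dict[str, float] | None = None  # None → drawn per device (gain_sd)
    gain_sd: float = 0.01
    participant_cv: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PARTICIPANT_CV)
    )
    sex_sigma_factor: float = 1.0  # multiplies sigma for female participants
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if not 0 <= self.phi < 1:
            raise ValueError("phi must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if any(v < 0 for v in self.sigma.values()):
            raise ValueError("sigma values must be non-negative")
        if self.gains is not None and any(g <= 0 for g in self.gains.values()):
            raise ValueError("gains must be positive")
        for loc in BODY_LOCATIONS:
            sig = [self.sigma.get((c, loc)) for c in DIFFICULTY_ORDER]
            sig = [s for s in sig if s is not None]
            if any(b < a for a, b in zip(sig, sig[1:])):
                warnings.warn(
                    f"sigma at {loc} is not non-decreasing along the difficulty order",
                    stacklevel=2,
                )

    @property
    def n_samples(self) -> int:
        return round(self.fs * self.duration)


def _ar1(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1) series of length n with marginal std ``sd``."""
    if sd == 0:
        return np.zeros(n)
    e = rng.normal(0.0, sd * math.sqrt(1.0 - phi * phi), size=n)
    e[0] = rng.normal(0.0, sd)  # draw x0 from the stationary distribution
    return lfilter([1.0], [1.0, -phi], e)


def _apply_gains(arr: np.ndarray, gains: Mapping[str, float]) -> np.ndarray:
    out = np.empty_like(arr)
    for i, axis in enumerate("xyz"):
        pos = arr[:, i] >= 0
        out[pos, i] = arr[pos, i] * gains[f"{axis}+"]
        out[~pos, i] = arr[~pos, i] * gains[f"{axis}-"]
    return out


def _unit_gains() -> dict[str, float]:
    return {d: 1.0 for d in DIRECTIONS}


def _recording_from_array(
    arr: np.ndarray, fs: float, *, device_id: str, **meta
) -> Recording:
    t = np.arange(arr.shape[0]) / fs
    samples = [TriaxialSample(float(ti), *map(float, row)) for ti, row in zip(t, arr)]
    return Recording(device_id=device_id, samples=samples, nominal_rate=fs, **meta)


def simulate_static(
    direction: str,
    gains: Mapping[str, float] | None = None,
    noise_sd: float = 0.03,
    fs: float = 15.0,
    duration: float = 30.0,
    seed: int | np.random.Generator = 0,
    device_id: str = "sim",
) -> Recording:
    """A calibration recording: the device at rest with ``direction`` vertical.

    The vertical axis reads gain × (±9.81 m/s²) plus white noise; the other
    two axes read noise only.
    """
    direction = direction.replace("−", "-")
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    gains = dict(gains) if gains is not None else _unit_gains()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = round(fs * duration)
    axis = "xyz".index(direction[0])
    sign = 1.0 if direction[1] == "+" else -1.0

    arr = rng.normal(0.0, noise_sd, size=(n, 3)) if noise_sd > 0 else np.zeros((n, 3))
    arr[:, axis] += sign * gains[direction] * STANDARD_GRAVITY
    return _recording_from_array(
        arr, fs, device_id=device_id, purpose="calibration", orientation=direction
    )


def simulate_trial(
    condition: str,
    leg: str,
    body_location: str,
    params: SwayParams,
    *,
    seed: int | Sequence[int] | np.random.Generator | None = None,
    gains: Mapping[str, float] | None = None,
    sigma_scale: float = 1.0,
    device_id: str | None = None,
) -> Recording:
    """One synthetic 30 s balance trial.

    The device's y axis is near-vertical (strapped upright on the limb or
    torso), tilted ``tilt_deg`` towards x; sway acceleration is AR(1) in the
    two horizontal device axes with the configured stationary standard
    deviation split evenly between them.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    if leg not in LEGS:
        raise ValueError(f"unknown leg {leg!r}")
    if body_location not in BODY_LOCATIONS:
        raise ValueError(f"unknown body_location {body_location!r}")
    if seed is None:
        seed = [params.seed, CONDITIONS.index(condition), LEGS.index(leg),
                BODY_LOCATIONS.index(body_location)]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if gains is None:
        gains = params.gains if params.gains is not None else _unit_gains()
    if device_id is None:
        device_id = DEVICE_IDS[body_location]

    n = params.n_samples
    tilt = math.radians(params.tilt_deg)
    gravity = STANDARD_GRAVITY * np.array([math.sin(tilt), math.cos(tilt), 0.0])

    sd = params.sigma[(condition, body_location)] * sigma_scale
    sway = np.zeros((n, 3))
    sway[:, 0] = _ar1(rng, n, sd / math.sqrt(2.0), params.phi)
    sway[:, 2] = _ar1(rng, n, sd / math.sqrt(2.0), params.phi)

    noise = rng.normal(0.0, params.noise_sd, size=(n, 3)) if params.noise_sd > 0 else 0.0
    true = gravity[None, :] + sway + noise
    measured = _apply_gains(true, gains)
    return _recording_from_array(
        measured, params.fs, device_id=device_id, purpose="trial",
        condition=condition, leg=leg, body_location=body_location,
    )


def _draw_device_gains(params: SwayParams, rng: np.random.Generator) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for loc in BODY_LOCATIONS:
        dev = DEVICE_IDS[loc]
        if params.gains is not None:
            out[dev] = dict(params.gains)
        else:
            out[dev] = {
                d: float(max(0.5, rng.normal(1.0, params.gain_sd))) for d in DIRECTIONS
            }
    return out


def simulate_study(
    n_participants: int,
    params: SwayParams | None = None,
    seed: int | None = None,
) -> tuple[list[Session], dict]:
    """Simulate a study fully in memory: one Session per participant plus
    ground truth (device gains, sigma table, true difficulty order).

    Each of the three body locations has its own device, calibrated once per
    study.  Per-participant sway idiosyncrasy is a lognormal multiplier per
    body location, widest at the ankle.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    params = params if params is not None else SwayParams()
    root = params.seed if seed is None else seed

    gains_rng = np.random.default_rng([root, 101])
    device_gains = _draw_device_gains(params, gains_rng)

    calibrations: dict[str, dict[str, Recording]] = {}
    for di, loc in enumerate(BODY_LOCATIONS):
        dev = DEVICE_IDS[loc]
        calibrations[dev] = {
            d: simulate_static(
                d, gains=device_gains[dev], noise_sd=params.noise_sd,
                fs=params.fs, duration=params.duration,
                seed=np.random.default_rng([root, 202, di, k]),
                device_id=dev,
            )
            for k, d in enumerate(DIRECTIONS)
        }

    sessions: list[Session] = []
    for p in range(n_participants):
        p_rng = np.random.default_rng([root, 303, p])
        sex = "female" if p_rng.random() < 0.5 else "male"
        sway_factor = {
            loc: float(p_rng.lognormal(0.0, params.participant_cv[loc]))
            for loc in BODY_LOCATIONS
        }
        sex_factor = params.sex_sigma_factor if sex == "female" else 1.0

        trials: dict[tuple[str, str, str], Recording] = {}
        for ci, cond in enumerate(CONDITIONS):
            for li, leg in enumerate(LEGS):
                for bi, loc in enumerate(BODY_LOCATIONS):
                    dev = DEVICE_IDS[loc]
                    rec = simulate_trial(
                        cond, leg, loc, params,
                        seed=np.random.default_rng([root, 404, p, ci, li, bi]),
                        gains=device_gains[dev],
                        sigma_scale=sway_factor[loc] * sex_factor,
                        device_id=dev,
                    )
                    trials[(cond, leg, loc)] = rec

        pid = f"P{p + 1:02d}"
        manifest = SessionManifest(
            participant_id=pid,
            sex=sex,
            trials=[
                TrialEntry(
                    path=Path(f"{pid}/{c}_{l}_{b}.csv"),
                    device_id=trials[(c, l, b)].device_id,
                    condition=c, leg=l, body_location=b,
                )
                for (c, l, b) in trials
            ],
            calibration_files={
                dev: {d: Path(f"calibration/{dev}_{d.replace('+', 'p').replace('-', 'n')}.csv")
                      for d in DIRECTIONS}
                for dev in calibrations
            },
            nominal_rate=params.fs,
        )
        sessions.append(Session(manifest=manifest, trials=trials, calibrations=calibrations))

    ground_truth = {
        "seed": root,
        "fs": params.fs,
        "duration": params.duration,
        "device_gains": device_gains,
        "sigma": {f"{c}|{loc}": v for (c, loc), v in params.sigma.items()},
        "true_difficulty_order": list(DIFFICULTY_ORDER),
    }
    return sessions, ground_truth


def simulate_session(
    out_dir: str | Path,
    n_participants: int,
    params: SwayParams | None = None,
    seed: int | None = None,
) -> Path:
    """Simulate a study and write it to disk: trial and calibration CSVs, a
    YAML manifest and a ground-truth JSON.  Returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sessions, ground_truth = simulate_study(n_participants, params, seed)

    # calibrations are shared across sessions; write once
    for dev, calib in sessions[0].calibrations.items():
        for d, rec in calib.items():
            write_trial_csv(rec, out_dir / sessions[0].manifest.calibration_files[dev][d])

    participants_doc = []
    for session in sessions:
        m = session.manifest
        for entry in m.trials:
            write_trial_csv(session.trials[entry.cell], out_dir / entry.path)
        participants_doc.append(
            {
                "participant_id": m.participant_id,
                "sex": m.sex,
                "nominal_rate": m.nominal_rate,
                "devices": {
                    dev: {"calibration": {d: str(p) for d, p in calib.items()}}
                    for dev, calib in m.calibration_files.items()
                },
                "trials": [
                    {
                        "file": str(e.path),
                        "device": e.device_id,
                        "condition": e.condition,
                        "leg": e.leg,
                        "body_location": e.body_location,
                    }
                    for e in m.trials
                ],
            }
        )

    manifest_path = out_dir / "manifest.yaml"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"participants": participants_doc}, fh, sort_keys=False)
    with open(out_dir / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(ground_truth, fh, indent=2, sort_keys=True)
    return manifest_path


def simulate_rater(
    true_difficulty: Mapping[str, float],
    tau: float,
    seed: int | np.random.Generator = 0,
    assessor_id: str = "sim_rater",
) -> RankingTable:
    """A noisy clinical rater: perceives each condition's true difficulty score
    through independent Gaussian noise of SD ``tau`` and ranks ascending
    (rank 1 = least difficult).  Exact perceived ties are re-drawn."""
    if tau < 0:
        raise ValueError("tau must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    conds = list(true_difficulty)
    scores = np.array([true_difficulty[c] for c in conds], dtype=float)
    for _ in range(100):
        perceived = scores + (rng.normal(0.0, tau, size=len(conds)) if tau > 0 else 0.0)
        if len(np.unique(perceived)) == len(conds):
            break
    else:  # pragma: no cover - requires pathological inputs
        raise RuntimeError("could not break perceived-score ties")
    order = np.argsort(perceived, kind="stable")
    ranks = {conds[idx]: i + 1 for i, idx in enumerate(order)}
    return RankingTable(assessor_id, ranks)
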