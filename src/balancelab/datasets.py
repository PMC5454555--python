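"""Bundled reference data: the clinical difficulty-ranking study inputs.

Eight therapists (sports-medicine clinicians) each ranked the eight balance
conditions from least (1) to most (8) difficult; the device produced its own
ranking from mean reciprocal R at the knee.  These small printed tables are
the inputs to the concordance analysis and are bundled here so the validity
computation is reproducible end to end.
"""

from __future__ import annotations

from .concordance import RankingTable

__all__ = [
    "therapist_rankings",
    "device_ranking",
    "device_knee_reciprocal_means",
]

# assessor -> conditions in rank order (rank 1 first)
_THERAPIST_ORDERS: dict[str, tuple[str, ...]] = {
    "Therapist A": ("DL", "FT", "TAN", "SLS", "FDL", "SLSE", "FSLS", "FSLSE"),
    "Therapist B": ("DL", "FT", "SLS", "FDL", "TAN", "FSLS", "SLSE", "FSLSE"),
    "Therapist C": ("DL", "FT", "TAN", "SLS", "FDL", "FSLS", "SLSE", "FSLSE"),
    "Therapist D": ("DL", "FT", "FDL", "TAN", "SLS", "FSLS", "SLSE", "FSLSE"),
    "Therapist E": ("DL", "FT", "TAN", "FDL", "SLS", "FSLS", "SLSE", "FSLSE"),
    "Therapist F": ("DL", "FT", "FDL", "SLS", "TAN", "SLSE", "FSLS", "FSLSE"),
    "Therapist G": ("DL", "FT", "TAN", "FDL", "SLS", "SLSE", "FSLS", "FSLSE"),
    "Therapist H": ("DL", "FT", "FDL", "TAN", "SLS", "SLSE", "FSLS", "FSLSE"),
}

#: Mean reciprocal R (s²/m) per condition for the device at the knee location.
_DEVICE_KNEE_RECIP: dict[str, float] = {
    "DL": 8.0,
    "FT": 6.9,
    "FDL": 6.0,
    "TAN": 4.6,
    "SLS": 2.5,
    "SLSE": 1.2,
    "FSLS": 0.9,
    "FSLSE": 0.5,
}


def therapist_rankings() -> list[RankingTable]:
    """The eight clinical raters' difficulty rankings."""
    return [
        RankingTable(name, {cond: i + 1 for i, cond in enumerate(order)})
        for name, order in _THERAPIST_ORDERS.items()
    ]


def device_knee_reciprocal_means() -> dict[str, float]:
    """Mean reciprocal R per condition measured by the device at the knee."""
    return dict(_DEVICE_KNEE_RECIP)


def device_ranking() -> RankingTable:
    """The device's difficulty ranking, derived from its knee reciprocal means."""
    from .concordance import rank_by_difficulty

    return rank_by_difficulty(device_knee_reciprocal_means(), assessor_id="device")
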