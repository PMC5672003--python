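"""Oligomerization-state calls from apparent masses.

R_app = M_app / M_mono compares a peak's apparent mass with the annotated
monomer mass.  A twofold shift corresponds to roughly four column fractions,
so R_app >= 2 in at least one biological replicate of a reproducible peak is
the complex-prediction threshold.  The state classes follow the same ratio:
degraded (< 0.5), monomer ([0.5, 2)), small complex ([2, 10)) and large
complex (>= 10).  Peaks confined to the void have no apparent mass and are
reported as "unresolved" instead of one of the four classes.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from typing import Sequence

from .reproducibility import ReproduciblePeak

RAPP_COMPLEX = 2.0
RAPP_DEGRADED = 0.5
RAPP_LARGE = 10.0


class OligomerState(str, enum.Enum):
    DEGRADED = "degraded"
    MONOMER = "monomer"
    SMALL_COMPLEX = "small_complex"
    LARGE_COMPLEX = "large_complex"
    UNRESOLVED = "unresolved"


@dataclasses.dataclass
class OligomerCall:
    protein_id: str
    label: str | None
    r_app_rep1: float | None
    r_app_rep2: float | None
    r_app_mean: float | None
    state: OligomerState
    is_complex: bool


def compute_rapp(m_app_kda: float, m_mono_kda: float) -> float:
    """Apparent-to-monomer mass ratio."""
    if m_app_kda <= 0 or m_mono_kda <= 0:
        raise ValueError("masses must be positive")
    return m_app_kda / m_mono_kda


def classify_state(
    r_app: float,
    degraded_below: float = RAPP_DEGRADED,
    complex_at: float = RAPP_COMPLEX,
    large_at: float = RAPP_LARGE,
) -> OligomerState:
    """Boundary-inclusive state classification (0.5 / 2 / 10 by default)."""
    if r_app < 0:
        raise ValueError("r_app must be >= 0")
    if r_app < degraded_below:
        return OligomerState.DEGRADED
    if r_app < complex_at:
        return OligomerState.MONOMER
    if r_app < large_at:
        return OligomerState.SMALL_COMPLEX
    return OligomerState.LARGE_COMPLEX


def predict_complex(
    r_apps: Sequence[float], reproducible: bool, threshold: float = RAPP_COMPLEX
) -> bool:
    """Complex prediction: reproducible peak with R_app >= 2 in >=1 replicate."""
    return bool(reproducible) and any(r >= threshold for r in r_apps)


def call_oligomer(
    peak: ReproduciblePeak,
    m_mono_kda: float,
    complex_threshold: float = RAPP_COMPLEX,
    degraded_below: float = RAPP_DEGRADED,
    large_at: float = RAPP_LARGE,
) -> OligomerCall:
    """Full oligomer call for one reproducible peak.

    R_app is evaluated per replicate (the complex rule reads "in one
    biological replicate"); the consensus R_app used for the state class is
    the geometric mean, consistent with the consensus mass.
    """
    if not peak.resolved or peak.m_app_rep1 is None or peak.m_app_rep2 is None:
        return OligomerCall(
            peak.protein_id, peak.label, None, None, None, OligomerState.UNRESOLVED, False
        )
    r1 = compute_rapp(peak.m_app_rep1, m_mono_kda)
    r2 = compute_rapp(peak.m_app_rep2, m_mono_kda)
    r_mean = math.sqrt(r1 * r2)
    return OligomerCall(
        protein_id=peak.protein_id,
        label=peak.label,
        r_app_rep1=r1,
        r_app_rep2=r2,
        r_app_mean=r_mean,
        state=classify_state(r_mean, degraded_below, complex_threshold, large_at),
        is_complex=predict_complex((r1, r2), reproducible=True, threshold=complex_threshold),
    )
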