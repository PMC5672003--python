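"""True membrane-association calls and dual-localization mass shifts.

Microsomal preparations carry abundant cytosolic contaminants (RUBISCO being
the classic case).  A protein detected in the cholate-solubilized membrane
profiling is accepted as truly membrane-associated if it was never seen in
the cytosol, or if its sucrose velocity-gradient peak penetrates beyond
fraction 8 — soluble proteins, even the largest cytosolic complexes, stay in
the top eight fractions.  Proteins with both a membrane and a cytosolic pool
are screened for oligomerization shifts between compartments: a cytosol/
membrane apparent-mass ratio above 2 or below 0.5 flags a shift, and
cytosolic proteins of >= 450 kDa are excluded from the dual-localized set
because masses that large could reach deep sucrose fractions on their own.
"""

from __future__ import annotations

import dataclasses
import enum

from .reproducibility import ReproduciblePeak

SUCROSE_BOUNDARY = 8
LARGE_CYTOSOLIC_KDA = 450.0
DUAL_RATIO_HIGH = 2.0
DUAL_RATIO_LOW = 0.5


class MembraneStatus(str, enum.Enum):
    MEMBRANE_ASSOCIATED = "membrane_associated"
    CYTOSOLIC_CONTAMINANT = "cytosolic_contaminant"
    UNRESOLVED = "unresolved"


class SucroseEvidence(str, enum.Enum):
    CHOLATE_ONLY = "cholate_only"
    SUCROSE_DEEP = "sucrose_deep"
    SUCROSE_SHALLOW = "sucrose_shallow"
    NO_SUCROSE_PEAK = "no_sucrose_peak"


@dataclasses.dataclass
class MembraneCall:
    protein_id: str
    status: MembraneStatus
    evidence: SucroseEvidence


@dataclasses.dataclass
class DualLocalization:
    protein_id: str
    m_app_cytosol_kda: float
    m_app_membrane_kda: float
    ratio: float | None
    shifted: bool | None
    excluded_large_cytosolic: bool


def sucrose_deep_peak(center: float, boundary_fraction: float = SUCROSE_BOUNDARY) -> bool:
    """True iff the peak center lies strictly beyond the boundary fraction."""
    return center > boundary_fraction


def sucrose_evidence(
    peaks: list[ReproduciblePeak], boundary_fraction: float = SUCROSE_BOUNDARY
) -> SucroseEvidence:
    """Evidence from a protein's reproducible sucrose peaks.

    The dominant (highest-amplitude) reproducible peak decides depth;
    alternate peaks on the other side of the boundary are logged by callers.
    No reproducible peak at all counts as shallow evidence.
    """
    if not peaks:
        return SucroseEvidence.NO_SUCROSE_PEAK
    dominant = max(peaks, key=lambda p: p.amplitude)
    if sucrose_deep_peak(dominant.center_mean, boundary_fraction):
        return SucroseEvidence.SUCROSE_DEEP
    return SucroseEvidence.SUCROSE_SHALLOW


def call_membrane(
    protein_id: str,
    in_cholate: bool,
    in_cytosol: bool,
    evidence: SucroseEvidence,
) -> MembraneCall:
    """Membrane-association status for one cholate-detected protein.

    Cholate-only detection is sufficient; a protein also seen in the cytosol
    must additionally have a deep sucrose peak, otherwise it is a likely
    cytosolic contaminant.
    """
    if not in_cholate:
        raise ValueError(f"{protein_id}: only cholate-detected proteins are called")
    if not in_cytosol:
        return MembraneCall(protein_id, MembraneStatus.MEMBRANE_ASSOCIATED,
                            SucroseEvidence.CHOLATE_ONLY)
    if evidence is SucroseEvidence.SUCROSE_DEEP:
        return MembraneCall(protein_id, MembraneStatus.MEMBRANE_ASSOCIATED, evidence)
    return MembraneCall(protein_id, MembraneStatus.CYTOSOLIC_CONTAMINANT, evidence)


def flag_dual_localized(
    protein_id: str,
    m_app_cytosol_kda: float,
    m_app_membrane_kda: float,
    large_cytosolic_cutoff_kda: float = LARGE_CYTOSOLIC_KDA,
    ratio_high: float = DUAL_RATIO_HIGH,
    ratio_low: float = DUAL_RATIO_LOW,
) -> DualLocalization:
    """Compare the cytosolic and membrane apparent masses of a dual-localized
    protein; cytosolic masses at or above the cutoff are excluded and carry no
    shift verdict."""
    if m_app_cytosol_kda <= 0 or m_app_membrane_kda <= 0:
        raise ValueError("apparent masses must be positive")
    if m_app_cytosol_kda >= large_cytosolic_cutoff_kda:
        return DualLocalization(
            protein_id, m_app_cytosol_kda, m_app_membrane_kda,
            ratio=None, shifted=None, excluded_large_cytosolic=True,
        )
    ratio = m_app_cytosol_kda / m_app_membrane_kda
    return DualLocalization(
        protein_id, m_app_cytosol_kda, m_app_membrane_kda,
        ratio=ratio,
        shifted=ratio > ratio_high or ratio < ratio_low,
        excluded_large_cytosolic=False,
    )
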