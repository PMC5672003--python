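"""Apparent-mass calibration of size-exclusion columns.

On an SEC column log10(mass) falls linearly with elution position, so an
ordinary least-squares fit of log10(mass_kda) against the peak fraction of a
set of standards converts any continuous peak center into an apparent mass
M_app.  Masses outside the standards' range are extrapolations and flagged as
such.  A peak is "resolved" only if it sits at least one full fraction past
the void; void peaks get no mass.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import stats


@dataclasses.dataclass(frozen=True)
class CalibrationModel:
    """Log-linear standards regression: log10(kDa) = slope * fraction + intercept."""

    slope: float
    intercept: float
    standards: tuple[tuple[float, float], ...]
    r_squared: float
    mass_range_kda: tuple[float, float]
    #: Column-specific upper bound on quotable masses (e.g. ~900 kDa for a
    #: Superdex 200, ~5 MDa for a Superose 6); None disables the check.
    upper_quotable_kda: float | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        with open(path) as fh:
            d = json.load(fh)
        d["standards"] = tuple(tuple(s) for s in d["standards"])
        d["mass_range_kda"] = tuple(d["mass_range_kda"])
        return cls(**d)


def fit_calibration(
    standards: list[tuple[float, float]],
    upper_quotable_kda: float | None = None,
) -> CalibrationModel:
    """OLS of log10(mass_kda) on peak fraction for >=2 SEC standards."""
    if len(standards) < 2:
        raise ValueError("need at least 2 calibration standards")
    masses = np.array([m for m, _ in standards], dtype=float)
    fracs = np.array([f for _, f in standards], dtype=float)
    if np.any(masses <= 0):
        raise ValueError("standard masses must be positive")
    if np.ptp(fracs) == 0:
        raise ValueError("standards must span more than one peak fraction")

    res = stats.linregress(fracs, np.log10(masses))
    r2 = 1.0 if len(standards) == 2 else float(res.rvalue) ** 2
    model = CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        standards=tuple((float(m), float(f)) for m, f in standards),
        r_squared=r2,
        mass_range_kda=(float(masses.min()), float(masses.max())),
        upper_quotable_kda=upper_quotable_kda,
    )
    if model.slope >= 0:
        raise ValueError(
            "calibration slope must be negative (larger complexes elute earlier)"
        )
    return model


def apparent_mass(model: CalibrationModel, center: float) -> tuple[float, bool]:
    """Apparent mass (kDa) at a continuous peak center, plus extrapolation flag.

    The flag is True when the mass falls outside the range spanned by the
    standards; the value is still returned.
    """
    mass = float(10.0 ** (model.slope * center + model.intercept))
    lo, hi = model.mass_range_kda
    # small relative tolerance so a peak exactly at a standard's fraction is
    # never flagged by floating-point rounding alone
    inside = lo * (1.0 - 1e-12) <= mass <= hi * (1.0 + 1e-12)
    return mass, not inside


def is_resolved(center: float, void_fraction: int | None) -> bool:
    """True iff the peak center lies at least one fraction past the void.

    Schemes without a void (sucrose gradients) resolve everything.
    """
    if void_fraction is None:
        return True
    return center >= void_fraction + 1
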