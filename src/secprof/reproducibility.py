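"""Cross-replicate peak matching and P1/P2/P3 labelling.

A fitted peak is accepted only if the two biological replicates place it
within two fractions of each other; everything else is dropped as
non-reproducible.  Matched resolved peaks get per-replicate apparent masses
from the calibration regression and a geometric-mean consensus mass, and each
protein's peaks are labelled P1, P2, ... in decreasing apparent mass (void
peaks, which elute first, lead the ordering but carry no mass).
"""

from __future__ import annotations

import dataclasses
import itertools
import math

from .calibration import CalibrationModel, apparent_mass
from .peakfit import FittedPeak, PeakModel

MAX_SHIFT = 2.0


@dataclasses.dataclass
class ReproduciblePeak:
    protein_id: str
    center_rep1: float
    center_rep2: float
    shift: float
    resolved: bool
    amplitude: float  # mean of the two replicate amplitudes
    label: str | None = None
    m_app_rep1: float | None = None
    m_app_rep2: float | None = None
    m_app_mean: float | None = None
    extrapolated: bool = False

    @property
    def center_mean(self) -> float:
        return 0.5 * (self.center_rep1 + self.center_rep2)


def match_peaks(
    model_rep1: PeakModel,
    model_rep2: PeakModel,
    max_shift: float = MAX_SHIFT,
) -> tuple[list[ReproduciblePeak], list[tuple[str, FittedPeak]]]:
    """One-to-one matching of fitted peaks across the two replicates.

    Pairs are accepted greedily by smallest center shift, each peak used at
    most once, and only when the shift is <= ``max_shift`` (inclusive).
    Because peaks within a replicate are themselves >= 4 fractions apart while
    the shift tolerance is 2, each peak can match at most one partner, so the
    greedy matching coincides with the optimal assignment.  Unmatched peaks
    are returned in a drop log tagged with their replicate.
    """
    if model_rep1.protein_id != model_rep2.protein_id:
        raise ValueError("peak models belong to different proteins")
    p1, p2 = model_rep1.peaks, model_rep2.peaks
    pairs = sorted(
        ((abs(a.center - b.center), i, j) for (i, a), (j, b) in
         itertools.product(enumerate(p1), enumerate(p2))),
        key=lambda t: (t[0], t[1], t[2]),
    )
    used1: set[int] = set()
    used2: set[int] = set()
    matched: list[ReproduciblePeak] = []
    for shift, i, j in pairs:
        if shift > max_shift or i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        matched.append(
            ReproduciblePeak(
                protein_id=model_rep1.protein_id,
                center_rep1=p1[i].center,
                center_rep2=p2[j].center,
                shift=shift,
                resolved=p1[i].resolved and p2[j].resolved,
                amplitude=0.5 * (p1[i].amplitude + p2[j].amplitude),
            )
        )
    unmatched = [("rep1", p) for i, p in enumerate(p1) if i not in used1]
    unmatched += [("rep2", p) for j, p in enumerate(p2) if j not in used2]
    for peak in matched:
        assert peak.shift <= max_shift
    return matched, unmatched


def assign_labels(
    matched: list[ReproduciblePeak], cal: CalibrationModel
) -> list[ReproduciblePeak]:
    """Compute apparent masses for resolved peaks and assign P1..P4 labels.

    The consensus mass is the geometric mean of the two per-replicate masses
    (masses live on a log scale along the column).  Labels follow decreasing
    apparent mass, i.e. increasing mean elution position, which puts
    unresolved void peaks first; those carry a label but no mass.
    """
    out = []
    for pk in sorted(matched, key=lambda p: p.center_mean):
        pk = dataclasses.replace(pk)
        if pk.resolved:
            m1, flag1 = apparent_mass(cal, pk.center_rep1)
            m2, flag2 = apparent_mass(cal, pk.center_rep2)
            pk.m_app_rep1, pk.m_app_rep2 = m1, m2
            pk.m_app_mean = math.sqrt(m1 * m2)
            pk.extrapolated = flag1 or flag2
        out.append(pk)
    for rank, pk in enumerate(out, start=1):
        pk.label = f"P{rank}"
    return out
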