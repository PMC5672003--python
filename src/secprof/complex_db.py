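"""Ortholog-projected reference complexes and coverage classification.

Curated complex databases (CORUM-style) describe metazoan complexes; their
subunits are projected into the target species through one or more external
ortholog mappings.  Complexes whose projected subunit sets coincide across
source species are collapsed, coverage of each complex is classified from the
fraction of subunits with orthologs, and the calculated mass of the fully
assembled complex (sum of subunit monomer masses, unit stoichiometry) is
compared with the measured apparent masses of its subunits.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclasses.dataclass
class ReferenceComplex:
    complex_id: str
    source_species: str
    subunit_ids: tuple[str, ...]
    ortholog_map: dict[str, str] = dataclasses.field(default_factory=dict)
    aliases: list[str] = dataclasses.field(default_factory=list)
    m_calc_source_kda: float | None = None

    @property
    def n_subunits(self) -> int:
        return len(self.subunit_ids)

    @property
    def n_matched(self) -> int:
        return len(self.ortholog_map)

    @property
    def coverage_class(self) -> str:
        return classify_coverage(self.n_matched, self.n_subunits)

    @property
    def target_subunits(self) -> frozenset[str]:
        return frozenset(self.ortholog_map.values())

    def m_calc_target_kda(self, monomer_masses: Mapping[str, float]) -> float | None:
        """Sum of target-ortholog monomer masses; defined only at 100% coverage."""
        if self.n_matched < self.n_subunits:
            return None
        masses = [monomer_masses.get(t) for t in self.ortholog_map.values()]
        if any(m is None for m in masses):
            return None
        return calc_complex_mass([m for m in masses if m is not None])


def read_complex_db(path: str | Path) -> list[ReferenceComplex]:
    """CSV with columns complex_id, species, subunit_id (one row per subunit)."""
    df = pd.read_csv(path, sep=None, engine="python")
    out = []
    for (cid, sp), grp in df.groupby(["complex_id", "species"], sort=True):
        out.append(
            ReferenceComplex(str(cid), str(sp), tuple(str(s) for s in grp["subunit_id"]))
        )
    return out


def read_ortholog_map(path: str | Path) -> dict[str, str]:
    """Two-column CSV mapping source subunit accession -> target locus.

    Conflicting one-to-many mappings keep the first target in file order; the
    multiplicity is recorded on the returned dict under ``.attrs`` semantics
    (a plain dict is returned; callers wanting the full many-to-many table
    should read the file themselves).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    src, tgt = df.columns[:2]
    return dict(zip(df[src].astype(str), df[tgt].astype(str)))


def apply_orthology(
    complexes: Sequence[ReferenceComplex], *maps: Mapping[str, str]
) -> list[ReferenceComplex]:
    """Populate each complex's ortholog_map from the union of mapping sources.

    Any-source match counts; the first source listing a subunit wins when
    sources disagree on the target locus.
    """
    out = []
    for cx in complexes:
        omap: dict[str, str] = {}
        for sub in cx.subunit_ids:
            for m in maps:
                if sub in m:
                    omap[sub] = m[sub]
                    break
        out.append(dataclasses.replace(cx, ortholog_map=omap))
    return out


def dedupe_complexes(complexes: Sequence[ReferenceComplex]) -> list[ReferenceComplex]:
    """Collapse complexes whose projected target subunit sets are identical.

    The first record (input order) is kept; the other species' complex ids are
    listed as aliases.  Complexes with no mapped subunits are never collapsed
    into each other.  Idempotent.
    """
    seen: dict[frozenset[str], ReferenceComplex] = {}
    out: list[ReferenceComplex] = []
    for cx in complexes:
        key = cx.target_subunits
        if key and key in seen:
            seen[key].aliases.append(f"{cx.source_species}:{cx.complex_id}")
        else:
            cx = dataclasses.replace(cx, aliases=list(cx.aliases))
            if key:
                seen[key] = cx
            out.append(cx)
    return out


def classify_coverage(n_matched: int, n_subunits: int) -> str:
    """Coverage class from ortholog counts.

    high: >=80% of subunits, or 3 of 4, or 2 of 3; medium: [60%, 80%);
    low: [40%, 60%); none below that.
    """
    if n_subunits < 1 or not 0 <= n_matched <= n_subunits:
        raise ValueError("need 0 <= n_matched <= n_subunits and n_subunits >= 1")
    frac = n_matched / n_subunits
    if frac >= 0.8 or (n_matched, n_subunits) in {(3, 4), (2, 3)}:
        return "high"
    if frac >= 0.6:
        return "medium"
    if frac >= 0.4:
        return "low"
    return "none"


def calc_complex_mass(subunit_masses_kda: Sequence[float]) -> float:
    """Calculated mass of the assembled complex: sum of monomer masses,
    assuming one copy of each subunit."""
    if len(subunit_masses_kda) == 0:
        raise ValueError("empty subunit mass list")
    if any(m <= 0 for m in subunit_masses_kda):
        raise ValueError("subunit masses must be positive")
    return float(sum(subunit_masses_kda))


def compare_masses(
    complexes: Sequence[ReferenceComplex],
    m_app_by_protein: Mapping[str, float],
    monomer_masses: Mapping[str, float],
) -> tuple[pd.DataFrame, float | None]:
    """Per-complex comparison of calculated vs measured masses.

    Returns one row per (complex, measured target subunit) with the complex's
    M_calc (target masses at full coverage) and the subunit's measured M_app,
    plus log10(M_app / M_calc); and the Pearson correlation of
    log10(M_app) vs log10(M_calc) over all rows (None with < 3 rows).
    Complexes with no measured subunits still contribute a row with empty
    measurements so the output enumerates every complex.
    """
    rows = []
    for cx in complexes:
        m_calc = cx.m_calc_target_kda(monomer_masses)
        measured = [
            (t, m_app_by_protein[t]) for t in sorted(cx.target_subunits)
            if t in m_app_by_protein
        ]
        if not measured:
            rows.append(
                {"complex_id": cx.complex_id, "coverage_class": cx.coverage_class,
                 "m_calc_kda": m_calc, "subunit": None, "m_app_kda": None,
                 "log10_ratio": None}
            )
            continue
        for locus, m_app in measured:
            rows.append(
                {"complex_id": cx.complex_id, "coverage_class": cx.coverage_class,
                 "m_calc_kda": m_calc, "subunit": locus, "m_app_kda": m_app,
                 "log10_ratio": (np.log10(m_app / m_calc) if m_calc else None)}
            )
    df = pd.DataFrame(rows)
    scatter = df.dropna(subset=["m_calc_kda", "m_app_kda"])
    r = None
    if len(scatter) >= 3:
        r = float(
            np.corrcoef(np.log10(scatter["m_calc_kda"]), np.log10(scatter["m_app_kda"]))[0, 1]
        )
    return df, r
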