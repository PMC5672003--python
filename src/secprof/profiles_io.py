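"""Readers, writers and domain types for co-fractionation quantification tables.

The central object is the :class:`ElutionProfile`: one protein in one
biological replicate of one separation (SEC column or sucrose velocity
gradient), as a vector of raw XIC-based protein intensities over ordered
fractions.  Input tables are MaxQuant ``proteinGroups``-style exports with one
intensity column per replicate/fraction; absent signal is stored as zero
(an XIC below the detection limit, not missing data).
"""

from __future__ import annotations

import dataclasses
import enum
import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Default pattern for per-fraction intensity columns, e.g. ``Intensity bio1 7``
#: or ``Intensity.bio2.12``.  Group 1 is the replicate id, group 2 the fraction.
INTENSITY_COLUMN_PATTERN = r"^Intensity[._ ](?P<rep>[A-Za-z0-9]+)[._ ](?P<frac>\d+)$"

_ID_COLUMNS = ("protein_id", "Protein IDs", "Majority protein IDs", "Locus")
_PEPTIDE_COLUMNS = ("peptides", "Peptides")
_SCORE_COLUMNS = ("score", "Score")


class SeparationKind(str, enum.Enum):
    SEC_SUPERDEX = "sec_superdex"
    SEC_SUPEROSE = "sec_superose"
    SUCROSE = "sucrose"


@dataclasses.dataclass(frozen=True)
class FractionScheme:
    """Ordered fraction layout of one separation.

    ``void_fraction`` is the fraction containing the column void (blue-dextran
    peak); sucrose gradients have none.  Fraction ids are 1-based, strictly
    increasing and contiguous, so a Gaussian peak center is a continuous
    position on the same axis.
    """

    separation_kind: SeparationKind
    fraction_ids: tuple[int, ...]
    void_fraction: int | None = None

    def __post_init__(self) -> None:
        ids = tuple(int(i) for i in self.fraction_ids)
        object.__setattr__(self, "fraction_ids", ids)
        if len(ids) < 3:
            raise ValueError("a fraction scheme needs at least 3 fractions")
        diffs = np.diff(ids)
        if not np.all(diffs == 1):
            raise ValueError("fraction_ids must be strictly increasing and contiguous")
        if self.void_fraction is not None and self.void_fraction not in ids:
            raise ValueError(
                f"void_fraction {self.void_fraction} not among fraction_ids"
            )

    @property
    def n_fractions(self) -> int:
        return len(self.fraction_ids)


@dataclasses.dataclass
class ElutionProfile:
    """Per-fraction intensity vector for one protein x replicate x separation."""

    protein_id: str
    replicate_id: str
    scheme: FractionScheme
    intensities: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.intensities, dtype=float)
        if y.shape != (self.scheme.n_fractions,):
            raise ValueError(
                f"{self.protein_id}/{self.replicate_id}: expected "
                f"{self.scheme.n_fractions} intensities, got {y.shape}"
            )
        if np.any(y < 0) or not np.all(np.isfinite(y)):
            raise ValueError(f"{self.protein_id}: intensities must be finite and >= 0")
        self.intensities = y

    def nonzero_fractions(self) -> np.ndarray:
        """Fraction ids with intensity > 0."""
        ids = np.asarray(self.scheme.fraction_ids)
        return ids[self.intensities > 0]

    @property
    def is_empty(self) -> bool:
        return bool(np.all(self.intensities == 0))


@dataclasses.dataclass
class ProteinRecord:
    """Identification metadata and annotation for one protein group."""

    protein_id: str
    peptide_count: int = 1
    id_score: float = float("inf")
    monomer_mass_kda: float | None = None
    localization_label: str | None = None
    tmd_count: int | None = None

    def __post_init__(self) -> None:
        if self.peptide_count < 1:
            raise ValueError(f"{self.protein_id}: peptide_count must be >= 1")
        if self.monomer_mass_kda is not None and self.monomer_mass_kda <= 0:
            raise ValueError(f"{self.protein_id}: monomer_mass_kda must be > 0")


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _find_column(df: pd.DataFrame, candidates: Sequence[str], what: str) -> str:
    for c in candidates:
        if c in df.columns:
            return c
    raise ValueError(f"no {what} column found (tried {', '.join(candidates)})")


def read_quant_table(
    path: str | Path,
    scheme: FractionScheme,
    intensity_pattern: str = INTENSITY_COLUMN_PATTERN,
) -> tuple[list[ElutionProfile], dict[str, ProteinRecord]]:
    """Parse a proteinGroups-style quantification table.

    Returns one :class:`ElutionProfile` per protein per replicate found in the
    intensity columns, plus a :class:`ProteinRecord` per protein carrying the
    peptide count and identification score.  Blank intensity cells become 0.

    Raises ``ValueError`` if a declared fraction has no intensity column for a
    replicate, or if a protein id appears twice.
    """
    path = Path(path)
    # round_trip parsing: the default C float parser is off by one ulp on
    # some values, which would break bit-exact write/read round trips
    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#",
                     float_precision="round_trip")
    pat = re.compile(intensity_pattern)

    # map replicate -> {fraction -> column name}
    columns: dict[str, dict[int, str]] = {}
    for col in df.columns:
        m = pat.match(str(col))
        if m:
            columns.setdefault(m.group("rep"), {})[int(m.group("frac"))] = col
    if not columns:
        raise ValueError(f"{path}: no intensity columns match {intensity_pattern!r}")
    for rep, frac_cols in columns.items():
        for fid in scheme.fraction_ids:
            if fid not in frac_cols:
                raise ValueError(
                    f"{path}: replicate {rep} is missing the intensity column "
                    f"for fraction {fid}"
                )

    id_col = _find_column(df, _ID_COLUMNS, "protein id")
    if df[id_col].duplicated().any():
        dup = df[id_col][df[id_col].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate protein_id {dup!r}")

    pep_col = next((c for c in _PEPTIDE_COLUMNS if c in df.columns), None)
    score_col = next((c for c in _SCORE_COLUMNS if c in df.columns), None)

    profiles: list[ElutionProfile] = []
    records: dict[str, ProteinRecord] = {}
    for _, row in df.iterrows():
        pid = str(row[id_col])
        records[pid] = ProteinRecord(
            protein_id=pid,
            peptide_count=int(row[pep_col]) if pep_col else 1,
            id_score=float(row[score_col]) if score_col else float("inf"),
        )
        for rep in sorted(columns):
            vals = np.array(
                [row[columns[rep][fid]] for fid in scheme.fraction_ids], dtype=float
            )
            vals = np.nan_to_num(vals, nan=0.0)
            profiles.append(ElutionProfile(pid, rep, scheme, vals))
    return profiles, records


def write_quant_table(
    profiles: Iterable[ElutionProfile],
    records: dict[str, ProteinRecord] | None,
    path: str | Path,
) -> None:
    """Write profiles (and optional id metadata) as a tab-separated table.

    The column layout round-trips through :func:`read_quant_table` with the
    default intensity pattern, preserving intensities bit-exactly.
    """
    by_protein: dict[str, dict[str, ElutionProfile]] = {}
    schemes: list[FractionScheme] = []
    for p in profiles:
        by_protein.setdefault(p.protein_id, {})[p.replicate_id] = p
        schemes.append(p.scheme)
    if not by_protein:
        raise ValueError("nothing to write")
    scheme = schemes[0]
    reps = sorted({p.replicate_id for d in by_protein.values() for p in d.values()})

    rows = []
    for pid, reps_d in by_protein.items():
        row: dict[str, object] = {"protein_id": pid}
        if records and pid in records:
            row["peptides"] = records[pid].peptide_count
            row["score"] = records[pid].id_score
        for rep in reps:
            prof = reps_d.get(rep)
            y = prof.intensities if prof is not None else np.zeros(scheme.n_fractions)
            for fid, v in zip(scheme.fraction_ids, y):
                row[f"Intensity {rep} {fid}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def filter_identifications(
    records: dict[str, ProteinRecord],
) -> dict[str, ProteinRecord]:
    """Drop single-peptide identifications with score < 5; keep everything else.

    Idempotent, never adds records.
    """
    return {
        pid: r
        for pid, r in records.items()
        if not (r.peptide_count == 1 and r.id_score < 5.0)
    }


def pair_replicates(
    profiles: Iterable[ElutionProfile],
) -> tuple[list[tuple[ElutionProfile, ElutionProfile]], list[str]]:
    """Pair each protein's profiles across the two biological replicates.

    A protein is "detected" in a replicate if any intensity is nonzero; only
    proteins detected in both replicates are paired.  Returns the pairs and a
    drop log of protein ids seen in one replicate only.
    """
    by_protein: dict[str, dict[str, ElutionProfile]] = {}
    rep_ids: set[str] = set()
    for p in profiles:
        if not p.is_empty:
            by_protein.setdefault(p.protein_id, {})[p.replicate_id] = p
            rep_ids.add(p.replicate_id)
    if len(rep_ids) > 2:
        raise ValueError(f"expected at most 2 replicates, got {sorted(rep_ids)}")

    pairs: list[tuple[ElutionProfile, ElutionProfile]] = []
    dropped: list[str] = []
    for pid in sorted(by_protein):
        reps = by_protein[pid]
        if len(reps) == 2:
            r1, r2 = sorted(reps)
            pairs.append((reps[r1], reps[r2]))
        else:
            dropped.append(pid)
            log.debug("protein %s detected in one replicate only; dropped", pid)
    return pairs, dropped


def read_calibration_table(path: str | Path) -> list[tuple[float, float]]:
    """Read SEC standards as (mass_kda, peak_fraction) pairs from CSV/TSV."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    if not {"mass_kda", "peak_fraction"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns mass_kda, peak_fraction")
    return list(zip(df["mass_kda"].astype(float), df["peak_fraction"].astype(float)))


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read the protein annotation table (locus, monomer mass, localization, TMDs)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    if "protein_id" not in df.columns or "monomer_mass_kda" not in df.columns:
        raise ValueError(f"{path}: expected columns protein_id, monomer_mass_kda")
    return df


def attach_annotations(
    records: dict[str, ProteinRecord], annotations: pd.DataFrame
) -> dict[str, ProteinRecord]:
    """Merge annotation columns into existing records (by protein_id)."""
    ann = annotations.set_index("protein_id")
    out: dict[str, ProteinRecord] = {}
    for pid, rec in records.items():
        rec = dataclasses.replace(rec)
        if pid in ann.index:
            row = ann.loc[pid]
            rec.monomer_mass_kda = float(row["monomer_mass_kda"])
            if "localization_label" in ann.columns and pd.notna(
                row.get("localization_label")
            ):
                rec.localization_label = str(row["localization_label"])
            if "tmd_count" in ann.columns and pd.notna(row.get("tmd_count")):
                rec.tmd_count = int(row["tmd_count"])
        out[pid] = rec
    return out


def write_table(df: pd.DataFrame, path: str | Path, config_hash: str | None = None) -> None:
    """Write a result table as TSV, optionally prefixed with a config-hash comment."""
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)
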