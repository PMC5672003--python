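"""Presence/absence acceptance of CoIP-MS interactors.

The design is three biological replicates with the antibody of interest and
three with preimmune serum.  A protein counts as "identified" in a replicate
when its XIC intensity is nonzero; intensities are otherwise not compared.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

N_REPLICATES = 3


@dataclasses.dataclass(frozen=True)
class CoIPDetection:
    protein_id: str
    peptide_count: int
    antibody_hits: int
    control_hits: int

    def __post_init__(self) -> None:
        for name, hits in (("antibody", self.antibody_hits), ("control", self.control_hits)):
            if not 0 <= hits <= N_REPLICATES:
                raise ValueError(
                    f"{self.protein_id}: {name}_hits {hits} outside [0, {N_REPLICATES}]"
                )


def accept_interactor(d: CoIPDetection) -> bool:
    """Accept a CoIP interactor on replicate presence/absence.

    Requires two or more peptides, and either detection in 2 of 3 antibody
    replicates with zero signal in every control, or detection in all 3
    antibody replicates with signal in at most one control.
    """
    if d.peptide_count < 2:
        return False
    return (d.antibody_hits >= 2 and d.control_hits == 0) or (
        d.antibody_hits == 3 and d.control_hits <= 1
    )


def filter_coip_table(path: str | Path) -> pd.DataFrame:
    """Apply the acceptance rule to a table of raw CoIP intensities.

    Expected columns: protein_id, peptides, ab1..ab3, ctl1..ctl3.  Returns the
    table with antibody_hits, control_hits and accepted columns appended.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    ab_cols = [c for c in df.columns if c.lower().startswith("ab")]
    ctl_cols = [c for c in df.columns if c.lower().startswith("ctl")]
    if len(ab_cols) != N_REPLICATES or len(ctl_cols) != N_REPLICATES:
        raise ValueError(f"expected {N_REPLICATES} antibody and control columns")
    df["antibody_hits"] = (df[ab_cols] > 0).sum(axis=1)
    df["control_hits"] = (df[ctl_cols] > 0).sum(axis=1)
    df["accepted"] = [
        accept_interactor(
            CoIPDetection(str(r.protein_id), int(r.peptides),
                          int(r.antibody_hits), int(r.control_hits))
        )
        for r in df.itertuples()
    ]
    return df
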