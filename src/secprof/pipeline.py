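"""End-to-end orchestration of the profiling analysis.

Stages: identification filtering -> replicate pairing -> calibration ->
Gaussian deconvolution per replicate -> cross-replicate peak matching and
labelling -> apparent masses and oligomer calls -> sucrose-based membrane
filtering -> dual-localization screening -> reference-complex coverage ->
replicate-correlation and clustering analytics.  Every stage logs how many
records it kept and dropped so kept + dropped always reconciles with the
input count.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import (
    calibration,
    complex_db,
    localization,
    oligomer,
    peakfit,
    profile_analytics,
    profiles_io,
    reproducibility,
)
from .profiles_io import ElutionProfile, ProteinRecord


@dataclasses.dataclass
class PipelineConfig:
    """All decision thresholds of the pipeline, with their standard defaults."""

    max_shift: float = 2.0
    rapp_complex: float = 2.0
    rapp_large: float = 10.0
    rapp_degraded: float = 0.5
    secondary_height: float = 0.2
    min_separation: float = 4.0
    sucrose_boundary: float = 8.0
    large_cytosolic_kda: float = 450.0
    max_peaks: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("max_shift", "rapp_complex", "rapp_large", "rapp_degraded",
                     "secondary_height", "min_separation", "sucrose_boundary",
                     "large_cytosolic_kda"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 1 <= self.max_peaks <= 4:
            raise ValueError("max_peaks must be in 1..4")

    @property
    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def peak_models_to_table(models: Sequence[peakfit.PeakModel]) -> pd.DataFrame:
    rows = []
    for m in models:
        if not m.peaks:
            rows.append({"protein_id": m.protein_id, "replicate": m.replicate_id,
                         "method": m.method.value, "peak_index": None, "center": None,
                         "sigma": None, "amplitude": None, "relative_height": None,
                         "resolved": None, "bic": m.bic})
        for j, p in enumerate(m.peaks):
            rows.append({"protein_id": m.protein_id, "replicate": m.replicate_id,
                         "method": m.method.value, "peak_index": j, "center": p.center,
                         "sigma": p.sigma, "amplitude": p.amplitude,
                         "relative_height": p.relative_height, "resolved": p.resolved,
                         "bic": m.bic})
    return pd.DataFrame(rows)


def peak_models_from_table(df: pd.DataFrame) -> list[peakfit.PeakModel]:
    models = []
    for (pid, rep), grp in df.groupby(["protein_id", "replicate"], sort=True):
        method = peakfit.FitMethod(grp["method"].iloc[0])
        peaks = [
            peakfit.FittedPeak(
                center=float(r.center), sigma=float(r.sigma),
                amplitude=float(r.amplitude),
                relative_height=float(r.relative_height), resolved=bool(r.resolved),
            )
            for r in grp.itertuples()
            if pd.notna(r.center)
        ]
        bic = grp["bic"].iloc[0]
        models.append(
            peakfit.PeakModel(str(pid), str(rep), method, peaks,
                              bic=None if pd.isna(bic) else float(bic))
        )
    return models


def _fit_pairs(
    pairs: Iterable[tuple[ElutionProfile, ElutionProfile]],
    cfg: PipelineConfig,
) -> tuple[list[peakfit.PeakModel], list[tuple], list[str]]:
    """Fit both replicates of each paired protein; drop proteins with an
    ineligible replicate."""
    models: list[peakfit.PeakModel] = []
    fitted_pairs: list[tuple] = []
    dropped: list[str] = []
    for p1, p2 in pairs:
        void = p1.scheme.void_fraction
        m1 = peakfit.fit_profile(
            p1, void_fraction=void, max_peaks=cfg.max_peaks,
            min_separation=cfg.min_separation,
            min_relative_height=cfg.secondary_height,
        )
        m2 = peakfit.fit_profile(
            p2, void_fraction=void, max_peaks=cfg.max_peaks,
            min_separation=cfg.min_separation,
            min_relative_height=cfg.secondary_height,
        )
        if m1.method is peakfit.FitMethod.INELIGIBLE or m2.method is peakfit.FitMethod.INELIGIBLE:
            dropped.append(p1.protein_id)
            continue
        models += [m1, m2]
        fitted_pairs.append((m1, m2))
    return models, fitted_pairs, dropped


def _reproducible_table(peaks: list[reproducibility.ReproduciblePeak]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"protein_id": p.protein_id, "label": p.label,
             "center_rep1": p.center_rep1, "center_rep2": p.center_rep2,
             "shift": p.shift, "resolved": p.resolved, "amplitude": p.amplitude,
             "m_app_rep1": p.m_app_rep1, "m_app_rep2": p.m_app_rep2,
             "m_app_mean": p.m_app_mean, "extrapolated": p.extrapolated}
            for p in peaks
        ],
        columns=["protein_id", "label", "center_rep1", "center_rep2", "shift",
                 "resolved", "amplitude", "m_app_rep1", "m_app_rep2", "m_app_mean",
                 "extrapolated"],
    )


def run_pipeline(
    sec_profiles: Sequence[ElutionProfile],
    records: dict[str, ProteinRecord],
    standards: list[tuple[float, float]],
    config: PipelineConfig | None = None,
    sucrose_profiles: Sequence[ElutionProfile] | None = None,
    cytosol_table: pd.DataFrame | None = None,
    complexes: Sequence[complex_db.ReferenceComplex] | None = None,
    ortholog_maps: Sequence[dict] = (),
) -> dict:
    """Run every analysis stage on in-memory inputs.

    Returns a dict of result tables (``peaks``, ``reproducible``,
    ``oligomer_calls``, ``membrane_calls``, ``dual_localization``,
    ``coverage``, ``correlation``, ``cluster_newick``) plus a ``drop_log``
    reconciling record counts and the ``config_hash``.
    """
    cfg = config or PipelineConfig()
    drop_log: dict[str, int] = {"input_proteins": len(records)}

    # 1. identification filter
    kept = profiles_io.filter_identifications(records)
    drop_log["id_filter_dropped"] = len(records) - len(kept)
    sec = [p for p in sec_profiles if p.protein_id in kept]

    # 2. replicate pairing
    pairs, single_rep = profiles_io.pair_replicates(sec)
    drop_log["single_replicate_dropped"] = len(single_rep)

    # 3. calibration
    cal = calibration.fit_calibration(standards)

    # 4. deconvolution
    models, fitted_pairs, ineligible = _fit_pairs(pairs, cfg)
    drop_log["ineligible_dropped"] = len(ineligible)
    peaks_table = peak_models_to_table(models)

    # 5-6. reproducibility, labels, oligomer calls
    reproducible: list[reproducibility.ReproduciblePeak] = []
    calls: list[oligomer.OligomerCall] = []
    no_reproducible: list[str] = []
    for m1, m2 in fitted_pairs:
        matched, _ = reproducibility.match_peaks(m1, m2, max_shift=cfg.max_shift)
        if not matched:
            no_reproducible.append(m1.protein_id)
            continue
        labelled = reproducibility.assign_labels(matched, cal)
        reproducible += labelled
        m_mono = kept[m1.protein_id].monomer_mass_kda
        if m_mono is None:
            continue
        for pk in labelled:
            calls.append(
                oligomer.call_oligomer(
                    pk, m_mono,
                    complex_threshold=cfg.rapp_complex,
                    degraded_below=cfg.rapp_degraded,
                    large_at=cfg.rapp_large,
                )
            )
    drop_log["no_reproducible_peak_dropped"] = len(no_reproducible)
    drop_log["proteins_with_reproducible_peaks"] = len(
        {p.protein_id for p in reproducible}
    )
    detected = {p.protein_id for p in sec if not p.is_empty}
    drop_log["not_detected_dropped"] = len(kept) - len(detected)
    # conservation: every input protein is accounted for exactly once
    assert drop_log["input_proteins"] == (
        drop_log["id_filter_dropped"]
        + drop_log["not_detected_dropped"]
        + drop_log["single_replicate_dropped"]
        + drop_log["ineligible_dropped"]
        + drop_log["no_reproducible_peak_dropped"]
        + drop_log["proteins_with_reproducible_peaks"]
    )

    rep_table = _reproducible_table(reproducible)
    calls_table = pd.DataFrame(
        [
            {"protein_id": c.protein_id, "label": c.label,
             "r_app_rep1": c.r_app_rep1, "r_app_rep2": c.r_app_rep2,
             "r_app_mean": c.r_app_mean, "state": c.state.value,
             "is_complex": c.is_complex}
            for c in calls
        ],
        columns=["protein_id", "label", "r_app_rep1", "r_app_rep2", "r_app_mean",
                 "state", "is_complex"],
    )

    # 7. sucrose-based membrane filter
    membrane_rows = []
    dual_rows = []
    if sucrose_profiles is not None:
        suc = [p for p in sucrose_profiles if p.protein_id in kept]
        suc_pairs, _ = profiles_io.pair_replicates(suc)
        _, suc_fitted, _ = _fit_pairs(suc_pairs, cfg)
        suc_matched: dict[str, list[reproducibility.ReproduciblePeak]] = {}
        for m1, m2 in suc_fitted:
            matched, _ = reproducibility.match_peaks(m1, m2, max_shift=cfg.max_shift)
            suc_matched[m1.protein_id] = matched

        cytosol_ids = (
            set(cytosol_table["protein_id"].astype(str))
            if cytosol_table is not None
            else set()
        )
        cytosol_masses = (
            cytosol_table.dropna(subset=["m_app_cytosol_kda"])
            .set_index("protein_id")["m_app_cytosol_kda"]
            .to_dict()
            if cytosol_table is not None
            else {}
        )
        detected_in_sec = {p.protein_id for p in sec if not p.is_empty}
        membrane_masses = (
            rep_table[rep_table["resolved"]]
            .sort_values(["protein_id", "amplitude"], ascending=[True, False])
            .groupby("protein_id")["m_app_mean"]
            .first()
            .to_dict()
        )
        for pid in sorted(detected_in_sec):
            evidence = localization.sucrose_evidence(
                suc_matched.get(pid, []), boundary_fraction=cfg.sucrose_boundary
            )
            call = localization.call_membrane(
                pid, in_cholate=True, in_cytosol=pid in cytosol_ids, evidence=evidence
            )
            membrane_rows.append(
                {"protein_id": pid, "status": call.status.value,
                 "evidence": call.evidence.value}
            )
            # 8. dual-localization screen
            if (
                call.status is localization.MembraneStatus.MEMBRANE_ASSOCIATED
                and pid in cytosol_masses
                and pid in membrane_masses
            ):
                d = localization.flag_dual_localized(
                    pid, float(cytosol_masses[pid]), float(membrane_masses[pid]),
                    large_cytosolic_cutoff_kda=cfg.large_cytosolic_kda,
                )
                dual_rows.append(
                    {"protein_id": pid, "m_app_cytosol_kda": d.m_app_cytosol_kda,
                     "m_app_membrane_kda": d.m_app_membrane_kda, "ratio": d.ratio,
                     "shifted": d.shifted,
                     "excluded_large_cytosolic": d.excluded_large_cytosolic}
                )
    membrane_table = pd.DataFrame(
        membrane_rows, columns=["protein_id", "status", "evidence"]
    )
    dual_table = pd.DataFrame(
        dual_rows,
        columns=["protein_id", "m_app_cytosol_kda", "m_app_membrane_kda", "ratio",
                 "shifted", "excluded_large_cytosolic"],
    )

    # 9. reference-complex coverage
    coverage_table = pd.DataFrame(
        columns=["complex_id", "species", "n_subunits", "n_matched",
                 "coverage_class", "aliases"]
    )
    comparison_table, mass_corr = pd.DataFrame(), None
    if complexes is not None:
        mapped = complex_db.apply_orthology(complexes, *ortholog_maps)
        deduped = complex_db.dedupe_complexes(mapped)
        coverage_table = pd.DataFrame(
            [
                {"complex_id": cx.complex_id, "species": cx.source_species,
                 "n_subunits": cx.n_subunits, "n_matched": cx.n_matched,
                 "coverage_class": cx.coverage_class,
                 "aliases": ";".join(cx.aliases)}
                for cx in deduped
            ]
        )
        m_app_by_protein = (
            rep_table[rep_table["resolved"]]
            .groupby("protein_id")["m_app_mean"].max().to_dict()
        )
        monomer_masses = {
            pid: r.monomer_mass_kda
            for pid, r in kept.items()
            if r.monomer_mass_kda is not None
        }
        comparison_table, mass_corr = complex_db.compare_masses(
            deduped, m_app_by_protein, monomer_masses
        )

    # 10. analytics
    correlation = None
    cluster_newick = None
    by_rep: dict[str, list[ElutionProfile]] = {}
    for p in sec:
        by_rep.setdefault(p.replicate_id, []).append(p)
    reps = sorted(by_rep)
    if len(reps) == 2:
        m1 = profile_analytics.profiles_to_matrix(by_rep[reps[0]])
        m2 = profile_analytics.profiles_to_matrix(by_rep[reps[1]])
        try:
            correlation = profile_analytics.fraction_correlation(m1, m2)
        except ValueError:
            correlation = None
    rep1_models = [m for m, _ in fitted_pairs if m.peaks]
    if len(rep1_models) >= 3:
        grid = sec_profiles[0].scheme.fraction_ids
        recon = profile_analytics.reconstruct_profiles(rep1_models, grid)
        norm = profile_analytics.normalize_unit_max(recon)
        if len(norm.data) >= 3:
            leaves, linkage = profile_analytics.cluster_profiles(norm)
            cluster_newick = profile_analytics.linkage_to_newick(
                linkage, list(norm.data.sort_index().index)
            )

    return {
        "peaks": peaks_table,
        "reproducible": rep_table,
        "oligomer_calls": calls_table,
        "membrane_calls": membrane_table,
        "dual_localization": dual_table,
        "coverage": coverage_table,
        "mass_comparison": comparison_table,
        "mass_correlation": mass_corr,
        "correlation": correlation,
        "cluster_newick": cluster_newick,
        "calibration": cal,
        "drop_log": drop_log,
        "config_hash": cfg.hash,
    }


def write_results(results: dict, outdir) -> None:
    """Write every tabular result (and the dendrogram) into a directory."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = results["config_hash"]
    for key in ("peaks", "reproducible", "oligomer_calls", "membrane_calls",
                "dual_localization", "coverage", "mass_comparison"):
        profiles_io.write_table(results[key], outdir / f"{key}.tsv", config_hash=h)
    if results["correlation"] is not None:
        results["correlation"].to_csv(outdir / "replicate_correlation.tsv", sep="\t")
    if results["cluster_newick"] is not None:
        (outdir / "profile_clusters.nwk").write_text(results["cluster_newick"] + "\n")
    results["calibration"].to_json(outdir / "calibration.json")
    with open(outdir / "run_log.json", "w") as fh:
        json.dump({"config_hash": h, "drop_log": results["drop_log"]}, fh, indent=2)
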