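"""Ground-truth-labelled simulation of co-fractionation profiling experiments.

The generator emulates the inputs of a membrane PCP study: two biological
replicates of SEC elution profiles (24 fractions, void in fraction 2) and of
a sucrose velocity gradient (25 fractions), a noiseless log-linear standards
table spanning 29-669 kDa, and a protein annotation table.  Each protein is
assigned an oligomerization state (degraded / monomer / small complex /
large complex at target R_app 0.3 / 1 / 4 / 12), its primary SEC peak is
placed at the fraction implied by M_app = R_app x M_mono through the
calibration law, and optional secondary peaks, replicate jitter,
multiplicative (log-normal) noise, an additive floor, and per-fraction
dropout are layered on top.  A configurable subpopulation is void-trapped
(aggregates that never leave the void) and another is cytosolic contaminants
whose sucrose peaks stay in the top eight fractions, with occasional
bleed-through, while true membrane proteins penetrate to fractions 10-24.

Every generated quantity is recorded in a :class:`GroundTruth` so any stage
of the analysis can be scored against the simulation.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .profiles_io import (
    ElutionProfile,
    FractionScheme,
    ProteinRecord,
    SeparationKind,
    write_quant_table,
)

#: Gel-filtration standard masses (kDa), 669 down to 29.
STANDARD_MASSES_KDA = (669.0, 443.0, 200.0, 150.0, 66.0, 29.0)

STATE_NAMES = ("degraded", "monomer", "small_complex", "large_complex")


@dataclasses.dataclass
class SimulationConfig:
    """Knobs of the simulated study; the seed fully determines the output."""

    seed: int = 0
    n_proteins: int = 500
    sec_fractions: int = 24
    sucrose_fractions: int = 25
    void_fraction: int = 2
    # peak counts per protein, probabilities for 1..4 peaks
    peak_count_probs: tuple[float, ...] = (0.82, 0.14, 0.03, 0.01)
    min_separation: float = 4.0
    sigma_range: tuple[float, float] = (1.0, 2.5)
    secondary_height_range: tuple[float, float] = (0.4, 1.0)
    amplitude_log_mean: float = math.log(1e7)
    amplitude_log_sd: float = 1.0
    jitter_sd: float = 0.5
    jitter_max: float = 2.0
    noise_cv: float = 0.2
    additive_floor_rel: float = 0.01
    detection_floor_rel: float = 0.002
    dropout_prob: float = 0.05
    #: dropout emulates detection loss, so it only strikes fractions whose
    #: noiseless signal is below this fraction of the profile maximum
    dropout_max_rel: float = 0.25
    void_trapped_frac: float = 0.10
    contaminant_frac: float = 0.30
    dual_localized_frac: float = 0.30
    dual_shift_prob: float = 0.25
    contaminant_bleed_prob: float = 0.10
    state_probs: tuple[float, ...] = (0.05, 0.45, 0.30, 0.20)
    state_rapp: tuple[float, ...] = (0.3, 1.0, 4.0, 12.0)
    monomer_mass_range_kda: tuple[float, float] = (15.0, 200.0)

    def __post_init__(self) -> None:
        for probs in (self.peak_count_probs, self.state_probs):
            if any(p < 0 for p in probs) or not math.isclose(sum(probs), 1.0, abs_tol=1e-9):
                raise ValueError("probability vectors must be nonnegative and sum to 1")
        for p in (self.dropout_prob, self.void_trapped_frac, self.contaminant_frac,
                  self.dual_localized_frac, self.dual_shift_prob,
                  self.contaminant_bleed_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        span = (self.sec_fractions - 1) - (self.void_fraction + 1)
        max_feasible = 1 + int(span // self.min_separation)
        wanted = max(k + 1 for k, p in enumerate(self.peak_count_probs) if p > 0)
        if wanted > max_feasible:
            raise ValueError(
                f"{wanted} peaks with >= {self.min_separation}-fraction separation "
                f"do not fit in {span} resolvable fractions"
            )


@dataclasses.dataclass
class GroundTruth:
    """Per-protein and per-peak truth tables for one simulated dataset."""

    proteins: pd.DataFrame
    sec_peaks: pd.DataFrame
    sucrose_peaks: pd.DataFrame


@dataclasses.dataclass
class SimulatedDataset:
    config: SimulationConfig
    sec_scheme: FractionScheme
    sucrose_scheme: FractionScheme
    sec_profiles: list[ElutionProfile]
    sucrose_profiles: list[ElutionProfile]
    records: dict[str, ProteinRecord]
    standards: list[tuple[float, float]]
    annotations: pd.DataFrame
    cytosol_table: pd.DataFrame
    truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        """Write all inputs as plain-text tables readable by profiles_io."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_quant_table(self.sec_profiles, self.records, outdir / "sec_quant.tsv")
        write_quant_table(self.sucrose_profiles, self.records, outdir / "sucrose_quant.tsv")
        pd.DataFrame(self.standards, columns=["mass_kda", "peak_fraction"]).to_csv(
            outdir / "standards.csv", index=False
        )
        self.annotations.to_csv(outdir / "annotations.csv", index=False)
        self.cytosol_table.to_csv(outdir / "cytosol_masses.csv", index=False)
        self.truth.proteins.to_csv(outdir / "truth_proteins.tsv", sep="\t", index=False)
        self.truth.sec_peaks.to_csv(outdir / "truth_sec_peaks.tsv", sep="\t", index=False)
        self.truth.sucrose_peaks.to_csv(
            outdir / "truth_sucrose_peaks.tsv", sep="\t", index=False
        )


def calibration_law(cfg: SimulationConfig) -> tuple[float, float]:
    """Slope/intercept of the noiseless log10(kDa)-vs-fraction law.

    Anchored so the largest standard (669 kDa) elutes one fraction past the
    void and the smallest (29 kDa) in the penultimate fraction.
    """
    f_hi = cfg.void_fraction + 1
    f_lo = cfg.sec_fractions - 1
    m_hi, m_lo = max(STANDARD_MASSES_KDA), min(STANDARD_MASSES_KDA)
    slope = (math.log10(m_lo) - math.log10(m_hi)) / (f_lo - f_hi)
    intercept = math.log10(m_hi) - slope * f_hi
    return slope, intercept


def make_standards(cfg: SimulationConfig) -> list[tuple[float, float]]:
    """Standards placed exactly on the calibration law (noiseless)."""
    slope, intercept = calibration_law(cfg)
    return [
        (m, (math.log10(m) - intercept) / slope) for m in STANDARD_MASSES_KDA
    ]


def _center_from_mass(mass: float, slope: float, intercept: float) -> float:
    return (math.log10(mass) - intercept) / slope


def _mass_from_center(center: float, slope: float, intercept: float) -> float:
    return 10.0 ** (slope * center + intercept)


def _jitter(rng: np.random.Generator, cfg: SimulationConfig) -> float:
    return float(np.clip(rng.normal(0.0, cfg.jitter_sd), -cfg.jitter_max, cfg.jitter_max))


def _render_profile(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    grid: np.ndarray,
    peaks: list[tuple[float, float, float]],  # (amplitude, center, sigma)
) -> np.ndarray:
    y0 = np.zeros_like(grid)
    for a, mu, s in peaks:
        y0 += a * np.exp(-((grid - mu) ** 2) / (2.0 * s**2))
    a_max = max(a for a, _, _ in peaks)
    y = y0.copy()
    if cfg.noise_cv > 0:
        sd_ln = math.sqrt(math.log(1.0 + cfg.noise_cv**2))
        y = y * rng.lognormal(mean=-0.5 * sd_ln**2, sigma=sd_ln, size=y.shape)
    if cfg.additive_floor_rel > 0:
        y = y + np.abs(rng.normal(0.0, cfg.additive_floor_rel * a_max, size=y.shape))
    if cfg.dropout_prob > 0:
        # detection loss: only low-signal fractions can drop out entirely
        droppable = y0 < cfg.dropout_max_rel * a_max
        y[droppable & (rng.random(y.shape) < cfg.dropout_prob)] = 0.0
    y[y < cfg.detection_floor_rel * a_max] = 0.0
    return y


def simulate_dataset(cfg: SimulationConfig, outdir: str | Path | None = None) -> SimulatedDataset:
    """Generate a full labelled dataset; deterministic for a given seed."""
    rng = np.random.default_rng(cfg.seed)
    slope, intercept = calibration_law(cfg)
    sec_scheme = FractionScheme(
        SeparationKind.SEC_SUPERDEX,
        tuple(range(1, cfg.sec_fractions + 1)),
        void_fraction=cfg.void_fraction,
    )
    suc_scheme = FractionScheme(
        SeparationKind.SUCROSE, tuple(range(1, cfg.sucrose_fractions + 1))
    )
    sec_grid = np.arange(1, cfg.sec_fractions + 1, dtype=float)
    suc_grid = np.arange(1, cfg.sucrose_fractions + 1, dtype=float)
    center_lo = cfg.void_fraction + 1.2
    center_hi = cfg.sec_fractions - 1.0
    m_lo, m_hi = cfg.monomer_mass_range_kda

    sec_profiles: list[ElutionProfile] = []
    suc_profiles: list[ElutionProfile] = []
    records: dict[str, ProteinRecord] = {}
    prot_rows, sec_rows, suc_rows, ann_rows, cyt_rows = [], [], [], [], []

    for i in range(cfg.n_proteins):
        pid = f"SIM{i:05d}"
        contaminant = rng.random() < cfg.contaminant_frac
        void_trapped = (not contaminant) and rng.random() < cfg.void_trapped_frac
        state_idx = int(rng.choice(len(cfg.state_probs), p=cfg.state_probs))
        r_target = cfg.state_rapp[state_idx]

        # monomer mass: log-uniform, resampled until the implied primary peak
        # lands inside the resolvable window
        for _ in range(1000):
            m_mono = float(np.exp(rng.uniform(math.log(m_lo), math.log(m_hi))))
            center0 = _center_from_mass(r_target * m_mono, slope, intercept)
            if center_lo <= center0 <= center_hi:
                break
        else:
            center0 = float(np.clip(center0, center_lo, center_hi))
            m_mono = _mass_from_center(center0, slope, intercept) / r_target

        a_primary = float(rng.lognormal(cfg.amplitude_log_mean, cfg.amplitude_log_sd))

        if void_trapped:
            base_peaks = [(a_primary, float(cfg.void_fraction), 1.0)]
        else:
            n_peaks = 1 + int(rng.choice(len(cfg.peak_count_probs), p=cfg.peak_count_probs))
            centers = [center0]
            for _ in range(n_peaks - 1):
                for _try in range(200):
                    c = float(rng.uniform(center_lo, center_hi))
                    if all(abs(c - c0) >= cfg.min_separation for c0 in centers):
                        centers.append(c)
                        break
            base_peaks = []
            for j, c in enumerate(centers):
                h = 1.0 if j == 0 else float(rng.uniform(*cfg.secondary_height_range))
                s = float(rng.uniform(*cfg.sigma_range))
                base_peaks.append((a_primary * h, c, s))

        # SEC replicates with independent per-peak jitter
        for rep in ("bio1", "bio2"):
            jittered = [
                (a, mu + _jitter(rng, cfg), s) for a, mu, s in base_peaks
            ]
            y = _render_profile(rng, cfg, sec_grid, jittered)
            sec_profiles.append(ElutionProfile(pid, rep, sec_scheme, y))
            for j, (a, mu, s) in enumerate(jittered):
                resolved = mu >= cfg.void_fraction + 1
                m_app = _mass_from_center(mu, slope, intercept) if resolved else None
                sec_rows.append(
                    {"protein_id": pid, "replicate": rep, "peak_index": j,
                     "center": mu, "base_center": base_peaks[j][1], "sigma": s,
                     "amplitude": a, "resolved": resolved, "m_app_kda": m_app,
                     "r_app": (m_app / m_mono) if m_app else None}
                )

        # sucrose gradient: membrane proteins penetrate deep, contaminants stay
        # shallow (with occasional low-level bleed-through)
        if contaminant:
            suc_center = float(rng.uniform(2.0, 7.5))
        else:
            suc_center = float(rng.uniform(10.0, cfg.sucrose_fractions - 1.0))
        suc_sigma = float(rng.uniform(*cfg.sigma_range))
        suc_amp = float(rng.lognormal(cfg.amplitude_log_mean, cfg.amplitude_log_sd))
        suc_base = [(suc_amp, suc_center, suc_sigma)]
        if contaminant and rng.random() < cfg.contaminant_bleed_prob:
            suc_base.append(
                (0.1 * suc_amp, float(rng.uniform(12.0, 20.0)), suc_sigma)
            )
        for rep in ("bio1", "bio2"):
            jittered = [(a, mu + _jitter(rng, cfg), s) for a, mu, s in suc_base]
            y = _render_profile(rng, cfg, suc_grid, jittered)
            suc_profiles.append(ElutionProfile(pid, rep, suc_scheme, y))
            for j, (a, mu, s) in enumerate(jittered):
                suc_rows.append(
                    {"protein_id": pid, "replicate": rep, "peak_index": j,
                     "center": mu, "base_center": suc_base[j][1], "sigma": s,
                     "amplitude": a}
                )

        # identification metadata and annotations
        peptide_count = 1 + int(rng.poisson(4))
        id_score = float(rng.uniform(2.0, 60.0))
        passes_id = not (peptide_count == 1 and id_score < 5.0)
        localization = "cytosol" if contaminant else str(
            rng.choice(["plasma membrane", "endoplasmic reticulum", "golgi", "mitochondrion"])
        )
        tmd = 0 if contaminant else int(rng.poisson(1.0))
        records[pid] = ProteinRecord(pid, peptide_count, id_score, m_mono, localization, tmd)
        ann_rows.append(
            {"protein_id": pid, "monomer_mass_kda": m_mono,
             "localization_label": localization, "tmd_count": tmd}
        )

        # cytosolic pool: contaminants always; a fraction of membrane proteins
        # are dual-localized
        in_cytosol = contaminant or (rng.random() < cfg.dual_localized_frac)
        m_app_primary = (
            None if void_trapped else _mass_from_center(center0, slope, intercept)
        )
        m_app_cyt = None
        dual_shifted = None
        if in_cytosol and m_app_primary is not None:
            if contaminant:
                factor = float(rng.lognormal(0.0, 0.1))
            elif rng.random() < cfg.dual_shift_prob:
                factor = float(rng.choice([4.0, 0.25]))
            else:
                factor = float(rng.lognormal(0.0, 0.1))
            m_app_cyt = m_app_primary * factor
            dual_shifted = (not contaminant) and (factor > 2.0 or factor < 0.5)
            cyt_rows.append({"protein_id": pid, "m_app_cytosol_kda": m_app_cyt})
        elif in_cytosol:
            in_cytosol = True  # void-trapped dual proteins: present, no mass
            cyt_rows.append({"protein_id": pid, "m_app_cytosol_kda": np.nan})

        # protein-level truth: a complex if any resolved base peak implies
        # R_app >= 2
        is_complex = False
        if not void_trapped:
            for a, c, s in base_peaks:
                if c >= cfg.void_fraction + 1:
                    if _mass_from_center(c, slope, intercept) / m_mono >= 2.0:
                        is_complex = True
        prot_rows.append(
            {"protein_id": pid, "monomer_mass_kda": m_mono,
             "state": "unresolved" if void_trapped else STATE_NAMES[state_idx],
             "r_app_primary": None if void_trapped else r_target,
             "n_peaks": len(base_peaks), "is_complex": is_complex,
             "contaminant": contaminant, "void_trapped": void_trapped,
             "in_cytosol": in_cytosol, "m_app_cytosol_kda": m_app_cyt,
             "dual_shifted": dual_shifted, "passes_id_filter": passes_id,
             "sucrose_center": suc_center}
        )

    truth = GroundTruth(
        proteins=pd.DataFrame(prot_rows),
        sec_peaks=pd.DataFrame(sec_rows),
        sucrose_peaks=pd.DataFrame(suc_rows),
    )
    ds = SimulatedDataset(
        config=cfg,
        sec_scheme=sec_scheme,
        sucrose_scheme=suc_scheme,
        sec_profiles=sec_profiles,
        sucrose_profiles=suc_profiles,
        records=records,
        standards=make_standards(cfg),
        annotations=pd.DataFrame(ann_rows),
        cytosol_table=pd.DataFrame(cyt_rows, columns=["protein_id", "m_app_cytosol_kda"]),
        truth=truth,
    )
    if outdir is not None:
        ds.write(outdir)
    return ds


def evaluate_against_truth(results: dict, truth: GroundTruth) -> dict:
    """Score pipeline result tables against the generating truth.

    ``results`` is the table bundle from :func:`secprof.pipeline.run_pipeline`
    (keys ``reproducible``, ``oligomer_calls``, ``membrane_calls``).  Returns
    peak recall/precision and center RMSE (within a one-fraction matching
    tolerance, resolved peaks only), complex-call sensitivity/specificity,
    state accuracy on dominant resolved peaks, and the membrane-call confusion
    counts with contaminant recall.
    """
    prot = truth.proteins.set_index("protein_id")
    eligible = prot[prot["passes_id_filter"]]

    # --- peak recovery (resolved truth peaks of rep1/rep2 averaged) ---
    rep_tab = results["reproducible"]
    truth_peaks = (
        truth.sec_peaks[truth.sec_peaks["resolved"]]
        .groupby(["protein_id", "peak_index"])
        .agg(center=("center", "mean"))
        .reset_index()
    )
    truth_peaks = truth_peaks[truth_peaks["protein_id"].isin(eligible.index)]
    n_truth = len(truth_peaks)
    n_pred = len(rep_tab)
    matched = 0
    sq_err = []
    pred_by_prot: dict[str, list[float]] = {}
    if n_pred:
        for r in rep_tab.itertuples():
            center = 0.5 * (r.center_rep1 + r.center_rep2)
            pred_by_prot.setdefault(r.protein_id, []).append(center)
    used: set[tuple[str, int]] = set()
    for t in truth_peaks.itertuples():
        cands = [
            (abs(c - t.center), k)
            for k, c in enumerate(pred_by_prot.get(t.protein_id, []))
            if (t.protein_id, k) not in used and abs(c - t.center) <= 1.0
        ]
        if cands:
            err, k = min(cands)
            used.add((t.protein_id, k))
            matched += 1
            sq_err.append(err**2)
    recall = matched / n_truth if n_truth else float("nan")
    precision = matched / n_pred if n_pred else float("nan")
    rmse = math.sqrt(np.mean(sq_err)) if sq_err else float("nan")

    # --- complex calls ---
    calls = results["oligomer_calls"]
    pred_complex = (
        calls.groupby("protein_id")["is_complex"].any() if len(calls) else pd.Series(dtype=bool)
    )
    tp = fp = tn = fn = 0
    for pid, row in eligible.iterrows():
        pred = bool(pred_complex.get(pid, False))
        if row["is_complex"]:
            tp += pred
            fn += not pred
        else:
            fp += pred
            tn += not pred
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")

    # --- state accuracy on the dominant resolved call ---
    state_hits = state_total = 0
    if len(calls) and len(rep_tab):
        dom = (
            rep_tab.sort_values(["protein_id", "amplitude"], ascending=[True, False])
            .groupby("protein_id")
            .first()
            .reset_index()[["protein_id", "label"]]
        )
        dom_calls = calls.merge(dom, on=["protein_id", "label"])
        for r in dom_calls.itertuples():
            t_state = prot.loc[r.protein_id, "state"] if r.protein_id in prot.index else None
            if t_state in STATE_NAMES and r.state != "unresolved":
                state_total += 1
                state_hits += r.state == t_state
    state_accuracy = state_hits / state_total if state_total else float("nan")

    # --- membrane calls ---
    mem = results["membrane_calls"]
    mem_status = (
        mem.set_index("protein_id")["status"] if len(mem) else pd.Series(dtype=object)
    )
    cont_tp = cont_total = mem_tp = mem_total = 0
    for pid, row in eligible.iterrows():
        pred = mem_status.get(pid)
        if row["contaminant"]:
            cont_total += 1
            cont_tp += pred == "cytosolic_contaminant"
        else:
            mem_total += 1
            mem_tp += pred == "membrane_associated"
    return {
        "peak_recall": recall,
        "peak_precision": precision,
        "center_rmse": rmse,
        "n_truth_peaks": n_truth,
        "n_predicted_peaks": n_pred,
        "complex_sensitivity": sensitivity,
        "complex_specificity": specificity,
        "complex_tp": tp, "complex_fp": fp, "complex_tn": tn, "complex_fn": fn,
        "state_accuracy": state_accuracy,
        "contaminant_recall": cont_tp / cont_total if cont_total else float("nan"),
        "membrane_recall": mem_tp / mem_total if mem_total else float("nan"),
    }
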