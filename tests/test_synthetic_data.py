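"""Properties of the labelled data generator and the truth-based scorer."""

import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from secprof.calibration import apparent_mass, fit_calibration
from secprof.peakfit import eligible_for_fitting
from secprof.synthetic_data import (
    SimulationConfig,
    evaluate_against_truth,
    make_standards,
    simulate_dataset,
)


def _file_bytes(root):
    return {p.name: p.read_bytes() for p in sorted(Path(root).iterdir())}


class TestDeterminism:
    def test_same_seed_writes_identical_bytes(self, tmp_path):
        simulate_dataset(SimulationConfig(seed=11, n_proteins=15), tmp_path / "a")
        simulate_dataset(SimulationConfig(seed=11, n_proteins=15), tmp_path / "b")
        assert _file_bytes(tmp_path / "a") == _file_bytes(tmp_path / "b")

    def test_different_seed_differs(self, tmp_path):
        simulate_dataset(SimulationConfig(seed=1, n_proteins=15), tmp_path / "a")
        simulate_dataset(SimulationConfig(seed=2, n_proteins=15), tmp_path / "b")
        assert _file_bytes(tmp_path / "a") != _file_bytes(tmp_path / "b")


class TestGeneratedData:
    def test_standards_span_stated_range_on_exact_law(self):
        cfg = SimulationConfig()
        standards = make_standards(cfg)
        masses = [m for m, _ in standards]
        assert min(masses) == 29.0 and max(masses) == 669.0
        model = fit_calibration(standards)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)
        for m, f in standards:
            assert apparent_mass(model, f)[0] == pytest.approx(m, rel=1e-9)

    def test_profiles_eligible_without_dropout(self):
        ds = simulate_dataset(
            SimulationConfig(seed=3, n_proteins=40, dropout_prob=0.0)
        )
        for p in ds.sec_profiles:
            assert eligible_for_fitting(p), p.protein_id

    def test_truth_rapp_matches_state_target(self):
        """The primary-peak R_app implied by the calibration law equals the
        state's target ratio (calibration round trip on noiseless standards)."""
        cfg = SimulationConfig(seed=5, n_proteins=40)
        ds = simulate_dataset(cfg)
        prot = ds.truth.proteins
        targets = dict(zip(("degraded", "monomer", "small_complex", "large_complex"),
                           cfg.state_rapp))
        base = (
            ds.truth.sec_peaks[ds.truth.sec_peaks.peak_index == 0]
            .groupby("protein_id")["base_center"].first()
        )
        model = fit_calibration(ds.standards)
        for row in prot.itertuples():
            if row.void_trapped:
                continue
            m_app, _ = apparent_mass(model, base[row.protein_id])
            assert m_app / row.monomer_mass_kda == pytest.approx(
                targets[row.state], rel=1e-9
            )

    def test_noiseless_jitter_free_profiles_recover_centers(self):
        cfg = SimulationConfig(
            seed=4, n_proteins=25, noise_cv=0.0, jitter_sd=0.0,
            additive_floor_rel=0.0, dropout_prob=0.0,
        )
        ds = simulate_dataset(cfg)
        from secprof.peakfit import fit_gaussian_mixture

        truth = ds.truth.sec_peaks
        for p in ds.sec_profiles:
            t = truth[
                (truth.protein_id == p.protein_id) & (truth.replicate == p.replicate_id)
            ]
            if ds.truth.proteins.set_index("protein_id").loc[p.protein_id, "void_trapped"]:
                continue  # void peaks are truncated by the column, centers shift
            m = fit_gaussian_mixture(p, void_fraction=2)
            fitted = sorted(pk.center for pk in m.peaks)
            for c in sorted(t.center):
                assert min(abs(c - f) for f in fitted) <= 0.05

    def test_infeasible_peak_layout_rejected(self):
        with pytest.raises(ValueError, match="separation"):
            SimulationConfig(sec_fractions=12, peak_count_probs=(0.0, 0.0, 0.0, 1.0))

    def test_contaminants_have_shallow_sucrose_truth(self):
        ds = simulate_dataset(SimulationConfig(seed=6, n_proteins=60))
        prot = ds.truth.proteins
        assert (prot.loc[prot.contaminant, "sucrose_center"] <= 8).all()
        assert (prot.loc[~prot.contaminant, "sucrose_center"] > 8).all()


class TestEvaluation:
    def _perfect_results(self, ds):
        """Build result tables directly from the truth (the ideal analyst)."""
        prot = ds.truth.proteins.set_index("protein_id")
        peaks = (
            ds.truth.sec_peaks[ds.truth.sec_peaks.resolved]
            .groupby(["protein_id", "peak_index"])
            .agg(center=("center", "mean"), amplitude=("amplitude", "mean"))
            .reset_index()
        )
        peaks = peaks[prot.loc[peaks.protein_id, "passes_id_filter"].to_numpy()]
        rep = pd.DataFrame(
            {
                "protein_id": peaks.protein_id,
                "label": [f"P{i + 1}" for i in peaks.peak_index],
                "center_rep1": peaks.center,
                "center_rep2": peaks.center,
                "amplitude": peaks.amplitude,
                "resolved": True,
            }
        )
        calls = pd.DataFrame(
            {
                "protein_id": prot.index,
                "label": "P1",
                "is_complex": prot.is_complex.to_numpy(),
                "state": prot.state.to_numpy(),
            }
        )
        mem = pd.DataFrame(
            {
                "protein_id": prot.index,
                "status": np.where(
                    prot.contaminant, "cytosolic_contaminant", "membrane_associated"
                ),
            }
        )
        return {"reproducible": rep, "oligomer_calls": calls, "membrane_calls": mem}

    def test_perfect_results_score_perfectly(self):
        ds = simulate_dataset(SimulationConfig(seed=2, n_proteins=40))
        m = evaluate_against_truth(self._perfect_results(ds), ds.truth)
        assert m["peak_recall"] == 1.0
        assert m["center_rmse"] == pytest.approx(0.0, abs=1e-12)
        assert m["complex_sensitivity"] == 1.0
        assert m["complex_specificity"] == 1.0
        assert m["contaminant_recall"] == 1.0

    def test_systematic_one_fraction_shift_gives_unit_rmse(self):
        ds = simulate_dataset(SimulationConfig(seed=2, n_proteins=40))
        results = self._perfect_results(ds)
        results["reproducible"] = results["reproducible"].assign(
            center_rep1=results["reproducible"].center_rep1 + 1.0,
            center_rep2=results["reproducible"].center_rep2 + 1.0,
        )
        m = evaluate_against_truth(results, ds.truth)
        assert m["center_rmse"] == pytest.approx(1.0, abs=1e-9)

    def test_all_monomer_predictor_scores_at_prevalence(self):
        ds = simulate_dataset(SimulationConfig(seed=2, n_proteins=40))
        results = self._perfect_results(ds)
        results["oligomer_calls"] = results["oligomer_calls"].assign(is_complex=False)
        m = evaluate_against_truth(results, ds.truth)
        assert m["complex_sensitivity"] == 0.0
        assert m["complex_specificity"] == 1.0
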