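"""Gaussian mixture deconvolution: eligibility, BIC, constraints, fallback."""

import math

import numpy as np
import pytest

from secprof.peakfit import (
    FitMethod,
    bic_score,
    eligible_for_fitting,
    fit_gaussian_mixture,
    gaussian_mixture,
    global_max_peak,
)
from secprof.profiles_io import ElutionProfile, FractionScheme, SeparationKind
from secprof.synthetic_data import SimulationConfig, simulate_dataset

SCHEME = FractionScheme(SeparationKind.SEC_SUPERDEX, tuple(range(1, 25)), void_fraction=2)
GRID = np.arange(1, 25, dtype=float)


def _profile(values, pid="P1", rep="bio1", scheme=SCHEME):
    return ElutionProfile(pid, rep, scheme, np.asarray(values, dtype=float))


def _gaussian_profile(*peaks):
    """Noiseless profile from (amplitude, center, sigma) triplets."""
    params = [v for pk in peaks for v in pk]
    return _profile(gaussian_mixture(GRID, *params))


class TestEligibility:
    @pytest.mark.parametrize(
        "nonzero,expected",
        [
            ({3, 4, 9}, True),   # three fractions, two adjacent
            ({2, 5, 9}, False),  # no adjacent pair
            ({3, 4}, False),     # only two fractions
            ({1, 2, 3, 4}, True),
            (set(), False),
        ],
    )
    def test_three_fractions_two_adjacent(self, nonzero, expected):
        values = [5.0 if f in nonzero else 0.0 for f in SCHEME.fraction_ids]
        assert eligible_for_fitting(_profile(values)) is expected


class TestBic:
    def test_penalty_monotone_in_peak_count(self):
        assert bic_score(24, 10.0, 1) < bic_score(24, 10.0, 2)

    def test_closed_form(self):
        # n=24, rss=24, K=1: 24*ln(1) + 3*ln(24)
        assert bic_score(24, 24.0, 1) == pytest.approx(3 * math.log(24), rel=1e-12)

    def test_zero_rss_stays_finite(self):
        assert math.isfinite(bic_score(24, 0.0, 1))

    def test_rejects_underdetermined_fit(self):
        with pytest.raises(ValueError):
            bic_score(6, 1.0, 2)


class TestGaussianFit:
    def test_single_noiseless_gaussian_recovered(self):
        model = fit_gaussian_mixture(_gaussian_profile((100.0, 10.0, 1.5)), void_fraction=2)
        assert model.method is FitMethod.GAUSSIAN
        assert model.n_peaks == 1
        assert model.peaks[0].center == pytest.approx(10.0, abs=0.05)
        assert model.peaks[0].sigma == pytest.approx(1.5, abs=0.05)
        assert model.peaks[0].amplitude == pytest.approx(100.0, rel=0.01)

    def test_single_peak_matches_grid_search_oracle(self):
        profile = _gaussian_profile((80.0, 13.3, 1.8))
        model = fit_gaussian_mixture(profile, void_fraction=2)
        # dense grid search over (mu, sigma) with closed-form amplitude
        y = profile.intensities
        best = None
        for mu in np.arange(12.0, 15.0, 0.001):
            for s in np.arange(1.5, 2.1, 0.01):
                g = np.exp(-((GRID - mu) ** 2) / (2 * s**2))
                a = float(g @ y / (g @ g))
                rss = float(((y - a * g) ** 2).sum())
                if best is None or rss < best[0]:
                    best = (rss, mu, s, a)
        _, mu, s, a = best
        assert model.peaks[0].center == pytest.approx(mu, abs=1e-3)
        assert model.peaks[0].sigma == pytest.approx(s, abs=1e-2)
        assert model.peaks[0].amplitude == pytest.approx(a, rel=1e-3)

    def test_two_well_separated_gaussians_recovered(self):
        model = fit_gaussian_mixture(
            _gaussian_profile((100.0, 6.0, 1.5), (50.0, 14.0, 1.5)), void_fraction=2
        )
        assert model.n_peaks == 2
        centers = sorted(p.center for p in model.peaks)
        assert centers[0] == pytest.approx(6.0, abs=0.1)
        assert centers[1] == pytest.approx(14.0, abs=0.1)

    def test_close_peaks_collapse_to_single_model(self):
        # separation 2 < 4: the two-peak candidate violates the separation
        # rule, so a single-peak model must come back
        model = fit_gaussian_mixture(
            _gaussian_profile((100.0, 6.0, 1.2), (80.0, 8.0, 1.2)), void_fraction=2
        )
        assert model.n_peaks == 1

    def test_faint_secondary_peak_pruned(self):
        model = fit_gaussian_mixture(
            _gaussian_profile((100.0, 6.0, 1.5), (10.0, 16.0, 1.5)), void_fraction=2
        )
        assert model.n_peaks == 1
        assert model.peaks[0].center == pytest.approx(6.0, abs=0.1)

    def test_void_peak_flagged_unresolved(self):
        model = fit_gaussian_mixture(
            _gaussian_profile((100.0, 2.0, 1.0), (60.0, 12.0, 1.5)), void_fraction=2
        )
        by_center = sorted(model.peaks, key=lambda p: p.center)
        assert not by_center[0].resolved
        assert by_center[1].resolved

    def test_ineligible_profile_rejected(self):
        values = [0.0] * 24
        values[2], values[8], values[14] = 5.0, 5.0, 5.0  # no adjacent pair
        with pytest.raises(ValueError, match="eligible"):
            fit_gaussian_mixture(_profile(values))

    def test_constraints_hold_on_noisy_simulated_profiles(self):
        """Every returned model satisfies the separation and 20% rules."""
        ds = simulate_dataset(SimulationConfig(seed=5, n_proteins=40))
        checked = 0
        for p in ds.sec_profiles:
            if not eligible_for_fitting(p):
                continue
            m = fit_gaussian_mixture(p, void_fraction=2)
            centers = [pk.center for pk in m.peaks]
            for i in range(len(centers)):
                for j in range(i + 1, len(centers)):
                    assert abs(centers[i] - centers[j]) >= 4.0
            amax = max(pk.amplitude for pk in m.peaks)
            for pk in m.peaks:
                assert pk.amplitude >= 0.2 * amax - 1e-9
            checked += 1
        assert checked >= 30


class TestGlobalMax:
    def test_peak_at_argmax_fraction(self):
        values = [0.0] * 24
        values[7] = 9.0  # fraction 8
        model = global_max_peak(_profile(values), void_fraction=2)
        assert model.method is FitMethod.GLOBAL_MAX
        assert model.peaks[0].center == 8.0

    def test_tie_goes_to_earlier_fraction(self):
        values = [0.0] * 24
        values[7] = values[8] = 9.0
        model = global_max_peak(_profile(values))
        assert model.peaks[0].center == 8.0

    def test_all_zero_profile_is_ineligible(self):
        model = global_max_peak(_profile([0.0] * 24))
        assert model.method is FitMethod.INELIGIBLE
        assert model.n_peaks == 0
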