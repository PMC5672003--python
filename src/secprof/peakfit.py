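"""Gaussian deconvolution of elution profiles.

A protein's per-fraction intensity profile is modelled as a sum of 1-4
Gaussian peaks, I(f) = sum_k A_k * exp(-(f - mu_k)^2 / (2 sigma_k^2)),
fitted by bounded nonlinear least squares.  The number of peaks is chosen by
the lowest Bayesian information criterion, with two acceptance rules applied
to every candidate model:

* peak centers must be separated by at least 4 fractions (the column cannot
  genuinely resolve closer species), and
* every secondary peak must reach at least 20% of the most intense peak's
  amplitude (smaller bumps are treated as noise and pruned, with a refit at
  the reduced peak count).

Profiles are only fitted when the protein was identified in at least three
fractions, two of them adjacent; when the optimizer fails everywhere, the
profile's global maximum serves as a single integer-position peak.
"""

from __future__ import annotations

import dataclasses
import enum
import logging

import numpy as np
from scipy.optimize import curve_fit

from .calibration import is_resolved
from .profiles_io import ElutionProfile

log = logging.getLogger(__name__)

MAX_PEAKS = 4
MIN_SEPARATION = 4.0
MIN_RELATIVE_HEIGHT = 0.2
SIGMA_BOUNDS = (0.5, 5.0)
SIGMA_INIT = 1.5
RSS_FLOOR = 1e-12


class FitMethod(str, enum.Enum):
    GAUSSIAN = "gaussian"
    GLOBAL_MAX = "global_max"
    INELIGIBLE = "ineligible"


@dataclasses.dataclass
class FittedPeak:
    center: float
    sigma: float
    amplitude: float
    relative_height: float
    resolved: bool


@dataclasses.dataclass
class PeakModel:
    """Deconvolution result for one profile; peaks sorted by decreasing amplitude."""

    protein_id: str
    replicate_id: str
    method: FitMethod
    peaks: list[FittedPeak]
    bic: float | None = None
    rss: float | None = None
    min_separation: float = MIN_SEPARATION
    min_relative_height: float = MIN_RELATIVE_HEIGHT

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: -p.amplitude)
        if len(self.peaks) > MAX_PEAKS:
            raise ValueError("more than 4 peaks retained")
        centers = [p.center for p in self.peaks]
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                if abs(centers[i] - centers[j]) < self.min_separation:
                    raise ValueError(
                        f"{self.protein_id}: peaks at {centers[i]:.2f} and "
                        f"{centers[j]:.2f} violate the {self.min_separation}-fraction "
                        "separation rule"
                    )
        for p in self.peaks[1:]:
            if p.relative_height < self.min_relative_height:
                raise ValueError(
                    f"{self.protein_id}: secondary peak below the "
                    f"{self.min_relative_height:.0%} relative-height rule"
                )

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def dominant(self) -> FittedPeak | None:
        return self.peaks[0] if self.peaks else None


def eligible_for_fitting(profile: ElutionProfile) -> bool:
    """Identified in >=3 fractions, at least two of them adjacent."""
    nz = profile.nonzero_fractions()
    if len(nz) < 3:
        return False
    return bool(np.any(np.diff(nz) == 1))


def bic_score(
    n_points: int, rss: float, n_peaks: int, rss_floor: float = RSS_FLOOR
) -> float:
    """BIC of a K-peak Gaussian least-squares fit; lower is better.

    Each peak contributes 3 parameters (center, width, amplitude):
    BIC = n * ln(rss / n) + 3K * ln(n).  A perfect fit (rss == 0) is scored
    at a small floor so the value stays finite.
    """
    if n_points <= 3 * n_peaks:
        raise ValueError("need more data points than fitted parameters")
    if rss < 0:
        raise ValueError("rss must be >= 0")
    rss = max(rss, rss_floor)
    n = float(n_points)
    return n * np.log(rss / n) + 3 * n_peaks * np.log(n)


def gaussian_mixture(f: np.ndarray, *params: float) -> np.ndarray:
    """Sum of Gaussians; params interleaved as (A1, mu1, s1, A2, mu2, s2, ...)."""
    f = np.asarray(f, dtype=float)
    out = np.zeros_like(f)
    for k in range(0, len(params), 3):
        a, mu, s = params[k : k + 3]
        out += a * np.exp(-((f - mu) ** 2) / (2.0 * s**2))
    return out


def _seed_centers(fracs: np.ndarray, y: np.ndarray) -> list[float]:
    """Candidate peak centers: local maxima of a 3-point moving average,
    ranked by raw height, falling back to the largest remaining raw points."""
    s = np.convolve(y, np.ones(3) / 3.0, mode="same")
    n = len(y)
    maxima = [
        i
        for i in range(n)
        if y[i] > 0
        and (i == 0 or s[i] >= s[i - 1])
        and (i == n - 1 or s[i] >= s[i + 1])
    ]
    maxima.sort(key=lambda i: (-y[i], i))
    seeds = [float(fracs[i]) for i in maxima]
    # pad with the tallest raw points not adjacent to an existing seed
    extra = sorted(range(n), key=lambda i: (-y[i], i))
    for i in extra:
        if len(seeds) >= MAX_PEAKS:
            break
        if y[i] > 0 and all(abs(fracs[i] - c) >= 2.0 for c in seeds):
            seeds.append(float(fracs[i]))
    return seeds


def _mixture_jacobian(f: np.ndarray, *params: float) -> np.ndarray:
    """Analytic Jacobian of the Gaussian mixture wrt (A, mu, sigma) per peak."""
    f = np.asarray(f, dtype=float)
    cols = []
    for k in range(0, len(params), 3):
        a, mu, s = params[k : k + 3]
        d = f - mu
        g = np.exp(-(d**2) / (2.0 * s**2))
        cols += [g, a * g * d / s**2, a * g * d**2 / s**3]
    return np.column_stack(cols)


def _fit_k(
    fracs: np.ndarray,
    y: np.ndarray,
    centers0: list[float],
    sigma_bounds: tuple[float, float],
) -> np.ndarray | None:
    """Bounded least-squares fit with one Gaussian per seed; None on failure.

    Intensities are rescaled to unit maximum before fitting (XIC signals span
    orders of magnitude and would otherwise stall the optimizer); amplitudes
    are rescaled back afterwards.
    """
    ymax = float(y.max())
    yn = y / ymax
    p0, lo, hi = [], [], []
    for c in centers0:
        a0 = float(np.clip(np.interp(c, fracs, yn), 1e-3, 1.0))
        p0 += [a0, c, SIGMA_INIT]
        lo += [1e-9, float(fracs[0]) - 1.0, sigma_bounds[0]]
        hi += [2.0, float(fracs[-1]) + 1.0, sigma_bounds[1]]
    try:
        popt, _ = curve_fit(
            gaussian_mixture,
            fracs,
            yn,
            p0=p0,
            bounds=(lo, hi),
            jac=_mixture_jacobian,
            method="trf",
            maxfev=200 * (3 * len(centers0) + 1),
        )
    except (RuntimeError, ValueError):
        return None
    popt = np.asarray(popt, dtype=float)
    popt[0::3] *= ymax
    return popt


def _params_to_peaks(popt: np.ndarray) -> list[tuple[float, float, float]]:
    """(amplitude, center, sigma) triplets, sorted by decreasing amplitude."""
    triplets = [
        (float(popt[i]), float(popt[i + 1]), float(popt[i + 2]))
        for i in range(0, len(popt), 3)
    ]
    return sorted(triplets, key=lambda t: -t[0])


def _separation_ok(triplets: list[tuple[float, float, float]], min_sep: float) -> bool:
    centers = [mu for _, mu, _ in triplets]
    return all(
        abs(centers[i] - centers[j]) >= min_sep
        for i in range(len(centers))
        for j in range(i + 1, len(centers))
    )


def global_max_peak(
    profile: ElutionProfile, void_fraction: int | None = None
) -> PeakModel:
    """Single peak at the profile's global maximum (integer fraction center).

    Ties go to the earlier fraction.  An all-zero profile yields an
    ineligible, peak-free model.
    """
    y = profile.intensities
    if np.all(y == 0):
        return PeakModel(profile.protein_id, profile.replicate_id, FitMethod.INELIGIBLE, [])
    idx = int(np.argmax(y))
    if np.sum(y == y[idx]) > 1:
        log.debug(
            "%s/%s: tied global max; earlier fraction chosen",
            profile.protein_id,
            profile.replicate_id,
        )
    center = float(profile.scheme.fraction_ids[idx])
    peak = FittedPeak(
        center=center,
        sigma=SIGMA_INIT,
        amplitude=float(y[idx]),
        relative_height=1.0,
        resolved=is_resolved(center, void_fraction),
    )
    return PeakModel(profile.protein_id, profile.replicate_id, FitMethod.GLOBAL_MAX, [peak])


def fit_gaussian_mixture(
    profile: ElutionProfile,
    max_peaks: int = MAX_PEAKS,
    min_separation: float = MIN_SEPARATION,
    min_relative_height: float = MIN_RELATIVE_HEIGHT,
    sigma_bounds: tuple[float, float] = SIGMA_BOUNDS,
    void_fraction: int | None = None,
) -> PeakModel:
    """Deconvolve an eligible profile into 1..max_peaks Gaussian peaks.

    For each candidate peak count K the mixture is fitted by bounded nonlinear
    least squares; peaks below the relative-height rule are pruned with a
    refit at the reduced count, and candidates violating the separation rule
    are discarded.  The surviving candidate with the lowest BIC wins.  If no
    candidate survives, the global maximum is used instead.
    """
    if not eligible_for_fitting(profile):
        raise ValueError(
            f"{profile.protein_id}/{profile.replicate_id} is not eligible for fitting"
        )
    fracs = np.asarray(profile.scheme.fraction_ids, dtype=float)
    y = profile.intensities
    seeds = _seed_centers(fracs, y)

    candidates: dict[int, tuple[float, list[tuple[float, float, float]], float]] = {}
    for k in range(1, min(max_peaks, len(seeds)) + 1):
        popt = _fit_k(fracs, y, seeds[:k], sigma_bounds)
        if popt is None:
            continue
        # prune sub-threshold secondary peaks, refitting at the reduced count
        for _ in range(max_peaks):
            triplets = _params_to_peaks(popt)
            amax = triplets[0][0]
            keep = [t for t in triplets if t[0] >= min_relative_height * amax]
            if len(keep) == len(triplets):
                break
            popt = _fit_k(fracs, y, [mu for _, mu, _ in keep], sigma_bounds)
            if popt is None:
                break
        if popt is None:
            continue
        triplets = _params_to_peaks(popt)
        amax = triplets[0][0]
        if any(t[0] < min_relative_height * amax for t in triplets[1:]):
            continue
        if not _separation_ok(triplets, min_separation):
            continue
        rss = float(np.sum((y - gaussian_mixture(fracs, *popt)) ** 2))
        kf = len(triplets)
        bic = bic_score(len(y), rss, kf)
        if kf not in candidates or bic < candidates[kf][0]:
            candidates[kf] = (bic, triplets, rss)

    if not candidates:
        log.debug(
            "%s/%s: no Gaussian candidate accepted; global max used",
            profile.protein_id,
            profile.replicate_id,
        )
        return global_max_peak(profile, void_fraction)

    bic, triplets, rss = min(candidates.values(), key=lambda t: t[0])
    amax = triplets[0][0]
    peaks = [
        FittedPeak(
            center=mu,
            sigma=s,
            amplitude=a,
            relative_height=a / amax,
            resolved=is_resolved(mu, void_fraction),
        )
        for a, mu, s in triplets
    ]
    return PeakModel(
        profile.protein_id,
        profile.replicate_id,
        FitMethod.GAUSSIAN,
        peaks,
        bic=bic,
        rss=rss,
        min_separation=min_separation,
        min_relative_height=min_relative_height,
    )


def fit_profile(
    profile: ElutionProfile,
    void_fraction: int | None = None,
    **kwargs,
) -> PeakModel:
    """Fit a profile if eligible; otherwise return an ineligible, peak-free model.

    The eligibility rule gates inclusion entirely: a profile seen in fewer
    than three fractions (or without adjacent detections) is excluded, not
    rescued by the global max.  The global-max fallback applies only when an
    eligible profile defeats the Gaussian optimizer.
    """
    if eligible_for_fitting(profile):
        return fit_gaussian_mixture(profile, void_fraction=void_fraction, **kwargs)
    return PeakModel(profile.protein_id, profile.replicate_id, FitMethod.INELIGIBLE, [])
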