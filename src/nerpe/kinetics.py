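"""Kinetic analyses: pseudo-first-order rates, Michaelis–Menten binding,
ΔΔG from Km ratios, and rate-ratio stalling factors.

Units follow the experimental convention throughout: rate constants in
h⁻¹, substrate concentrations in mM, free energies in kcal/mol, with
ΔΔG°25 evaluated at 298.15 K.

The time-course model is F(t) = P·(1 − e^(−k·t)) with the plateau P
fitted (bounded to (0, 1]) rather than fixed at 1, because primer
extension endpoints rarely reach completion. Saturation curves are fit
with unweighted nonlinear least squares to kobs(c) = kobs_max·c/(Km + c),
initialized from the double-reciprocal linearization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

__all__ = [
    "TimeCourse", "SaturationCurve", "FirstOrderFit", "MMFit", "FitError",
    "fit_first_order", "fit_michaelis_menten", "delta_delta_g",
    "stalling_factor_rates", "simulate_time_course", "round_sig",
]

R_KCAL = 1.987e-3  # gas constant, kcal mol^-1 K^-1
T25 = 298.15  # 25 degC in kelvin


class FitError(RuntimeError):
    """A kinetic fit failed to converge or produced invalid parameters."""


@dataclass(frozen=True)
class TimeCourse:
    """Fraction of primer extended versus time (hours)."""

    times: np.ndarray
    fraction_extended: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fraction_extended, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fraction_extended", f)
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError("times and fraction_extended must be equal-length 1-D")
        if len(t) < 3:
            raise ValueError("need at least 3 time points")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be nonnegative and strictly increasing")
        if np.any((f < 0) | (f > 1)):
            raise ValueError("fraction_extended must lie in [0, 1]")


@dataclass(frozen=True)
class SaturationCurve:
    """Observed rate constants (h⁻¹) versus substrate concentration (mM)."""

    concentrations: np.ndarray
    kobs: np.ndarray
    sd: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        k = np.asarray(self.kobs, dtype=float)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "kobs", k)
        if self.sd is not None:
            object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if c.shape != k.shape or c.ndim != 1:
            raise ValueError("concentrations and kobs must be equal-length 1-D")
        if len(np.unique(c)) < 3:
            raise ValueError("need at least 3 distinct concentrations")
        if np.any(c <= 0) or np.any(k < 0):
            raise ValueError("concentrations must be > 0 and kobs >= 0")


@dataclass(frozen=True)
class FirstOrderFit:
    kobs: float
    plateau: float
    kobs_se: float
    plateau_se: float
    converged: bool


@dataclass(frozen=True)
class MMFit:
    kobs_max: float
    km: float
    kobs_max_se: float
    km_se: float
    converged: bool
    saturated: bool = True

    @property
    def specificity(self) -> float:
        """kobs_max / Km, h⁻¹ mM⁻¹."""
        return self.kobs_max / self.km


def _first_order(t: np.ndarray, k: float, plateau: float) -> np.ndarray:
    return plateau * (1.0 - np.exp(-k * t))


def fit_first_order(tc: TimeCourse) -> FirstOrderFit:
    """Fit F(t) = P·(1 − e^(−k·t)) by least squares.

    k is initialized from the log-linear transform ln(P̂ − F) against t
    with P̂ = min(1, 1.05·max F); P is bounded to (0, 1].
    """
    t, f = tc.times, tc.fraction_extended
    if np.all(f == 0):
        raise FitError("no signal: all fractions are zero")
    p_hat = min(1.0, 1.05 * float(f.max()))
    resid = p_hat - f
    mask = (resid > 0) & (t > 0)
    if mask.sum() >= 2:
        slope = np.polyfit(t[mask], np.log(resid[mask]), 1)[0]
        k0 = max(-slope, 1e-6)
    else:
        k0 = 1.0
    try:
        popt, pcov = optimize.curve_fit(
            _first_order, t, f, p0=[k0, p_hat],
            bounds=([1e-12, 1e-12], [np.inf, 1.0]), maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitError(f"first-order fit did not converge: {exc}") from exc
    k, plateau = popt
    if k <= 0 or plateau <= 0:
        raise FitError(f"invalid parameters (k={k:.3g}, P={plateau:.3g})")
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    return FirstOrderFit(float(k), float(plateau), float(se[0]), float(se[1]), True)


def _mm(c: np.ndarray, kmax: float, km: float) -> np.ndarray:
    return kmax * c / (km + c)


def fit_michaelis_menten(sc: SaturationCurve) -> MMFit:
    """Fit kobs(c) = kobs_max·c/(Km + c) by unweighted least squares.

    Initialization uses the double-reciprocal (Lineweaver–Burk)
    linearization. A curve with no saturation signal (Km far beyond the
    measured range) returns with ``saturated=False`` and a warning, not
    a silent failure.
    """
    c, k = sc.concentrations, sc.kobs
    pos = k > 0
    if pos.sum() >= 2:
        coef = np.polyfit(1.0 / c[pos], 1.0 / k[pos], 1)
        # 1/k = (Km/kmax)(1/c) + 1/kmax
        kmax0 = 1.0 / coef[1] if coef[1] > 0 else float(k.max()) * 2
        km0 = coef[0] * kmax0 if coef[0] * kmax0 > 0 else float(np.median(c))
    else:
        kmax0, km0 = float(k.max() or 1.0), float(np.median(c))
    try:
        popt, pcov = optimize.curve_fit(
            _mm, c, k, p0=[kmax0, km0],
            bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitError(f"Michaelis–Menten fit did not converge: {exc}") from exc
    kmax, km = popt
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    saturated = bool(km <= 10 * float(c.max()))
    if not saturated:
        warnings.warn(
            "no saturation signal: fitted Km lies far beyond the measured "
            "concentration range; kobs_max and Km are poorly determined",
            RuntimeWarning, stacklevel=2,
        )
    return MMFit(float(kmax), float(km), float(se[0]), float(se[1]), True, saturated)


def delta_delta_g(km_alt: float, km_ref: float, temperature: float = T25) -> float:
    """Binding free-energy difference from a Km ratio: R·T·ln(Km_alt/Km_ref).

    Negative when the alternative substrate binds more tightly
    (Km_alt < Km_ref). Result in kcal/mol.
    """
    if km_alt <= 0 or km_ref <= 0 or temperature <= 0:
        raise ValueError("Km values and temperature must be positive")
    return R_KCAL * temperature * math.log(km_alt / km_ref)


def stalling_factor_rates(k_matched: float, k_mismatched: float) -> float:
    """Stalling factor S: rate past a complementary over a mismatched pair."""
    if k_matched <= 0 or k_mismatched <= 0:
        raise ValueError("rate constants must be positive")
    return k_matched / k_mismatched


def simulate_time_course(
    k: float,
    plateau: float,
    times: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TimeCourse:
    """Seeded synthetic time course: F(t) + Gaussian noise, clipped to [0, 1]."""
    if k <= 0 or not 0 < plateau <= 1:
        raise ValueError("k must be > 0 and plateau in (0, 1]")
    t = np.asarray(times, dtype=float)
    f = _first_order(t, k, plateau)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd, size=t.shape)
    return TimeCourse(t, np.clip(f, 0.0, 1.0))


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (606.06 → 610 at sig=2)."""
    if x == 0:
        return 0.0
    return float(round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1)))
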