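"""Proton-resonance-frequency (PRF) thermometry from single-voxel MR spectra.

A serial PRESS acquisition yields one magnitude spectrum every few minutes.
Each spectrum carries two resonances of interest: tissue water (~4.7 ppm)
and the CH2 methylene line of fat (~1.3 ppm).  The water resonance drifts
with temperature at ~0.01 ppm/degC while CH2 is temperature-stable, so the
water - CH2 chemical-shift separation tracks tissue temperature.  Fitting
both lines per timepoint and dividing the baseline-referenced separation
change by the PRF coefficient gives a temperature-change time series.

Line shapes are Lorentzian by default (Gaussian selectable) on the magnitude
spectrum, over a low-order polynomial baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

__all__ = [
    "Spectrum",
    "PeakFit",
    "ResonanceFit",
    "TemperatureSeries",
    "LorentzianPeakFitter",
    "PRFThermometer",
    "fit_peaks",
    "shift_difference",
    "temperature_series",
    "WATER_WINDOW_PPM",
    "CH2_WINDOW_PPM",
    "PRF_COEFF_PPM_PER_C",
    "GYROMAGNETIC_MHZ_PER_T",
]

#: PRF temperature coefficient of the water resonance, ppm per degC.
PRF_COEFF_PPM_PER_C = 0.01

#: Proton gyromagnetic ratio over 2*pi, MHz/T (ppm<->Hz conversion).
GYROMAGNETIC_MHZ_PER_T = 42.577

#: Search windows for the two resonances, ppm.
WATER_WINDOW_PPM = (4.2, 5.2)
CH2_WINDOW_PPM = (0.9, 1.8)


@dataclass(frozen=True)
class Spectrum:
    """One frequency-domain single-voxel spectrum.

    ``amplitude`` may be complex (the magnitude is fitted) or already a
    magnitude.  The ppm axis must be strictly monotone and cover at least
    [0.5, 5.5] ppm so both resonances are in-window.
    """

    ppm: np.ndarray
    amplitude: np.ndarray
    field_strength_T: float = 7.0
    timestamp_s: float = 0.0
    tissue_label: str = "BAT"

    def __post_init__(self):
        ppm = np.asarray(self.ppm, dtype=float)
        amp = np.asarray(self.amplitude)
        if ppm.ndim != 1 or amp.shape != ppm.shape:
            raise ValueError("ppm and amplitude must be 1-D arrays of equal length")
        d = np.diff(ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotone")
        if not np.all(np.isfinite(amp)):
            raise ValueError("amplitude values must be finite")
        if ppm.min() > 0.5 or ppm.max() < 5.5:
            raise ValueError("ppm axis must cover at least [0.5, 5.5] ppm")
        object.__setattr__(self, "ppm", ppm)
        object.__setattr__(self, "amplitude", amp)

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.amplitude).astype(float)

    def hz_per_ppm(self) -> float:
        return GYROMAGNETIC_MHZ_PER_T * self.field_strength_T


@dataclass(frozen=True)
class ResonanceFit:
    """Fitted parameters of a single resonance."""

    label: str
    center_ppm: float
    fwhm_ppm: float
    amplitude: float
    detected: bool


@dataclass(frozen=True)
class PeakFit:
    """Two-resonance fit of one spectrum (water + CH2 over a baseline)."""

    water: ResonanceFit
    ch2: ResonanceFit
    baseline_coeffs: tuple[float, ...]
    residual_norm: float
    converged: bool
    timestamp_s: float = 0.0

    def shift_difference_ppm(self) -> float:
        """water - CH2 separation; NaN when either line is undetected."""
        if not (self.converged and self.water.detected and self.ch2.detected):
            return float("nan")
        return self.water.center_ppm - self.ch2.center_ppm


def _lorentzian(x: np.ndarray, amp: float, center: float, fwhm: float) -> np.ndarray:
    h = 0.5 * fwhm
    return amp * h * h / ((x - center) ** 2 + h * h)


def _gaussian(x: np.ndarray, amp: float, center: float, fwhm: float) -> np.ndarray:
    s = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return amp * np.exp(-0.5 * ((x - center) / s) ** 2)


_SHAPES = {"lorentzian": _lorentzian, "gaussian": _gaussian}


class LorentzianPeakFitter(BaseEstimator):
    """Nonlinear least-squares fit of the water and CH2 resonances.

    Two line-shape profiles (Lorentzian by default) plus a polynomial
    baseline are fitted to the magnitude spectrum, each center constrained
    to its resonance window.  A line is reported *detected* only when its
    fitted amplitude clears a noise floor, so failed or empty windows never
    fabricate a center.

    Parameters
    ----------
    lineshape : {"lorentzian", "gaussian"}
    baseline_degree : polynomial baseline order, default 2 (quadratic).
    water_window_ppm, ch2_window_ppm : center constraint windows.
    noise_multiple : detection requires amplitude >= noise_multiple * sigma,
        sigma being a robust residual scale estimate.
    min_amplitude_fraction : additional absolute floor as a fraction of the
        spectrum's dynamic range (guards the noiseless case where sigma ~ 0).
    max_fwhm_ppm : upper bound on linewidth.

    Attributes
    ----------
    fit_ : PeakFit for the last spectrum fitted.
    """

    def __init__(
        self,
        lineshape: str = "lorentzian",
        baseline_degree: int = 2,
        water_window_ppm: tuple[float, float] = WATER_WINDOW_PPM,
        ch2_window_ppm: tuple[float, float] = CH2_WINDOW_PPM,
        noise_multiple: float = 3.0,
        min_amplitude_fraction: float = 0.02,
        max_fwhm_ppm: float = 0.5,
    ):
        self.lineshape = lineshape
        self.baseline_degree = baseline_degree
        self.water_window_ppm = water_window_ppm
        self.ch2_window_ppm = ch2_window_ppm
        self.noise_multiple = noise_multiple
        self.min_amplitude_fraction = min_amplitude_fraction
        self.max_fwhm_ppm = max_fwhm_ppm

    # -- model ---------------------------------------------------------

    def _model(self, params: np.ndarray, x: np.ndarray) -> np.ndarray:
        nb = self.baseline_degree + 1
        shape = _SHAPES[self.lineshape]
        y = np.polyval(params[:nb], x)
        for k in range(2):
            amp, center, fwhm = params[nb + 3 * k : nb + 3 * k + 3]
            y = y + shape(x, amp, center, fwhm)
        return y

    def fit(self, spectrum: Spectrum) -> "LorentzianPeakFitter":
        if self.lineshape not in _SHAPES:
            raise ValueError(f"unknown lineshape {self.lineshape!r}")
        x = spectrum.ppm
        y = spectrum.magnitude
        windows = [tuple(self.water_window_ppm), tuple(self.ch2_window_ppm)]
        for lo, hi in windows:
            if lo < x.min() - 1e-9 or hi > x.max() + 1e-9:
                raise ValueError(
                    f"resonance window ({lo}, {hi}) ppm outside spectrum axis"
                )

        nb = self.baseline_degree + 1
        yspan = float(y.max() - y.min())
        p0 = np.zeros(nb + 6)
        p0[nb - 1] = float(np.median(y))
        lb = np.full(nb + 6, -np.inf)
        ub = np.full(nb + 6, np.inf)
        for k, (lo, hi) in enumerate(windows):
            sel = (x >= lo) & (x <= hi)
            i = np.argmax(y[sel])
            p0[nb + 3 * k] = max(y[sel][i] - np.median(y), 1e-6 * max(yspan, 1.0))
            p0[nb + 3 * k + 1] = x[sel][i]
            p0[nb + 3 * k + 2] = 0.05
            lb[nb + 3 * k : nb + 3 * k + 3] = (0.0, lo, 1e-4)
            ub[nb + 3 * k : nb + 3 * k + 3] = (np.inf, hi, self.max_fwhm_ppm)

        sol = least_squares(
            lambda p: self._model(p, x) - y,
            p0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14, gtol=1e-14,
            max_nfev=2000,
        )
        resid = self._model(sol.x, x) - y
        sigma = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
        floor = max(self.noise_multiple * sigma,
                    self.min_amplitude_fraction * yspan)

        labels = ("water", "CH2")
        fits = []
        for k in range(2):
            amp, center, fwhm = sol.x[nb + 3 * k : nb + 3 * k + 3]
            fits.append(ResonanceFit(
                label=labels[k],
                center_ppm=float(center),
                fwhm_ppm=float(fwhm),
                amplitude=float(amp),
                detected=bool(sol.success and amp >= floor),
            ))
        self.fit_ = PeakFit(
            water=fits[0],
            ch2=fits[1],
            baseline_coeffs=tuple(float(c) for c in sol.x[:nb]),
            residual_norm=float(np.linalg.norm(resid)),
            converged=bool(sol.success),
            timestamp_s=spectrum.timestamp_s,
        )
        return self


def fit_peaks(spectrum: Spectrum, **config) -> PeakFit:
    """Fit water and CH2 resonances in one spectrum. See LorentzianPeakFitter."""
    return LorentzianPeakFitter(**config).fit(spectrum).fit_


def shift_difference(fit: PeakFit) -> float:
    """Water - CH2 chemical-shift separation in ppm (NaN if undetected)."""
    return fit.shift_difference_ppm()


@dataclass(frozen=True)
class TemperatureSeries:
    """Temperature change vs. a pre-cooling baseline, per accepted timepoint."""

    timestamps_s: np.ndarray
    delta_T_C: np.ndarray
    shift_ppm: np.ndarray
    baseline_mask: np.ndarray
    coefficient_ppm_per_C: float
    tissue_label: str = "BAT"
    excluded_timestamps_s: tuple[float, ...] = field(default_factory=tuple)

    def delta_T_at(self, t_s: float) -> float:
        """Temperature change at the accepted timepoint nearest ``t_s``."""
        if len(self.timestamps_s) == 0:
            return float("nan")
        i = int(np.argmin(np.abs(self.timestamps_s - t_s)))
        return float(self.delta_T_C[i])


def temperature_series(
    timestamps_s: Sequence[float],
    shift_ppm: Sequence[float],
    baseline_end_s: float | None = None,
    baseline_mask: Sequence[bool] | None = None,
    coefficient_ppm_per_C: float = PRF_COEFF_PPM_PER_C,
    warmer_water_upfield: bool = True,
    tissue_label: str = "BAT",
) -> TemperatureSeries:
    """Convert a water-CH2 separation series into temperature changes.

    delta_T(t) = sign * (shift(t) - mean(shift over baseline)) / coefficient.
    With the default sign convention a *decrease* in the water-CH2
    separation is a temperature *increase* (warmer tissue moves the water
    line upfield, toward the CH2 line).

    Timepoints whose shift is NaN (failed fits) are excluded, not
    interpolated.  The baseline is either every accepted timepoint with
    timestamp <= ``baseline_end_s``, or an explicit ``baseline_mask``.
    """
    t = np.asarray(timestamps_s, dtype=float)
    d = np.asarray(shift_ppm, dtype=float)
    if t.shape != d.shape or t.ndim != 1:
        raise ValueError("timestamps and shifts must be 1-D arrays of equal length")
    if coefficient_ppm_per_C <= 0:
        raise ValueError("coefficient_ppm_per_C must be positive")

    ok = np.isfinite(d)
    excluded = tuple(float(x) for x in t[~ok])
    t, d = t[ok], d[ok]

    if baseline_mask is not None:
        base = np.asarray(baseline_mask, dtype=bool)[ok]
    elif baseline_end_s is not None:
        base = t <= baseline_end_s
    else:
        raise ValueError("provide baseline_end_s or baseline_mask")
    if not base.any():
        raise ValueError("baseline window contains no accepted timepoint")

    sign = -1.0 if warmer_water_upfield else 1.0
    delta = sign * (d - d[base].mean()) / coefficient_ppm_per_C
    return TemperatureSeries(
        timestamps_s=t,
        delta_T_C=delta,
        shift_ppm=d,
        baseline_mask=base,
        coefficient_ppm_per_C=coefficient_ppm_per_C,
        tissue_label=tissue_label,
        excluded_timestamps_s=excluded,
    )


class PRFThermometer(BaseEstimator):
    """End-to-end thermometry: fit every spectrum, difference the shifts,
    reference to the pre-cooling baseline and scale by the PRF coefficient.

    Parameters
    ----------
    coefficient_ppm_per_C : PRF coefficient, default 0.01 ppm/degC.
    baseline_end_s : timepoints at or before this time form the baseline
        reference window (default 0 -> only the first spectrum unless the
        series starts earlier).
    warmer_water_upfield : sign convention, see :func:`temperature_series`.
    fitter_params : keyword overrides for :class:`LorentzianPeakFitter`.

    Attributes
    ----------
    series_ : TemperatureSeries
    fits_ : list of PeakFit, one per input spectrum
    timestamps_, delta_T_, shift_ppm_ : accepted-timepoint arrays
    """

    def __init__(
        self,
        coefficient_ppm_per_C: float = PRF_COEFF_PPM_PER_C,
        baseline_end_s: float = 0.0,
        warmer_water_upfield: bool = True,
        fitter_params: dict | None = None,
    ):
        self.coefficient_ppm_per_C = coefficient_ppm_per_C
        self.baseline_end_s = baseline_end_s
        self.warmer_water_upfield = warmer_water_upfield
        self.fitter_params = fitter_params

    def fit(self, spectra: Sequence[Spectrum]) -> "PRFThermometer":
        spectra = sorted(spectra, key=lambda s: s.timestamp_s)
        fitter = LorentzianPeakFitter(**(self.fitter_params or {}))
        self.fits_ = [fitter.fit(s).fit_ for s in spectra]
        label = spectra[0].tissue_label if spectra else "BAT"
        self.series_ = temperature_series(
            [f.timestamp_s for f in self.fits_],
            [f.shift_difference_ppm() for f in self.fits_],
            baseline_end_s=self.baseline_end_s,
            coefficient_ppm_per_C=self.coefficient_ppm_per_C,
            warmer_water_upfield=self.warmer_water_upfield,
            tissue_label=label,
        )
        self.timestamps_ = self.series_.timestamps_s
        self.delta_T_ = self.series_.delta_T_C
        self.shift_ppm_ = self.series_.shift_ppm
        return self

    def transform(self, spectra: Sequence[Spectrum]) -> np.ndarray:
        """Fit and return the delta-T array for a series of spectra."""
        return self.fit(spectra).delta_T_
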