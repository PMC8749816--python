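"""Spectral assessment of intraoperative fiber-to-fiber monitoring spectra.

During interstitial photodynamic therapy (iPDT) of brain tumors, spectra are
recorded between pairs of implanted cylindrical diffuser fibers (CDFs), once
before and once after the illumination.  Each spectrum carries two signals of
interest:

* the transmitted treatment light around 635 nm, quantified by its integral
  intensity ``I_t`` over the 626-642 nm window, and
* the protoporphyrin IX (PpIX) fluorescence around 705 nm, quantified by the
  peak ``I_f`` of the fitted PpIX component within 702-708 nm.

A per-spectrum noise level is estimated from the signal-free 500-550 nm range
and drives a three-sigma detectability criterion for both signals.  The ratio
``R = I_t,pre / I_t,post`` summarizes the intra-operative change in treatment
light transmission for one ordered fiber pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "Spectrum",
    "FluorescenceBasis",
    "SpectralResult",
    "SpectrumError",
    "FitDegeneracyError",
    "noise_level",
    "integrate_transmission",
    "fit_fluorescence",
    "is_detectable",
    "assess_spectrum",
    "threshold_equivalent_intensity",
    "transmission_ratio",
    "TRANSMISSION_WINDOW",
    "FLUORESCENCE_WINDOW",
    "FLUORESCENCE_PEAK_WINDOW",
    "NOISE_WINDOW",
    "DETECTION_MULTIPLIER",
]

#: Wavelength window (nm) of the transmitted 635 nm treatment light.
TRANSMISSION_WINDOW = (626.0, 642.0)
#: Window (nm) used for the two-component fluorescence fit.
FLUORESCENCE_WINDOW = (650.0, 750.0)
#: Window (nm) in which the PpIX fluorescence peak intensity is read off.
FLUORESCENCE_PEAK_WINDOW = (702.0, 708.0)
#: Signal-free window (nm) used for the per-spectrum noise estimate.
NOISE_WINDOW = (500.0, 550.0)
#: Detectability criterion: peak signal must exceed this multiple of the noise.
DETECTION_MULTIPLIER = 3.0


class SpectrumError(ValueError):
    """Raised for spectra that do not satisfy an operation's preconditions."""


class FitDegeneracyError(RuntimeError):
    """Raised when the fluorescence basis spectra are (near-)collinear."""


@dataclass
class Spectrum:
    """One monitoring acquisition: intensity in counts/ms on a nm grid.

    Parameters
    ----------
    wavelengths
        Strictly increasing wavelength grid in nm.
    intensities
        Measured intensity in counts/ms, same length as ``wavelengths``.
    meta
        Free-form metadata; by convention ``case_id``, ``emitter``,
        ``detector`` and ``phase`` (``"pre"`` or ``"post"``).
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.shape != self.intensities.shape:
            raise SpectrumError("wavelengths and intensities must be matching 1-D arrays")
        if self.wavelengths.size < 2 or np.any(np.diff(self.wavelengths) <= 0):
            raise SpectrumError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise SpectrumError("intensities must be finite")

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        return (self.wavelengths >= lo) & (self.wavelengths <= hi)

    def covers(self, lo: float, hi: float) -> bool:
        return self.wavelengths[0] <= lo and self.wavelengths[-1] >= hi

    def require_window(self, lo: float, hi: float, *, min_samples: int = 2) -> np.ndarray:
        """Return the indices inside [lo, hi], or raise :class:`SpectrumError`."""
        if not self.covers(lo, hi):
            raise SpectrumError(
                f"spectrum grid [{self.wavelengths[0]:g}, {self.wavelengths[-1]:g}] nm "
                f"does not cover the required window [{lo:g}, {hi:g}] nm"
            )
        idx = np.nonzero(self.window_mask(lo, hi))[0]
        if idx.size < min_samples:
            raise SpectrumError(
                f"window [{lo:g}, {hi:g}] nm holds only {idx.size} samples "
                f"(need >= {min_samples})"
            )
        return idx


@dataclass
class FluorescenceBasis:
    """Normalized PpIX and tissue autofluorescence basis spectra on 650-750 nm.

    Each basis is non-negative with maximum 1 inside the fluorescence window.
    """

    wavelengths: np.ndarray
    ppix: np.ndarray
    auto: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.ppix = np.asarray(self.ppix, dtype=float)
        self.auto = np.asarray(self.auto, dtype=float)
        lo, hi = FLUORESCENCE_WINDOW
        win = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        for name, vals in (("ppix", self.ppix), (("auto"), self.auto)):
            if vals.shape != self.wavelengths.shape:
                raise SpectrumError(f"{name} basis length mismatch")
            if np.any(vals < -1e-12):
                raise SpectrumError(f"{name} basis must be non-negative")
            if win.any() and not np.isclose(vals[win].max(), 1.0, atol=1e-6):
                raise SpectrumError(f"{name} basis must have maximum 1 within 650-750 nm")

    def resampled(self, wavelengths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Linearly resample both bases onto a target grid (0 outside support)."""
        ppix = np.interp(wavelengths, self.wavelengths, self.ppix, left=0.0, right=0.0)
        auto = np.interp(wavelengths, self.wavelengths, self.auto, left=0.0, right=0.0)
        return ppix, auto


@dataclass
class SpectralResult:
    """Quantities extracted from one spectrum.

    ``i_t`` is the integral treatment-light transmission (counts/ms*nm), ``i_f``
    the fitted PpIX fluorescence peak (counts/ms), ``a``/``b`` the PpIX and
    autofluorescence weights, ``noise`` the 500-550 nm noise level (counts/ms).
    """

    i_t: float
    i_f: float
    a: float
    b: float
    noise: float
    transmission_detectable: bool
    fluorescence_detectable: bool
    meta: dict = field(default_factory=dict)


def noise_level(spectrum: Spectrum, window: tuple[float, float] = NOISE_WINDOW) -> float:
    """Noise level of one spectrum: standard deviation over the 500-550 nm range.

    A constant baseline is removed first, so the value is the standard deviation
    of the fluctuations in the signal-free window.  An exactly constant window
    yields 0.0 with a "degenerate" warning.
    """
    idx = spectrum.require_window(*window, min_samples=5)
    vals = spectrum.intensities[idx]
    if np.ptp(vals) == 0.0:
        warnings.warn("noise window is exactly constant; noise level degenerate (0)")
        return 0.0
    return float(np.std(vals - vals.mean(), ddof=1))


def integrate_transmission(
    spectrum: Spectrum, window: tuple[float, float] = TRANSMISSION_WINDOW
) -> float:
    """Integral transmitted treatment-light intensity I_t over 626-642 nm.

    Trapezoidal integration on the native grid; the window endpoints are
    included by linear interpolation so the integral covers exactly the window.
    """
    lo, hi = window
    spectrum.require_window(lo, hi)
    mask = (spectrum.wavelengths > lo) & (spectrum.wavelengths < hi)
    wl = np.concatenate(([lo], spectrum.wavelengths[mask], [hi]))
    vals = np.concatenate(
        (
            [np.interp(lo, spectrum.wavelengths, spectrum.intensities)],
            spectrum.intensities[mask],
            [np.interp(hi, spectrum.wavelengths, spectrum.intensities)],
        )
    )
    return float(np.trapezoid(vals, wl))


def fit_fluorescence(
    spectrum: Spectrum, basis: FluorescenceBasis
) -> tuple[float, float, float]:
    """Fit ``a*ppix + b*auto`` to the 650-750 nm window; return ``(a, b, I_f)``.

    The fit is non-negative least squares (negative PpIX amplitude would be
    unphysical).  ``I_f`` is the maximum of the fitted PpIX component
    ``a * ppix`` inside 702-708 nm.
    """
    idx = spectrum.require_window(*FLUORESCENCE_WINDOW, min_samples=4)
    wl = spectrum.wavelengths[idx]
    y = spectrum.intensities[idx]
    ppix, auto = basis.resampled(wl)
    design = np.column_stack([ppix, auto])
    norms = np.linalg.norm(design, axis=0)
    if np.any(norms == 0):
        raise FitDegeneracyError("a basis spectrum vanishes on the fit window")
    cosang = abs(float(design[:, 0] @ design[:, 1]) / (norms[0] * norms[1]))
    if cosang > 1.0 - 1e-10:
        raise FitDegeneracyError("PpIX and autofluorescence bases are collinear")
    (a, b), _ = nnls(design, y)
    peak_mask = (wl >= FLUORESCENCE_PEAK_WINDOW[0]) & (wl <= FLUORESCENCE_PEAK_WINDOW[1])
    if not peak_mask.any():
        raise SpectrumError("no grid samples inside the 702-708 nm peak window")
    i_f = float(a * ppix[peak_mask].max())
    return float(a), float(b), i_f


def is_detectable(
    spectrum: Spectrum,
    window: tuple[float, float],
    noise: float,
    multiplier: float = DETECTION_MULTIPLIER,
) -> bool:
    """True iff the maximum intensity in ``window`` strictly exceeds 3x noise."""
    idx = spectrum.require_window(*window)
    return bool(spectrum.intensities[idx].max() > multiplier * noise)


def assess_spectrum(
    spectrum: Spectrum,
    basis: FluorescenceBasis,
    multiplier: float = DETECTION_MULTIPLIER,
) -> SpectralResult:
    """Full spectral assessment of one acquisition.

    Computes the noise level, I_t with its detectability (peak in 626-642 nm
    versus ``multiplier`` x noise), the fluorescence fit and I_f with its
    detectability (fitted PpIX peak versus the same criterion).
    """
    noise = noise_level(spectrum)
    i_t = integrate_transmission(spectrum)
    trans_det = is_detectable(spectrum, TRANSMISSION_WINDOW, noise, multiplier)
    a, b, i_f = fit_fluorescence(spectrum, basis)
    fluor_det = i_f > multiplier * noise
    return SpectralResult(
        i_t=i_t,
        i_f=i_f,
        a=a,
        b=b,
        noise=noise,
        transmission_detectable=trans_det,
        fluorescence_detectable=bool(fluor_det),
        meta=dict(spectrum.meta),
    )


def threshold_equivalent_intensity(
    noise: float,
    multiplier: float = DETECTION_MULTIPLIER,
    window_width_nm: float = TRANSMISSION_WINDOW[1] - TRANSMISSION_WINDOW[0],
) -> float:
    """Integral intensity equivalent of the detection threshold.

    A peak sitting exactly at the detection threshold (``multiplier`` x noise)
    across the full transmission window would integrate to this value; it is
    used as a stand-in for I_t when the post-iPDT signal is undetectable.
    """
    return multiplier * noise * window_width_nm


def transmission_ratio(
    pre: SpectralResult,
    post: SpectralResult,
    threshold_equivalent: float | None = None,
) -> tuple[float, str]:
    """Treatment-light transmission ratio R = I_t,pre / I_t,post for one pair.

    Returns ``(R, qualifier)`` with qualifier one of:

    * ``"measured"`` - both signals detectable, plain ratio;
    * ``"pre-undetectable"`` - R defined as 0;
    * ``"lower-bound"`` - post signal undetectable; the detection-threshold
      equivalent intensity is substituted for I_t,post, so the true R is at
      least the returned value.
    """
    if not pre.transmission_detectable:
        return 0.0, "pre-undetectable"
    if post.transmission_detectable:
        if post.i_t == 0:
            raise ValueError("post I_t is 0 but flagged detectable")
        return float(pre.i_t / post.i_t), "measured"
    te = threshold_equivalent
    if te is None:
        te = threshold_equivalent_intensity(post.noise)
    if te <= 0:
        raise ValueError("threshold-equivalent intensity must be positive")
    return float(pre.i_t / te), "lower-bound"
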