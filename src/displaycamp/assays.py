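"""Biophysical assay scores from raw instrument data.

Three developability assays are scored here:

* **AC-SINS** — affinity-capture self-interaction nanoparticle
  spectroscopy.  The plasmon wavelength (absorbance maximum of
  antibody-coated gold nanoparticles, located by a local second-order
  polynomial fit) red-shifts with self-association; the score is the shift
  in nm of the sample versus a PBS blank.
* **Polyreactivity ELISA** — mean blank-subtracted OD450 over a panel of
  six unrelated antigens at four antibody concentrations.
* **nanoDSF Tm** — unfolding midpoint from the inflection of the
  F350/F330 intrinsic-fluorescence ratio versus temperature, located via
  the maximum of the smoothed first derivative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "Spectrum",
    "AcsinsResult",
    "ElisaPlate",
    "ElisaResult",
    "MeltCurve",
    "BoundaryPeakError",
    "AmbiguousTransitionError",
    "IncompletePlateError",
    "plasmon_wavelength",
    "acsins_score",
    "polyreactivity_score",
    "melting_temperature",
    "ELISA_ANTIGENS",
    "ELISA_CONCENTRATIONS_NG_ML",
]

ELISA_ANTIGENS = ("dsDNA", "ssDNA", "LPS", "KLH", "cardiolipin", "insulin")
ELISA_CONCENTRATIONS_NG_ML = (1000.0, 250.0, 62.5, 15.6)


class BoundaryPeakError(ValueError):
    """Absorbance maximum sits on the grid boundary; no vertex can be fit."""


class AmbiguousTransitionError(ValueError):
    """No single unfolding transition could be located."""

    def __init__(self, message: str, candidates: Sequence[float] = ()):
        super().__init__(message)
        self.candidates = tuple(candidates)


class IncompletePlateError(ValueError):
    pass


@dataclass
class Spectrum:
    """One absorbance spectrum (default grid 500-600 nm, 1 nm steps)."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    sample_id: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.shape != self.absorbance.shape:
            raise ValueError("wavelength and absorbance grids differ in length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")


def plasmon_wavelength(spectrum: Spectrum, fit_halfwidth_nm: float = 10.0) -> float:
    """Vertex wavelength of a parabola fit around the absorbance maximum.

    A second-order polynomial is least-squares fitted to the points within
    `fit_halfwidth_nm` of the raw argmax and its vertex abscissa returned;
    if the fitted parabola opens upward the raw argmax is returned instead.
    A raw argmax on the grid boundary raises BoundaryPeakError.
    """
    wl, ab = spectrum.wavelengths, spectrum.absorbance
    i_max = int(np.argmax(ab))
    if i_max == 0 or i_max == len(wl) - 1:
        raise BoundaryPeakError(
            f"absorbance maximum at grid boundary ({wl[i_max]:g} nm)"
        )
    window = np.abs(wl - wl[i_max]) <= fit_halfwidth_nm
    if window.sum() < 5:
        raise ValueError("fewer than 5 points inside the fit window")
    a, b, _ = np.polyfit(wl[window], ab[window], 2)
    if a >= 0:  # degenerate fit; fall back to the raw maximum
        return float(wl[i_max])
    vertex = -b / (2.0 * a)
    lo, hi = wl[window][0], wl[window][-1]
    return float(min(max(vertex, lo), hi))


@dataclass(frozen=True)
class AcsinsResult:
    plasmon_sample_nm: float
    plasmon_blank_nm: float

    @property
    def score_nm(self) -> float:
        return self.plasmon_sample_nm - self.plasmon_blank_nm


def acsins_score(
    sample_spectra: Sequence[Spectrum],
    blank_spectra: Sequence[Spectrum],
    fit_halfwidth_nm: float = 10.0,
) -> AcsinsResult:
    """AC-SINS score: mean sample plasmon wavelength minus mean blank.

    The plasmon wavelength is fitted per replicate and then averaged
    (robust to replicate-to-replicate baseline shifts); negative scores
    are permitted.
    """
    if not sample_spectra or not blank_spectra:
        raise ValueError("need at least one sample and one blank spectrum")
    sample = float(
        np.mean([plasmon_wavelength(s, fit_halfwidth_nm) for s in sample_spectra])
    )
    blank = float(
        np.mean([plasmon_wavelength(s, fit_halfwidth_nm) for s in blank_spectra])
    )
    return AcsinsResult(plasmon_sample_nm=sample, plasmon_blank_nm=blank)


@dataclass
class ElisaPlate:
    """OD450 of one antibody over 6 antigens x 4 concentrations + PBS blank."""

    od450: np.ndarray  # shape (6 antigens, 4 concentrations)
    blank_od450: float
    antigens: tuple[str, ...] = ELISA_ANTIGENS
    concentrations_ng_ml: tuple[float, ...] = ELISA_CONCENTRATIONS_NG_ML
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.od450 = np.asarray(self.od450, dtype=float)
        expected = (len(self.antigens), len(self.concentrations_ng_ml))
        if self.od450.shape != expected:
            raise IncompletePlateError(
                f"OD matrix must have shape {expected}, got {self.od450.shape}"
            )
        if np.any(np.isnan(self.od450)):
            raise IncompletePlateError("OD matrix contains missing wells")


@dataclass(frozen=True)
class ElisaResult:
    score: float
    per_antigen: dict[str, float] = field(default_factory=dict)


def polyreactivity_score(plate: ElisaPlate) -> ElisaResult:
    """Mean blank-subtracted OD over all 24 wells, plus per-antigen means."""
    net = plate.od450 - plate.blank_od450
    per_antigen = {
        antigen: float(net[i].mean()) for i, antigen in enumerate(plate.antigens)
    }
    return ElisaResult(score=float(net.mean()), per_antigen=per_antigen)


@dataclass
class MeltCurve:
    """Intrinsic-fluorescence melt curve on a temperature ramp."""

    temperature_c: np.ndarray
    f330: np.ndarray | None = None
    f350: np.ndarray | None = None
    ratio: np.ndarray | None = None  # F350/F330, computed if absent
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.temperature_c = np.asarray(self.temperature_c, dtype=float)
        if self.ratio is None:
            if self.f330 is None or self.f350 is None:
                raise ValueError("provide either the ratio or both f330 and f350")
            self.ratio = np.asarray(self.f350, dtype=float) / np.asarray(
                self.f330, dtype=float
            )
        else:
            self.ratio = np.asarray(self.ratio, dtype=float)
        if self.temperature_c.shape != self.ratio.shape:
            raise ValueError("temperature and ratio grids differ in length")
        if np.any(np.diff(self.temperature_c) <= 0):
            raise ValueError("temperature grid must be strictly increasing")


def melting_temperature(curve: MeltCurve, smooth_window_c: float = 3.0) -> float:
    """Unfolding midpoint: temperature of the maximum first derivative.

    The ratio series is smoothed by local quadratic regression
    (Savitzky-Golay) over `smooth_window_c` degrees, the first derivative
    taken from the smoothed fit, and the derivative peak refined by a
    parabola through its three surrounding points.  A flat curve, or
    several well-separated near-equal derivative maxima, raises
    AmbiguousTransitionError (candidates attached).
    """
    temp, ratio = curve.temperature_c, curve.ratio
    if len(temp) < 20:
        raise ValueError("need at least 20 points spanning the transition")
    step = float(np.median(np.diff(temp)))
    window = max(5, int(round(smooth_window_c / step)) | 1)  # odd, >= 5
    window = min(window, len(temp) - (1 - len(temp) % 2))
    deriv = savgol_filter(ratio, window_length=window, polyorder=2, deriv=1, delta=step)
    span = float(np.max(ratio) - np.min(ratio))
    scale = max(abs(float(np.max(ratio))), abs(float(np.min(ratio))), 1e-30)
    if span <= 1e-9 * scale or np.max(deriv) <= 0:
        raise AmbiguousTransitionError("no unfolding transition: flat ratio curve")
    i_max = int(np.argmax(deriv))
    # ambiguity check: near-equal derivative maxima far enough apart to be
    # distinct transitions (within a smoothing window = one transition)
    near = np.flatnonzero(deriv >= 0.95 * deriv[i_max])
    groups = np.split(near, np.flatnonzero(np.diff(near) > 1) + 1)
    candidates = [float(temp[g[np.argmax(deriv[g])]]) for g in groups]
    if max(candidates) - min(candidates) > 2.0 * smooth_window_c:
        raise AmbiguousTransitionError(
            f"multiple candidate transitions at {candidates}", candidates
        )
    if i_max == 0 or i_max == len(temp) - 1:
        return float(temp[i_max])
    # refine the derivative peak with a parabola over the smoothing window
    sel = np.abs(temp - temp[i_max]) <= smooth_window_c
    if sel.sum() < 3:
        sel = slice(i_max - 1, i_max + 2)
    tw, dw = temp[sel], deriv[sel]
    a, b, _ = np.polyfit(tw, dw, 2)
    if a >= 0:
        return float(temp[i_max])
    vertex = -b / (2.0 * a)
    return float(min(max(vertex, tw[0]), tw[-1]))
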