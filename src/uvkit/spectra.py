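"""Absorbance spectra and the model bands used to fit them.

An :class:`AbsorbanceSpectrum` is a sampled optical-density curve A(λ) on a
strictly increasing wavelength grid (nm).  Two model bands are provided:

* :func:`pigment_template` — the standard A1 (11-cis-retinal) visual-pigment
  absorbance nomogram, a fixed spectral shape fully determined by its
  absorption maximum λmax.  It is the sum of the main α-band and the
  secondary UV-side β-band, normalised to unit peak absorbance.
* :func:`gaussian_band` — a plain Gaussian in wavelength, used for the
  UV-absorbing (11-cis retinal, protonated-Schiff-base-free) form whose
  shape is not well described by the visual-pigment template.

All binary operations require identical grids; use :func:`resample` to bring
spectra onto a common grid explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DomainError, GridMismatchError

__all__ = [
    "AbsorbanceSpectrum",
    "PigmentBand",
    "TEMPLATE_A1",
    "pigment_template",
    "gaussian_band",
    "difference_spectrum",
    "resample",
    "normalize_to_peak",
]

# FWHM of a Gaussian in units of its standard deviation.
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class AbsorbanceSpectrum:
    """A sampled absorbance curve.

    Parameters
    ----------
    wavelengths
        Strictly increasing wavelength grid in nm, length >= 2.
    absorbance
        Optical density at each grid point; finite, may be negative
        (difference spectra).
    label
        Free-text tag, typically the irradiation state ("dark", "uv_1", ...).
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    label: str = ""

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise DomainError("wavelength grid must be 1-D with length >= 2")
        if ab.shape != wl.shape:
            raise DomainError(
                f"absorbance length {ab.size} != wavelength length {wl.size}"
            )
        if not np.all(np.diff(wl) > 0):
            raise DomainError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(ab)):
            raise DomainError("absorbance values must be finite")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbance", ab)

    # -- convenience -------------------------------------------------------
    def same_grid(self, other: "AbsorbanceSpectrum") -> bool:
        return (
            self.wavelengths.shape == other.wavelengths.shape
            and np.array_equal(self.wavelengths, other.wavelengths)
        )

    def peak_wavelength(self) -> float:
        """Wavelength of maximal absorbance."""
        return float(self.wavelengths[int(np.argmax(self.absorbance))])

    def band(self, lo: float, hi: float) -> "AbsorbanceSpectrum":
        """Restriction to the closed wavelength interval [lo, hi]."""
        m = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        if m.sum() < 2:
            raise DomainError(f"band [{lo}, {hi}] nm covers < 2 grid points")
        return AbsorbanceSpectrum(self.wavelengths[m], self.absorbance[m], self.label)

    def with_label(self, label: str) -> "AbsorbanceSpectrum":
        return replace(self, label=label)


@dataclass(frozen=True)
class PigmentBand:
    """One absorbing component: a template pigment band or a Gaussian.

    ``width`` is the Gaussian standard deviation σ in nm (ignored for
    ``kind="template"``); the full width at half maximum is ``2.3548·σ``.
    ``sign`` records whether the band enters a difference spectrum with
    positive or negative amplitude; ``amplitude`` is always the magnitude.
    """

    lambda_max: float
    amplitude: float
    kind: str = "template"
    width: float | None = None
    sign: int = 1

    def __post_init__(self):
        if self.kind not in ("template", "gaussian"):
            raise DomainError(f"unknown band kind {self.kind!r}")
        if not (250.0 <= self.lambda_max <= 700.0):
            raise DomainError(
                f"lambda_max {self.lambda_max} nm outside [250, 700] nm"
            )
        if self.amplitude < 0:
            raise DomainError("amplitude must be >= 0 (sign carried separately)")
        if self.kind == "gaussian":
            if self.width is None or self.width <= 0:
                raise DomainError("gaussian band requires width (sigma) > 0")
        if self.sign not in (-1, 1):
            raise DomainError("sign must be +1 or -1")

    @property
    def fwhm(self) -> float | None:
        if self.width is None:
            return None
        return FWHM_PER_SIGMA * self.width

    def sample(self, grid) -> AbsorbanceSpectrum:
        """Evaluate the signed band on a wavelength grid."""
        if self.kind == "template":
            base = pigment_template(self.lambda_max, grid)
        else:
            base = gaussian_band(self.lambda_max, self.width, 1.0, grid)
        return AbsorbanceSpectrum(
            base.wavelengths,
            self.sign * self.amplitude * base.absorbance,
            label=f"{self.kind}@{self.lambda_max:.1f}nm",
        )


# ---------------------------------------------------------------------------
# A1 visual-pigment nomogram
# ---------------------------------------------------------------------------

#: Constants of the A1 pigment absorbance template (α-band log-normal-like
#: shape plus β-band Gaussian).  Kept as configuration so an alternative
#: template (e.g. an A2 porphyropsin nomogram) can be swapped in.
TEMPLATE_A1 = {
    "A": 69.7,
    "B": 28.0,
    "C": -14.9,
    "D": 0.674,
    "b": 0.922,
    "c": 1.104,
    # a = a0 + a1 * exp(-(lmax - a2)^2 / a3)
    "a0": 0.8795,
    "a1": 0.0459,
    "a2": 300.0,
    "a3": 11940.0,
    # β-band: amplitude, center = m0 + m1*lmax, bandwidth = w0 + w1*center
    "beta_amp": 0.26,
    "beta_m0": 189.0,
    "beta_m1": 0.315,
    "beta_w0": -40.5,
    "beta_w1": 0.195,
    "lambda_max_range": (330.0, 650.0),
}


def _template_raw(lambda_max: float, wl: np.ndarray, c: dict) -> np.ndarray:
    """Unnormalised α+β template evaluated at wavelengths ``wl``."""
    a = c["a0"] + c["a1"] * np.exp(-((lambda_max - c["a2"]) ** 2) / c["a3"])
    x = lambda_max / wl
    alpha = 1.0 / (
        np.exp(c["A"] * (a - x))
        + np.exp(c["B"] * (c["b"] - x))
        + np.exp(c["C"] * (c["c"] - x))
        + c["D"]
    )
    beta_center = c["beta_m0"] + c["beta_m1"] * lambda_max
    beta_width = c["beta_w0"] + c["beta_w1"] * beta_center
    beta = c["beta_amp"] * np.exp(-(((wl - beta_center) / beta_width) ** 2))
    return alpha + beta


def pigment_template(
    lambda_max: float, grid, *, constants: dict | None = None
) -> AbsorbanceSpectrum:
    """A1 pigment absorbance template with maximum ``lambda_max``.

    The curve is normalised so its true peak (located numerically on a fine
    internal grid spanning 250–700 nm) equals 1; the requested ``grid`` may
    therefore cover only a limb of the band, in which case all returned
    values are < 1.

    Raises
    ------
    DomainError
        If ``lambda_max`` lies outside the template's validity range
        (330–650 nm by default).
    """
    c = TEMPLATE_A1 if constants is None else constants
    lo, hi = c["lambda_max_range"]
    if not (lo <= lambda_max <= hi):
        raise DomainError(
            f"template lambda_max {lambda_max} nm outside validity "
            f"range [{lo}, {hi}] nm"
        )
    wl = np.asarray(grid, dtype=float)
    if wl.size == 0:
        raise DomainError("empty wavelength grid")
    fine = np.arange(250.0, 700.0 + 0.05, 0.1)
    peak = float(np.max(_template_raw(lambda_max, fine, c)))
    vals = _template_raw(lambda_max, wl, c) / peak
    return AbsorbanceSpectrum(wl, vals, label=f"template@{lambda_max:.1f}nm")


def gaussian_band(
    center: float, sigma: float, amplitude: float, grid
) -> AbsorbanceSpectrum:
    """Gaussian absorbance band amplitude·exp(−(λ−center)²/(2σ²))."""
    if sigma <= 0:
        raise DomainError(f"sigma must be > 0, got {sigma}")
    if amplitude < 0:
        raise DomainError(f"amplitude must be >= 0, got {amplitude}")
    wl = np.asarray(grid, dtype=float)
    vals = amplitude * np.exp(-((wl - center) ** 2) / (2.0 * sigma**2))
    return AbsorbanceSpectrum(wl, vals, label=f"gaussian@{center:.1f}nm")


# ---------------------------------------------------------------------------
# grid operations
# ---------------------------------------------------------------------------


def difference_spectrum(
    after: AbsorbanceSpectrum, before: AbsorbanceSpectrum
) -> AbsorbanceSpectrum:
    """Pointwise ``after − before`` on a shared grid."""
    if not after.same_grid(before):
        raise GridMismatchError(
            "spectra are on different wavelength grids; resample() both onto "
            "a common grid before subtracting"
        )
    return AbsorbanceSpectrum(
        after.wavelengths,
        after.absorbance - before.absorbance,
        label=f"{after.label}-{before.label}",
    )


def resample(spectrum: AbsorbanceSpectrum, grid) -> AbsorbanceSpectrum:
    """Linear interpolation onto ``grid``; extrapolation is refused."""
    wl = np.asarray(grid, dtype=float)
    if wl.size < 2 or not np.all(np.diff(wl) > 0):
        raise DomainError("target grid must be strictly increasing, length >= 2")
    src = spectrum.wavelengths
    if wl[0] < src[0] or wl[-1] > src[-1]:
        raise DomainError(
            f"target grid [{wl[0]}, {wl[-1]}] nm extends beyond source range "
            f"[{src[0]}, {src[-1]}] nm; refusing to extrapolate"
        )
    vals = np.interp(wl, src, spectrum.absorbance)
    return AbsorbanceSpectrum(wl, vals, label=spectrum.label)


def normalize_to_peak(
    spectrum: AbsorbanceSpectrum, reference_peak: float
) -> AbsorbanceSpectrum:
    """Divide all values by a positive reference peak absorbance."""
    if reference_peak <= 0:
        raise DomainError(f"reference_peak must be > 0, got {reference_peak}")
    return AbsorbanceSpectrum(
        spectrum.wavelengths,
        spectrum.absorbance / reference_peak,
        label=spectrum.label,
    )
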