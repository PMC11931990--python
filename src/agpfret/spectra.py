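"""Spectral decomposition and spectroscopic FRET-efficiency estimators.

A mixture of donor-labeled Agp2 and acceptor-labeled Agp1 is measured as an
absorbance spectrum and an emission spectrum.  Both are decomposed into the
single-component reference spectra by linear least squares; the resulting
component amplitudes give the absorbances and integrated intensities that
enter the two classical estimators:

* donor quenching:      ``E = 1 - (I_DA * A_D) / (I_D * A_DA)``
* stimulated emission:  ``E = (I_AD * A_A - I_A * A_AD) / (I_A * A_DA)``

where ``I`` are integrated emission intensities, ``A`` absorbances at the
excitation wavelength, subscript ``D``/``A`` donor/acceptor alone and
``DA``/``AD`` the same species inside the mixture.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.optimize import nnls

from .exceptions import InvalidArgumentError

#: Default integration band for donor emission (nm).
DONOR_EMISSION_BAND = (500.0, 560.0)
#: Default integration band for acceptor emission (nm).
ACCEPTOR_EMISSION_BAND = (575.0, 650.0)

#: Molar extinction coefficients (M^-1 cm^-1) used for incorporation ratios.
EXTINCTION_COEFFICIENTS = {
    "agp1_apo_280nm": 100_000.0,
    "agp1_pcm_apo_280nm": 78_400.0,
    "agp1_pr_700nm": 90_000.0,
    "agp2_apo_280nm": 81_300.0,
    "agp2_pcm_apo_280nm": 57_900.0,
    "agp2_hk_rr_280nm": 23_600.0,
    "agp2_pfr_750nm": 45_000.0,
    "free_bv_696nm_meoh_hcl": 30_800.0,
    "atto495_495nm": 80_000.0,
    "atto565_565nm": 120_000.0,
}

#: Bound Atto-495 absorbs ~0.7x relative to the free fluorophore.
BOUND_ATTO495_CORRECTION = 0.7


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-gridded absorbance or emission trace.

    ``wavelengths`` must be a strictly increasing grid in nm; ``values`` are
    absorbance (AU) or fluorescence counts (arbitrary units).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "emission"  # {"absorbance", "emission"}

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", v)
        if wl.ndim != 1 or v.shape != wl.shape or wl.size < 2:
            raise InvalidArgumentError("wavelengths/values must be equal-length 1-D, >= 2 points")
        if np.any(np.diff(wl) <= 0):
            raise InvalidArgumentError("wavelength grid must be strictly increasing")
        if self.kind not in ("absorbance", "emission"):
            raise InvalidArgumentError(f"unknown spectrum kind {self.kind!r}")
        if self.kind == "absorbance" and np.any(v < -1e-3):
            raise InvalidArgumentError("absorbance below -1e-3 (beyond baseline noise)")

    def value_at(self, wavelength: float) -> float:
        """Linearly interpolated value at ``wavelength`` (no extrapolation)."""
        wl = self.wavelengths
        if not wl[0] <= wavelength <= wl[-1]:
            raise InvalidArgumentError(
                f"wavelength {wavelength} nm outside grid [{wl[0]}, {wl[-1]}]"
            )
        return float(np.interp(wavelength, wl, self.values))

    def resampled(self, grid: np.ndarray) -> "Spectrum":
        """Linear interpolation onto ``grid``; extrapolation is an error."""
        grid = np.asarray(grid, dtype=float)
        if grid[0] < self.wavelengths[0] - 1e-9 or grid[-1] > self.wavelengths[-1] + 1e-9:
            raise InvalidArgumentError(
                "target grid extends beyond the spectrum range (no extrapolation)"
            )
        return replace(self, wavelengths=grid, values=np.interp(grid, self.wavelengths, self.values))


@dataclass(frozen=True)
class DecompositionResult:
    """Least-squares amplitudes of the two reference components."""

    coeff_donor: float
    coeff_acceptor: float
    residual_rms: float


@dataclass(frozen=True)
class FretSpectralQuantities:
    """The intensities/absorbances entering the two efficiency estimators.

    Integrated intensities are in arbitrary (but mutually consistent) units;
    absorbances are AU at the excitation wavelength unless noted.  The
    integration bands used are recorded alongside the values.
    """

    I_DA: float = np.nan
    I_D: float = np.nan
    I_AD: float = np.nan
    I_A: float = np.nan
    A_D: float = np.nan
    A_DA: float = np.nan
    A_A: float = np.nan
    A_AD: float = np.nan
    donor_band: tuple = DONOR_EMISSION_BAND
    acceptor_band: tuple = ACCEPTOR_EMISSION_BAND


def read_spectrum(path, kind: str = "emission") -> Spectrum:
    """Read a two-column (wavelength, value) text file; '#' starts a comment."""
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] < 2:
        raise InvalidArgumentError(f"{path}: expected two columns (wavelength, value)")
    return Spectrum(data[:, 0], data[:, 1], kind=kind)


def write_spectrum(path, spectrum: Spectrum, header: str = "") -> None:
    """Write a spectrum as two-column text with an optional '#' header."""
    np.savetxt(
        path,
        np.column_stack([spectrum.wavelengths, spectrum.values]),
        fmt="%.6g",
        header=header or f"{spectrum.kind} spectrum: wavelength_nm value",
    )


def decompose_mixture(
    mixture: Spectrum,
    donor_ref: Spectrum,
    acceptor_ref: Spectrum,
    nonnegative: bool = True,
) -> DecompositionResult:
    """Decompose a mixture spectrum into donor and acceptor components.

    Solves ``min || mixture - a*donor - b*acceptor ||_2`` on the mixture
    grid (references resampled by linear interpolation).  With
    ``nonnegative=True`` (default) the amplitudes are constrained to be
    physical, ``a, b >= 0``.
    """
    grid = mixture.wavelengths
    lo = max(grid[0], donor_ref.wavelengths[0], acceptor_ref.wavelengths[0])
    hi = min(grid[-1], donor_ref.wavelengths[-1], acceptor_ref.wavelengths[-1])
    if lo >= hi:
        raise InvalidArgumentError("spectra wavelength ranges do not overlap")
    sel = (grid >= lo) & (grid <= hi)
    grid = grid[sel]
    y = mixture.values[sel]
    d = donor_ref.resampled(grid).values
    a = acceptor_ref.resampled(grid).values

    X = np.column_stack([d, a])
    if np.linalg.matrix_rank(X, tol=1e-10 * np.abs(X).max()) < 2:
        raise np.linalg.LinAlgError(
            "donor and acceptor reference spectra are collinear; decomposition is rank-deficient"
        )
    if nonnegative:
        coeffs, _ = nnls(X, y)
    else:
        coeffs, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coeffs
    return DecompositionResult(
        coeff_donor=float(coeffs[0]),
        coeff_acceptor=float(coeffs[1]),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def integrate_band(spectrum: Spectrum, lo: float, hi: float) -> float:
    """Trapezoidal integral of the spectrum over [lo, hi] nm."""
    if not lo < hi:
        raise InvalidArgumentError(f"band limits must satisfy lo < hi, got [{lo}, {hi}]")
    wl = spectrum.wavelengths
    if lo < wl[0] or hi > wl[-1]:
        raise InvalidArgumentError(
            f"band [{lo}, {hi}] outside grid [{wl[0]}, {wl[-1]}]"
        )
    inner = wl[(wl > lo) & (wl < hi)]
    grid = np.concatenate([[lo], inner, [hi]])
    vals = np.interp(grid, wl, spectrum.values)
    return float(np.trapezoid(vals, grid))


def efret_donor_quenching(q: FretSpectralQuantities) -> float:
    """Efficiency from the reduction of donor emission in the mixture."""
    if not q.I_D > 0 or not q.A_DA > 0:
        raise InvalidArgumentError("efret_donor_quenching requires I_D > 0 and A_DA > 0")
    return 1.0 - (q.I_DA * q.A_D) / (q.I_D * q.A_DA)


def efret_stimulated_emission(q: FretSpectralQuantities) -> float:
    """Efficiency from the acceptor-emission surplus in the mixture.

    The surplus acceptor emission beyond direct excitation, normalized to the
    donor's absorbed quanta.  May return a (flagged by sign) negative value
    when the mixture acceptor emission falls below the direct-excitation
    expectation; callers decide how to treat it.
    """
    if not q.I_A > 0 or not q.A_DA > 0:
        raise InvalidArgumentError("efret_stimulated_emission requires I_A > 0 and A_DA > 0")
    return (q.I_AD * q.A_A - q.I_A * q.A_AD) / (q.I_A * q.A_DA)


def emission_ratio(
    spectrum: Spectrum, num_wavelength: float = 590.0, den_wavelength: float = 523.0
) -> float:
    """Fluorescence ratio F(num)/F(den), default 590/523 nm.

    The acceptor-maximum to donor-maximum ratio is a relative FRET indicator
    for comparing otherwise identical samples (it rises with transfer).
    """
    num = spectrum.value_at(num_wavelength)
    den = spectrum.value_at(den_wavelength)
    if den == 0:
        raise InvalidArgumentError(f"zero denominator intensity at {den_wavelength} nm")
    return num / den


def molar_ratio(
    a_signal: float,
    eps_signal: float,
    a_280: float,
    eps_280: float,
    correction: float = 1.0,
) -> float:
    """Molar chromophore/fluorophore-to-protein incorporation ratio.

    ``(a_signal / (eps_signal * correction)) / (a_280 / eps_280)`` with A_280
    as the protein-concentration measure and an optional bound-state
    extinction correction (0.7 for Agp2-bound Atto-495).
    """
    for name, v in (
        ("a_signal", a_signal),
        ("eps_signal", eps_signal),
        ("a_280", a_280),
        ("eps_280", eps_280),
        ("correction", correction),
    ):
        if not v > 0:
            raise InvalidArgumentError(f"{name} must be positive, got {v}")
    return (a_signal / (eps_signal * correction)) / (a_280 / eps_280)


def estimate_fret_from_spectra(
    donor_abs: Spectrum,
    acceptor_abs: Spectrum,
    mixture_abs: Spectrum,
    donor_em: Spectrum,
    acceptor_em: Spectrum,
    mixture_em: Spectrum,
    excitation_nm: float = 470.0,
    acceptor_reference_nm: float | None = None,
    donor_band: tuple = DONOR_EMISSION_BAND,
    acceptor_band: tuple = ACCEPTOR_EMISSION_BAND,
    nonnegative: bool = True,
):
    """Run the full spectroscopic pipeline on one sample triple.

    Decomposes the mixture absorbance and emission spectra into the
    single-component references, extracts the estimator quantities and
    returns ``(E_donor_quenching, E_stimulated_emission, quantities)``.

    ``acceptor_reference_nm`` is the wavelength at which the acceptor-alone
    absorbance ``A_A`` is read (defaults to the excitation wavelength, the
    reading under which the stimulated-emission estimator is exact for a
    linear photon-budget model).
    """
    if acceptor_reference_nm is None:
        acceptor_reference_nm = excitation_nm

    dec_abs = decompose_mixture(mixture_abs, donor_abs, acceptor_abs, nonnegative)
    dec_em = decompose_mixture(mixture_em, donor_em, acceptor_em, nonnegative)

    a_d = donor_abs.value_at(excitation_nm)
    a_a = acceptor_abs.value_at(acceptor_reference_nm)
    i_d = integrate_band(donor_em, *donor_band)
    i_a = integrate_band(acceptor_em, *acceptor_band)
    q = FretSpectralQuantities(
        I_DA=dec_em.coeff_donor * i_d,
        I_D=i_d,
        I_AD=dec_em.coeff_acceptor * i_a,
        I_A=i_a,
        A_D=a_d,
        A_DA=dec_abs.coeff_donor * a_d,
        A_A=a_a,
        A_AD=dec_abs.coeff_acceptor * acceptor_abs.value_at(excitation_nm),
        donor_band=donor_band,
        acceptor_band=acceptor_band,
    )
    return efret_donor_quenching(q), efret_stimulated_emission(q), q
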