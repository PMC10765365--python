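"""Chromophore absorption spectra for unmixing and phantom synthesis.

Holds per-wavelength molar absorption coefficients of oxygenated (HbO2) and
deoxygenated (Hb) hemoglobin, plus a relative melanin absorption, and exposes
the difference spectrum eps_delta = eps_hbo2 - eps_hb that the oxygen-saturation
closed form needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ChromophoreSpectra",
    "toy_spectra",
    "default_phantom_spectra",
    "literature_spectra",
    "read_spectra_csv",
    "write_spectra_csv",
]


@dataclass(frozen=True)
class ChromophoreSpectra:
    """Absorption coefficients per wavelength.

    ``eps_hbo2`` / ``eps_hb`` are molar absorption coefficients
    (L·mol⁻¹·cm⁻¹); ``eps_melanin`` is a relative melanin absorption in
    arbitrary units (melanin has no meaningful molar concentration here).
    Wavelengths must be strictly increasing and all coefficients positive.
    """

    wavelengths_nm: tuple[float, ...]
    eps_hbo2: tuple[float, ...]
    eps_hb: tuple[float, ...]
    eps_melanin: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        if wl.ndim != 1 or wl.size == 0:
            raise ValueError("wavelengths_nm must be a non-empty 1D sequence")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        mel = self.eps_melanin if self.eps_melanin else tuple(1.0 for _ in wl)
        for name, arr in (
            ("eps_hbo2", self.eps_hbo2),
            ("eps_hb", self.eps_hb),
            ("eps_melanin", mel),
        ):
            a = np.asarray(arr, dtype=float)
            if a.shape != wl.shape:
                raise ValueError(f"{name} must match wavelengths in length")
            if not np.all(a > 0):
                raise ValueError(f"{name} coefficients must all be > 0")
        object.__setattr__(self, "wavelengths_nm", tuple(float(w) for w in wl))
        object.__setattr__(self, "eps_hbo2", tuple(float(v) for v in self.eps_hbo2))
        object.__setattr__(self, "eps_hb", tuple(float(v) for v in self.eps_hb))
        object.__setattr__(self, "eps_melanin", tuple(float(v) for v in mel))

    def _index(self, wavelength_nm: float) -> int:
        for i, w in enumerate(self.wavelengths_nm):
            if abs(w - wavelength_nm) < 0.5:
                return i
        raise KeyError(
            f"wavelength {wavelength_nm} nm not in spectra "
            f"(available: {self.wavelengths_nm})"
        )

    def hbo2(self, wavelength_nm: float) -> float:
        return self.eps_hbo2[self._index(wavelength_nm)]

    def hb(self, wavelength_nm: float) -> float:
        return self.eps_hb[self._index(wavelength_nm)]

    def melanin(self, wavelength_nm: float) -> float:
        return self.eps_melanin[self._index(wavelength_nm)]

    def delta(self, wavelength_nm: float) -> float:
        """eps_HbO2 - eps_Hb at the given wavelength."""
        i = self._index(wavelength_nm)
        return self.eps_hbo2[i] - self.eps_hb[i]


def toy_spectra() -> ChromophoreSpectra:
    """Small hand-checkable spectra used throughout the test suite.

    At (λ1, λ2) = (575, 586): eps_hb = (4, 1), eps_hbo2 = (2, 3), so a voxel
    with true saturation 0.6 has amplitude ratio 2.8/2.2 and the closed form
    must return 0.6 exactly.  No external constant is load-bearing.
    """
    return ChromophoreSpectra(
        wavelengths_nm=(575.0, 586.0, 650.0),
        eps_hbo2=(2.0, 3.0, 0.4),
        eps_hb=(4.0, 1.0, 0.9),
        eps_melanin=(1.0, 1.0, 1.0),
    )


def default_phantom_spectra() -> ChromophoreSpectra:
    """Spectra used by the synthetic cohort's forward model.

    Stylized, not literature, by design: hemoglobin absorbs strongly in the
    visible band at 575/586 nm and weakly at 650 nm, where melanin dominates,
    and the melanin spectrum is deliberately flat between 575 and 650 nm so
    the 575 − 650 subtraction cancels melanin exactly — the idealisation
    under which spectral-subtraction vessel imaging is exact.  The HbO2/Hb
    difference changes sign between the oximetry pair (positive at 575,
    negative at 586), which keeps the amplitude-ratio inversion
    well-conditioned so saturation errors stay dominated by the injected
    amplitude noise rather than by the spectral geometry.
    """
    return ChromophoreSpectra(
        wavelengths_nm=(575.0, 586.0, 650.0),
        eps_hbo2=(55000.0, 30000.0, 368.0),
        eps_hb=(42000.0, 45000.0, 3750.0),
        eps_melanin=(40000.0, 40000.0, 40000.0),
    )


def literature_spectra() -> ChromophoreSpectra:
    """Approximate literature hemoglobin molar absorption coefficients.

    Values (L·mol⁻¹·cm⁻¹) are rounded from standard tabulated compilations of
    human hemoglobin absorption; intended for real-data use where the actual
    acquisition wavelengths are 575/586/650 nm.  The melanin column is a
    relative absorption following the usual monotone decay with wavelength.
    These constants are shipped for convenience and are not used by any test.
    """
    return ChromophoreSpectra(
        wavelengths_nm=(575.0, 586.0, 650.0),
        eps_hbo2=(55500.0, 31600.0, 368.0),
        eps_hb=(42100.0, 33000.0, 3750.0),
        eps_melanin=(1.00, 0.94, 0.66),
    )


def read_spectra_csv(path: str | Path) -> ChromophoreSpectra:
    """Read a spectra table ``wavelength_nm,eps_hbo2,eps_hb[,eps_melanin]``."""
    df = pd.read_csv(path)
    required = {"wavelength_nm", "eps_hbo2", "eps_hb"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"spectra CSV {path} must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    df = df.sort_values("wavelength_nm")
    mel = (
        tuple(df["eps_melanin"].astype(float))
        if "eps_melanin" in df.columns
        else ()
    )
    return ChromophoreSpectra(
        wavelengths_nm=tuple(df["wavelength_nm"].astype(float)),
        eps_hbo2=tuple(df["eps_hbo2"].astype(float)),
        eps_hb=tuple(df["eps_hb"].astype(float)),
        eps_melanin=mel,
    )


def write_spectra_csv(spectra: ChromophoreSpectra, path: str | Path) -> None:
    pd.DataFrame(
        {
            "wavelength_nm": spectra.wavelengths_nm,
            "eps_hbo2": spectra.eps_hbo2,
            "eps_hb": spectra.eps_hb,
            "eps_melanin": spectra.eps_melanin,
        }
    ).to_csv(path, index=False)
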