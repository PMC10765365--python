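"""Dual-wavelength spectral unmixing and oxygen-saturation mapping.

Three channels are derived from a multi-wavelength scan:

* **vessel channel** — hemoglobin structures isolated by subtracting the
  melanin-dominated 650 nm amplitude from the hemoglobin-dominated 575 nm
  amplitude, clipped at zero;
* **melanin channel** — the 650 nm amplitude, optionally restricted to a
  superficial depth band where the epidermal melanin lives;
* **SO2 map** — per-voxel oxygen saturation from the 575/586 nm amplitude
  ratio, assuming amplitude ∝ absorption µ_a and known molar absorption
  coefficients.

With S the oxygen saturation and T total hemoglobin,
``µ_a(λ) ∝ T · (ε_Hb(λ) + S · ε_ΔHb(λ))`` where ε_ΔHb = ε_HbO2 − ε_Hb.
The amplitude ratio q = µ_a(λ1)/µ_a(λ2) is independent of T and inverts in
closed form:

    S = (ε_Hb(λ1) − q·ε_Hb(λ2)) / (q·ε_ΔHb(λ2) − ε_ΔHb(λ1))

Any shared scale factor (fluence, Grüneisen, units) cancels in q, so SO2
depends only on the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MultiwavelengthScan
from .spectra import ChromophoreSpectra

__all__ = ["SO2Map", "vessel_channel", "melanin_channel", "compute_so2"]

VESSEL_PAIR = (575.0, 650.0)
OXIMETRY_PAIR = (575.0, 586.0)
MELANIN_WAVELENGTH = 650.0

#: raw SO2 outside this window is treated as nonphysical and invalidated;
#: small overshoot inside it is clamped to [0, 1]
SO2_ACCEPT_RANGE = (-0.25, 1.25)

#: voxels with µa(λ2) below this fraction of the volume maximum give a
#: meaningless ratio and are marked invalid
DENOMINATOR_FLOOR_FRAC = 1e-6


@dataclass
class SO2Map:
    """Per-voxel oxygen saturation with a validity mask.

    ``so2`` is finite and in [0, 1] exactly where ``valid`` is True; invalid
    voxels hold NaN.
    """

    so2: np.ndarray
    valid: np.ndarray
    wavelengths_used: tuple[float, float]

    def __post_init__(self) -> None:
        good = self.so2[self.valid]
        if good.size and (not np.all(np.isfinite(good)) or good.min() < 0 or good.max() > 1):
            raise ValueError("so2 must be finite and in [0, 1] on valid voxels")


def vessel_channel(scan: MultiwavelengthScan) -> np.ndarray:
    """Hemoglobin channel: max(PA(575) − PA(650), 0), elementwise.

    Negative differences are clipped to zero — amplitudes are non-negative
    energies and the subtraction target is a non-negative vessel image.
    """
    lo, hi = VESSEL_PAIR
    return np.maximum(scan.volume(lo) - scan.volume(hi), 0.0)


def melanin_channel(
    scan: MultiwavelengthScan, depth_band_um: tuple[float, float] | None = None
) -> np.ndarray:
    """Melanin channel: the 650 nm amplitude volume.

    If ``depth_band_um`` is given, voxels outside the half-open band
    [lo, hi) µm are zeroed — epidermal melanin analysis is superficial.
    """
    vol = scan.volume(MELANIN_WAVELENGTH).astype(float, copy=True)
    if depth_band_um is not None:
        lo, hi = depth_band_um
        depth = (np.arange(vol.shape[0], dtype=float) + 0.5) * scan.spacing_um[0]
        outside = (depth < lo) | (depth >= hi)
        vol[outside, :, :] = 0.0
    return vol


def compute_so2(
    scan: MultiwavelengthScan,
    spectra: ChromophoreSpectra,
    wavelengths_nm: tuple[float, float] = OXIMETRY_PAIR,
    denominator_floor_frac: float = DENOMINATOR_FLOOR_FRAC,
) -> SO2Map:
    """Closed-form per-voxel oxygen saturation from a two-wavelength ratio.

    Voxels are invalidated when the λ2 amplitude sits at the noise floor,
    when the closed form is non-finite, or when the raw value falls outside
    ``SO2_ACCEPT_RANGE``; surviving values are clamped to [0, 1].

    Raises if the spectra lack a wavelength or are degenerate (the Hb and
    ΔHb spectra proportional across the pair, which makes the ratio
    uninformative for every voxel).
    """
    l1, l2 = wavelengths_nm
    a1 = scan.volume(l1).astype(float)
    a2 = scan.volume(l2).astype(float)
    eh1, eh2 = spectra.hb(l1), spectra.hb(l2)
    ed1, ed2 = spectra.delta(l1), spectra.delta(l2)
    # singular system: eps_hb and eps_delta proportional across the pair
    # makes numerator and denominator vanish together for every ratio
    if abs(eh1 * ed2 - eh2 * ed1) < 1e-12 * max(abs(eh1 * ed2), abs(eh2 * ed1), 1.0):
        raise ValueError(
            f"degenerate spectra at {wavelengths_nm}: ε_Hb and ε_ΔHb are "
            "proportional across the wavelength pair; SO2 is unidentifiable"
        )

    floor = denominator_floor_frac * max(float(a2.max()), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = a1 / a2
        raw = (eh1 - q * eh2) / (q * ed2 - ed1)
    valid = (a2 > floor) & np.isfinite(raw)
    lo, hi = SO2_ACCEPT_RANGE
    valid &= (raw >= lo) & (raw <= hi)
    so2 = np.full(raw.shape, np.nan)
    so2[valid] = np.clip(raw[valid], 0.0, 1.0)
    return SO2Map(so2=so2, valid=valid, wavelengths_used=(float(l1), float(l2)))
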