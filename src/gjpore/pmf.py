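"""Free-energy profiles by Boltzmann inversion of axial ion densities.

The potential of mean force along the pore axis is obtained from the
equilibrium density as

    dG(z) = -R T ln( rho(z) / rho_ref ),

with rho_ref the mean density over a bulk reference band so that the
bulk plateau sits at zero.  The density uncertainty propagates to the
profile as sigma_dG = |R T sigma_rho / rho| (first-order in
sigma_rho/rho).  Bins with zero density are flagged undefined rather
than mapped to infinity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_T, R_KCAL
from .density import DensityProfile

__all__ = ["FreeEnergyProfile", "boltzmann_invert", "propagate_error", "extract_barrier"]


@dataclass
class FreeEnergyProfile:
    """dG(z) +/- sigma in kcal/mol, referenced to a bulk band."""

    z_centers: np.ndarray
    dG: np.ndarray
    sigma_dG: np.ndarray
    defined: np.ndarray  # bool per bin; False where rho = 0
    reference_band: tuple[float, float]
    T: float
    species: str

    def __post_init__(self):
        self.z_centers = np.asarray(self.z_centers, dtype=float)
        self.dG = np.asarray(self.dG, dtype=float)
        self.sigma_dG = np.asarray(self.sigma_dG, dtype=float)
        self.defined = np.asarray(self.defined, dtype=bool)
        if np.any(self.sigma_dG[self.defined] < 0):
            raise ValueError("sigma_dG must be non-negative where defined")


def boltzmann_invert(
    profile: DensityProfile,
    T: float = DEFAULT_T,
    reference_band: tuple[float, float] | None = None,
) -> FreeEnergyProfile:
    """Invert an axial density profile into a free-energy profile.

    ``reference_band`` is the (z_lo, z_hi) bulk region whose mean
    density defines the zero of free energy; by default the outermost
    10 A at each end of the profile are pooled.  Scaling the density by
    any positive constant leaves the result unchanged.
    """
    z = profile.z_centers
    rho = profile.rho
    if reference_band is None:
        span = 10.0
        ref_mask = (z <= z[0] + span) | (z >= z[-1] - span)
        reference_band = (float(z[0]), float(z[-1]))
    else:
        ref_mask = (z >= reference_band[0]) & (z <= reference_band[1])
    ref_rho = rho[ref_mask]
    if not np.any(ref_rho > 0):
        raise ValueError("reference band has no bins with positive density")
    rho_ref = float(ref_rho.mean())
    defined = rho > 0
    dG = np.full(len(z), np.nan)
    dG[defined] = -R_KCAL * T * np.log(rho[defined] / rho_ref)
    sigma = propagate_error(profile, T=T)
    return FreeEnergyProfile(
        z_centers=z,
        dG=dG,
        sigma_dG=sigma,
        defined=defined,
        reference_band=reference_band,
        T=T,
        species=profile.species,
    )


def propagate_error(profile: DensityProfile, T: float = DEFAULT_T) -> np.ndarray:
    """First-order error propagation: sigma_dG = |R T sigma_rho / rho|.

    Bins with zero density get NaN (undefined), never a division."""
    rho = profile.rho
    sigma = np.full(len(rho), np.nan)
    ok = rho > 0
    sigma[ok] = np.abs(R_KCAL * T * profile.sigma_rho[ok] / rho[ok])
    return sigma


def extract_barrier(
    fe: FreeEnergyProfile, window: tuple[float, float] | None = None
) -> dict:
    """Barrier height (max dG relative to the bulk zero) and location
    inside ``window``; ties broken toward smaller |z|; undefined bins
    are skipped."""
    z = fe.z_centers
    mask = fe.defined.copy()
    if window is not None:
        mask &= (z >= window[0]) & (z <= window[1])
    if not np.any(mask):
        raise ValueError("no defined bins in the requested window")
    dg = fe.dG[mask]
    zz = z[mask]
    height = dg.max()
    candidates = zz[np.isclose(dg, height)]
    z_at = candidates[np.argmin(np.abs(candidates))]
    return {"height": float(height), "z_at": float(z_at)}
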