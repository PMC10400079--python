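"""Static pore-radius profiling by sphere insertion, and profile
comparison utilities.

At each axial position the pore radius is the radius of the largest
probe sphere that can be centred in that plane without overlapping any
atom's van der Waals sphere:

    r(z) = max over in-plane centres c of  min over atoms i (|c - x_i| - vdw_i)

The maximization uses deterministic multi-start local ascent (Nelder-
Mead on the in-plane coordinates) seeded on the axis point plus random
in-plane starts, in the spirit of HOLE but without simulated annealing.
Planes where the optimum exceeds 30 A are capped and flagged unbounded
(bulk/vestibule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .core import AxisFrame, StructureModel

__all__ = ["RadiusProfile", "static_radius_profile", "min_radius", "compare_structures"]

#: cap marking bulk / vestibule planes (A)
RADIUS_CAP = 30.0


@dataclass
class RadiusProfile:
    """Pore radius along the axis: mean, fluctuation, and provenance."""

    z_centers: np.ndarray
    radius: np.ndarray
    radius_sd: np.ndarray
    method: str  # "sphere_insertion" | "voxel_emptiness"
    structure_id: str = ""
    unbounded: np.ndarray | None = None  # bool flags for capped planes

    def __post_init__(self):
        self.z_centers = np.asarray(self.z_centers, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.radius_sd = np.asarray(self.radius_sd, dtype=float)
        if not (len(self.z_centers) == len(self.radius) == len(self.radius_sd)):
            raise ValueError("profile arrays must have equal length")
        if np.any(self.radius < 0):
            raise ValueError("radius must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"z_A": self.z_centers, "radius_A": self.radius, "sd_A": self.radius_sd}
        )
        if self.unbounded is not None:
            df["unbounded"] = self.unbounded
        return df


def _clearance(c_xy: np.ndarray, z: float, pos: np.ndarray, radii: np.ndarray) -> float:
    """min over atoms of (3D distance to centre) - vdw."""
    c = np.array([c_xy[0], c_xy[1], z])
    d = np.linalg.norm(pos - c, axis=1)
    return float(np.min(d - radii))


def static_radius_profile(
    structure: StructureModel,
    axis: AxisFrame,
    z_range: tuple[float, float],
    step: float = 0.5,
    n_starts: int = 8,
    max_iter: int = 200,
    seed: int = 0,
    start_spread: float = 3.0,
    center_bound: float = 5.0,
) -> RadiusProfile:
    """Sphere-insertion pore radius profile of a static structure.

    Deterministic given ``seed``: the optimizer starts from the axis
    point plus ``n_starts - 1`` random in-plane offsets drawn once per
    plane from a seeded generator.  The probe centre is confined within
    ``center_bound`` A of the axis (a steep penalty beyond it) so the
    ascent cannot leak out of the pore through the vestibule; widen it
    for channels whose lumen wanders off-axis.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    pos_all = axis.to_frame(structure.positions())
    if len(pos_all) < 4:
        raise ValueError("structure must have at least 4 atoms")
    radii_all = structure.radii()
    rng = np.random.default_rng(seed)
    z_centers = np.arange(z_range[0] + step / 2, z_range[1], step)
    out = np.empty(len(z_centers))
    unbounded = np.zeros(len(z_centers), dtype=bool)
    for k, z in enumerate(z_centers):
        near = np.abs(pos_all[:, 2] - z) <= RADIUS_CAP + radii_all.max()
        # also keep atoms whose spheres could still intersect the plane region
        if not np.any(near):
            out[k] = RADIUS_CAP
            unbounded[k] = True
            continue
        pos = pos_all[near]
        radii = radii_all[near]
        spread = min(start_spread, center_bound)
        starts = [np.zeros(2)]
        starts += list(rng.uniform(-spread, spread, size=(n_starts - 1, 2)))

        def objective(c):
            val = _clearance(c, z, pos, radii)
            off = np.hypot(c[0], c[1])
            if off > center_bound:
                val -= 10.0 * (off - center_bound)
            return -val

        best = -np.inf
        for s0 in starts:
            res = minimize(
                objective,
                s0,
                method="Nelder-Mead",
                options={"maxiter": max_iter, "xatol": 1e-4, "fatol": 1e-6},
            )
            best = max(best, -res.fun)
        if best >= RADIUS_CAP:
            out[k] = RADIUS_CAP
            unbounded[k] = True
        else:
            out[k] = max(best, 0.0)
    return RadiusProfile(
        z_centers=z_centers,
        radius=out,
        radius_sd=np.zeros_like(out),
        method="sphere_insertion",
        structure_id=structure.title,
        unbounded=unbounded,
    )


def min_radius(
    profile: RadiusProfile, window: tuple[float, float] | None = None
) -> dict:
    """Minimum radius and its axial position; ties toward smaller |z|."""
    z = profile.z_centers
    mask = np.ones(len(z), dtype=bool)
    if window is not None:
        mask = (z >= window[0]) & (z <= window[1])
    if not np.any(mask):
        raise ValueError("window selects no profile bins")
    r = profile.radius[mask]
    zz = z[mask]
    rmin = r.min()
    candidates = zz[np.isclose(r, rmin)]
    z_at = candidates[np.argmin(np.abs(candidates))]
    return {"r_min": float(rmin), "z_at": float(z_at)}


def compare_structures(profiles: list[RadiusProfile]) -> pd.DataFrame:
    """Align radius profiles on a common z grid (nearest bin, no
    interpolation) and tabulate per-structure radii plus r_min."""
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to compare")
    lo = max(p.z_centers.min() for p in profiles)
    hi = min(p.z_centers.max() for p in profiles)
    if lo > hi:
        raise ValueError("profiles have disjoint z ranges")
    base = profiles[0]
    sel = (base.z_centers >= lo) & (base.z_centers <= hi)
    z = base.z_centers[sel]
    data = {"z_A": z}
    for i, p in enumerate(profiles):
        name = p.structure_id or f"structure_{i}"
        idx = np.abs(p.z_centers[None, :] - z[:, None]).argmin(axis=1)
        data[name] = p.radius[idx]
    df = pd.DataFrame(data)
    df.attrs["r_min"] = {
        (p.structure_id or f"structure_{i}"): min_radius(p)["r_min"]
        for i, p in enumerate(profiles)
    }
    return df
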