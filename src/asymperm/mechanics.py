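"""Leaflet tensions from stress-tensor profiles.

The chain: tabulated stress profiles σxx(z), σyy(z), σzz(z) (bar) →
lateral and normal pressures P_L = -(σxx + σyy)/2, P_N = -σzz → the
membrane midplane z0 from the lipid-tail density → per-leaflet tensions

    γ+ = ∫_0^∞ (P_N - P_L) dz,    γ- = ∫_-∞^0 (P_N - P_L) dz,

with z = 0 at the midplane.  Unequal γ+ and γ- (differential stress) means
the leaflets are individually stretched/compressed even when the whole
bilayer is tension-free; tensions here are in mN/m (1 bar nm = 0.1 mN/m).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from asymperm.constants import BAR_NM_TO_MN_PER_M


@dataclass
class StressProfile:
    """Diagonal stress-tensor components along the membrane normal (bar)."""

    z: np.ndarray
    sigma_xx: np.ndarray
    sigma_yy: np.ndarray
    sigma_zz: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        for name in ("sigma_xx", "sigma_yy", "sigma_zz"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.z.shape:
                raise ValueError(f"{name} must share the z grid")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, arr)


@dataclass
class PressureProfile:
    """Lateral and normal pressure (bar) on the stress grid."""

    z: np.ndarray
    P_L: np.ndarray
    P_N: np.ndarray


@dataclass
class DensityProfile:
    """Lipid-tail density along the membrane normal (arbitrary units)."""

    z: np.ndarray
    rho_tail: np.ndarray

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.rho_tail = np.asarray(self.rho_tail, dtype=float)
        if self.rho_tail.shape != self.z.shape:
            raise ValueError("rho_tail must share the z grid")
        if np.any(self.rho_tail < 0):
            raise ValueError("densities must be non-negative")


@dataclass
class LeafletTensions:
    """Per-leaflet tensions (mN/m) and the midplane used to split them."""

    gamma_plus: float
    gamma_minus: float
    midplane_z: float

    @property
    def total(self) -> float:
        return self.gamma_plus + self.gamma_minus

    @property
    def differential(self) -> float:
        return self.gamma_plus - self.gamma_minus


def pressures_from_stress(s: StressProfile) -> PressureProfile:
    """P_L = -(σxx + σyy)/2 and P_N = -σzz, applied pointwise."""
    return PressureProfile(z=s.z.copy(),
                           P_L=-(s.sigma_xx + s.sigma_yy) / 2.0,
                           P_N=-s.sigma_zz.copy())


def midplane_from_density(d: DensityProfile, *,
                          convention: str = "weighted-mean") -> float:
    """Membrane midplane from the lipid-tail density.

    The default convention is the density-weighted mean z of the tail lobe.
    ``convention='peak-midpoint'`` instead returns the midpoint between the
    two outermost density peaks (useful when the per-leaflet tail lobes are
    resolved).  Both are documented conventions, not a unique definition.
    """
    if not np.any(d.rho_tail > 0):
        raise ValueError("all-zero tail density")
    if convention == "weighted-mean":
        return float(np.sum(d.z * d.rho_tail) / np.sum(d.rho_tail))
    if convention == "peak-midpoint":
        rho = d.rho_tail
        peaks = np.flatnonzero(
            (rho[1:-1] > rho[:-2]) & (rho[1:-1] >= rho[2:])) + 1
        if peaks.size < 2:
            # single unresolved lobe: fall back to the weighted mean
            return midplane_from_density(d)
        return float(0.5 * (d.z[peaks[0]] + d.z[peaks[-1]]))
    raise ValueError(f"unknown midplane convention {convention!r}")


def leaflet_tensions(p: PressureProfile, z0: float) -> LeafletTensions:
    """Integrate (P_N - P_L) above and below the midplane z0.

    Trapezoidal quadrature on the tabulated grid after shifting z0 to the
    origin; the midplane point itself is included in both half-integrals
    (its integrand contribution splits exactly).  Output in mN/m via
    1 bar nm = 0.1 mN/m.
    """
    z = p.z
    if not (z[0] <= z0 <= z[-1]):
        raise ValueError(f"midplane z0={z0} outside the grid "
                         f"[{z[0]}, {z[-1]}]")
    diff = p.P_N - p.P_L
    # insert an interpolated point exactly at z0 so the split is exact
    if z0 not in z:
        d0 = np.interp(z0, z, diff)
        idx = np.searchsorted(z, z0)
        z = np.insert(z, idx, z0)
        diff = np.insert(diff, idx, d0)
    upper = z >= z0
    lower = z <= z0
    gamma_plus = BAR_NM_TO_MN_PER_M * np.trapezoid(diff[upper], z[upper])
    gamma_minus = BAR_NM_TO_MN_PER_M * np.trapezoid(diff[lower], z[lower])
    return LeafletTensions(gamma_plus=float(gamma_plus),
                           gamma_minus=float(gamma_minus), midplane_z=float(z0))
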