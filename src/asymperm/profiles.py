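"""The central free-energy profile container."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class FreeEnergyProfile:
    """Free energy G as a function of a membrane-normal coordinate.

    Parameters
    ----------
    z : ndarray
        Strictly increasing grid in nm.
    G : ndarray
        Free energy in kJ/mol on ``z``.  NaN marks unsampled bins.
    err : ndarray, optional
        Pointwise standard error band in kJ/mol.
    reference : str
        Human-readable description of where G = 0 was anchored.

    Only free-energy *differences* are physical; every consumer in this
    package is gauge-invariant or re-references explicitly.
    """

    z: np.ndarray
    G: np.ndarray
    err: np.ndarray | None = None
    reference: str = ""

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.z.ndim != 1 or self.z.shape != self.G.shape:
            raise ValueError("z and G must be 1-D arrays of equal length")
        if self.z.size < 2:
            raise ValueError("profile needs at least two grid points")
        if not np.all(np.diff(self.z) > 0):
            raise ValueError("z grid must be strictly increasing")
        if self.err is not None:
            self.err = np.asarray(self.err, dtype=float)
            if self.err.shape != self.z.shape:
                raise ValueError("err must match the grid shape")

    @property
    def sampled(self) -> np.ndarray:
        """Boolean mask of grid points with finite G."""
        return np.isfinite(self.G)

    def shifted(self, offset: float) -> "FreeEnergyProfile":
        """Return a copy with ``offset`` added to G (err unchanged)."""
        return replace(self, G=self.G + offset)

    def restricted(self, lo: float, hi: float) -> "FreeEnergyProfile":
        """Return the sub-profile with lo <= z <= hi."""
        m = (self.z >= lo) & (self.z <= hi)
        if m.sum() < 2:
            raise ValueError(f"fewer than two grid points in [{lo}, {hi}]")
        err = self.err[m] if self.err is not None else None
        return FreeEnergyProfile(self.z[m], self.G[m], err, self.reference)

    def mirrored(self) -> "FreeEnergyProfile":
        """Return the profile under z -> -z (grid re-sorted increasing)."""
        err = self.err[::-1].copy() if self.err is not None else None
        return FreeEnergyProfile(-self.z[::-1], self.G[::-1].copy(), err,
                                 self.reference)

    def interp(self, z_new: np.ndarray, kind: str = "pchip") -> np.ndarray:
        """Interpolate G onto ``z_new``.

        Monotone cubic (PCHIP) by default to avoid overshoot at sharp
        barriers; ``kind='linear'`` is used for error bands.  Points outside
        the sampled support map to NaN.
        """
        from scipy.interpolate import PchipInterpolator

        m = self.sampled
        zs, Gs = self.z[m], self.G[m]
        if zs.size < 2:
            raise ValueError("not enough sampled points to interpolate")
        z_new = np.asarray(z_new, dtype=float)
        if kind == "pchip":
            out = PchipInterpolator(zs, Gs, extrapolate=False)(z_new)
        elif kind == "linear":
            out = np.interp(z_new, zs, Gs, left=np.nan, right=np.nan)
        else:
            raise ValueError(f"unknown interpolation kind {kind!r}")
        return out
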