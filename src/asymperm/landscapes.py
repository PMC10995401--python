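"""Synthetic translocation landscapes and biased-sampling generation.

Everything downstream of molecular dynamics in a peptide-permeation study —
WHAM, profile joining, barrier extraction, permeability models — can be
exercised on analytic potentials of mean force with known ground truth.
This module provides:

* parametric translocation PMFs with a solvent plateau, adsorption minima,
  headgroup barriers and a central barrier (:func:`build_pure_landscape`),
* sigmoidal blending of two pure-membrane PMFs into an asymmetric-membrane
  PMF with a tunable intermediate region (:func:`blend_landscapes`),
* tiered umbrella-window schemes (dense 0.05 nm spacing with stiff springs
  near the membrane center, 0.1 nm elsewhere; :func:`make_window_scheme`),
* biased single-particle samplers whose stationary distribution is the
  Boltzmann density of the biased potential (:func:`sample_window`),
* synthetic stress/density profiles with closed-form leaflet tensions
  (:func:`make_stress_profile`, :func:`make_tail_density`),
* membrane and peptide composition bookkeeping
  (:func:`membrane_asymmetry`, :func:`peptide_net_charge`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from asymperm.constants import BAR_NM_TO_MN_PER_M, KT_310K


class InvalidParameterError(ValueError):
    """A landscape/sampler parameter is outside its valid domain."""


class SamplerStabilityError(RuntimeError):
    """The integrator step size is too large for the stiffest force present."""


# ---------------------------------------------------------------------------
# Landscapes
# ---------------------------------------------------------------------------

def _trunc_gauss(z, center, sigma, cutoff):
    """Truncated Gaussian bump: exp(-d^2/2s^2) - exp(-c^2/2s^2), clipped at 0.

    Identically zero for |z - center| >= cutoff, continuous everywhere.
    """
    z = np.asarray(z, dtype=float)
    d2 = (z - center) ** 2
    val = np.exp(-d2 / (2.0 * sigma**2)) - math.exp(-cutoff**2 / (2.0 * sigma**2))
    return np.maximum(val, 0.0)


def _trunc_gauss_grad(z, center, sigma, cutoff):
    z = np.asarray(z, dtype=float)
    d = z - center
    inside = np.abs(d) < cutoff
    g = -d / sigma**2 * np.exp(-(d**2) / (2.0 * sigma**2))
    return np.where(inside, g, 0.0)


@dataclass
class PMFLandscape:
    """Analytic ground-truth translocation free-energy landscape.

    ``evaluate`` maps z (nm) to G (kJ/mol) on ``support``; outside the
    solvent boundary G equals the solvent plateau exactly.  ``grad`` is the
    closed-form dG/dz used by the Langevin sampler.
    """

    label: str
    support: tuple[float, float]
    params: dict
    _eval: callable = field(repr=False)
    _grad: callable = field(repr=False)

    def evaluate(self, z):
        z = np.asarray(z, dtype=float)
        return self._eval(z)

    def grad(self, z):
        z = np.asarray(z, dtype=float)
        return self._grad(z)

    def __call__(self, z):
        return self.evaluate(z)


@dataclass(frozen=True)
class BlendSpec:
    """Sigmoidal switch between the lower- and upper-leaflet landscapes.

    The blend weight ``w(z) = 1 / (1 + exp((z - switch_center)/switch_width))``
    is ~1 deep on the lower-leaflet side and ~0 on the upper-leaflet side;
    ``switch_width`` (nm) controls the width of the intermediate region.
    """

    switch_center: float = 0.0
    switch_width: float = 0.25

    def __post_init__(self):
        if self.switch_width <= 0:
            raise InvalidParameterError("switch_width must be > 0")

    def weight(self, z):
        z = np.asarray(z, dtype=float)
        # clip the argument to keep exp() finite for tiny widths
        arg = np.clip((z - self.switch_center) / self.switch_width, -700, 700)
        return 1.0 / (1.0 + np.exp(arg))

    def weight_grad(self, z):
        w = self.weight(z)
        return -w * (1.0 - w) / self.switch_width


def build_pure_landscape(
    *,
    label: str = "pure",
    solvent_plateau_G: float = 0.0,
    adsorption_well_depth: float = 40.0,
    adsorption_well_pos: float = 2.0,
    headgroup_barrier: float = 0.0,
    headgroup_pos: float | None = None,
    center_G: float = 150.0,
    widths: float | dict = 0.45,
    support: tuple[float, float] = (-4.5, 4.5),
    solvent_boundary: float | None = None,
) -> PMFLandscape:
    """Build a symmetric pure-membrane translocation PMF.

    The landscape is a solvent plateau plus truncated-Gaussian features: two
    adsorption wells at ``±adsorption_well_pos`` of depth
    ``adsorption_well_depth`` below the plateau, optional headgroup barriers,
    and a central barrier reaching exactly ``center_G`` at z = 0.  Feature
    amplitudes are solved from a linear system so the landscape passes
    through its control points exactly despite overlapping bumps.

    Parameters are in kJ/mol (energies) and nm (positions/widths).
    ``widths`` is either a single width applied to every feature or a dict
    with keys ``center``, ``well``, ``headgroup``.
    """

    if isinstance(widths, dict):
        w_center = widths.get("center", 0.45)
        w_well = widths.get("well", 0.45)
        w_head = widths.get("headgroup", 0.25)
    else:
        w_center = w_well = float(widths)
        w_head = float(widths)
    for w in (w_center, w_well, w_head):
        if w <= 0:
            raise InvalidParameterError("feature widths must be > 0")
    if adsorption_well_pos <= 0:
        raise InvalidParameterError("adsorption_well_pos must be > 0")
    lo, hi = support
    if hi <= lo:
        raise InvalidParameterError("empty support")

    if headgroup_pos is None:
        headgroup_pos = 0.5 * adsorption_well_pos
    if solvent_boundary is None:
        solvent_boundary = min(hi, -lo)

    # basis: central bump, symmetric well pair, symmetric headgroup pair;
    # every bump vanishes identically beyond the solvent boundary
    def cutoff(center):
        return max(solvent_boundary - abs(center), 3.0 * w_center)

    basis = [
        (0.0, w_center, cutoff(0.0)),
        (adsorption_well_pos, w_well, cutoff(adsorption_well_pos)),
        (-adsorption_well_pos, w_well, cutoff(adsorption_well_pos)),
        (headgroup_pos, w_head, cutoff(headgroup_pos)),
        (-headgroup_pos, w_head, cutoff(headgroup_pos)),
    ]
    # amplitudes tied pairwise: a = (a_center, a_well, a_head)
    control = np.array([0.0, adsorption_well_pos, headgroup_pos])
    target = np.array(
        [
            center_G - solvent_plateau_G,
            -adsorption_well_depth,
            headgroup_barrier,
        ]
    )

    def basis_matrix(zs):
        cols = []
        for group in ((0,), (1, 2), (3, 4)):
            col = sum(
                _trunc_gauss(zs, *basis[i]) for i in group
            )
            cols.append(col)
        return np.column_stack(cols)

    A = basis_matrix(control)
    amps = np.linalg.solve(A, target)

    amp_per_bump = np.array([amps[0], amps[1], amps[1], amps[2], amps[2]])

    def _eval(z):
        out = np.full_like(np.asarray(z, dtype=float), float(solvent_plateau_G))
        for a, (c, s, co) in zip(amp_per_bump, basis):
            if a != 0.0:
                out = out + a * _trunc_gauss(z, c, s, co)
        return out

    def _grad(z):
        out = np.zeros_like(np.asarray(z, dtype=float))
        for a, (c, s, co) in zip(amp_per_bump, basis):
            if a != 0.0:
                out = out + a * _trunc_gauss_grad(z, c, s, co)
        return out

    params = dict(
        solvent_plateau_G=solvent_plateau_G,
        adsorption_well_depth=adsorption_well_depth,
        adsorption_well_pos=adsorption_well_pos,
        headgroup_barrier=headgroup_barrier,
        headgroup_pos=headgroup_pos,
        center_G=center_G,
        widths={"center": w_center, "well": w_well, "headgroup": w_head},
        solvent_boundary=solvent_boundary,
    )
    return PMFLandscape(label=label, support=(lo, hi), params=params,
                        _eval=_eval, _grad=_grad)


def blend_landscapes(upper: PMFLandscape, lower: PMFLandscape,
                     blend: BlendSpec, label: str | None = None) -> PMFLandscape:
    """Blend two pure-membrane landscapes into an asymmetric-membrane one.

    ``G_asym(z) = w(z) G_lower(z) + (1 - w(z)) G_upper(z)`` with the
    sigmoidal weight from ``blend``.  Far above the switch the profile
    coincides with the upper-leaflet landscape, far below with the lower
    one, and it transitions gradually in between — the intermediate region.
    """
    if upper.support != lower.support:
        raise ValueError(
            f"mismatched supports {upper.support} vs {lower.support}")

    def _eval(z):
        w = blend.weight(z)
        return w * lower.evaluate(z) + (1.0 - w) * upper.evaluate(z)

    def _grad(z):
        w = blend.weight(z)
        dw = blend.weight_grad(z)
        return (w * lower.grad(z) + (1.0 - w) * upper.grad(z)
                + dw * (lower.evaluate(z) - upper.evaluate(z)))

    params = dict(upper=upper.params, lower=lower.params,
                  switch_center=blend.switch_center,
                  switch_width=blend.switch_width)
    return PMFLandscape(
        label=label or f"{upper.label}/{lower.label}",
        support=upper.support, params=params, _eval=_eval, _grad=_grad)


def landscape_profile(landscape: PMFLandscape, dz: float = 0.01):
    """Tabulate a landscape as a :class:`~asymperm.profiles.FreeEnergyProfile`."""
    from asymperm.profiles import FreeEnergyProfile

    lo, hi = landscape.support
    z = np.arange(lo, hi + 0.5 * dz, dz)
    return FreeEnergyProfile(z, landscape.evaluate(z),
                             reference=f"analytic ground truth '{landscape.label}'")


# ---------------------------------------------------------------------------
# Umbrella windows and sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UmbrellaWindow:
    """One harmonic umbrella window: bias U(z) = (k/2) (z - z0)^2.

    k = 0 is permitted and means an unbiased window (useful as a WHAM
    sanity check: a single unbiased window must reproduce the histogram).
    """

    z0: float  # nm
    k: float   # kJ/mol/nm^2
    label: str = ""

    def __post_init__(self):
        if self.k < 0:
            raise InvalidParameterError("force constant k must be >= 0")

    def bias(self, z):
        return 0.5 * self.k * (np.asarray(z, dtype=float) - self.z0) ** 2


@dataclass
class WindowTimeseries:
    """Biased samples of the collective variable from one umbrella window."""

    window: UmbrellaWindow
    samples: np.ndarray
    seed: int
    n_equil: int = 0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not 0 <= self.n_equil < len(self.samples):
            raise ValueError("need len(samples) > n_equil >= 0")

    @property
    def production(self) -> np.ndarray:
        """Samples after the equilibration discard."""
        return self.samples[self.n_equil:]


@dataclass
class SamplerParams:
    """Controls for the single-particle biased sampler.

    kT in kJ/mol (default 310 K), D in nm^2 per step-unit, dt in step-units.
    ``scheme`` is 'metropolis' (random-walk Metropolis, unconditionally
    stable) or 'overdamped-langevin' (Euler–Maruyama, subject to a stability
    limit checked at run time).  Only the stationary distribution matters to
    downstream analysis; both schemes target exp(-U/kT).
    """

    kT: float = KT_310K
    D: float = 0.01
    dt: float = 1.0
    n_steps: int = 5000
    n_equil: int | None = None
    scheme: str = "metropolis"

    def __post_init__(self):
        if self.kT <= 0 or self.D <= 0 or self.dt <= 0:
            raise InvalidParameterError("kT, D, dt must all be > 0")
        if self.scheme not in ("metropolis", "overdamped-langevin"):
            raise InvalidParameterError(f"unknown scheme {self.scheme!r}")
        if self.n_equil is None:
            self.n_equil = self.n_steps // 10


def make_window_scheme(
    support: tuple[float, float],
    surface_band: tuple[float, float],
    center_band: tuple[float, float],
    spacing_surface: float,
    spacing_center: float,
    k_tiers: tuple[float, float, float],
) -> list[UmbrellaWindow]:
    """Lay out a tiered umbrella-window scheme along the collective variable.

    ``center_band`` is a z-interval around the membrane center sampled with
    ``spacing_center`` and the center-tier spring; ``surface_band`` is a
    band in |z| (applied mirror-symmetrically) sampled with
    ``spacing_surface`` and the surface-tier spring; the remainder is the
    intermediate tier, also at ``spacing_surface``.  ``k_tiers`` is
    (surface, center, intermediate) in kJ/mol/nm^2.

    Within each contiguous band segment the window spacing is exact; one
    transitional (possibly shorter) gap may occur at each band boundary.
    """
    if spacing_surface <= 0 or spacing_center <= 0:
        raise InvalidParameterError("spacings must be > 0")
    lo, hi = support
    if hi <= lo:
        raise InvalidParameterError("empty support")
    c_lo, c_hi = center_band
    s_lo, s_hi = surface_band
    if s_lo < 0 or s_hi < s_lo:
        raise InvalidParameterError("surface_band is a band in |z|, need 0 <= lo <= hi")
    # a center band reaching into the |z| surface band would make the tier
    # assignment ambiguous
    if c_hi > c_lo and s_hi > s_lo and max(abs(c_lo), abs(c_hi)) > s_lo + 1e-12:
        raise InvalidParameterError(
            "center_band overlaps surface_band; bands must be disjoint")

    k_surface, k_center, k_intermediate = k_tiers

    def band_of(z):
        if c_lo <= z <= c_hi:
            return "center"
        if s_lo <= abs(z) <= s_hi:
            return "surface"
        return "intermediate"

    spacing = {"center": spacing_center, "surface": spacing_surface,
               "intermediate": spacing_surface}
    ktier = {"center": k_center, "surface": k_surface,
             "intermediate": k_intermediate}

    # split the support into maximal same-band segments
    cuts = sorted({lo, hi, c_lo, c_hi, -s_lo, s_lo, -s_hi, s_hi})
    cuts = [c for c in cuts if lo <= c <= hi]
    if cuts[0] > lo:
        cuts.insert(0, lo)
    if cuts[-1] < hi:
        cuts.append(hi)

    eps = 1e-9
    windows: list[UmbrellaWindow] = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        if b - a < eps:
            continue
        band = band_of(0.5 * (a + b))
        s = spacing[band]
        n = int(math.floor((b - a) / s + eps))
        pts = [a + i * s for i in range(n + 1)]
        if pts[-1] < b - eps:
            pts.append(b)
        for z0 in pts:
            w = UmbrellaWindow(z0=round(z0, 12), k=ktier[band], label=band)
            if windows and abs(z0 - windows[-1].z0) < eps:
                # shared band boundary: the center tier takes precedence
                if band == "center":
                    windows[-1] = w
                continue
            windows.append(w)
    return windows


def _check_langevin_stability(landscape, window, sp):
    # effective stiffness: window spring + numerical curvature bound of G
    lo, hi = landscape.support
    zg = np.linspace(lo, hi, 512)
    g = landscape.grad(zg)
    curv = np.max(np.abs(np.gradient(g, zg))) if zg.size > 2 else 0.0
    k_tot = window.k + curv
    crit = sp.D * sp.dt * k_tot / sp.kT
    if crit > 1.0:
        dt_sugg = 0.5 * sp.kT / (sp.D * k_tot)
        raise SamplerStabilityError(
            f"Langevin step too large (D*dt*k/kT = {crit:.2f} > 1); "
            f"use dt <= {dt_sugg:.3g} at the current D")


def sample_window(landscape: PMFLandscape, window: UmbrellaWindow,
                  sp: SamplerParams, seed: int) -> WindowTimeseries:
    """Draw biased samples of z from one umbrella window.

    The target density is ``exp(-U(z)/kT)`` with
    ``U(z) = G(z) + (k/2)(z - z0)^2``.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    lo, hi = landscape.support
    z = min(max(window.z0, lo), hi)
    beta = 1.0 / sp.kT
    n = sp.n_steps
    out = np.empty(n)

    if sp.scheme == "overdamped-langevin":
        _check_langevin_stability(landscape, window, sp)
        noise = rng.standard_normal(n) * math.sqrt(2.0 * sp.D * sp.dt)
        coef = sp.D * sp.dt * beta
        for i in range(n):
            force = -(landscape.grad(z) + window.k * (z - window.z0))
            z = z + coef * float(force) + noise[i]
            z = min(max(z, lo), hi)  # reflecting support boundaries
            out[i] = z
    else:  # random-walk Metropolis
        step = math.sqrt(2.0 * sp.D * sp.dt)
        prop = rng.standard_normal(n) * step
        accept_u = np.log(rng.random(n))
        u_cur = float(landscape.evaluate(z)) + float(window.bias(z))
        for i in range(n):
            z_new = z + prop[i]
            if z_new < lo or z_new > hi:
                out[i] = z
                continue
            u_new = float(landscape.evaluate(z_new)) + float(window.bias(z_new))
            if accept_u[i] <= -beta * (u_new - u_cur):
                z, u_cur = z_new, u_new
            out[i] = z

    return WindowTimeseries(window=window, samples=out, seed=seed,
                            n_equil=sp.n_equil)


def metropolis_params_for_window(window: UmbrellaWindow, kT: float = KT_310K,
                                 n_steps: int = 5000,
                                 n_equil: int | None = None) -> SamplerParams:
    """Sampler parameters with the Metropolis proposal matched to the window.

    Proposal std = sqrt(kT/k): roughly the biased-well width, which keeps
    the acceptance rate near 50% and the autocorrelation time to a few steps
    for any force-constant tier.
    """
    std = math.sqrt(kT / window.k)
    return SamplerParams(kT=kT, D=0.5 * std**2, dt=1.0, n_steps=n_steps,
                         n_equil=n_equil, scheme="metropolis")


def sample_scheme(landscape: PMFLandscape, windows: list[UmbrellaWindow],
                  seed: int, kT: float = KT_310K, n_steps: int = 5000,
                  n_equil: int | None = None) -> list[WindowTimeseries]:
    """Metropolis-sample every window of a scheme in one batched chain.

    The windows are independent chains (they never interact), so they are
    advanced together with vectorized proposals; per-window proposal widths
    are matched to each window's spring as in
    :func:`metropolis_params_for_window`.  Deterministic given ``seed``.
    """
    if n_equil is None:
        n_equil = n_steps // 10
    rng = np.random.default_rng(seed)
    lo, hi = landscape.support
    W = len(windows)
    z0 = np.array([w.z0 for w in windows])
    k = np.array([w.k for w in windows])
    # 2.4x the stationary width: the optimal-scaling proposal for 1-D
    # random-walk Metropolis, which roughly halves the autocorrelation time
    # compared to a width-matched proposal
    std = 2.4 * np.sqrt(kT / np.maximum(k, 1e-12))
    beta = 1.0 / kT

    z = np.clip(z0, lo, hi)
    u = landscape.evaluate(z) + 0.5 * k * (z - z0) ** 2
    out = np.empty((n_steps, W))
    for i in range(n_steps):
        z_new = z + std * rng.standard_normal(W)
        inside = (z_new >= lo) & (z_new <= hi)
        zt = np.where(inside, z_new, z)
        u_new = landscape.evaluate(zt) + 0.5 * k * (zt - z0) ** 2
        accept = inside & (np.log(rng.random(W)) <= -beta * (u_new - u))
        z = np.where(accept, zt, z)
        u = np.where(accept, u_new, u)
        out[i] = z
    return [WindowTimeseries(window=w, samples=out[:, j], seed=seed,
                             n_equil=n_equil)
            for j, w in enumerate(windows)]


# ---------------------------------------------------------------------------
# Synthetic mechanics inputs
# ---------------------------------------------------------------------------

def make_stress_profile(
    *,
    lobes: list[tuple[float, float, float]],
    z_range: tuple[float, float] = (-4.0, 4.0),
    dz: float = 0.01,
    baseline_bar: float = 1.0,
    midplane: float = 0.0,
):
    """Build a synthetic stress-tensor profile with closed-form leaflet tensions.

    ``lobes`` is a list of ``(center nm, sigma nm, amplitude bar)`` Gaussian
    contributions to the *differential* pressure P_N - P_L; the normal
    pressure is held at ``baseline_bar``.  The returned
    :class:`~asymperm.mechanics.StressProfile` carries metadata with the
    closed-form ``gamma_plus``/``gamma_minus`` (mN/m) implied by integrating
    each half-space about ``midplane`` — the oracle for quadrature tests.
    """
    from scipy.special import erfc

    from asymperm.mechanics import StressProfile

    lo, hi = z_range
    z = np.arange(lo, hi + 0.5 * dz, dz)
    diff = np.zeros_like(z)  # P_N - P_L
    gamma_plus = 0.0
    gamma_minus = 0.0
    for c, s, a in lobes:
        diff += a * np.exp(-((z - c) ** 2) / (2.0 * s**2))
        full = a * s * math.sqrt(2.0 * math.pi)
        upper = 0.5 * full * erfc((midplane - c) / (s * math.sqrt(2.0)))
        gamma_plus += BAR_NM_TO_MN_PER_M * upper
        gamma_minus += BAR_NM_TO_MN_PER_M * (full - upper)

    P_N = np.full_like(z, baseline_bar)
    P_L = P_N - diff
    sigma_zz = -P_N
    sigma_xx = sigma_yy = -P_L
    return StressProfile(
        z=z, sigma_xx=sigma_xx.copy(), sigma_yy=sigma_yy.copy(),
        sigma_zz=sigma_zz,
        metadata={"gamma_plus": float(gamma_plus),
                  "gamma_minus": float(gamma_minus),
                  "midplane": float(midplane)})


def lobes_for_tensions(gamma_plus: float, gamma_minus: float,
                       center_offset: float = 1.0, sigma: float = 0.3,
                       midplane: float = 0.0):
    """Two well-separated Gaussian lobes realizing the requested leaflet tensions.

    Tensions in mN/m; the lobe amplitudes (bar) follow from the closed-form
    Gaussian integral.  Lobes are placed ``center_offset`` nm above/below the
    midplane; with ``center_offset >> sigma`` the cross-talk between
    half-space integrals is negligible (< 1e-3 relative at the defaults).
    """
    full = sigma * math.sqrt(2.0 * math.pi)  # integral of unit-amp Gaussian
    a_plus = gamma_plus / (BAR_NM_TO_MN_PER_M * full)
    a_minus = gamma_minus / (BAR_NM_TO_MN_PER_M * full)
    return [(midplane + center_offset, sigma, a_plus),
            (midplane - center_offset, sigma, a_minus)]


def make_tail_density(center: float = 0.0, sigma: float = 1.0,
                      z_range: tuple[float, float] = (-4.0, 4.0),
                      dz: float = 0.01, amplitude: float = 1.0):
    """Synthetic lipid-tail density: one Gaussian lobe centered on the membrane core."""
    from asymperm.mechanics import DensityProfile

    lo, hi = z_range
    z = np.arange(lo, hi + 0.5 * dz, dz)
    rho = amplitude * np.exp(-((z - center) ** 2) / (2.0 * sigma**2))
    return DensityProfile(z=z, rho_tail=rho)


# ---------------------------------------------------------------------------
# Composition bookkeeping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MembraneSpec:
    """Per-leaflet lipid composition, e.g. upper=[('POPE', 144)]."""

    upper: tuple[tuple[str, int], ...]
    lower: tuple[tuple[str, int], ...]

    def __post_init__(self):
        object.__setattr__(self, "upper", tuple(map(tuple, self.upper)))
        object.__setattr__(self, "lower", tuple(map(tuple, self.lower)))
        for leaflet in (self.upper, self.lower):
            if not leaflet:
                raise ValueError("each leaflet needs at least one lipid entry")
            for name, count in leaflet:
                if not isinstance(count, int) or count <= 0:
                    raise ValueError(
                        f"lipid count for {name!r} must be a positive integer")

    @property
    def n_upper(self) -> int:
        return sum(c for _, c in self.upper)

    @property
    def n_lower(self) -> int:
        return sum(c for _, c in self.lower)


def membrane_asymmetry(spec: MembraneSpec) -> dict:
    """Total lipid count and leaflet number asymmetry of a membrane.

    Asymmetry is 100 |N_up - N_low| / (N_up + N_low); both the unrounded
    value and its nearest-integer rounding (the figure usually quoted) are
    returned.  A 144/106 POPC membrane gives 15%.
    """
    n_up, n_low = spec.n_upper, spec.n_lower
    total = n_up + n_low
    asym = 100.0 * abs(n_up - n_low) / total
    return {
        "total_lipids": total,
        "asymmetry_percent": asym,
        "asymmetry_percent_rounded": int(round(asym)),
    }


_AA = set("ACDEFGHIKLMNPQRSTVWY")
_POSITIVE = set("KR")
_NEGATIVE = set("DE")


@dataclass(frozen=True)
class PeptideSpec:
    """One-letter peptide sequence with terminus chemistry."""

    sequence: str
    n_term: str = "charged"   # charged | neutral
    c_term: str = "amidated"  # amidated | free

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty sequence")
        if self.n_term not in ("charged", "neutral"):
            raise ValueError(f"n_term must be charged|neutral, got {self.n_term!r}")
        if self.c_term not in ("amidated", "free"):
            raise ValueError(f"c_term must be amidated|free, got {self.c_term!r}")


def peptide_net_charge(spec: PeptideSpec) -> int:
    """Net charge in elementary charges at neutral pH.

    +1 per Lys/Arg, -1 per Asp/Glu, +1 for a charged N-terminus, -1 for a
    free C-terminus (0 if amidated).  Histidine counts as neutral.  The
    LK peptide (LKKLLKLLKKLLKLLKKLLKL-NH2, charged N-terminus) scores +10.
    """
    charge = 0
    for ch in spec.sequence.upper():
        if ch not in _AA:
            raise ValueError(f"unknown residue letter {ch!r}")
        if ch in _POSITIVE:
            charge += 1
        elif ch in _NEGATIVE:
            charge -= 1
    if spec.n_term == "charged":
        charge += 1
    if spec.c_term == "free":
        charge -= 1
    return charge
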