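"""Weighted histogram analysis method (WHAM) for umbrella-sampling data.

Umbrella windows bias the collective variable with harmonic springs
``U_i(z) = (k_i/2)(z - z0_i)^2``; WHAM combines the biased histograms into
one unbiased density by iterating the coupled self-consistency equations

    p(z_b) = sum_i H_ib / sum_i N_i exp[(f_i - U_i(z_b)) / kT]
    exp(-f_i / kT) = sum_b p(z_b) exp[-U_i(z_b) / kT]

until the per-window free-energy constants f_i stop changing.  The profile
is G(z) = -kT ln p(z), anchored to a declared reference region (the solvent
plateau).  Overlap diagnostics and a moving-block bootstrap error band are
included; adjacent-window histogram overlap is the practical check that the
window spacing/force-constant tiers were adequate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from asymperm.constants import KT_310K
from asymperm.landscapes import UmbrellaWindow, WindowTimeseries
from asymperm.profiles import FreeEnergyProfile


class WhamConvergenceError(RuntimeError):
    """Self-consistent iteration did not reach tolerance within max_iter."""

    def __init__(self, msg, residual=None, iterations=None):
        super().__init__(msg)
        self.residual = residual
        self.iterations = iterations


class DisconnectedWindowsError(RuntimeError):
    """The window-overlap graph splits into disconnected components."""

    def __init__(self, components):
        self.components = components
        super().__init__(
            "window histograms form disconnected overlap components: "
            + "; ".join(str(sorted(c)) for c in components))


@dataclass
class WhamSettings:
    """Solver controls: kT (kJ/mol), convergence tolerance on max |Δf_i|
    (kJ/mol), iteration cap, histogram bin width (nm), bootstrap replicates.

    The 0.02 nm default bin width is at most half the finest window spacing
    in the tiered schemes this package generates.
    """

    kT: float = KT_310K
    tol: float = 1e-6
    max_iter: int = 100_000
    bin_width: float = 0.02
    n_bootstrap: int = 20

    def __post_init__(self):
        if self.tol <= 0 or self.bin_width <= 0:
            raise ValueError("tol and bin_width must be > 0")


@dataclass
class HistogramSet:
    """Per-window counts on a shared bin grid."""

    bin_edges: np.ndarray          # (B+1,)
    counts: np.ndarray             # (W, B) integer
    n_samples: np.ndarray          # (W,)

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        self.n_samples = np.asarray(self.n_samples)
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ValueError("bin_edges must be increasing")
        if self.counts.shape != (len(self.n_samples),
                                 len(self.bin_edges) - 1):
            raise ValueError("counts shape must be (n_windows, n_bins)")
        if np.any(self.counts.sum(axis=1) != self.n_samples):
            raise ValueError("counts row sums must equal n_samples")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def histogram_windows(ts: list[WindowTimeseries],
                      settings: WhamSettings) -> HistogramSet:
    """Histogram the production part of every window on one shared grid.

    The first ``n_equil`` samples of each window are discarded; bins are
    half-open ``[lo, hi)``, aligned to multiples of the bin width, and cover
    the union of the sampled ranges.
    """
    prods = []
    for t in ts:
        p = t.production
        if p.size == 0:
            raise ValueError(
                f"window at z0={t.window.z0} has no samples after discarding "
                f"n_equil={t.n_equil}")
        prods.append(p)
    bw = settings.bin_width
    lo = np.floor(min(p.min() for p in prods) / bw) * bw
    hi = np.ceil((max(p.max() for p in prods) + 0.5 * bw) / bw) * bw
    nbin = int(round((hi - lo) / bw))
    edges = lo + bw * np.arange(nbin + 1)
    counts = np.empty((len(prods), nbin), dtype=np.int64)
    for i, p in enumerate(prods):
        idx = np.floor((p - lo) / bw).astype(np.int64)
        idx = np.clip(idx, 0, nbin - 1)
        counts[i] = np.bincount(idx, minlength=nbin)
    return HistogramSet(bin_edges=edges, counts=counts,
                        n_samples=counts.sum(axis=1))


def overlap_matrix(h: HistogramSet) -> np.ndarray:
    """Pairwise histogram overlap: sum of the min of the normalized rows.

    Symmetric with unit diagonal; 0 means disjoint sampling.  Values below
    ~0.1 between neighbours signal an inadequate window scheme.
    """
    p = h.counts / h.counts.sum(axis=1, keepdims=True)
    W = p.shape[0]
    out = np.empty((W, W))
    for i in range(W):
        out[i] = np.minimum(p[i][None, :], p).sum(axis=1)
    np.fill_diagonal(out, 1.0)
    return out


def _connected_components(h: HistogramSet):
    """Components of the graph where windows sharing a nonzero bin are linked."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    occ = (h.counts > 0)
    adj = (occ @ occ.T) > 0
    n, labels = connected_components(csr_matrix(adj), directed=False)
    return [set(np.flatnonzero(labels == i)) for i in range(n)]


def solve_wham(h: HistogramSet, windows: list[UmbrellaWindow],
               settings: WhamSettings,
               reference_region: tuple[float, float] | None = None,
               ) -> FreeEnergyProfile:
    """Solve the WHAM self-consistency equations on a histogram set.

    Returns G(z) = -kT ln p(z) with NaN at unsampled bins, shifted so the
    mean over ``reference_region`` (a z-interval; default: the whole sampled
    range's outermost 10% on each end, i.e. the solvent plateau) is zero.
    The result carries ``iterations`` and ``residual`` attributes.

    Raises :class:`DisconnectedWindowsError` when the histograms do not
    mutually overlap and :class:`WhamConvergenceError` on hitting max_iter.
    """
    comps = _connected_components(h)
    if len(comps) > 1:
        raise DisconnectedWindowsError(comps)

    kT = settings.kT
    z = h.centers
    W = len(windows)
    if h.counts.shape[0] != W:
        raise ValueError("histogram set / window list length mismatch")

    # bias Boltzmann factors, underflow to 0 is fine
    U = 0.5 * np.array([w.k for w in windows])[:, None] \
        * (z[None, :] - np.array([w.z0 for w in windows])[:, None]) ** 2
    with np.errstate(under="ignore"):
        C = np.exp(-U / kT)                      # (W, B)

    M = h.counts.sum(axis=0).astype(float)       # per-bin totals
    N = h.n_samples.astype(float)
    sampled = M > 0

    a = np.ones(W)                               # a_i = exp(f_i / kT)
    f = np.zeros(W)
    it = 0
    residual = np.inf
    for it in range(1, settings.max_iter + 1):
        denom = (N * a) @ C                      # (B,)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(sampled, M / denom, 0.0)
        zi = C @ p                               # exp(-f_i / kT)
        f_new = -kT * np.log(zi)
        f_new -= f_new[0]                        # gauge: f_0 = 0
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        with np.errstate(under="ignore"):
            a = np.exp(f / kT)
        if residual < settings.tol:
            break
    else:
        raise WhamConvergenceError(
            f"WHAM did not converge in {settings.max_iter} iterations "
            f"(residual {residual:.3g} kJ/mol)", residual=residual,
            iterations=settings.max_iter)

    p /= p.sum()
    with np.errstate(divide="ignore"):
        G = np.where(sampled, -kT * np.log(np.where(sampled, p, 1.0)), np.nan)

    if reference_region is None:
        # anchor on the top of the *window-covered* range: bins beyond the
        # outermost window carry few, heavily re-weighted samples and make
        # an unreliable zero
        z0s = np.array([w.z0 for w in windows])
        span = z0s.max() - z0s.min()
        ref_lo, ref_hi = z0s.max() - 0.1 * max(span, 0.1), z0s.max()
        if not np.any(sampled & (z >= ref_lo) & (z <= ref_hi)):
            # degenerate schemes (e.g. one unbiased window): fall back to
            # the top of the sampled range
            zs = z[sampled]
            ref_lo, ref_hi = zs.max() - 0.1 * (zs.max() - zs.min()), zs.max()
        ref_desc = f"solvent plateau z in [{ref_lo:.3f}, {ref_hi:.3f}] (auto)"
    else:
        ref_lo, ref_hi = reference_region
        ref_desc = f"solvent plateau z in [{ref_lo:.3f}, {ref_hi:.3f}]"
    ref_mask = sampled & (z >= ref_lo) & (z <= ref_hi)
    if not np.any(ref_mask):
        raise ValueError("reference region contains no sampled bins")
    G = G - np.nanmean(G[ref_mask])

    prof = FreeEnergyProfile(z=z, G=G, reference=ref_desc)
    prof.iterations = it
    prof.residual = residual
    return prof


# ---------------------------------------------------------------------------
# Bootstrap errors
# ---------------------------------------------------------------------------

def integrated_autocorr_time(x: np.ndarray, cap: int | None = None) -> float:
    """Integrated autocorrelation time by initial-positive-sequence summation."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or np.var(x) == 0:
        return 1.0
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1))
    acf /= acf[0]
    tau = 1.0
    for t in range(1, min(n // 2, 2000)):
        if acf[t] <= 0:
            break
        tau += 2.0 * acf[t]
    if cap is not None:
        tau = min(tau, cap)
    return max(tau, 1.0)


def _block_resample(x: np.ndarray, block: int, rng) -> np.ndarray:
    """Moving-block bootstrap resample of the same length as x."""
    n = x.size
    block = max(1, min(block, n))
    n_blocks = int(np.ceil(n / block))
    starts = rng.integers(0, n - block + 1, size=n_blocks)
    out = np.concatenate([x[s:s + block] for s in starts])
    return out[:n]


def bootstrap_error(ts: list[WindowTimeseries], windows: list[UmbrellaWindow],
                    settings: WhamSettings, seed: int,
                    reference_region: tuple[float, float] | None = None,
                    ) -> FreeEnergyProfile:
    """WHAM profile with a moving-block-bootstrap error band.

    Each replicate resamples every window's production series in blocks of
    length ~2x the integrated autocorrelation time (capped at n/10), solves
    WHAM, re-anchors to the reference region, and err(z) is the pointwise
    standard deviation over replicates.  Fails if more than 20% of
    replicates fail to converge.
    """
    if settings.n_bootstrap < 2:
        raise ValueError("n_bootstrap must be >= 2")
    rng = np.random.default_rng(seed)

    base_hist = histogram_windows(ts, settings)
    base = solve_wham(base_hist, windows, settings, reference_region)

    blocks = []
    for t in ts:
        p = t.production
        tau = integrated_autocorr_time(p, cap=max(1, p.size // 10))
        blocks.append(max(1, min(int(round(2 * tau)), p.size // 10 or 1)))

    reps, failures = [], 0
    for _ in range(settings.n_bootstrap):
        ts_rep = [
            WindowTimeseries(window=t.window,
                             samples=_block_resample(t.production, b, rng),
                             seed=t.seed, n_equil=0)
            for t, b in zip(ts, blocks)
        ]
        try:
            hist = histogram_windows(ts_rep, settings)
            prof = solve_wham(hist, windows, settings, reference_region)
        except (WhamConvergenceError, DisconnectedWindowsError, ValueError):
            failures += 1
            continue
        reps.append(prof.interp(base.z, kind="linear"))
    if failures > 0.2 * settings.n_bootstrap:
        raise RuntimeError(
            f"{failures}/{settings.n_bootstrap} bootstrap replicates failed")

    stack = np.vstack(reps)
    err = np.nanstd(stack, axis=0, ddof=1)
    err[~base.sampled] = np.nan
    out = FreeEnergyProfile(z=base.z, G=base.G, err=err,
                            reference=base.reference)
    out.iterations = base.iterations
    out.residual = base.residual
    out.n_replicates = len(reps)
    return out
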