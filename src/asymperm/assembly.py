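"""Assembling full translocation profiles from subprocess profiles.

A translocation event across a membrane decomposes into subprocesses —
adsorption onto and insertion from each leaflet, for each peptide terminus
(eight subprocesses for an asymmetric membrane, four independent ones for a
symmetric membrane).  Each subprocess is unbiased separately, so each
profile carries its own arbitrary free-energy constant; joining them into a
full directional path requires aligning the constants over the overlap
regions and anchoring the result to the entry-side solvent plateau.

This module also provides the mimicking/intermediate region decomposition:
the spans of an asymmetric-membrane profile that are indistinguishable
(within a threshold, 5 kJ/mol by default) from the corresponding pure
symmetric membranes, and the intermediate region between them where the
profile transitions gradually from one pure profile to the other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from asymperm.profiles import FreeEnergyProfile


class AlignmentError(RuntimeError):
    """Profiles do not overlap sufficiently to determine a relative offset."""


# ---------------------------------------------------------------------------
# Referencing and alignment
# ---------------------------------------------------------------------------

def zero_reference(p: FreeEnergyProfile,
                   solvent_region: tuple[float, float]) -> FreeEnergyProfile:
    """Shift a profile so its mean over the solvent region is zero.

    The error band is unchanged (the shift is a constant).
    """
    lo, hi = solvent_region
    m = p.sampled & (p.z >= lo) & (p.z <= hi)
    if not np.any(m):
        raise ValueError(
            f"solvent region [{lo}, {hi}] outside the sampled grid")
    shift = -float(np.mean(p.G[m]))
    out = p.shifted(shift)
    out.reference = f"solvent plateau z in [{lo}, {hi}], mean = 0"
    return out


def align_segments(a: FreeEnergyProfile, b: FreeEnergyProfile,
                   overlap: tuple[float, float]) -> tuple[float, float]:
    """Least-squares constant offset making b match a over the overlap.

    Returns ``(offset, residual_rms)`` such that ``b + offset`` best matches
    ``a`` in the mean-squared sense on a common grid over ``overlap``; the
    closed form is the mean of (a - b).  Free-energy constants are pure
    gauge, so a constant is the only admissible alignment transform.
    """
    lo, hi = overlap
    za = a.z[a.sampled & (a.z >= lo) & (a.z <= hi)]
    zb = b.z[b.sampled & (b.z >= lo) & (b.z <= hi)]
    glo = max(lo, za.min() if za.size else np.inf,
              zb.min() if zb.size else np.inf)
    ghi = min(hi, za.max() if za.size else -np.inf,
              zb.max() if zb.size else -np.inf)
    if not np.isfinite(glo) or ghi <= glo:
        raise AlignmentError(f"no common coverage in overlap [{lo}, {hi}]")
    n = max(int(np.ceil((ghi - glo) / _min_spacing(a, b))) + 1, 3)
    zg = np.linspace(glo, ghi, n)
    ga = a.interp(zg)
    gb = b.interp(zg)
    ok = np.isfinite(ga) & np.isfinite(gb)
    if ok.sum() < 3:
        raise AlignmentError(
            f"fewer than 3 common grid points in overlap [{lo}, {hi}]")
    diff = ga[ok] - gb[ok]
    offset = float(diff.mean())
    residual = float(np.sqrt(np.mean((diff - offset) ** 2)))
    return offset, residual


def _min_spacing(*profiles):
    return min(float(np.min(np.diff(p.z))) for p in profiles)


# ---------------------------------------------------------------------------
# Joining subprocess profiles
# ---------------------------------------------------------------------------

_TERMINI = ("N", "C")
_SIDES = ("upper", "lower")
_PROCESSES = ("adsorption", "insertion")


@dataclass
class SubprocessProfile:
    """One subprocess profile in its own frame.

    The frame convention: the leaflet the process belongs to is at positive
    z (solvent above), so adsorption profiles span surface -> solvent
    (increasing z) and insertion profiles span across the center from the
    positive-z surface.
    """

    profile: FreeEnergyProfile
    terminus: str   # N | C
    side: str       # upper | lower
    process: str    # adsorption | insertion

    def __post_init__(self):
        if self.terminus not in _TERMINI:
            raise ValueError(f"terminus must be N|C, got {self.terminus!r}")
        if self.side not in _SIDES:
            raise ValueError(f"side must be upper|lower, got {self.side!r}")
        if self.process not in _PROCESSES:
            raise ValueError(
                f"process must be adsorption|insertion, got {self.process!r}")


@dataclass
class TranslocationAssembly:
    """A joined directional translocation profile with its audit trail.

    ``path_profiles`` maps ``(terminus, entry_side)`` to the full profile on
    the path coordinate (entry solvent at positive values, decreasing
    through the membrane to the exit solvent at negative values);
    ``offsets`` records the constant shift applied to each segment;
    ``states`` annotates positions of the solvent (1), adsorbed (2a),
    terminus-inserted (3a) and transmembrane (4a) states.
    """

    path_profiles: dict
    offsets: dict
    states: dict


def _opposite(x, pair):
    return pair[1 - pair.index(x)]


def _select(subs, process, side, terminus, symmetric):
    for s in subs:
        if (s.process, s.side, s.terminus) == (process, side, terminus):
            return s.profile, False
    if symmetric:
        # symmetric membrane: either side's segment represents both leaflets
        for s in subs:
            if (s.process, s.terminus) == (process, terminus):
                return s.profile, False
    raise ValueError(
        f"missing segment: {process}({side}, {terminus}-terminus)")


def join_translocation(subs: list[SubprocessProfile], terminus: str,
                       entry_side: str = "upper", *, symmetric: bool = False,
                       overlap_width: float = 0.3,
                       overlaps: dict | None = None,
                       solvent_width: float = 0.5) -> TranslocationAssembly:
    """Join four subprocess profiles into one directional translocation path.

    The path for ``terminus`` entering from ``entry_side`` consists of:

    1. adsorption(entry_side, terminus)          — entry solvent -> surface
    2. insertion(entry_side, terminus)           — surface -> across center
    3. insertion(opposite side, opposite terminus), mirrored — center -> exit surface
    4. adsorption(opposite side, opposite terminus), mirrored — surface -> exit solvent

    Exit-side segments are measured in their own frame (their leaflet at
    positive z) and are mapped onto the path coordinate by z -> -z.
    Segments are chain-aligned by least-squares constant offsets over their
    overlaps (default: a ``overlap_width``-wide interval centered in each
    pairwise support intersection — the adsorbed-minimum neighbourhood for
    adsorption/insertion junctions, the transmembrane neighbourhood for the
    insertion/insertion junction), cross-faded into a jump-free profile, and
    zero-referenced at the entry solvent plateau.

    For a symmetric membrane pass ``symmetric=True``: segments present for
    only one side stand in for both (mirrored), and the result is invariant
    under ``entry_side`` swap.
    """
    exit_side = _opposite(entry_side, _SIDES)
    exit_term = _opposite(terminus, _TERMINI)

    ads_in, _ = _select(subs, "adsorption", entry_side, terminus, symmetric)
    ins_in, _ = _select(subs, "insertion", entry_side, terminus, symmetric)
    ins_out, _ = _select(subs, "insertion", exit_side, exit_term, symmetric)
    ads_out, _ = _select(subs, "adsorption", exit_side, exit_term, symmetric)

    segments = [ads_in, ins_in, ins_out.mirrored(), ads_out.mirrored()]
    names = ["adsorption_entry", "insertion_entry",
             "insertion_exit", "adsorption_exit"]

    # chain alignment from the entry (high path coordinate) downward; each
    # segment is aligned to the already-shifted previous one, so the stored
    # offset is the total shift applied
    offsets = {names[0]: 0.0}
    aligned = [segments[0]]
    for seg, name in zip(segments[1:], names[1:]):
        prev = aligned[-1]
        if overlaps and name in overlaps:
            ov = overlaps[name]
        else:
            lo = max(prev.z.min(), seg.z.min())
            hi = min(prev.z.max(), seg.z.max())
            if hi <= lo:
                raise AlignmentError(
                    f"segments {name} do not overlap on the path coordinate")
            mid = 0.5 * (lo + hi)
            ov = (max(lo, mid - 0.5 * overlap_width),
                  min(hi, mid + 0.5 * overlap_width))
        off, _res = align_segments(prev, seg, ov)
        offsets[name] = off
        aligned.append(seg.shifted(off))

    joined = _crossfade(aligned)
    entry_hi = joined.z.max()
    joined = zero_reference(joined, (entry_hi - solvent_width, entry_hi))

    states = _annotate_states(joined)
    return TranslocationAssembly(
        path_profiles={(terminus, entry_side): joined},
        offsets=offsets, states=states)


def _crossfade(segments: list[FreeEnergyProfile]) -> FreeEnergyProfile:
    """Merge aligned, path-ordered segments on the union grid.

    Segments are ordered from the entry (topmost support) downward.  Each
    segment has weight 1 in its exclusive zone and ramps linearly to 0
    across the pairwise overlap with its neighbour, so exactly-aligned
    segments merge exactly and noisy ones merge continuously (jump-free).
    """
    zs = np.unique(np.concatenate([s.z for s in segments]))
    bounds = [(s.z.min(), s.z.max()) for s in segments]
    weights = []
    for j, (a, b) in enumerate(bounds):
        w = ((zs >= a - 1e-12) & (zs <= b + 1e-12)).astype(float)
        if j > 0:  # overlap with the segment above: [a_prev, b_j]
            lo, hi = bounds[j - 1][0], b
            if hi > lo:
                ramp = (zs >= lo) & (zs <= hi)
                w[ramp] *= np.clip((hi - zs[ramp]) / (hi - lo), 0.0, 1.0)
        if j < len(bounds) - 1:  # overlap with the segment below: [a_j, b_next]
            lo, hi = a, bounds[j + 1][1]
            if hi > lo:
                ramp = (zs >= lo) & (zs <= hi)
                w[ramp] *= np.clip((zs[ramp] - lo) / (hi - lo), 0.0, 1.0)
        weights.append(w)
    G = np.zeros_like(zs)
    Wsum = np.zeros_like(zs)
    for s, w in zip(segments, weights):
        gi = s.interp(zs)
        ok = np.isfinite(gi) & (w > 0)
        G[ok] += w[ok] * gi[ok]
        Wsum += np.where(ok, w, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Gm = np.where(Wsum > 0, G / Wsum, np.nan)
    return FreeEnergyProfile(z=zs, G=Gm, reference="joined path")


def _annotate_states(p: FreeEnergyProfile) -> dict:
    """Annotate canonical translocation states on a joined path profile.

    1: entry solvent (path start); 2a: adsorbed state (deepest local
    minimum on the entry half outside the center); 4a: transmembrane state
    (stationary point nearest the center); 3a: terminus-inserted, taken as
    the midpoint between 2a and 4a (schematic, not a free-energy feature).
    """
    z, G = p.z, p.G
    ok = np.isfinite(G)
    zz, gg = z[ok], G[ok]
    states = {"1": float(zz.max())}
    interior = (zz > zz.min() + 0.2) & (zz < zz.max() - 0.2)
    mins = np.zeros_like(gg, dtype=bool)
    mins[1:-1] = (gg[1:-1] <= gg[:-2]) & (gg[1:-1] <= gg[2:])
    entry_half = mins & interior & (zz > 0.3)
    if np.any(entry_half):
        states["2a"] = float(zz[entry_half][np.argmin(gg[entry_half])])
    i4 = int(np.argmin(np.abs(zz)))
    states["4a"] = float(zz[i4])
    if "2a" in states:
        states["3a"] = 0.5 * (states["2a"] + states["4a"])
    return states


# ---------------------------------------------------------------------------
# Comparison and region decomposition
# ---------------------------------------------------------------------------

def compare_profiles(p: FreeEnergyProfile, q: FreeEnergyProfile,
                     region: tuple[float, float],
                     ref_region: tuple[float, float] | None = None) -> dict:
    """Shape comparison of two profiles over a region.

    Both profiles are independently zero-referenced over ``ref_region``
    (default: ``region`` itself) before computing deviations, so constant
    offsets — pure gauge — never contribute.  Used e.g. for hysteresis
    checks between forward and backward window generations.
    """
    lo, hi = region
    if hi <= lo:
        raise ValueError("empty comparison region")
    rr = ref_region if ref_region is not None else region
    p0 = zero_reference(p, rr)
    q0 = zero_reference(q, rr)
    n = max(int(np.ceil((hi - lo) / _min_spacing(p, q))) + 1, 3)
    zg = np.linspace(lo, hi, n)
    dp = p0.interp(zg)
    dq = q0.interp(zg)
    ok = np.isfinite(dp) & np.isfinite(dq)
    if not np.any(ok):
        raise ValueError("profiles have no common coverage in region")
    d = dp[ok] - dq[ok]
    return {"max_abs_dev": float(np.max(np.abs(d))),
            "rmsd": float(np.sqrt(np.mean(d**2)))}


@dataclass
class RegionDecomposition:
    """Mimicking/intermediate decomposition of an asymmetric profile.

    ``mimic_upper``/``mimic_lower`` are the maximal contiguous z-intervals
    from each solvent end where the asymmetric profile stays within
    ``threshold`` of the corresponding pure membrane profile; everything
    between is ``intermediate``.  Empty intervals are None.
    """

    mimic_upper: tuple[float, float] | None
    mimic_lower: tuple[float, float] | None
    intermediate: tuple[float, float] | None
    threshold: float

    @property
    def intermediate_width(self) -> float:
        if self.intermediate is None:
            return 0.0
        return self.intermediate[1] - self.intermediate[0]


def classify_regions(asym: FreeEnergyProfile, pure_upper: FreeEnergyProfile,
                     pure_lower: FreeEnergyProfile,
                     threshold: float = 5.0) -> RegionDecomposition:
    """Decompose an asymmetric-membrane profile into three regions.

    Sweeping inward from the upper solvent end, the mimicking-upper region
    is the maximal contiguous run with |G_asym - G_pure_upper| <= threshold;
    the mimicking-lower region is found analogously from the lower end
    against the lower-leaflet pure profile; the remainder is the
    intermediate region.  All inputs must be referenced consistently (each
    to its own solvent plateau).  The 5 kJ/mol default matches the
    calculation error bound quoted for the underlying profiles.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    z = asym.z[asym.sampled]
    gu = pure_upper.interp(z)
    gl = pure_lower.interp(z)
    ga = asym.G[asym.sampled]
    ok_u = np.isfinite(gu)
    ok_l = np.isfinite(gl)
    within_u = ok_u & (np.abs(ga - gu) <= threshold)
    within_l = ok_l & (np.abs(ga - gl) <= threshold)
    n = z.size

    # maximal contiguous run from the top end
    i_top = n
    while i_top > 0 and within_u[i_top - 1]:
        i_top -= 1
    # maximal contiguous run from the bottom end
    i_bot = 0
    while i_bot < n and within_l[i_bot]:
        i_bot += 1

    if i_bot > i_top:
        # sweeps crossed (both pures mimic in between): no intermediate
        # region; the upper sweep keeps its full maximal extent
        i_bot = i_top

    mimic_upper = (float(z[i_top]), float(z[-1])) if i_top < n else None
    mimic_lower = (float(z[0]), float(z[i_bot - 1])) if i_bot > 0 else None
    if i_bot < i_top:
        intermediate = (float(z[i_bot - 1]) if i_bot > 0 else float(z[0]),
                        float(z[i_top]))
    else:
        intermediate = None
    return RegionDecomposition(mimic_upper=mimic_upper,
                               mimic_lower=mimic_lower,
                               intermediate=intermediate,
                               threshold=threshold)
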