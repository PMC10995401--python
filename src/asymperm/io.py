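"""Text formats, run configuration and provenance.

All on-disk formats are whitespace-column text with ``#``/``@`` comment
headers (deliberately compatible with common pull/umbrella output layouts):

* free-energy profile: columns ``z  G  [err]``;
* window timeseries: columns ``step  z``, one file per window, plus a
  window-metadata table with columns ``label z0 k n_equil seed n_samples``;
* stress profile: columns ``z  sigma_xx  sigma_yy  sigma_zz``;
* density profile: columns ``z  rho_tail``.

Run configuration is YAML; every artifact written by the CLI carries a
provenance header (tool version, timestamp, config hash).
"""

from __future__ import annotations

import hashlib
import io as _io
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from asymperm.landscapes import UmbrellaWindow, WindowTimeseries
from asymperm.mechanics import DensityProfile, StressProfile
from asymperm.profiles import FreeEnergyProfile

_COMMENTS = ("#", "@")


class FormatError(ValueError):
    """A data file violates its documented column layout."""


def _load_columns(path, n_min: int, n_max: int | None = None) -> np.ndarray:
    """Parse whitespace columns, ignoring '#'/'@' lines; error with line number."""
    rows = []
    width = None
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s[0] in _COMMENTS:
                continue
            parts = s.split()
            if len(parts) < n_min or (n_max is not None and len(parts) > n_max):
                raise FormatError(
                    f"{path}:{ln}: expected {n_min}"
                    + (f"-{n_max}" if n_max and n_max != n_min else "")
                    + f" columns, got {len(parts)}")
            if width is None:
                width = len(parts)
            elif len(parts) != width:
                raise FormatError(f"{path}:{ln}: ragged row "
                                  f"({len(parts)} columns, expected {width})")
            try:
                rows.append([float(v) for v in parts])
            except ValueError as e:
                raise FormatError(f"{path}:{ln}: {e}") from None
    if not rows:
        raise FormatError(f"{path}: no data rows")
    return np.asarray(rows)


def _header(extra: dict | None = None) -> str:
    from asymperm import __version__

    lines = [f"# asymperm {__version__}"]
    for k, v in (extra or {}).items():
        lines.append(f"# {k} = {v}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def write_profile(path, p: FreeEnergyProfile, header: dict | None = None):
    """Write a profile as (z, G[, err]) columns with a key=value header."""
    meta = {"reference": p.reference}
    for attr in ("iterations", "residual"):
        if hasattr(p, attr):
            meta[attr] = getattr(p, attr)
    meta.update(header or {})
    cols = [p.z, p.G] + ([p.err] if p.err is not None else [])
    with open(path, "w") as fh:
        fh.write(_header(meta))
        np.savetxt(fh, np.column_stack(cols), fmt="%.17g")


def read_profile(path) -> FreeEnergyProfile:
    data = _load_columns(path, 2, 3)
    err = data[:, 2] if data.shape[1] == 3 else None
    reference = ""
    with open(path) as fh:
        for line in fh:
            if line.startswith("# reference ="):
                reference = line.split("=", 1)[1].strip()
                break
    return FreeEnergyProfile(z=data[:, 0], G=data[:, 1], err=err,
                             reference=reference)


# ---------------------------------------------------------------------------
# Window timeseries
# ---------------------------------------------------------------------------

def write_timeseries(directory, ts: list[WindowTimeseries],
                     header: dict | None = None) -> Path:
    """Write one (step, z) file per window plus the window-metadata table.

    Returns the path of the metadata table (``windows.dat``).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta_path = directory / "windows.dat"
    with open(meta_path, "w") as mh:
        mh.write(_header(header))
        mh.write("# columns: index label z0 k n_equil seed n_samples file\n")
        for i, t in enumerate(ts):
            fname = f"window_{i:03d}.xvg"
            with open(directory / fname, "w") as fh:
                fh.write(_header({"z0": t.window.z0, "k": t.window.k,
                                  "n_equil": t.n_equil, "seed": t.seed}))
                fh.write("@ columns: step z\n")
                np.savetxt(fh, np.column_stack(
                    [np.arange(len(t.samples)), t.samples]),
                    fmt=["%d", "%.17g"])
            label = t.window.label or "-"
            mh.write(f"{i} {label} {t.window.z0:.17g} {t.window.k:.17g} "
                     f"{t.n_equil} {t.seed} {len(t.samples)} {fname}\n")
    return meta_path


def read_timeseries(meta_path) -> list[WindowTimeseries]:
    """Read the window set written by :func:`write_timeseries`."""
    meta_path = Path(meta_path)
    out = []
    with open(meta_path) as fh:
        for ln, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s[0] in _COMMENTS:
                continue
            parts = s.split()
            if len(parts) != 8:
                raise FormatError(f"{meta_path}:{ln}: expected 8 columns")
            _, label, z0, k, n_equil, seed, n_samples, fname = parts
            data = _load_columns(meta_path.parent / fname, 2, 2)
            if data.shape[0] != int(n_samples):
                raise FormatError(
                    f"{fname}: {data.shape[0]} samples, metadata says {n_samples}")
            win = UmbrellaWindow(z0=float(z0), k=float(k),
                                 label="" if label == "-" else label)
            out.append(WindowTimeseries(window=win, samples=data[:, 1],
                                        seed=int(seed), n_equil=int(n_equil)))
    if not out:
        raise FormatError(f"{meta_path}: no window entries")
    return out


# ---------------------------------------------------------------------------
# Mechanics inputs
# ---------------------------------------------------------------------------

def read_stress(path) -> StressProfile:
    data = _load_columns(path, 4, 4)
    return StressProfile(z=data[:, 0], sigma_xx=data[:, 1],
                         sigma_yy=data[:, 2], sigma_zz=data[:, 3])


def write_stress(path, s: StressProfile, header: dict | None = None):
    meta = dict(header or {})
    meta.update({f"meta_{k}": v for k, v in s.metadata.items()})
    with open(path, "w") as fh:
        fh.write(_header(meta))
        fh.write("@ columns: z sigma_xx sigma_yy sigma_zz (nm, bar)\n")
        np.savetxt(fh, np.column_stack([s.z, s.sigma_xx, s.sigma_yy,
                                        s.sigma_zz]), fmt="%.17g")


def read_density(path) -> DensityProfile:
    data = _load_columns(path, 2, 2)
    return DensityProfile(z=data[:, 0], rho_tail=data[:, 1])


def write_density(path, d: DensityProfile, header: dict | None = None):
    with open(path, "w") as fh:
        fh.write(_header(header))
        fh.write("@ columns: z rho_tail\n")
        np.savetxt(fh, np.column_stack([d.z, d.rho_tail]), fmt="%.17g")


# ---------------------------------------------------------------------------
# Run configuration and provenance
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Serializable run configuration; a run is reproducible from this + seeds."""

    params: dict = field(default_factory=dict)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            params = yaml.safe_load(fh) or {}
        if not isinstance(params, dict):
            raise FormatError(f"{path}: top level must be a mapping")
        return cls(params=params)

    def dump(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.params, fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        buf = _io.StringIO()
        yaml.safe_dump(self.params, buf, sort_keys=True)
        return hashlib.sha256(buf.getvalue().encode()).hexdigest()[:12]

    def provenance(self) -> dict:
        from asymperm import __version__

        return {
            "tool": f"asymperm {__version__}",
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "config_hash": self.config_hash,
        }
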