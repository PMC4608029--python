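"""File formats: MRC density maps, trace/manifest CSV, pseudo-atom PDB,
and the plain-text key-value run configuration.

Conventions
-----------
* MRC maps are written in mode 2 (32-bit float) with the voxel size in the
  header cell parameters and the volume origin in the ORIGIN header words;
  axis order is normalized to X, Y, Z on read.
* Curves travel as CSV with columns ``record_id, vertex_index, x_A, y_A,
  z_A`` (coordinates in Angstroms).
* Every tabular output can carry a provenance column with the
  configuration hash.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .curves import ClosedCurve
from .volume import DensityVolume

__all__ = [
    "read_mrc", "write_mrc", "write_trace_csv", "read_trace_csv",
    "write_pseudo_pdb", "read_config", "write_config", "config_hash",
]


# ---------------------------------------------------------------------------
# MRC
# ---------------------------------------------------------------------------

def write_mrc(volume: DensityVolume, path) -> None:
    """Write a density volume as a mode-2 (float32) MRC map.

    The voxel size is recorded through the cell dimensions and the world
    position of voxel (0,0,0) in the ORIGIN header fields.
    """
    nx, ny, nz = volume.shape
    grid = gemmi.FloatGrid(nx, ny, nz)
    np.array(grid, copy=False)[:] = volume.data
    grid.unit_cell = gemmi.UnitCell(nx * volume.voxel_size,
                                    ny * volume.voxel_size,
                                    nz * volume.voxel_size, 90, 90, 90)
    grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    for k in range(3):
        m.set_header_float(50 + k, float(volume.origin[k]))
    m.write_ccp4_map(str(path))


def read_mrc(path) -> DensityVolume:
    """Read a mode-2 MRC map into a DensityVolume.

    The axis order is normalized to X, Y, Z; the voxel size must be
    (near-)isotropic.  Corrupt or truncated files raise a descriptive
    error instead of returning garbage.
    """
    path = Path(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise IOError(f"cannot read MRC map {path}: {exc}") from exc
    mode = m.header_i32(4)
    if mode != 2:
        raise IOError(f"{path}: unsupported MRC mode {mode} (expected 2)")
    m.setup(float("nan"))  # normalize axis order to X, Y, Z
    data = np.array(m.grid, copy=True)
    if not np.all(np.isfinite(data)):
        raise IOError(f"{path}: map contains non-finite values after setup")
    cell = m.grid.unit_cell
    nx, ny, nz = data.shape
    vsizes = np.array([cell.a / nx, cell.b / ny, cell.c / nz])
    if np.ptp(vsizes) > 1e-3 * vsizes.mean():
        raise IOError(f"{path}: anisotropic voxel size {vsizes} is not "
                      f"supported")
    origin = np.array([m.header_float(50 + k) for k in range(3)])
    return DensityVolume(data.astype(np.float32), float(vsizes.mean()),
                         origin)


# ---------------------------------------------------------------------------
# trace CSV and pseudo-atom PDB
# ---------------------------------------------------------------------------

def write_trace_csv(curves: dict, path, extra: dict | None = None) -> None:
    """Write one or more curves to CSV (record_id, vertex_index, x/y/z_A).

    ``curves`` maps record_id -> ClosedCurve; ``extra`` adds constant
    provenance columns (e.g. the config hash).
    """
    rows = []
    for rid, curve in curves.items():
        for i, (x, y, z) in enumerate(curve.vertices):
            rows.append({"record_id": rid, "vertex_index": i,
                         "x_A": x, "y_A": y, "z_A": z})
    df = pd.DataFrame(rows)
    for k, v in (extra or {}).items():
        df[k] = v
    df.to_csv(path, index=False)


def read_trace_csv(path) -> dict:
    """Read curves from a trace CSV; returns record_id -> ClosedCurve."""
    df = pd.read_csv(path)
    needed = {"record_id", "vertex_index", "x_A", "y_A", "z_A"}
    missing = needed - set(df.columns)
    if missing:
        raise IOError(f"{path}: missing trace columns {sorted(missing)}")
    out = {}
    for rid, sub in df.groupby("record_id", sort=False):
        sub = sub.sort_values("vertex_index")
        out[rid] = ClosedCurve(sub[["x_A", "y_A", "z_A"]].to_numpy())
    return out


def write_pseudo_pdb(curve: ClosedCurve, path, record_id: str = "TRACE"
                     ) -> None:
    """Write a trace as pseudo-atoms (one HETATM per vertex) for viewing.

    Consecutive vertices are linked by CONECT records, closing the loop.
    """
    n = curve.n_vertices
    lines = [f"REMARK   minicircle trace {record_id} ({n} vertices)"]
    for i, (x, y, z) in enumerate(curve.vertices, start=1):
        lines.append(
            f"HETATM{i:>5d}  P   DNA A{1:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           P")
    for i in range(1, n + 1):
        j = i % n + 1
        lines.append(f"CONECT{i:>5d}{j:>5d}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# plain-text configuration
# ---------------------------------------------------------------------------

def _coerce(value: str):
    value = value.strip()
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    if value.lower() in ("true", "false"):
        return value.lower() == "true"
    return value


def read_config(path) -> dict:
    """Parse a plain-text key=value configuration file.

    Lines are ``key = value`` (``#`` comments allowed); dotted keys create
    nested sections (``population.noise_sd = 0.1``); ``counts.<class>``
    builds the per-class molecule counts.
    """
    cfg: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', "
                             f"got {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        target = cfg
        parts = key.split(".")
        for part in parts[:-1]:
            target = target.setdefault(part, {})
        target[parts[-1]] = _coerce(value)
    return cfg


def write_config(cfg: dict, path) -> None:
    """Serialize a (possibly nested) config dict as key = value lines."""
    lines: list[str] = []

    def _emit(prefix: str, d: dict) -> None:
        for k in sorted(d):
            v = d[k]
            full = f"{prefix}{k}"
            if isinstance(v, dict):
                _emit(full + ".", v)
            else:
                lines.append(f"{full} = {v}")

    _emit("", cfg)
    Path(path).write_text("\n".join(lines) + "\n")


def config_hash(cfg: dict) -> str:
    """Short stable hash of a config dict, for output provenance."""
    flat: list[str] = []

    def _emit(prefix: str, d: dict) -> None:
        for k in sorted(d):
            v = d[k]
            if isinstance(v, dict):
                _emit(f"{prefix}{k}.", v)
            else:
                flat.append(f"{prefix}{k}={v!r}")

    _emit("", cfg)
    return hashlib.sha256("\n".join(flat).encode()).hexdigest()[:12]
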