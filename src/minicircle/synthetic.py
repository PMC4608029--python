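"""Synthetic minicircle phantoms: ground-truth curves and tube-density volumes.

DNA minicircles imaged by cryo-electron tomography appear as closed tubes of
density whose backbone adopts one of a small set of conformational classes:
open circle, open figure-8, figure-8, racquet, handcuffs, needle and rod.
This module generates ground-truth closed curves for each class, rasterizes
them into tube-like density volumes at a chosen voxel size, and corrupts the
result with blur and additive Gaussian noise, so the tracing and shape
analysis stages can be exercised end to end with known answers.

Geometry conventions: a 336 bp circle at the canonical B-DNA rise of
3.4 A/bp has contour length 1142.4 A; the tube density falls off as a
Gaussian of the distance to the backbone with sigma equal to ``tube_radius``
(10 A, the B-DNA radius).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .curves import ClosedCurve
from .volume import DensityVolume

__all__ = [
    "SHAPE_CLASSES", "ShapeSpec", "PopulationSpec", "PopulationRecord",
    "make_curve", "rasterize", "corrupt", "generate_population",
]

#: The conformational taxonomy, in order of increasing compactness.
SHAPE_CLASSES = ("open_circle", "open_figure8", "figure8", "racquet",
                 "handcuffs", "needle", "rod")

#: Canonical contour length of a 336 bp minicircle (3.4 A/bp rise).
DEFAULT_CONTOUR_LENGTH = 336 * 3.4

_DEFAULT_LOOP_FRACTION = {"racquet": 0.55, "needle": 0.20, "handcuffs": 0.30}
_DEFAULT_CROSSING_OFFSET = {"figure8": 25.0, "open_figure8": 70.0}


class InfeasibleShapeError(ValueError):
    """Raised when a ShapeSpec's parameters cannot produce a valid curve."""


@dataclass
class ShapeSpec:
    """Parameters of one ground-truth minicircle conformation.

    Parameters
    ----------
    shape_class : str
        One of :data:`SHAPE_CLASSES`.
    contour_length : float
        Total backbone length in Angstroms (default 336 bp x 3.4 A/bp).
    ellipticity_param : float
        Target long/short principal-axis ratio (open circle only), in
        [1, 5].  Calibrated so the *measured* covariance-axis ratio of the
        generated curve equals this value.
    loop_fraction : float, optional
        Fraction of the contour in the loop (racquet/needle) or in each
        loop (handcuffs).  Class-specific default if None.
    handle_gap : float
        Center-to-center distance in Angstroms between juxtaposed backbone
        strands (racquet/needle/handcuffs handles, rod strands).
    crossing_offset : float, optional
        Out-of-plane strand separation at the crossing for the figure-8
        family.  Class-specific default if None.
    chirality : int
        Sign of the crossing for the figure-8 family: -1 (default) gives
        the right-handed crossover of negatively supercoiled DNA (negative
        writhe), +1 the left-handed crossover of positive supercoiling.
    n_points : int
        Vertex count of the returned ground-truth curve.
    """

    shape_class: str
    contour_length: float = DEFAULT_CONTOUR_LENGTH
    ellipticity_param: float = 1.0
    loop_fraction: float | None = None
    handle_gap: float = 30.0
    crossing_offset: float | None = None
    chirality: int = -1
    n_points: int = 200

    def __post_init__(self) -> None:
        if self.shape_class not in SHAPE_CLASSES:
            raise ValueError(
                f"unknown shape_class {self.shape_class!r}; "
                f"expected one of {SHAPE_CLASSES}")
        if self.loop_fraction is None:
            self.loop_fraction = _DEFAULT_LOOP_FRACTION.get(self.shape_class)
        if self.crossing_offset is None:
            self.crossing_offset = _DEFAULT_CROSSING_OFFSET.get(
                self.shape_class, 25.0)
        self.validate()

    def validate(self) -> None:
        if self.contour_length <= 0:
            raise InfeasibleShapeError("contour_length must be positive")
        if not 1.0 <= self.ellipticity_param <= 5.0:
            raise InfeasibleShapeError(
                f"ellipticity_param must be in [1, 5], got "
                f"{self.ellipticity_param}")
        if self.handle_gap <= 0:
            raise InfeasibleShapeError("handle_gap must be positive")
        if self.n_points < 8:
            raise InfeasibleShapeError("n_points must be at least 8")
        if self.loop_fraction is not None:
            if not 0.0 < self.loop_fraction < 1.0:
                raise InfeasibleShapeError(
                    f"loop_fraction must be in (0, 1), got "
                    f"{self.loop_fraction}")


@dataclass
class PopulationSpec:
    """A synthetic population: per-class counts plus imaging parameters.

    ``noise_sd`` is relative to the peak tube density (1.0 on the backbone
    axis); ``blur_sigma`` is in Angstroms.  ``margin`` is the clearance kept
    between the curve and every box face (at least 180 A so the
    radius-of-gyration mask is never truncated).  ``jitter`` is the relative
    spread of per-record shape-parameter variation.
    """

    counts: dict = field(default_factory=dict)
    voxel_size: float = 4.52
    box_edge: int | None = None
    tube_radius: float = 10.0
    noise_sd: float = 0.1
    blur_sigma: float = 0.0
    margin: float = 180.0
    contour_length: float = DEFAULT_CONTOUR_LENGTH
    jitter: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.counts = {str(k): int(v) for k, v in self.counts.items()}
        for cls, n in self.counts.items():
            if cls not in SHAPE_CLASSES:
                raise ValueError(f"unknown shape class in counts: {cls!r}")
            if n < 0:
                raise ValueError("counts must be non-negative")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.tube_radius <= 0:
            raise ValueError("tube_radius must be positive")
        if self.noise_sd < 0 or self.blur_sigma < 0:
            raise ValueError("noise_sd and blur_sigma must be non-negative")


@dataclass
class PopulationRecord:
    """One generated phantom with its provenance."""

    record_id: str
    shape_class: str
    seed: int
    spec: ShapeSpec
    curve: ClosedCurve
    volume: DensityVolume


# ---------------------------------------------------------------------------
# curve construction
# ---------------------------------------------------------------------------

def _uniform_closed(points: np.ndarray, n: int, length: float) -> ClosedCurve:
    """Resample a closed polyline to n uniform vertices of exact perimeter."""
    curve = ClosedCurve(points).resample(max(n, 512)).resample(n)
    return curve.transformed(scale=length / curve.arc_length())


def _covariance_axis_ratio(points: np.ndarray) -> float:
    c = points - points.mean(axis=0)
    w = np.linalg.eigvalsh(c.T @ c / len(c))
    return float(np.sqrt(w[-1] / w[-2]))


def _ellipse_points(q: float, n: int = 4096) -> np.ndarray:
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([q * np.cos(t), np.sin(t), np.zeros(n)])
    # re-space to uniform arc length before measuring moments
    return ClosedCurve(pts).resample(2048).vertices


def _calibrated_semi_axis_ratio(target: float) -> float:
    """Semi-axis ratio q whose arc-uniform covariance ratio equals target.

    The covariance-axis ratio of points spread uniformly in arc length over
    an ellipse is slightly below the semi-axis ratio (arc length accumulates
    faster along the flat sides); the generator compensates so that the
    requested ellipticity is the one the shape-metrics module measures.
    """
    if target <= 1.0 + 1e-9:
        return 1.0
    f = lambda q: _covariance_axis_ratio(_ellipse_points(q)) - target
    return brentq(f, target, 3.0 * target, xtol=1e-6)


def _open_circle_curve(spec: ShapeSpec) -> np.ndarray:
    q = _calibrated_semi_axis_ratio(spec.ellipticity_param)
    t = np.linspace(0.0, 2 * np.pi, 4096, endpoint=False)
    return np.column_stack([q * np.cos(t), np.sin(t), np.zeros_like(t)])


def _figure8_curve(spec: ShapeSpec) -> np.ndarray:
    """Lemniscate-like closed curve with one crossing.

    In-plane shape x = s sin t, y = (s/2) sin 2t; the two central passages
    (t = 0 and t = pi) are lifted out of plane by +-crossing_offset/2.  The
    in-plane scale s is solved so the contour length matches the spec.
    """
    c = 0.5 * spec.crossing_offset * spec.chirality
    t = np.linspace(0.0, 2 * np.pi, 4096, endpoint=False)

    def pts(s: float) -> np.ndarray:
        return np.column_stack([s * np.sin(t), 0.5 * s * np.sin(2 * t),
                                c * np.cos(t)])

    def length(s: float) -> float:
        p = pts(s)
        return float(np.linalg.norm(np.roll(p, -1, 0) - p, axis=1).sum())

    L = spec.contour_length
    if length(L / 20.0) > L:
        raise InfeasibleShapeError(
            "crossing_offset too large for the contour length")
    s = brentq(lambda s: length(s) - L, L / 20.0, L, xtol=1e-6)
    return pts(s)


def _arc(center: np.ndarray, radius: float, a0: float, a1: float,
         n: int) -> np.ndarray:
    """Planar (z=0) circular arc from angle a0 to a1, endpoint excluded."""
    ang = np.linspace(a0, a1, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(ang),
                            center[1] + radius * np.sin(ang),
                            np.zeros(n)])


def _seg(p0: np.ndarray, p1: np.ndarray, n: int) -> np.ndarray:
    u = np.linspace(0.0, 1.0, n, endpoint=False)[:, None]
    return (1 - u) * np.asarray(p0, float) + u * np.asarray(p1, float)


def _loop_radius(arc_length: float, gap: float) -> float:
    """Radius of a circle whose major arc between two points a distance
    ``gap`` apart (straddling the x axis) has the given length."""
    lo = gap / 2 + 1e-9

    def f(r: float) -> float:
        phi = np.arctan2(gap / 2, -np.sqrt(r ** 2 - (gap / 2) ** 2))
        return 2 * phi * r - arc_length

    if f(lo) > 0:
        raise InfeasibleShapeError(
            f"loop arc length {arc_length:.1f} A is too short for "
            f"handle_gap {gap:.1f} A (loop radius would fall below gap/2)")
    return brentq(f, lo, arc_length, xtol=1e-9)


def _racquet_curve(spec: ShapeSpec) -> np.ndarray:
    """Loop plus doubled-back handle ending in a U-turn (racquet/needle)."""
    L, g, f = spec.contour_length, spec.handle_gap, spec.loop_fraction
    loop_len = f * L
    handle_len = L - loop_len - np.pi * g / 2
    if handle_len <= g:
        raise InfeasibleShapeError(
            f"loop_fraction {f} leaves no room for the handle "
            f"(handle length {handle_len:.1f} A <= handle_gap)")
    h = handle_len / 2
    r = _loop_radius(loop_len, g)
    cx = np.sqrt(r ** 2 - (g / 2) ** 2)
    center = np.array([cx, 0.0])
    phi = np.arctan2(g / 2, -cx)          # angle of (0, +g/2) seen from center
    n_loop = max(int(1024 * f), 64)
    parts = [
        _arc(center, r, phi, -phi, n_loop),     # (0,g/2) -> (0,-g/2) via +x
        _seg([0, -g / 2, 0], [-h, -g / 2, 0], 256),
        _arc(np.array([-h, 0.0]), g / 2, -np.pi / 2, -3 * np.pi / 2, 64),
        _seg([-h, g / 2, 0], [0, g / 2, 0], 256),
    ]
    return np.vstack(parts)


def _rod_curve(spec: ShapeSpec) -> np.ndarray:
    """Two apical U-turns joined by long juxtaposed straight strands."""
    L, g = spec.contour_length, spec.handle_gap
    straight = (L - np.pi * g) / 2
    if straight <= g:
        raise InfeasibleShapeError(
            f"handle_gap {g:.1f} A leaves no straight segment in a rod of "
            f"contour length {L:.1f} A")
    parts = [
        _seg([0, g / 2, 0], [straight, g / 2, 0], 512),
        _arc(np.array([straight, 0.0]), g / 2, np.pi / 2, -np.pi / 2, 64),
        _seg([straight, -g / 2, 0], [0, -g / 2, 0], 512),
        _arc(np.array([0.0, 0.0]), g / 2, -np.pi / 2, -3 * np.pi / 2, 64),
    ]
    return np.vstack(parts)


def _handcuffs_curve(spec: ShapeSpec) -> np.ndarray:
    """Two terminal loops joined by a doubled straight handle."""
    L, g, f = spec.contour_length, spec.handle_gap, spec.loop_fraction
    loop_len = f * L
    h = (L - 2 * loop_len) / 2
    if h <= g:
        raise InfeasibleShapeError(
            f"loop_fraction {f} per loop leaves handle length {h:.1f} A "
            f"<= handle_gap in a handcuffs shape")
    rA = _loop_radius(loop_len, g)
    cA = np.sqrt(rA ** 2 - (g / 2) ** 2)
    phiA = np.arctan2(g / 2, -cA)
    n_loop = max(int(1024 * f), 64)
    left = _arc(np.array([-cA, 0.0]), rA, np.pi - phiA,
                np.pi + phiA, n_loop)
    right = _arc(np.array([h + cA, 0.0]), rA, -phiA, phiA, n_loop)
    parts = [
        left,                                           # (0,g/2) -> (0,-g/2) via -x
        _seg([0, -g / 2, 0], [h, -g / 2, 0], 384),
        right,                                          # (h,-g/2) -> (h,g/2) via +x
        _seg([h, g / 2, 0], [0, g / 2, 0], 384),
    ]
    return np.vstack(parts)


_BUILDERS = {
    "open_circle": _open_circle_curve,
    "open_figure8": _figure8_curve,
    "figure8": _figure8_curve,
    "racquet": _racquet_curve,
    "needle": _racquet_curve,
    "handcuffs": _handcuffs_curve,
    "rod": _rod_curve,
}


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def make_curve(spec: ShapeSpec, seed: int = 0) -> ClosedCurve:
    """Generate the ground-truth closed curve for a shape specification.

    The canonical curve for the class is built in a reference frame, scaled
    to the exact contour length, resampled to ``spec.n_points`` uniformly
    spaced vertices, then rotated by a uniformly random orientation drawn
    from ``seed`` and centered at the origin.  Deterministic for fixed
    (spec, seed).
    """
    spec.validate()
    raw = _BUILDERS[spec.shape_class](spec)
    curve = _uniform_closed(raw, spec.n_points, spec.contour_length)
    rng = np.random.default_rng(seed)
    curve = curve.transformed(rotation=_random_rotation(rng),
                              translation=-curve.centroid())
    curve = ClosedCurve(curve.vertices - curve.centroid())
    # reject geometries that self-collide below the strand-gap scale
    min_d = curve.min_nonadjacent_distance(arc_exclusion=3 * spec.handle_gap)
    if min_d < 0.9 * min(spec.handle_gap, spec.crossing_offset):
        raise InfeasibleShapeError(
            f"{spec.shape_class} curve self-approaches to {min_d:.1f} A, "
            f"closer than the strand gap; adjust loop_fraction/handle_gap")
    return curve


# ---------------------------------------------------------------------------
# rasterization and corruption
# ---------------------------------------------------------------------------

def rasterize(curve: ClosedCurve, pop: PopulationSpec) -> DensityVolume:
    """Rasterize a curve into a tube-density volume.

    Density at a voxel center is ``exp(-d^2 / (2 tube_radius^2))`` where
    ``d`` is the distance to the curve; voxels farther than 3 tube radii
    are exactly zero.  The box is centered on the curve centroid; its edge
    is ``pop.box_edge`` voxels, or the smallest cube accommodating the curve
    plus ``pop.margin`` if unset.
    """
    v = curve.vertices - curve.centroid()
    half_extent = float(np.abs(v).max())
    needed = int(np.ceil(2 * (half_extent + pop.margin) / pop.voxel_size)) + 1
    edge = pop.box_edge if pop.box_edge is not None else needed
    if edge < needed:
        raise ValueError(
            f"box_edge={edge} voxels cannot hold the curve with a "
            f"{pop.margin:.0f} A margin; need at least {needed} voxels")

    origin = curve.centroid() - (edge - 1) / 2.0 * pop.voxel_size
    vol = DensityVolume(np.zeros((edge, edge, edge), dtype=np.float32),
                        pop.voxel_size, origin)
    _add_tube_density(vol, curve, pop.tube_radius)
    return vol


def _add_tube_density(vol: DensityVolume, curve: ClosedCurve,
                      tube_radius: float) -> None:
    """Add the Gaussian tube profile of a curve into ``vol`` in place."""
    cutoff = 3.0 * tube_radius
    samples = curve.dense_samples(spacing=0.5)
    tree = cKDTree(samples)
    lo = vol.world_to_index(samples.min(axis=0) - cutoff)
    hi = vol.world_to_index(samples.max(axis=0) + cutoff)
    lo = np.clip(np.floor(lo).astype(int), 0, np.array(vol.shape) - 1)
    hi = np.clip(np.ceil(hi).astype(int) + 1, 1, np.array(vol.shape))
    axes = [vol.origin[k] + vol.voxel_size * np.arange(lo[k], hi[k])
            for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    d, _ = tree.query(pts, distance_upper_bound=cutoff)
    dens = np.where(np.isfinite(d),
                    np.exp(-0.5 * (d / tube_radius) ** 2), 0.0)
    dens[d > cutoff] = 0.0
    block = dens.reshape(gx.shape).astype(np.float32)
    vol.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += block


def corrupt(volume: DensityVolume, noise_sd: float, blur_sigma: float,
            seed: int = 0) -> DensityVolume:
    """Blur a volume and add i.i.d. Gaussian noise.

    Output = Gaussian blur (sigma in Angstroms) of the input, plus noise of
    standard deviation ``noise_sd`` (in units of the peak tube density).
    With both parameters zero, the data are returned unchanged.
    Deterministic for fixed seed.
    """
    if noise_sd < 0 or blur_sigma < 0:
        raise ValueError("noise_sd and blur_sigma must be non-negative")
    data = volume.data
    if blur_sigma > 0:
        data = gaussian_filter(data.astype(np.float64),
                               sigma=blur_sigma / volume.voxel_size)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd, size=volume.data.shape)
    return DensityVolume(np.asarray(data, dtype=np.float32).copy(),
                         volume.voxel_size, volume.origin.copy())


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------

def _record_seed(master_seed: int, index: int) -> int:
    """Deterministic per-record seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _jittered_spec(spec: ShapeSpec, jitter: float,
                   rng: np.random.Generator) -> ShapeSpec:
    """Perturb shape parameters by a relative amount, staying feasible."""
    if jitter <= 0:
        return spec
    kw = {}
    if spec.shape_class == "open_circle":
        e = spec.ellipticity_param * (1 + jitter * rng.normal())
        kw["ellipticity_param"] = float(np.clip(e, 1.0, 2.6))
    if spec.shape_class in ("racquet", "needle", "handcuffs"):
        f = spec.loop_fraction * (1 + jitter * rng.normal())
        lo, hi = {"racquet": (0.45, 0.70), "needle": (0.19, 0.30),
                  "handcuffs": (0.25, 0.35)}[spec.shape_class]
        kw["loop_fraction"] = float(np.clip(f, lo, hi))
    if spec.shape_class in ("figure8", "open_figure8"):
        c = spec.crossing_offset * (1 + jitter * rng.normal())
        lo, hi = ((15.0, 45.0) if spec.shape_class == "figure8"
                  else (65.0, 110.0))
        kw["crossing_offset"] = float(np.clip(c, lo, hi))
    return replace(spec, **kw) if kw else spec


def generate_population(pop: PopulationSpec,
                        specs: dict | None = None) -> list[PopulationRecord]:
    """Generate phantoms for every entry of ``pop.counts``.

    Returns one record per molecule, in deterministic order (classes in
    taxonomy order, then record index).  Each record carries its own seed so
    it can be regenerated in isolation; two calls with the same spec produce
    identical populations.

    Parameters
    ----------
    pop : PopulationSpec
    specs : dict, optional
        Per-class ShapeSpec overrides; defaults are built from
        ``pop.contour_length``.
    """
    total = sum(pop.counts.values())
    if total == 0:
        raise ValueError("empty population: all counts are zero")
    records: list[PopulationRecord] = []
    index = 0
    for cls in SHAPE_CLASSES:
        n = pop.counts.get(cls, 0)
        base = (specs or {}).get(cls) or ShapeSpec(
            cls, contour_length=pop.contour_length)
        for i in range(n):
            seed = _record_seed(pop.seed, index)
            rng = np.random.default_rng(seed)
            spec = _jittered_spec(base, pop.jitter, rng)
            curve = make_curve(spec, seed=seed)
            clean = rasterize(curve, pop)
            vol = corrupt(clean, pop.noise_sd, pop.blur_sigma, seed=seed)
            records.append(PopulationRecord(
                record_id=f"{cls}_{i:03d}", shape_class=cls, seed=seed,
                spec=spec, curve=curve, volume=vol))
            index += 1
    return records


def population_manifest(records: list[PopulationRecord]):
    """Tabular manifest (pandas DataFrame) from which any record can be
    regenerated: id, class, seed and the shape parameters used."""
    import pandas as pd

    rows = []
    for r in records:
        rows.append({
            "record_id": r.record_id, "shape_class": r.shape_class,
            "seed": r.seed, "contour_length": r.spec.contour_length,
            "ellipticity_param": r.spec.ellipticity_param,
            "loop_fraction": r.spec.loop_fraction,
            "handle_gap": r.spec.handle_gap,
            "crossing_offset": r.spec.crossing_offset,
            "chirality": r.spec.chirality, "n_points": r.spec.n_points,
        })
    return pd.DataFrame(rows)
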