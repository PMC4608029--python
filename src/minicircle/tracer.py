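"""Closed-loop polygon tracing of a DNA minicircle in a density volume.

The backbone of a minicircle appears in a cryo-ET subvolume as a closed tube
of density.  The tracer fits a closed polygon to that tube by maximising a
score with three terms: the (interpolated) density at the vertices, a
quadratic penalty on edge-length deviations from the target edge length
(expected contour length / vertex count), and a quadratic penalty on
interior-angle deviations from the regular-polygon angle.  The length and
angle terms act as restoring forces that keep the polygon an open loop
wherever the density permits.

Optimisation is staged: a small polygon (5 vertices) is refined by gradient
ascent, then the vertex count is doubled by edge-midpoint insertion and
refinement repeated, ending at 20 vertices.  Convergence is verified by
running multiple random starting orientations and measuring the agreement
of the resulting curves.

The model/results split follows the fitting idiom: build a
:class:`Tracer` from a volume and an expected contour length, call
:meth:`Tracer.fit`, and read estimates and diagnostics off the returned
:class:`TraceResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .curves import ClosedCurve, align_closed_curves
from .volume import DensityVolume

__all__ = ["TracerConfig", "ScoreBreakdown", "TraceResult", "Tracer",
           "preprocess", "score_polygon", "refine", "subdivide", "trace"]


@dataclass
class TracerConfig:
    """Tunable parameters of the closed-loop tracer.

    Weights are in units that make the three score terms comparable on a
    z-scored volume: ``w_density`` multiplies density in sd units,
    ``w_length`` is per Angstrom^2 of edge-length deviation, ``w_angle``
    per radian^2 of interior-angle deviation.
    """

    contour_length: float = 336 * 3.4   # expected backbone length, Angstroms
    n_init: int = 5
    n_final: int = 20
    w_density: float = 1.0
    w_length: float = 0.02
    w_angle: float = 1.0
    step_size: float = 2.0              # max vertex move per iteration, A
    max_iters: int = 200                # per refinement stage
    convergence_tol: float = 1e-6       # relative score improvement
    n_starts: int = 4
    agreement_tol: float = 10.0         # multi-start mean vertex distance, A
    lowpass_sigma: float = 8.0          # preprocessing low-pass, A
    placement_nodes: int = 100          # elastic-ring nodes for placement
    placement_epochs: int = 80
    stage_blur_fraction: float = 0.1    # extra stage blur, x edge length
    edge_sampling: bool = False         # also sample density at edge midpoints
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_init < 3:
            raise ValueError("n_init must be >= 3")
        k = self.n_final / self.n_init
        if k < 1 or abs(k - 2 ** round(np.log2(k))) > 1e-9:
            raise ValueError("n_final must be n_init * 2**k for integer k")
        if min(self.w_density, self.w_length, self.w_angle) < 0:
            raise ValueError("score weights must be non-negative")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass
class ScoreBreakdown:
    """Score components of a polygon against a volume (higher is better)."""

    total: float
    density: float
    length_penalty: float
    angle_penalty: float


@dataclass
class TraceResult:
    """Fitted trace with its diagnostics.

    Attributes
    ----------
    curve : ClosedCurve
        Best-scoring fitted polygon (n_final vertices).
    score : ScoreBreakdown
    stage_iterations : list of int
        Gradient-ascent iterations used in each refinement stage.
    agreement : float
        Mean vertex distance (Angstroms) between the best start and the
        other starts, after cyclic/orientation alignment; 0.0 when only one
        start was run.
    converged : bool
        True when the starts agree to within ``agreement_tol`` (multi-start)
        or the single start's refinement converged.
    """

    curve: ClosedCurve
    score: ScoreBreakdown
    stage_iterations: list = field(default_factory=list)
    agreement: float = 0.0
    converged: bool = True
    n_starts: int = 1
    start_scores: list = field(default_factory=list)
    config: TracerConfig | None = None

    def summary(self) -> str:
        c = self.config or TracerConfig()
        lines = [
            "Minicircle trace",
            "=" * 44,
            f"vertices              {self.curve.n_vertices:>10d}",
            f"perimeter (A)         {self.curve.arc_length():>10.1f}",
            f"expected contour (A)  {c.contour_length:>10.1f}",
            f"score (total)         {self.score.total:>10.3f}",
            f"  density term        {self.score.density:>10.3f}",
            f"  length penalty      {self.score.length_penalty:>10.3f}",
            f"  angle penalty       {self.score.angle_penalty:>10.3f}",
            f"starts                {self.n_starts:>10d}",
            f"agreement (A)         {self.agreement:>10.2f}",
            f"converged             {str(self.converged):>10s}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(volume: DensityVolume, config: TracerConfig | None = None
               ) -> DensityVolume:
    """Normalize, low-pass filter, and strip disconnected density.

    The volume is Gaussian low-pass filtered (``lowpass_sigma`` in
    Angstroms; 0 disables filtering), standardized to zero mean and unit
    standard deviation, and finally all above-threshold connected
    components except the largest are zeroed (threshold = mean + 1 sd of
    the filtered volume, i.e. 1.0 after standardization; 26-connectivity).
    """
    config = config or TracerConfig()
    data = volume.data.astype(np.float64)
    if data.std() == 0:
        raise ValueError("no density: volume is constant")
    if config.lowpass_sigma > 0:
        data = ndimage.gaussian_filter(
            data, sigma=config.lowpass_sigma / volume.voxel_size)
    data = (data - data.mean()) / data.std()
    mask = data > 1.0
    if mask.any():
        labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), int))
        if n > 1:
            sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                       index=np.arange(1, n + 1))
            keep = 1 + int(np.argmax(sizes))
            data[(labels != 0) & (labels != keep)] = 0.0
    return DensityVolume(data.astype(np.float32), volume.voxel_size,
                         volume.origin.copy())


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _check_inside(curve: ClosedCurve, volume: DensityVolume) -> None:
    inside = volume.contains(curve.vertices)
    if not inside.all():
        bad = int(np.nonzero(~inside)[0][0])
        raise ValueError(f"vertex {bad} at {curve.vertices[bad]} lies "
                         f"outside the volume")


def _interior_angles(v: np.ndarray) -> np.ndarray:
    u = np.roll(v, 1, axis=0) - v     # towards previous vertex
    w = np.roll(v, -1, axis=0) - v    # towards next vertex
    nu = np.linalg.norm(u, axis=1)
    nw = np.linalg.norm(w, axis=1)
    cos = np.sum(u * w, axis=1) / np.maximum(nu * nw, 1e-30)
    return np.arccos(np.clip(cos, -1.0, 1.0))


def score_polygon(curve: ClosedCurve, volume: DensityVolume,
                  config: TracerConfig) -> ScoreBreakdown:
    """Score = w_d * sum rho(v_i) - w_l * sum (|e_i| - Lbar)^2
    - w_a * sum (theta_i - theta_bar)^2.

    ``Lbar`` is the expected contour length divided by the vertex count and
    ``theta_bar = pi - 2 pi / n`` the regular-polygon interior angle.  With
    ``edge_sampling`` enabled, density is additionally averaged over edge
    midpoints (off by default; the score samples density at vertices only).
    """
    _check_inside(curve, volume)
    v = curve.vertices
    n = len(v)
    dens = float(np.sum(volume.interpolate(v)))
    if config.edge_sampling:
        mid = 0.5 * (v + np.roll(v, -1, axis=0))
        dens = 0.5 * (dens + float(np.sum(volume.interpolate(mid))))
    lbar = config.contour_length / n
    len_pen = float(np.sum((curve.edge_lengths - lbar) ** 2))
    tbar = np.pi - 2 * np.pi / n
    ang_pen = float(np.sum((_interior_angles(v) - tbar) ** 2))
    total = (config.w_density * dens - config.w_length * len_pen
             - config.w_angle * ang_pen)
    return ScoreBreakdown(total=total, density=config.w_density * dens,
                          length_penalty=config.w_length * len_pen,
                          angle_penalty=config.w_angle * ang_pen)


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------

def _density_gradient(v: np.ndarray, volume: DensityVolume,
                      config: TracerConfig) -> np.ndarray:
    """Central finite differences of interpolated density at each vertex."""
    h = 0.5 * volume.voxel_size
    probes = np.repeat(v[None, :, :], 6, axis=0)
    for k in range(3):
        probes[2 * k, :, k] += h
        probes[2 * k + 1, :, k] -= h
    vals = volume.interpolate(probes.reshape(-1, 3)).reshape(6, -1)
    g = np.empty_like(v)
    for k in range(3):
        g[:, k] = (vals[2 * k] - vals[2 * k + 1]) / (2 * h)
    return g


def _length_penalty_gradient(v: np.ndarray, lbar: float) -> np.ndarray:
    e = np.roll(v, -1, axis=0) - v
    el = np.linalg.norm(e, axis=1)
    u = e / np.maximum(el, 1e-30)[:, None]
    coef = 2.0 * (el - lbar)
    # d/dv_k: edge (k-1,k) contributes +coef*u, edge (k,k+1) contributes -coef*u
    return (np.roll(coef, 1)[:, None] * np.roll(u, 1, axis=0)
            - coef[:, None] * u)


def _angle_penalty_gradient(v: np.ndarray, tbar: float) -> np.ndarray:
    u = np.roll(v, 1, axis=0) - v
    w = np.roll(v, -1, axis=0) - v
    nu = np.maximum(np.linalg.norm(u, axis=1), 1e-30)
    nw = np.maximum(np.linalg.norm(w, axis=1), 1e-30)
    cos = np.clip(np.sum(u * w, axis=1) / (nu * nw), -1.0, 1.0)
    # floor on sin(theta) caps the gradient near degenerate angles, where
    # the exact 1/sin factor would otherwise dominate every other force
    sin = np.maximum(np.sqrt(np.maximum(1.0 - cos ** 2, 0.0)), 0.1)
    theta = np.arccos(cos)
    # d(theta)/du and d(theta)/dw
    du = -(w / (nu * nw)[:, None] - (cos / nu ** 2)[:, None] * u) / sin[:, None]
    dw = -(u / (nu * nw)[:, None] - (cos / nw ** 2)[:, None] * w) / sin[:, None]
    coef = 2.0 * (theta - tbar)
    grad = np.zeros_like(v)
    grad += coef[:, None] * (-(du + dw))           # dtheta_i / dv_i
    grad += np.roll(coef[:, None] * du, -1, axis=0)  # dtheta_{i+1}/dv_i ...
    grad += np.roll(coef[:, None] * dw, 1, axis=0)
    return grad


def _score_gradient(v: np.ndarray, volume: DensityVolume,
                    config: TracerConfig) -> np.ndarray:
    n = len(v)
    lbar = config.contour_length / n
    tbar = np.pi - 2 * np.pi / n
    ramp = _penalty_ramp(n, config)
    g = config.w_density * _density_gradient(v, volume, config)
    g -= config.w_length * ramp * _length_penalty_gradient(v, lbar)
    g -= config.w_angle * ramp * _angle_penalty_gradient(v, tbar)
    return g


def _penalty_ramp(n: int, config: TracerConfig) -> float:
    """Scale the restoring forces with stage resolution.

    At coarse vertex counts a correct compact trace is necessarily far from
    the regular polygon: a folded conformation sampled at 5 vertices has
    near-degenerate angles, and its chords under-measure the contour, so
    full-strength angle/length forces would unfold it.  The weights ramp
    quadratically to full strength at ``n_final``.
    """
    return min(1.0, (n / config.n_final) ** 2)


# ---------------------------------------------------------------------------
# refinement
# ---------------------------------------------------------------------------

def subdivide(curve: ClosedCurve) -> ClosedCurve:
    """Double the vertex count by edge-midpoint insertion (polyline
    preserved; see :meth:`ClosedCurve.subdivide`)."""
    return curve.subdivide()


def refine(curve: ClosedCurve, volume: DensityVolume, config: TracerConfig
           ) -> tuple[ClosedCurve, int, bool]:
    """Gradient-ascent refinement of a polygon at fixed vertex count.

    Every iteration moves all vertices along the score gradient; the step
    is scaled so the largest vertex displacement is ``step_size`` and is
    halved (backtracking) while the total score would decrease.  Stops when
    the relative score improvement falls below ``convergence_tol`` or after
    ``max_iters`` iterations.  The returned score never falls below the
    input score.  Vertices pushed outside the volume are clamped to the
    boundary; if more than half the vertices are clamped the refinement is
    flagged non-converged.

    Returns ``(curve, n_iterations, converged)``.
    """
    _check_inside(curve, volume)
    v = curve.vertices.copy()
    lo = volume.origin
    hi = volume.origin + (np.array(volume.shape) - 1) * volume.voxel_size

    # stage-consistent objective: the penalty weights ramp with resolution,
    # and the backtracking accept/reject must match the ascended gradient
    ramp = _penalty_ramp(len(v), config)

    def stage_score(vv: np.ndarray) -> float:
        sb = score_polygon(ClosedCurve(vv), volume, config)
        return sb.total + (1.0 - ramp) * (sb.angle_penalty
                                          + sb.length_penalty)

    score = stage_score(v)
    converged = False
    it = 0
    for it in range(1, config.max_iters + 1):
        g = _score_gradient(v, volume, config)
        norms = np.linalg.norm(g, axis=1)
        gmax = norms.max()
        if gmax < 1e-12:
            converged = True
            break
        # every vertex moves step_size along its own gradient direction
        d = g * (config.step_size / np.maximum(norms, 1e-12))[:, None]
        accepted = False
        for _ in range(10):
            vn = np.clip(v + d, lo, hi)
            clamped = np.any((v + d) != vn, axis=1)
            new_score = stage_score(vn)
            if new_score >= score:
                accepted = True
                break
            d *= 0.5
        if not accepted:
            converged = True
            break
        if clamped.mean() > 0.5:
            converged = False
            v = vn
            score = new_score
            break
        rel = (new_score - score) / max(abs(score), 1e-12)
        v, score = vn, new_score
        if rel < config.convergence_tol:
            converged = True
            break
    return ClosedCurve(v), it, converged


# ---------------------------------------------------------------------------
# initialization and full trace
# ---------------------------------------------------------------------------

def _density_moments(volume: DensityVolume) -> tuple[np.ndarray, np.ndarray,
                                                     np.ndarray]:
    """Weighted centroid and covariance eigendecomposition of the
    above-threshold density (threshold = mean + 1 sd)."""
    data = volume.data.astype(np.float64)
    thr = data.mean() + data.std()
    mask = data > thr
    if not mask.any():
        raise ValueError("no above-threshold density to initialize from")
    idx = np.argwhere(mask)
    w = data[mask] - thr
    pts = volume.index_to_world(idx)
    ctr = np.average(pts, axis=0, weights=w)
    c = pts - ctr
    cov = (c * w[:, None]).T @ c / w.sum()
    evals, evecs = np.linalg.eigh(cov)
    return ctr, evals[::-1], evecs[:, ::-1]


def _initial_polygon(volume: DensityVolume, config: TracerConfig,
                     rotation: np.ndarray | None) -> ClosedCurve:
    ctr, evals, evecs = _density_moments(volume)
    radius = float(np.sqrt(max(evals[0], 0) + max(evals[1], 0)))
    radius = max(radius, 2 * volume.voxel_size)
    t = np.linspace(0, 2 * np.pi, config.n_init, endpoint=False)
    ring = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)]) * radius
    frame = evecs  # columns: principal axes
    if rotation is not None:
        frame = frame @ rotation
    v = ring @ frame.T + ctr
    lo = volume.origin
    hi = volume.origin + (np.array(volume.shape) - 1) * volume.voxel_size
    return ClosedCurve(np.clip(v, lo, hi))


def _density_cloud(volume: DensityVolume) -> tuple[np.ndarray, np.ndarray]:
    """Above-threshold voxel positions and excess-density weights.

    Restricted to the largest connected component so scattered noise
    voxels cannot distract the elastic-ring placement.
    """
    data = volume.data.astype(np.float64)
    thr = data.mean() + data.std()
    mask = data > thr
    if not mask.any():
        raise ValueError("no above-threshold density to initialize from")
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), int))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    pts = volume.index_to_world(np.argwhere(mask))
    return pts, data[mask] - thr


def _elastic_ring(volume: DensityVolume, config: TracerConfig,
                  rotation: np.ndarray | None) -> ClosedCurve:
    """Fit a closed elastic ring to the density point cloud.

    A cyclic chain of nodes is initialized as a circle in the density's
    principal plane (optionally re-oriented per start) and updated by batch
    self-organizing-map iterations: every above-threshold voxel is assigned
    to its nearest node and each node moves to the kernel-weighted mean of
    the assignments of its ring neighbourhood, with the neighbourhood width
    shrinking geometrically.  The wide-kernel early epochs make the basin of
    attraction global, so the ring discovers the correct closed tour even
    for compact conformations with juxtaposed strands; the score-based
    refinement stages then polish the geometry locally.
    """
    pts, w = _density_cloud(volume)
    ctr, evals, evecs = _density_moments(volume)
    radius = max(float(np.sqrt(max(evals[0], 0) + max(evals[1], 0))),
                 2 * volume.voxel_size)
    m = config.placement_nodes
    t = np.linspace(0, 2 * np.pi, m, endpoint=False)
    ring = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)]) * radius
    frame = evecs if rotation is None else evecs @ rotation
    nodes = ring @ frame.T + ctr

    dj = np.abs(np.arange(m)[:, None] - np.arange(m)[None, :])
    dj = np.minimum(dj, m - dj)
    epochs = config.placement_epochs
    sig0, sig1 = m / 2.0, 0.8
    for e in range(epochs):
        sig = sig0 * (sig1 / sig0) ** (e / max(epochs - 1, 1))
        kernel = np.exp(-0.5 * (dj / sig) ** 2)
        _, assign = cKDTree(nodes).query(pts)
        sw = np.bincount(assign, weights=w, minlength=m)
        sx = np.column_stack([
            np.bincount(assign, weights=w * pts[:, k], minlength=m)
            for k in range(3)])
        denom = kernel @ sw
        nodes = (kernel @ sx) / denom[:, None]
    return ClosedCurve(nodes)


def _stage_volumes(volume: DensityVolume, config: TracerConfig) -> dict:
    """Per-stage refinement volumes, blurred to the stage's resolution.

    After a subdivision, freshly inserted edge midpoints can sit far from
    the tube where the sharp map offers no gradient (and, with noise, a
    misleading one); blurring by a fraction of the stage's edge length
    extends the capture range to match.  The initial stage (whose polygon
    comes straight from the elastic-ring placement, already on the tube)
    and the final polishing stage both use the unblurred volume.
    """
    out = {config.n_init: volume, config.n_final: volume}
    n = config.n_init * 2
    while n < config.n_final:
        sigma = config.stage_blur_fraction * config.contour_length / n
        if sigma > 0:
            data = ndimage.gaussian_filter(volume.data.astype(np.float64),
                                           sigma=sigma / volume.voxel_size)
            sd = data.std()
            if sd > 0:
                data = (data - data.mean()) / sd
            out[n] = DensityVolume(data.astype(np.float32),
                                   volume.voxel_size, volume.origin.copy())
        else:
            out[n] = volume
        n *= 2
    return out


def _single_start(volume: DensityVolume, config: TracerConfig,
                  rotation: np.ndarray | None,
                  stage_volumes: dict | None = None
                  ) -> tuple[ClosedCurve, list, bool]:
    stage_volumes = stage_volumes or _stage_volumes(volume, config)
    curve = _elastic_ring(volume, config, rotation).resample(config.n_init)
    iters = []
    conv = True
    n = config.n_init
    while True:
        curve, it, ok = refine(curve, stage_volumes[n], config)
        iters.append(it)
        conv = conv and ok
        if n >= config.n_final:
            break
        curve = subdivide(curve)
        n *= 2
    return curve, iters, conv


def trace(volume: DensityVolume, config: TracerConfig | None = None,
          seed: int | None = None) -> TraceResult:
    """Trace a minicircle backbone in a preprocessed volume.

    Runs ``n_starts`` independent initializations (the first aligned with
    the density's principal axes, the rest uniformly randomly oriented),
    refines each through the 5 -> 10 -> 20 vertex-doubling schedule, and
    returns the best-scoring polygon.  Agreement is the mean cyclic-aligned
    vertex distance between the best start and the others; the result is
    converged when agreement < ``agreement_tol``.
    """
    config = config or TracerConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    stage_volumes = _stage_volumes(volume, config)
    results = []
    for s in range(config.n_starts):
        rot = None if s == 0 else _random_rotation(rng)
        curve, iters, conv = _single_start(volume, config, rot,
                                           stage_volumes)
        score = score_polygon(curve, volume, config)
        results.append((score.total, curve, iters, conv, score))
    best_i = int(np.argmax([r[0] for r in results]))
    _, best_curve, best_iters, best_conv, best_score = results[best_i]
    if config.n_starts > 1:
        # compare on a finer resampling so sub-edge phase offsets between
        # otherwise identical traces do not inflate the distance
        n_cmp = 5 * config.n_final
        best_f = best_curve.resample(n_cmp)
        dists = [align_closed_curves(best_f, r[1].resample(n_cmp))[0]
                 for i, r in enumerate(results) if i != best_i]
        agreement = float(np.mean(dists))
        converged = agreement < config.agreement_tol
    else:
        agreement = 0.0
        converged = best_conv
    return TraceResult(curve=best_curve, score=best_score,
                       stage_iterations=best_iters, agreement=agreement,
                       converged=converged, n_starts=config.n_starts,
                       start_scores=[r[0] for r in results], config=config)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


class Tracer:
    """Model object: fit a closed backbone polygon to a density volume.

    Parameters
    ----------
    volume : DensityVolume
        Subvolume containing a single minicircle.
    contour_length : float, optional
        Expected backbone length in Angstroms (e.g. 336 bp x 3.4 A/bp);
        overrides ``config.contour_length``.
    config : TracerConfig, optional
    preprocess : bool
        Normalize/filter/clean the volume before fitting (default True);
        pass False if the volume has already been preprocessed.

    Examples
    --------
    >>> model = Tracer(volume, contour_length=336 * 3.4)
    >>> result = model.fit(seed=0)
    >>> print(result.summary())
    """

    def __init__(self, volume: DensityVolume,
                 contour_length: float | None = None,
                 config: TracerConfig | None = None,
                 preprocess: bool = True) -> None:
        self.config = config or TracerConfig()
        if contour_length is not None:
            self.config = replace(self.config, contour_length=contour_length)
        self.raw_volume = volume
        self.volume = (globals()["preprocess"](volume, self.config)
                       if preprocess else volume)

    @classmethod
    def from_bp(cls, volume: DensityVolume, n_bp: int, rise: float = 3.4,
                **kw) -> "Tracer":
        """Construct with the contour length of an ``n_bp`` circle."""
        return cls(volume, contour_length=n_bp * rise, **kw)

    def fit(self, seed: int | None = None) -> TraceResult:
        return trace(self.volume, self.config, seed=seed)
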