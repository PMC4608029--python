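"""Topology of closed DNA curves and minicircle topoisomer bookkeeping.

Covers the standard supercoiling quantities: the linking number Lk of a
covalently closed duplex, its relaxed reference Lk0 ~ n_bp / helical repeat,
the deviation dLk = Lk - Lk0, the superhelical density sigma = dLk / Lk0,
and the partition Lk = Tw + Wr between twist and writhe.  Writhe is
evaluated on a closed polygonal curve by the exact segment-pair solid-angle
form of the Gauss double integral.  Also included: signed projected
crossings (crossover handedness), the parity model of type-II topoisomerase
relaxation (steps of two in Lk), and circular restriction-fragment mapping
of a cleavage site.

Sign convention: a right-handed crossover (the geometry of negatively
supercoiled DNA) carries node sign -1, so underwound conformations have
Wr < 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import ClosedCurve

__all__ = [
    "Topoisomer", "CrossingRecord", "relaxed_lk", "writhe", "twist_of",
    "sigma", "crossing_signs", "projected_writhe", "relax_steps_of_two",
    "fragment_length_from_migration", "map_cleavage_site",
]


# ---------------------------------------------------------------------------
# topoisomer arithmetic
# ---------------------------------------------------------------------------

def relaxed_lk(n_bp: int, helical_repeat: float = 10.5) -> int:
    """Linking number of the torsionally relaxed circle.

    Nearest integer to ``n_bp / helical_repeat``; exact half-integer ties
    round away from zero (never reached for the standard constructs:
    336 bp / 10.5 = 32 exactly).
    """
    if n_bp <= 0:
        raise ValueError("n_bp must be positive")
    if helical_repeat <= 0:
        raise ValueError("helical_repeat must be positive")
    x = n_bp / helical_repeat
    return int(np.floor(x + 0.5)) if x >= 0 else int(np.ceil(x - 0.5))


def sigma(dLk: float, Lk0: int) -> float:
    """Superhelical density dLk / Lk0."""
    if Lk0 == 0:
        raise ValueError("Lk0 must be nonzero")
    return dLk / Lk0


def twist_of(topo: "Topoisomer", wr: float) -> float:
    """Twist from conservation of linking number: Tw = Lk - Wr."""
    return topo.Lk - wr


@dataclass
class Topoisomer:
    """Topological bookkeeping for one minicircle species.

    ``Lk0`` is derived from the base-pair count and helical repeat;
    ``dLk = Lk - Lk0`` and ``sigma = dLk / Lk0`` follow.
    """

    n_bp: int
    Lk: int
    helical_repeat: float = 10.5

    def __post_init__(self) -> None:
        if self.n_bp <= 0:
            raise ValueError("n_bp must be positive")

    @property
    def Lk0(self) -> int:
        return relaxed_lk(self.n_bp, self.helical_repeat)

    @property
    def dLk(self) -> int:
        return self.Lk - self.Lk0

    @property
    def sigma(self) -> float:
        return sigma(self.dLk, self.Lk0)

    def twist(self, wr: float) -> float:
        return twist_of(self, wr)


def relax_steps_of_two(Lk: int, Lk0: int) -> frozenset:
    """Terminal dLk values reachable by a type-II topoisomerase.

    Type-II enzymes change Lk in steps of two, so relaxation minimises
    ``|Lk - Lk0|`` while preserving the parity of Lk: when Lk and Lk0 share
    parity the unique terminus is dLk = 0; otherwise the enzyme ends at a
    mixture of dLk = -1 and +1.
    """
    if (Lk - Lk0) % 2 == 0:
        return frozenset({0})
    return frozenset({-1, +1})


# ---------------------------------------------------------------------------
# writhe
# ---------------------------------------------------------------------------

def writhe(curve: ClosedCurve) -> float:
    """Writhe of a closed polygonal curve.

    Evaluates the Gauss double integral exactly for a polygon: every
    ordered pair of non-adjacent segments contributes the signed solid
    angle of the quadrilateral spanned by the segment endpoints (the
    closed-form expression of Levitt / Klenin & Langowski), divided by
    4 pi.  Adjacent segments (sharing a vertex) contribute zero.
    """
    v = curve.vertices
    n = len(v)
    if n < 4:
        raise ValueError("writhe needs at least 4 vertices")
    e = np.roll(v, -1, axis=0) - v
    elen = np.linalg.norm(e, axis=1)
    bad = np.nonzero(elen < 1e-12)[0]
    if bad.size:
        raise ValueError(f"degenerate zero-length segments at indices "
                         f"{bad.tolist()}")
    total = 0.0
    for i in range(n - 2):
        jmax = n - 1 if i > 0 else n - 2  # skip the wrap-around adjacency
        j = np.arange(i + 2, jmax + 1)
        total += _solid_angle_pairs(v[i], v[i + 1], v[j], v[(j + 1) % n]).sum()
    # Wr = (1/4pi) * sum over ordered pairs = (1/2pi) * sum over i<j
    return float(total / (2.0 * np.pi))


def _solid_angle_pairs(p1: np.ndarray, p2: np.ndarray,
                       p3: np.ndarray, p4: np.ndarray) -> np.ndarray:
    """Signed solid angle subtended by segment pair (p1,p2) x (p3[k],p4[k]).

    The Gauss-integral contribution of a segment pair equals the signed
    spherical area swept by the unit vector between points of the two
    segments: a spherical quadrilateral with corners at the normalized
    endpoint-difference directions.  The area is evaluated as two spherical
    triangles with the van Oosterom-Strackee atan2 formula, which has no
    branch ambiguities for coplanar or (anti)parallel segments (where
    arcsine-based closed forms break down).
    """
    p3 = np.atleast_2d(p3)
    p4 = np.atleast_2d(p4)

    def _unit(x):
        nrm = np.linalg.norm(x, axis=-1, keepdims=True)
        return np.divide(x, nrm, out=np.zeros_like(x), where=nrm > 1e-30)

    # spherical quadrilateral corners, oriented to match the Gauss
    # integral's sign convention (right-handed crossover => negative)
    a = _unit(p3 - p1)
    d = _unit(p4 - p1)
    c = _unit(p4 - p2)
    b = _unit(p3 - p2)

    def _tri(u, v, w):
        num = np.sum(u * np.cross(v, w), axis=-1)
        den = (1.0 + np.sum(u * v, axis=-1) + np.sum(v * w, axis=-1)
               + np.sum(w * u, axis=-1))
        return 2.0 * np.arctan2(num, den)

    return _tri(a, b, c) + _tri(a, c, d)


def writhe_brute_force(curve: ClosedCurve, refine: int = 1) -> float:
    """Discretized Gauss double integral (midpoint rule) over segment pairs.

    Independent of :func:`writhe`; used as a numerical oracle.  ``refine``
    resamples the curve to ``refine * n`` vertices first.
    """
    c = curve.resample(refine * curve.n_vertices) if refine > 1 else curve
    v = c.vertices
    n = len(v)
    mid = 0.5 * (v + np.roll(v, -1, axis=0))
    t = np.roll(v, -1, axis=0) - v
    total = 0.0
    for i in range(n):
        r = mid[i] - mid
        d3 = np.linalg.norm(r, axis=1) ** 3
        cross = np.cross(t[i], t)
        integrand = np.sum(cross * r, axis=1)
        mask = d3 > 1e-12
        js = np.nonzero(mask)[0]
        js = js[(js != i) & (js != (i - 1) % n) & (js != (i + 1) % n)]
        total += np.sum(integrand[js] / d3[js])
    return float(total / (4.0 * np.pi))


# ---------------------------------------------------------------------------
# projected crossings
# ---------------------------------------------------------------------------

@dataclass
class CrossingRecord:
    """A transversal self-crossing of the curve projected along an axis.

    ``s_over`` / ``s_under`` are contour parameters (vertex index scale) of
    the strand nearer / farther along the projection axis; ``sign`` follows
    the node convention (right-handed crossover = -1).
    """

    axis: np.ndarray
    s_over: float
    s_under: float
    sign: int
    ambiguous: bool = False


def _projection_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    w = np.asarray(axis, dtype=float)
    w = w / np.linalg.norm(w)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, w)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(helper, w)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return u, v, w


def crossing_signs(curve: ClosedCurve, axis) -> list[CrossingRecord]:
    """Signed self-crossings of the curve projected along ``axis``.

    Projects the polygon onto the plane perpendicular to the (unit) axis,
    finds all transversal intersections between non-adjacent edges, and
    assigns each the standard chirality sign: with tangents t_o (strand
    passing over, i.e. nearer along +axis) and t_u (under), the sign is
    ``sign((t_o x t_u) . axis)``.  Near-tangential crossings are flagged
    ambiguous and excluded from the projected-writhe sum.
    """
    u, v, w = _projection_basis(axis)
    pts = curve.vertices
    n = len(pts)
    xy = np.column_stack([pts @ u, pts @ v])
    h = pts @ w
    nxt = (np.arange(n) + 1) % n
    recs: list[CrossingRecord] = []
    for i in range(n):
        a0, a1 = xy[i], xy[nxt[i]]
        da = a1 - a0
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # wrap-around adjacency
            b0, b1 = xy[j], xy[nxt[j]]
            db = b1 - b0
            denom = da[0] * db[1] - da[1] * db[0]
            if abs(denom) < 1e-12:
                continue
            diff = b0 - a0
            s = (diff[0] * db[1] - diff[1] * db[0]) / denom
            t = (diff[0] * da[1] - diff[1] * da[0]) / denom
            # closed interval with slack so crossings falling exactly on a
            # vertex are not lost; coincident duplicates are merged below
            eps = 1e-9
            if not (-eps <= s <= 1 + eps and -eps <= t <= 1 + eps):
                continue
            # chirality from heights along the axis at the crossing point
            ha = h[i] + s * (h[nxt[i]] - h[i])
            hb = h[j] + t * (h[nxt[j]] - h[j])
            ta3 = pts[nxt[i]] - pts[i]
            tb3 = pts[nxt[j]] - pts[j]
            cos_cross = abs(denom) / (np.linalg.norm(da) * np.linalg.norm(db))
            ambiguous = (cos_cross < 1e-6) or (abs(ha - hb) < 1e-9)
            if ha >= hb:
                t_over, t_under, so, su = ta3, tb3, i + s, j + t
            else:
                t_over, t_under, so, su = tb3, ta3, j + t, i + s
            sgn = int(np.sign(np.dot(np.cross(t_over, t_under), w)))
            recs.append(CrossingRecord(axis=w.copy(), s_over=so, s_under=su,
                                       sign=sgn, ambiguous=ambiguous))
    return _dedupe_crossings(recs, n)


def _dedupe_crossings(recs: list[CrossingRecord], n: int,
                      tol: float = 1e-6) -> list[CrossingRecord]:
    """Merge records describing the same geometric crossing (possible when
    an intersection falls exactly on a polygon vertex)."""
    out: list[CrossingRecord] = []
    for r in recs:
        dup = False
        for q in out:
            da = min(abs(r.s_over - q.s_over) % n,
                     n - abs(r.s_over - q.s_over) % n)
            db = min(abs(r.s_under - q.s_under) % n,
                     n - abs(r.s_under - q.s_under) % n)
            if max(da, db) < max(tol * n, 1e-3):
                dup = True
                break
        if not dup:
            out.append(r)
    return out


def projected_writhe(curve: ClosedCurve, axis) -> int:
    """Sum of crossing signs in the projection along ``axis``
    (ambiguous crossings excluded)."""
    return sum(r.sign for r in crossing_signs(curve, axis) if not r.ambiguous)


# ---------------------------------------------------------------------------
# gel migration and cleavage mapping
# ---------------------------------------------------------------------------

def fragment_length_from_migration(ladder, distance: float,
                                   allow_extrapolation: bool = False) -> float:
    """Fragment size (bp) from gel migration against a ladder standard.

    Fits log10(bp) as a linear least-squares function of migration distance
    over the ladder bands and evaluates the fit at ``distance``.  Distances
    outside the ladder span are refused unless ``allow_extrapolation``.
    """
    ladder = [(float(bp), float(d)) for bp, d in ladder]
    if len(ladder) < 2:
        raise ValueError("ladder needs at least 2 bands")
    bp = np.array([b for b, _ in ladder])
    dist = np.array([d for _, d in ladder])
    if np.any(bp <= 0):
        raise ValueError("ladder band sizes must be positive")
    lo, hi = dist.min(), dist.max()
    if not (lo <= distance <= hi) and not allow_extrapolation:
        raise ValueError(
            f"distance {distance} outside ladder span [{lo}, {hi}]; "
            f"pass allow_extrapolation=True to extrapolate")
    slope, intercept = np.polyfit(dist, np.log10(bp), 1)
    return float(10.0 ** (slope * distance + intercept))


def map_cleavage_site(circle_bp: int, enzyme_sites: dict,
                      fragments: dict, tolerance_bp: float = 10.0):
    """Locate a single cleavage site on a circle from double-digest fragments.

    Each enzyme cuts once at a known position; cutting the (already
    linearized) circle with it yields two fragments whose sizes place the
    unknown cleavage site at ``site +- fragment`` — two candidate positions
    per enzyme.  Intersecting candidates across enzymes pins the site down.

    Parameters
    ----------
    circle_bp : int
        Circle size in bp.
    enzyme_sites : dict
        ``{enzyme: position_bp}`` of each restriction site on the circle.
    fragments : dict
        ``{enzyme: (size1, size2)}`` double-digest fragment sizes; the two
        sizes must sum to ``circle_bp`` within ``tolerance_bp``.
    tolerance_bp : float
        Fragment-size measurement tolerance.

    Returns
    -------
    dict with keys ``positions`` (sorted consistent integer positions),
    ``interval`` ((start, end) circular interval containing them),
    ``width`` (bp), ``estimate`` (circular midpoint) and ``ambiguous``
    (True when a single enzyme leaves two disjoint candidates).
    """
    if not fragments:
        raise ValueError("no fragment data supplied")
    for enz, sizes in fragments.items():
        if enz not in enzyme_sites:
            raise ValueError(f"no site position for enzyme {enz!r}")
        if len(sizes) != 2:
            raise ValueError(f"enzyme {enz!r}: expected two fragment sizes")
        if abs(sum(sizes) - circle_bp) > 2 * tolerance_bp:
            raise ValueError(
                f"enzyme {enz!r}: fragments {sizes} do not sum to "
                f"{circle_bp} bp within tolerance")

    def circ_dist(a, b):
        d = abs(a - b) % circle_bp
        return min(d, circle_bp - d)

    positions = np.arange(circle_bp)
    ok = np.ones(circle_bp, dtype=bool)
    for enz, sizes in fragments.items():
        site = enzyme_sites[enz] % circle_bp
        # a cut at p splits the circle at {site, p}: arc lengths are
        # (p - site) mod N and (site - p) mod N
        arc = (positions - site) % circle_bp
        match = np.zeros(circle_bp, dtype=bool)
        for f in sizes:
            match |= np.abs(arc - f) <= tolerance_bp
            match |= np.abs(arc - (circle_bp - f)) <= tolerance_bp
        ok &= match
    hits = np.nonzero(ok)[0]
    if hits.size == 0:
        raise ValueError("inconsistent fragments: no circle position is "
                         "compatible with every digest")

    # smallest circular interval covering the hits
    hs = np.sort(hits)
    gaps = np.diff(np.concatenate([hs, [hs[0] + circle_bp]]))
    k = int(np.argmax(gaps))
    start = int(hs[(k + 1) % len(hs)])
    end = int(hs[k])
    width = (end - start) % circle_bp + 1
    mid = (start + ((end - start) % circle_bp) / 2.0) % circle_bp
    # ambiguity: two well-separated clusters (single-enzyme case)
    ambiguous = bool(len(fragments) < 2 and hits.size > 1 and
                     (np.sort(gaps)[-2] if len(gaps) > 1 else 0) >
                     4 * tolerance_bp)
    return {"positions": hits.tolist(), "interval": (start, end),
            "width": int(width), "estimate": float(mid),
            "ambiguous": ambiguous}
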