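"""Tumor region-of-interest geometry.

An ROI is defined by a handful of manually placed control points; a closed
interpolating curve through them is produced with Hobby's algorithm, the
spline scheme (used by METAFONT/MetaPost) that chooses Bézier control
points so that curvature varies as gently as possible through the knots.
The curve is discretized to a dense boundary polygon and rasterized to a
mask at any requested pixel pitch.

Hobby's construction, for a closed knot sequence z_0 … z_{n−1} with unit
tension: with chord lengths d_k = |z_{k+1} − z_k| and turning angles
ψ_k between consecutive chords, the departure angles θ_k (tangent
direction relative to the outgoing chord) solve the cyclic tridiagonal
system obtained by matching the "mock curvature" of adjacent cubics,

    d_k θ_{k−1} + 2(d_{k−1} + d_k) θ_k + d_{k−1} θ_{k+1}
        = −(2 d_k ψ_k + d_{k−1} ψ_{k+1}),

after which the arrival angles are φ_k = −ψ_k − θ_k and each span becomes
a cubic Bézier with handle lengths given by Hobby's velocity function.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["ROI", "hobby_closed_spline", "roi_from_control_points"]


def _hobby_velocity(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Hobby's rho(theta, phi): Bézier handle length as a fraction of d/3."""
    a = np.sqrt(2.0)
    b = 1.0 / 16.0
    c = 0.5 * (3.0 - np.sqrt(5.0))
    num = 2.0 + a * (np.sin(theta) - b * np.sin(phi)) * (np.sin(phi) - b * np.sin(theta)) * (np.cos(theta) - np.cos(phi))
    den = 1.0 + (1.0 - c) * np.cos(theta) + c * np.cos(phi)
    return num / den


def hobby_closed_spline(points: np.ndarray, samples_per_span: int = 64) -> np.ndarray:
    """Closed Hobby spline through ``points``; returns a dense polyline.

    Parameters
    ----------
    points
        (n, 2) control points, n >= 3, in order around the contour.
    samples_per_span
        Bézier evaluation points per knot span.

    Returns
    -------
    (n * samples_per_span, 2) array tracing the closed curve (the first
    point is not repeated at the end).
    """
    z = np.asarray(points, dtype=float)
    if z.ndim != 2 or z.shape[1] != 2 or len(z) < 3:
        raise ValueError("need at least 3 control points of dimension 2")
    n = len(z)
    nxt = np.roll(np.arange(n), -1)
    chords = z[nxt] - z
    d = np.hypot(chords[:, 0], chords[:, 1])
    if np.any(d == 0):
        raise ValueError("duplicate consecutive control points")
    ang = np.arctan2(chords[:, 1], chords[:, 0])
    # turning angle at knot k: from incoming chord (k-1) to outgoing chord (k)
    psi = ang - np.roll(ang, 1)
    psi = (psi + np.pi) % (2 * np.pi) - np.pi

    # cyclic tridiagonal system for the departure angles theta
    A = np.zeros((n, n))
    rhs = np.zeros(n)
    for k in range(n):
        km, kp = (k - 1) % n, (k + 1) % n
        A[k, km] += d[k]
        A[k, k] += 2.0 * (d[km] + d[k])
        A[k, kp] += d[km]
        rhs[k] = -(2.0 * d[k] * psi[k] + d[km] * psi[kp])
    theta = np.linalg.solve(A, rhs)
    phi = -psi - theta            # arrival angle at knot k (for the span ending there)

    t = np.linspace(0.0, 1.0, samples_per_span, endpoint=False)
    curve = []
    for k in range(n):
        kp = nxt[k]
        th, ph = theta[k], phi[kp]
        rho = _hobby_velocity(th, ph)
        sigma = _hobby_velocity(ph, th)
        dir_out = ang[k] + th
        dir_in = ang[k] - ph
        c1 = z[k] + rho * d[k] / 3.0 * np.array([np.cos(dir_out), np.sin(dir_out)])
        c2 = z[kp] - sigma * d[k] / 3.0 * np.array([np.cos(dir_in), np.sin(dir_in)])
        # cubic Bézier z_k, c1, c2, z_{k+1}
        b = ((1 - t) ** 3)[:, None] * z[k] + (3 * (1 - t) ** 2 * t)[:, None] * c1 \
            + (3 * (1 - t) * t ** 2)[:, None] * c2 + (t ** 3)[:, None] * z[kp]
        curve.append(b)
    return np.vstack(curve)


def _segments_intersect(p1, p2, p3, p4) -> bool:
    def orient(a, b, c):
        return np.sign((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))

    o1, o2 = orient(p1, p2, p3), orient(p1, p2, p4)
    o3, o4 = orient(p3, p4, p1), orient(p3, p4, p2)
    return o1 != o2 and o3 != o4


def _is_simple(poly: np.ndarray, stride: int = 1) -> bool:
    """Check (at polygon resolution) that the closed curve does not
    self-intersect; non-adjacent segment pairs only."""
    pts = poly[::stride]
    n = len(pts)
    segs = [(pts[i], pts[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue
            if _segments_intersect(*segs[i], *segs[j]):
                return False
    return True


@dataclass
class ROI:
    """Closed tumor contour in physical coordinates (mm).

    ``boundary`` is a dense (m, 2) polygon of (z_mm, x_mm) points tracing
    the Hobby spline through the control points.
    """

    boundary: np.ndarray
    control_points: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.boundary = np.asarray(self.boundary, dtype=float)
        if len(self.boundary) < 3:
            raise ValueError("ROI boundary needs at least 3 points")
        if self.area_mm2() <= 0:
            raise ValueError("ROI must enclose a positive area")

    def area_mm2(self) -> float:
        """Enclosed area by the shoelace formula (orientation-independent)."""
        z, x = self.boundary[:, 0], self.boundary[:, 1]
        return float(abs(np.sum(z * np.roll(x, -1) - x * np.roll(z, -1))) / 2.0)

    def rasterize(self, pitch_um: float, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask on a pixel grid of the given pitch (µm) and shape.

        Even-odd fill with pixel-center inclusion: pixel (i, j) is inside
        iff its center (i·pitch, j·pitch) is inside the polygon.  The
        polygon is canonicalized (fixed orientation, coordinates snapped
        to 1e-9 mm) first, so the mask is independent of the direction the
        contour was traced in.
        """
        from matplotlib.path import Path  # lazy: only needed for rasterization

        poly = np.round(self.boundary, 9)
        z, x = poly[:, 0], poly[:, 1]
        if np.sum(z * np.roll(x, -1) - x * np.roll(z, -1)) < 0:
            poly = poly[::-1]
        pitch_mm = pitch_um / 1000.0
        zz, xx = np.meshgrid(np.arange(shape[0]) * pitch_mm,
                             np.arange(shape[1]) * pitch_mm, indexing="ij")
        pts = np.column_stack([zz.ravel(), xx.ravel()])
        inside = Path(poly).contains_points(pts)
        return inside.reshape(shape)

    def to_json(self, path) -> None:
        obj = {"boundary": self.boundary.tolist()}
        if self.control_points is not None:
            obj["control_points"] = np.asarray(self.control_points).tolist()
        with open(path, "w") as f:
            json.dump(obj, f)

    @classmethod
    def from_json(cls, path) -> "ROI":
        with open(path) as f:
            obj = json.load(f)
        cp = obj.get("control_points")
        return cls(boundary=np.asarray(obj["boundary"]),
                   control_points=None if cp is None else np.asarray(cp))


def roi_from_control_points(points: np.ndarray, samples_per_span: int = 64,
                            min_boundary_points: int = 200) -> ROI:
    """Build a tumor ROI from ordered Bézier control points.

    The closed Hobby spline through the points is discretized to at least
    ``min_boundary_points`` boundary samples.  A self-intersecting contour
    is rejected.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        raise ValueError("ROI needs at least 3 control points")
    spans = len(points)
    samples_per_span = max(samples_per_span, int(np.ceil(min_boundary_points / spans)))
    boundary = hobby_closed_spline(points, samples_per_span=samples_per_span)
    if not _is_simple(boundary, stride=max(1, len(boundary) // 256)):
        raise ValueError("control points produce a self-intersecting contour")
    return ROI(boundary=boundary, control_points=points)
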