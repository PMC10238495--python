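"""Persistence length and bending mechanics from skeletonized ridge contours.

Each ridge branch is traced endpoint-to-endpoint along the skeleton, smoothed
with an orientation-searched Gaussian-weighted local fit, and densified by a
parametric cubic spline.  Along the contour the per-segment spacing Ds_k,
tangent angles theta_k, turn angles phi_k and local curvature
kappa ~ 2 phi / (Ds_{k-1} + Ds_k) are computed.  Rescaling the turn angle by
the square root of the adjacent spacing sum gives kappa_s, whose pooled
distribution over many branches is Gaussian for a worm-like chain:

    P(kappa_s) = sqrt(Lp / 4 pi) exp(-Lp kappa_s^2 / 4)

so the variance of kappa_s is 2 / Lp and the effective persistence length is
read off the distribution width.  The flexural rigidity follows as
EI = Lp kB T, and the Euler critical buckling force of a protrusion of
length L is f_c = pi^2 kB T Lp / L^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline
from scipy.optimize import curve_fit
from skimage.morphology import skeletonize

__all__ = ["ContourTrace", "CurvatureSeries", "LpEstimate", "KB",
           "trace_branches", "orient_and_smooth", "spline_interpolate",
           "curvature_series", "fit_lp", "critical_force"]

KB = 1.380649e-23   # Boltzmann constant, J/K


@dataclass
class ContourTrace:
    """Ordered endpoint-to-endpoint coordinates of one skeleton branch (µm)."""

    coords: np.ndarray            # (n, 2) array of (x, y), µm
    branch_id: int = 0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array")
        if len(self.coords) < 10:
            raise ValueError("a contour trace needs at least 10 points")

    @property
    def endpoints(self):
        return self.coords[0], self.coords[-1]


@dataclass
class CurvatureSeries:
    """Spacings, tangent/turn angles and curvature along one contour."""

    ds: np.ndarray        # N spacings Ds_k, µm
    theta: np.ndarray     # N tangent angles, rad
    arc_length: float     # L = sum Ds_k, µm
    phi: np.ndarray       # N-1 turn angles, rad
    kappa: np.ndarray     # N-1 curvatures, 1/µm
    kappa_s: np.ndarray   # N-1 rescaled curvatures, rad/sqrt(µm)


@dataclass
class LpEstimate:
    """Effective persistence length with flexural rigidity EI = Lp kB T."""

    lp: float             # µm
    ei: float             # N m^2
    lp_moment: float      # moment estimate 2 / var(kappa_s), µm
    lp_fit: float | None  # histogram least-squares fit, µm (None if failed)
    temperature: float    # K
    n_segments: int


# ---------------------------------------------------------------------------
# skeleton branch tracing
# ---------------------------------------------------------------------------

# 4-connected neighbors first: when a staircase corner offers both an edge
# and a diagonal continuation, taking the edge neighbor visits every pixel
_NEIGH = [(0, 1), (1, 0), (0, -1), (-1, 0), (1, 1), (1, -1), (-1, 1), (-1, -1)]


def _neighbor_count(skel: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3)); kernel[1, 1] = 0
    return ndimage.convolve(skel.astype(int), kernel, mode="constant")


def _walk_branch(pixels: set, start: tuple) -> list:
    """Walk an 8-connected simple path from one endpoint to the other."""
    path = [start]
    visited = {start}
    current = start
    while True:
        nxt = None
        for dr, dc in _NEIGH:
            cand = (current[0] + dr, current[1] + dc)
            if cand in pixels and cand not in visited:
                nxt = cand
                break
        if nxt is None:
            return path
        path.append(nxt)
        visited.add(nxt)
        current = nxt


def trace_branches(ridge_mask: np.ndarray, dx: float = 1.0, dy: float = 1.0,
                   min_points: int = 10):
    """Skeletonize a ridge mask and trace each branch endpoint to endpoint.

    Branch points (skeleton pixels with more than two 8-neighbors) are
    removed first so every remaining component is a simple arc.  Components
    without endpoints (loops) are skipped and counted; arcs shorter than
    ``min_points`` pixels are dropped.

    Returns ``(traces, n_loops_skipped)`` with coordinates scaled to µm.
    """
    skel = skeletonize(np.asarray(ridge_mask).astype(bool))
    nc = _neighbor_count(skel)
    branch_points = skel & (nc > 2)
    pruned = skel & ~branch_points
    labels, n = ndimage.label(pruned, structure=np.ones((3, 3)))
    traces = []
    n_loops = 0
    branch_id = 0
    for lab in range(1, n + 1):
        rr, cc = np.nonzero(labels == lab)
        if len(rr) < min_points:
            continue
        pixels = set(zip(rr.tolist(), cc.tolist()))
        comp_nc = {}
        for p in pixels:
            comp_nc[p] = sum(((p[0] + d0, p[1] + d1) in pixels) for d0, d1 in _NEIGH)
        endpoints = [p for p, k in comp_nc.items() if k == 1]
        if len(endpoints) != 2:
            if len(endpoints) == 0:
                n_loops += 1
            continue
        start = min(endpoints)   # deterministic orientation
        path = _walk_branch(pixels, start)
        if len(path) < min_points:
            continue
        coords = np.array([(c * dx, r * dy) for r, c in path])
        traces.append(ContourTrace(coords, branch_id))
        branch_id += 1
    return traces, n_loops


# ---------------------------------------------------------------------------
# smoothing and interpolation
# ---------------------------------------------------------------------------

def _gaussian_local_linear(series: np.ndarray, window: int, sigma: float) -> np.ndarray:
    """Gaussian-weighted local linear fit (Savitzky-Golay order 1).

    Exactly reproduces straight lines, including at the trace endpoints
    where a plain truncated moving average would be biased.
    """
    n = len(series)
    half = window // 2
    out = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        t = idx[lo:hi] - i
        w = np.exp(-0.5 * (t / sigma) ** 2)
        sw, swt, swtt = w.sum(), (w * t).sum(), (w * t * t).sum()
        sy, sty = (w * series[lo:hi]).sum(), (w * t * series[lo:hi]).sum()
        det = sw * swtt - swt ** 2
        if det <= 1e-15:
            out[i] = sy / sw
        else:
            out[i] = (swtt * sy - swt * sty) / det
    return out


def orient_and_smooth(trace, n_angles: int = 21, window: int = 5,
                      sigma: float = 1.0) -> np.ndarray:
    """Orientation-searched Gaussian smoothing of a skeleton trace.

    For each of ``n_angles`` rotation angles uniformly spanning [-pi, pi] the
    coordinates are rotated, smoothed with a window-5 Gaussian-weighted
    linear fit, and scored by the mean standardized Euclidean distance to the
    raw trace; the smoothed contour of the best-scoring angle is rotated back
    to the original frame.  Ties (which occur whenever the smoother commutes
    with rotation) keep the first minimum.
    """
    coords = trace.coords if isinstance(trace, ContourTrace) else np.asarray(trace, float)
    if len(coords) < 3:
        return coords.copy()
    stds = coords.std(axis=0)
    if np.any(stds < 1e-12):
        stds = np.where(stds < 1e-12, 1.0, stds)
    angles = np.linspace(-np.pi, np.pi, n_angles)
    best = None
    best_score = np.inf
    for theta in angles:
        c, s = np.cos(theta), np.sin(theta)
        R = np.array([[c, -s], [s, c]])
        rotated = coords @ R
        smoothed = np.column_stack([
            _gaussian_local_linear(rotated[:, 0], window, sigma),
            _gaussian_local_linear(rotated[:, 1], window, sigma),
        ])
        back = smoothed @ R.T
        score = np.mean(np.sqrt(np.sum(((back - coords) / stds) ** 2, axis=1)))
        if score < best_score - 1e-15:
            best_score = score
            best = back
    return best


def spline_interpolate(coords: np.ndarray, factor: int = 5) -> np.ndarray:
    """Parametric natural cubic spline through ordered points, densified.

    The parameter is cumulative chord length, so the sequence of points is
    preserved; repeated consecutive points are deduplicated first.  The
    interpolant passes through every input point.
    """
    coords = np.asarray(coords, dtype=float)
    keep = np.ones(len(coords), dtype=bool)
    keep[1:] = np.any(np.abs(np.diff(coords, axis=0)) > 1e-12, axis=1)
    coords = coords[keep]
    if len(coords) < 4:
        raise ValueError("spline interpolation needs at least 4 distinct points")
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(coords, axis=0), axis=1))])
    spline = CubicSpline(chord, coords, bc_type="natural")
    # sample each knot interval separately: knots are hit exactly (input
    # points preserved) and no two parameter values collide
    pieces = [np.linspace(a, b, factor + 1)[:-1] for a, b in zip(chord, chord[1:])]
    t_dense = np.concatenate(pieces + [chord[-1:]])
    return spline(t_dense)


# ---------------------------------------------------------------------------
# curvature and persistence length
# ---------------------------------------------------------------------------

def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return np.pi - np.mod(np.pi - a, 2 * np.pi)


def curvature_series(coords: np.ndarray) -> CurvatureSeries:
    """Spacings, tangent angles, turn angles and curvature along a contour.

    kappa   ~ 2 phi_k / (Ds_{k-1} + Ds_k)          (1/µm)
    kappa_s ~ 2 phi_k / sqrt(Ds_{k-1} + Ds_k)      (rad/sqrt(µm))
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 3:
        raise ValueError("curvature needs at least 3 points")
    diffs = np.diff(coords, axis=0)
    ds = np.linalg.norm(diffs, axis=1)
    if np.any(ds == 0):
        raise ValueError("zero-length segment in contour")
    theta = np.arctan2(diffs[:, 1], diffs[:, 0])
    phi = _wrap_angle(theta[1:] - theta[:-1])
    pair_sum = ds[:-1] + ds[1:]
    kappa = 2.0 * phi / pair_sum
    kappa_s = 2.0 * phi / np.sqrt(pair_sum)
    return CurvatureSeries(ds=ds, theta=theta, arc_length=float(ds.sum()),
                           phi=phi, kappa=kappa, kappa_s=kappa_s)


def fit_lp(kappa_s_pool: np.ndarray, temperature: float = 300.0) -> LpEstimate:
    """Effective persistence length from a pooled kappa_s sample.

    The zero-mean Gaussian P(kappa_s) = sqrt(Lp/4pi) exp(-Lp kappa_s^2 / 4)
    has variance 2/Lp, giving the moment estimator Lp = 2 / <kappa_s^2>.  A
    least-squares fit of the same form to the normalized histogram is
    reported alongside and preferred when it converges; on failure the
    moment estimate is used.  EI = Lp kB T in N m^2 (Lp converted to m).
    """
    ks = np.asarray(kappa_s_pool, dtype=float).ravel()
    ks = ks[np.isfinite(ks)]
    if len(ks) < 100:
        warnings.warn(f"only {len(ks)} kappa_s samples; Lp estimate is unreliable")
    var = float(np.mean(ks ** 2))
    if var <= 0:
        raise ValueError("kappa_s pool has zero variance; Lp is unbounded")
    lp_moment = 2.0 / var

    lp_fit = None
    try:
        counts, edges = np.histogram(ks, bins=81, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])

        def model(x, lp):
            return np.sqrt(lp / (4 * np.pi)) * np.exp(-lp * x ** 2 / 4.0)

        popt, _ = curve_fit(model, centers, counts, p0=[lp_moment], maxfev=2000)
        if popt[0] > 0 and np.isfinite(popt[0]):
            lp_fit = float(popt[0])
    except Exception:
        lp_fit = None

    lp = lp_fit if lp_fit is not None else lp_moment
    ei = lp * 1e-6 * KB * temperature
    return LpEstimate(lp=float(lp), ei=float(ei), lp_moment=float(lp_moment),
                      lp_fit=lp_fit, temperature=temperature, n_segments=len(ks))


def critical_force(lp: float, length: float, temperature: float = 300.0) -> float:
    """Euler critical buckling force f_c = pi^2 kB T Lp / L^2, in pN.

    ``lp`` and ``length`` in µm.  Above f_c a filament of length L buckles.
    """
    if lp <= 0 or length <= 0:
        raise ValueError("lp and length must be positive")
    f_newton = np.pi ** 2 * KB * temperature * (lp * 1e-6) / (length * 1e-6) ** 2
    return float(f_newton * 1e12)
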