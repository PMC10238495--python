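"""Optic-flow velocity fields, divergence and strain-rate decomposition.

Velocities between consecutive registered frames are estimated with a
Lucas–Kanade scheme: spatial derivatives by derivative-of-Gaussian, temporal
derivative by the frame difference, and a per-pixel least-squares solution of
the brightness-constancy constraint dI/dt = -v · grad I over a local window.
Rank-deficient local systems (textureless patches) get zero velocity and are
flagged.

From the (3x3 box-smoothed) velocity field the analysis computes the
divergence D = dvx/dx + dvy/dy, the velocity-gradient tensor V, the
strain-rate tensor S = (V + V^T)/2 with shear gamma^S and eigenvalues
Lam1 >= Lam2 (tensile/compressive), and the area–deviatoric split
S = S_area + S_dev with S_area = tr(S)/2 * Identity (so tr(S_dev) = 0 and
tr(S) = D exactly).  Regions with |D| above a threshold (default
0.12 min^-1) mark growth (D < 0, inflow: elongation/merging) and shrinkage
(D > 0, outflow: fragmentation/splitting) events, whose mean speeds are
reported; the overall principal-strain magnitude is sqrt(2) ||S||_F averaged
over ridge pixels with nonzero divergence and then over time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import PixelGrid, as_grid

__all__ = ["VelocityField", "StrainField", "FlowEventStats", "optic_flow",
           "smooth_field", "divergence", "event_velocities", "strain_tensor",
           "area_deviatoric_split", "principal_strain_series"]


@dataclass
class VelocityField:
    """Per-pixel velocity in physical units (µm/min)."""

    vx: PixelGrid
    vy: PixelGrid
    dt: float                    # min
    degenerate: np.ndarray = None  # True where the local system was rank-deficient

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.vx.values, self.vy.values)


@dataclass
class StrainField:
    """Velocity-gradient and strain-rate tensor fields."""

    div: PixelGrid          # D, min^-1
    V: np.ndarray           # (ny, nx, 2, 2) velocity gradient
    S: np.ndarray           # (ny, nx, 2, 2) symmetric strain rate
    gammaS: np.ndarray      # shear, (S_xy)
    Lam1: np.ndarray        # tensile eigenvalue (>= Lam2)
    Lam2: np.ndarray        # compressive eigenvalue
    S_area: np.ndarray
    S_dev: np.ndarray
    lam1_dev: np.ndarray
    lam2_dev: np.ndarray

    @property
    def principal_mag(self) -> np.ndarray:
        """sqrt(2) * Frobenius norm of S per pixel."""
        return np.sqrt(2.0) * np.sqrt(np.sum(self.S ** 2, axis=(-2, -1)))


@dataclass
class FlowEventStats:
    """Mean speeds at strong-divergence (growth/shrinkage) locations."""

    v_growth: float          # µm/min (NaN if no growth pixel)
    v_shrinkage: float       # µm/min (NaN if no shrinkage pixel)
    div_threshold: float     # min^-1
    n_growth_px: int
    n_shrink_px: int


# ---------------------------------------------------------------------------
# Lucas–Kanade flow
# ---------------------------------------------------------------------------

def optic_flow(frame_t, frame_t1, dt: float, *, window: int = 5,
               sigma: float = 1.5, gaussian_window: float = None,
               det_eps: float = 1e-9) -> VelocityField:
    """Lucas–Kanade derivative-of-Gaussian optic flow between two frames.

    Returns velocities in µm/min (pixel displacement scaled by the pixel
    pitch and divided by ``dt``).  Negating ``dt`` negates the field.

    The local least-squares system is aggregated over a ``window x window``
    box by default; passing ``gaussian_window`` (a sigma, px) switches to
    Gaussian weighting with wider support, which suppresses the
    texture-dependent bias in the *gradients* of the recovered field and is
    recommended whenever divergence or strain rates are the quantity of
    interest.
    """
    f0, f1 = as_grid(frame_t), as_grid(frame_t1)
    if f0.shape != f1.shape:
        raise ValueError("frames must share shape")
    if dt == 0:
        raise ValueError("dt must be nonzero")
    # all three derivatives at the same Gaussian scale, so the constraint
    # It + Ix dx + Iy dy = 0 is consistent
    I = 0.5 * (f0.values + f1.values)
    Ix = ndimage.gaussian_filter(I, sigma, order=(0, 1), mode="nearest")
    Iy = ndimage.gaussian_filter(I, sigma, order=(1, 0), mode="nearest")
    It = ndimage.gaussian_filter(f1.values - f0.values, sigma, mode="nearest")

    def wsum(a):
        if gaussian_window is not None:
            return ndimage.gaussian_filter(a, gaussian_window, mode="nearest")
        return ndimage.uniform_filter(a, size=window, mode="nearest")

    Axx, Axy, Ayy = wsum(Ix * Ix), wsum(Ix * Iy), wsum(Iy * Iy)
    bx, by = wsum(Ix * It), wsum(Iy * It)
    det = Axx * Ayy - Axy ** 2
    trace = Axx + Ayy
    degenerate = det <= det_eps * np.maximum(trace ** 2, 1e-30)
    safe_det = np.where(degenerate, 1.0, det)
    # displacement d (px/frame) solves A d = -b
    dx_px = np.where(degenerate, 0.0, (-bx * Ayy + by * Axy) / safe_det)
    dy_px = np.where(degenerate, 0.0, (-by * Axx + bx * Axy) / safe_det)
    vx = dx_px * f0.dx / dt
    vy = dy_px * f0.dy / dt
    return VelocityField(f0.with_values(vx), f0.with_values(vy), dt, degenerate)


def smooth_field(field: VelocityField) -> VelocityField:
    """3x3 box-mean smoothing of each velocity component (kernel (1/9) * ones)."""
    vx = ndimage.uniform_filter(field.vx.values, size=3, mode="nearest")
    vy = ndimage.uniform_filter(field.vy.values, size=3, mode="nearest")
    return VelocityField(field.vx.with_values(vx), field.vy.with_values(vy),
                         field.dt, field.degenerate)


# ---------------------------------------------------------------------------
# divergence, strain, decomposition
# ---------------------------------------------------------------------------

def _gradients(field: VelocityField):
    vx, vy = field.vx.values, field.vy.values
    dx, dy = field.vx.dx, field.vx.dy
    dvx_dy, dvx_dx = np.gradient(vx, dy, dx)
    dvy_dy, dvy_dx = np.gradient(vy, dy, dx)
    return dvx_dx, dvx_dy, dvy_dx, dvy_dy


def divergence(field: VelocityField) -> PixelGrid:
    """D = dvx/dx + dvy/dy by central differences with physical spacing."""
    dvx_dx, _, _, dvy_dy = _gradients(field)
    return field.vx.with_values(dvx_dx + dvy_dy)


def event_velocities(field: VelocityField, div: PixelGrid,
                     threshold: float = 0.12) -> FlowEventStats:
    """Mean speeds over strong-divergence growth/shrinkage locations.

    Growth: D < -threshold (inflow); shrinkage: D > +threshold (outflow).
    Empty sets report NaN for that statistic.
    """
    speed = field.speed
    d = div.values
    growth = d < -threshold
    shrink = d > threshold
    v_growth = float(speed[growth].mean()) if growth.any() else float("nan")
    v_shrink = float(speed[shrink].mean()) if shrink.any() else float("nan")
    return FlowEventStats(v_growth, v_shrink, threshold,
                          int(growth.sum()), int(shrink.sum()))


def strain_tensor(field: VelocityField) -> StrainField:
    """Velocity gradient V, strain rate S = (V + V^T)/2 and its decomposition.

    The antisymmetric (rotational) part of V is discarded.  Eigenvalues of
    the symmetric 2x2 tensor are computed in closed form and ordered
    Lam1 >= Lam2.
    """
    dvx_dx, dvx_dy, dvy_dx, dvy_dy = _gradients(field)
    ny, nx = dvx_dx.shape
    V = np.empty((ny, nx, 2, 2))
    V[..., 0, 0], V[..., 0, 1] = dvx_dx, dvx_dy
    V[..., 1, 0], V[..., 1, 1] = dvy_dx, dvy_dy
    S = 0.5 * (V + np.swapaxes(V, -1, -2))
    gammaS = S[..., 0, 1]
    mean = 0.5 * (S[..., 0, 0] + S[..., 1, 1])
    radius = np.sqrt((0.5 * (S[..., 0, 0] - S[..., 1, 1])) ** 2 + S[..., 0, 1] ** 2)
    Lam1, Lam2 = mean + radius, mean - radius
    S_area, S_dev, lam1_dev, lam2_dev = area_deviatoric_split(S)
    div = field.vx.with_values(dvx_dx + dvy_dy)
    return StrainField(div=div, V=V, S=S, gammaS=gammaS, Lam1=Lam1, Lam2=Lam2,
                       S_area=S_area, S_dev=S_dev,
                       lam1_dev=lam1_dev, lam2_dev=lam2_dev)


def area_deviatoric_split(S: np.ndarray):
    """Split S into area-changing and traceless (deviatoric) parts.

    S_area = tr(S)/2 * Identity (both eigenvalues tr(S)/2); S_dev = S - S_area
    with eigenvalues +/- |S_dev| (lam1_dev = -lam2_dev >= 0).
    """
    S = np.asarray(S, dtype=float)
    tr = S[..., 0, 0] + S[..., 1, 1]
    S_area = np.zeros_like(S)
    S_area[..., 0, 0] = S_area[..., 1, 1] = 0.5 * tr
    S_dev = S - S_area
    radius = np.sqrt(S_dev[..., 0, 0] ** 2 + S_dev[..., 0, 1] ** 2)
    return S_area, S_dev, radius, -radius


def principal_strain_series(strain_fields: list, ridge_masks: list):
    """Time series and mean of <sqrt(2)||S||> over ridge pixels with D != 0.

    Frames whose mask selects no pixel are skipped.  Returns
    ``(per_frame, time_mean)``.
    """
    if len(strain_fields) != len(ridge_masks):
        raise ValueError("need one ridge mask per strain field")
    series = []
    for sf, mask in zip(strain_fields, ridge_masks):
        mask = np.asarray(mask).astype(bool)
        sel = mask & (sf.div.values != 0)
        if not sel.any():
            continue
        series.append(float(sf.principal_mag[sel].mean()))
    if not series:
        return np.array([]), float("nan")
    return np.asarray(series), float(np.mean(series))
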