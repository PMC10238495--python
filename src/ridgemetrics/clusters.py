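"""Actin-cluster dynamics: ridge tracking, 1D intensity profiles along the
ridge axis, intensity-height Gaussian curvature and curvature/divergence
coincidence analysis.

Individual ridges (connected components of the segmented binary pattern) are
tracked frame to frame by minimum-cost assignment under a 2.3 µm centroid
cutoff.  For each ridge the dominant axis is the principal eigenvector of
the intensity-weighted covariance of its pixel coordinates; projecting each
pixel onto the axis, delta_l = (x_p, y_p) · (e1, e2), and summing intensities
per discretized delta_l bin yields the 1D intensity profile whose temporal
evolution reveals traveling actin clusters.

Treating image intensity as a height field z(x, y), the local Gaussian
curvature is computed from the first (E, F, G) and second (Lf, Mf, Nf)
fundamental forms of the Monge patch with derivatives taken by
derivative-of-Gaussian at sigma = 1.2 µm:

    K = (Lf*Nf - Mf^2) / (E*G - F^2).

Locations of strong curvature (|K| above a threshold, on images scaled to
[0, 1] with coordinates in µm) are compared against locations of strong flow
divergence, counting the overlap of the four sign pairings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import PixelGrid, as_grid
from .tracking import link_frame_pair
from scipy import ndimage

__all__ = ["RidgeComponent", "RidgeTrack", "IntensityProfile", "CurvatureMap",
           "components_from_mask", "track_ridges", "ridge_axis",
           "intensity_profile", "gaussian_curvature", "coincidence_analysis"]


@dataclass
class RidgeComponent:
    """One connected ridge component in one frame."""

    coords: np.ndarray        # (n, 2) pixel coords as (x, y), µm
    intensities: np.ndarray   # I_pv at those coords
    centroid: tuple           # (x, y), µm

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.coords) != len(self.intensities):
            raise ValueError("one intensity per coordinate required")


@dataclass
class RidgeTrack:
    """Per-frame linkage of one ridge with its components."""

    track_id: int
    samples: list = field(default_factory=list)   # [(t, component), ...]

    def add(self, t: int, comp: RidgeComponent) -> None:
        self.samples.append((t, comp))

    def __len__(self):
        return len(self.samples)


@dataclass
class IntensityProfile:
    """Summed intensity per discretized coordinate along the ridge axis."""

    delta_l: np.ndarray    # bin centers along the axis, µm
    I_p: np.ndarray        # summed intensity per bin
    e1: float
    e2: float


@dataclass
class CurvatureMap:
    """Gaussian curvature of the intensity-height surface plus form fields."""

    K: PixelGrid
    E: np.ndarray
    F: np.ndarray
    G: np.ndarray
    Lf: np.ndarray
    Mf: np.ndarray
    Nf: np.ndarray
    sigma_um: float


# ---------------------------------------------------------------------------
# components and tracking
# ---------------------------------------------------------------------------

def components_from_mask(mask: np.ndarray, intensity, dx: float = 1.0,
                         dy: float = 1.0, min_pixels: int = 2) -> list:
    """Connected components of a binary ridge mask with their intensities."""
    intensity = as_grid(intensity, dx, dy)
    labels, n = ndimage.label(np.asarray(mask).astype(bool),
                              structure=np.ones((3, 3)))
    comps = []
    for lab in range(1, n + 1):
        rr, cc = np.nonzero(labels == lab)
        if len(rr) < min_pixels:
            continue
        coords = np.column_stack([cc * intensity.dx, rr * intensity.dy])
        vals = intensity.values[rr, cc]
        w = vals.sum()
        centroid = (tuple(coords.mean(axis=0)) if w <= 0
                    else tuple((coords * vals[:, None]).sum(axis=0) / w))
        comps.append(RidgeComponent(coords, vals, centroid))
    return comps


def track_ridges(per_frame_components: list, cutoff: float = 2.3) -> list:
    """Link per-frame ridge components into tracks (LAP under the cutoff)."""
    tracks: list[RidgeTrack] = []
    active: dict[int, RidgeTrack] = {}
    next_id = 0
    prev_comps: list = []
    for t, comps in enumerate(per_frame_components):
        if t == 0:
            for i, comp in enumerate(comps):
                tr = RidgeTrack(next_id); next_id += 1
                tr.add(t, comp)
                tracks.append(tr)
                active[i] = tr
            prev_comps = comps
            continue
        links = link_frame_pair([c.centroid for c in prev_comps],
                                [c.centroid for c in comps], cutoff)
        linked_curr = {j for _, j in links}
        new_active: dict[int, RidgeTrack] = {}
        for i, j in links:
            tr = active[i]
            tr.add(t, comps[j])
            new_active[j] = tr
        for j, comp in enumerate(comps):
            if j not in linked_curr:
                tr = RidgeTrack(next_id); next_id += 1
                tr.add(t, comp)
                tracks.append(tr)
                new_active[j] = tr
        active = new_active
        prev_comps = comps
    return tracks


# ---------------------------------------------------------------------------
# axis and intensity profile
# ---------------------------------------------------------------------------

def ridge_axis(component: RidgeComponent):
    """Dominant axis: principal eigenvector of the intensity-weighted
    coordinate covariance, sign-fixed so e1 >= 0 (e2 > 0 on the tie).

    Returns ``(e1, e2, isotropic)``; ``isotropic`` flags (near-)equal
    eigenvalues, where the axis is arbitrary but deterministic.
    """
    coords = component.coords
    if len(coords) < 2:
        raise ValueError("ridge axis needs at least 2 pixels")
    w = np.clip(component.intensities, 0, None)
    if w.sum() <= 0:
        w = np.ones(len(coords))
    mean = (coords * w[:, None]).sum(axis=0) / w.sum()
    centered = coords - mean
    cov = (centered * w[:, None]).T @ centered / w.sum()
    evals, evecs = np.linalg.eigh(cov)
    e = evecs[:, np.argmax(evals)]
    isotropic = bool(np.isclose(evals[0], evals[1], rtol=1e-6, atol=1e-12))
    if e[0] < 0 or (e[0] == 0 and e[1] < 0):
        e = -e
    return float(e[0]), float(e[1]), isotropic


def intensity_profile(component: RidgeComponent, pitch: float = None) -> IntensityProfile:
    """1D intensity profile along the ridge axis.

    Pixel coordinates are projected onto the dominant axis
    (delta_l = x*e1 + y*e2) and intensities summed per bin of width
    ``pitch`` (default: the median nearest-coordinate spacing, i.e. one
    source-pixel pitch).  Binning conserves total intensity.
    """
    e1, e2, _ = ridge_axis(component)
    delta = component.coords @ np.array([e1, e2])
    if pitch is None:
        diffs = np.diff(np.unique(np.round(delta, 12)))
        pitch = float(np.median(diffs)) if len(diffs) else 1.0
    bins = np.round((delta - delta.min()) / pitch).astype(int)
    n_bins = bins.max() + 1
    I_p = np.bincount(bins, weights=component.intensities, minlength=n_bins)
    centers = delta.min() + np.arange(n_bins) * pitch
    return IntensityProfile(centers, I_p, e1, e2)


# ---------------------------------------------------------------------------
# Gaussian curvature of the intensity surface
# ---------------------------------------------------------------------------

def gaussian_curvature(intensity_img, dx: float = None, dy: float = None,
                       sigma: float = 1.2) -> CurvatureMap:
    """Local Gaussian curvature of intensity-as-height, Monge-patch form.

    Derivatives are derivative-of-Gaussian at physical scale ``sigma`` (µm),
    evaluated per µm (so K is in µm^-2 when intensity is unitless).  For a
    plane K = 0 identically; EG - F^2 = 1 + zx^2 + zy^2 >= 1 always.
    """
    img = as_grid(intensity_img, dx or 1.0, dy or 1.0)
    # subtract the mean height before differentiating: the sampled
    # second-derivative kernel is not exactly zero-sum, so a large constant
    # offset would otherwise leak into z_xx/z_yy; truncate=8 makes the
    # kernel moments accurate to machine precision
    z = img.values.astype(float)
    z = z - z.mean()
    sy, sx = sigma / img.dy, sigma / img.dx

    def d(order_y, order_x):
        out = ndimage.gaussian_filter(z, (sy, sx), order=(order_y, order_x),
                                      mode="nearest", truncate=8.0)
        return out / (img.dy ** order_y * img.dx ** order_x)

    zx, zy = d(0, 1), d(1, 0)
    zxx, zyy, zxy = d(0, 2), d(2, 0), d(1, 1)
    E = 1.0 + zx ** 2
    F = zx * zy
    G = 1.0 + zy ** 2
    denom = np.sqrt(1.0 + zx ** 2 + zy ** 2)
    Lf, Mf, Nf = zxx / denom, zxy / denom, zyy / denom
    K = (Lf * Nf - Mf ** 2) / (E * G - F ** 2)
    return CurvatureMap(img.with_values(K), E, F, G, Lf, Mf, Nf, sigma)


# ---------------------------------------------------------------------------
# coincidence of curvature and divergence extremes
# ---------------------------------------------------------------------------

def coincidence_analysis(K_maps: list, div_maps: list, k_threshold: float = 5.0,
                         div_threshold: float = 0.12) -> dict:
    """Overlap counts between strong-curvature and strong-divergence pixels.

    For each frame, pixel sets {+K, -K} (|K| > k_threshold, by sign) from the
    curvature at t and {+D, -D} (|D| > div_threshold) for the t -> t+1 flow
    are intersected, yielding four overlap counts per frame plus the
    fraction of strong-|K| pixels that are positive.
    """
    if len(K_maps) != len(div_maps):
        raise ValueError("need one divergence map per curvature map")
    rows = []
    for t, (kmap, dmap) in enumerate(zip(K_maps, div_maps)):
        K = kmap.K.values if isinstance(kmap, CurvatureMap) else np.asarray(kmap)
        D = dmap.values if isinstance(dmap, PixelGrid) else np.asarray(dmap)
        if K.shape != D.shape:
            raise ValueError(f"frame {t}: curvature and divergence grids misaligned")
        kp, kn = K > k_threshold, K < -k_threshold
        dp, dn = D > div_threshold, D < -div_threshold
        n_strong = int(kp.sum() + kn.sum())
        rows.append(dict(
            frame=t,
            pK_pD=int((kp & dp).sum()), pK_nD=int((kp & dn).sum()),
            nK_pD=int((kn & dp).sum()), nK_nD=int((kn & dn).sum()),
            frac_positive_K=float(kp.sum() / n_strong) if n_strong else float("nan"),
        ))
    return dict(frames=rows,
                totals={k: int(sum(r[k] for r in rows))
                        for k in ("pK_pD", "pK_nD", "nK_pD", "nK_nD")})
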