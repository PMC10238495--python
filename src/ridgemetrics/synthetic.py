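"""Synthetic fixtures with known ground truth for every pipeline stage.

The generators here emulate the essential geometry and statistics of confocal
recordings of microridge-patterned periderm cells, at the level the downstream
estimators care about:

* worm-like chains with a prescribed 2D persistence length (oracle for the
  curvature-distribution estimator),
* labyrinthine / striped ridge patterns with a known spatial period (oracle
  for the Fourier wavelength and for the ridge-labeling algorithm),
* image sequences advected by analytic velocity fields (oracle for the
  optic-flow, divergence and strain-rate machinery),
* two-population z-stacks whose slice entropies are separable by construction
  (oracle for entropy-based slice filtering),
* cell sheets with membrane outlines and ground-truth centroids (fixture for
  membrane segmentation, single-cell extraction and centroid tracking).

Each generator owns an independent random stream seeded from its ``seed``
argument, so scenes are bit-exactly reproducible and adding a generator never
perturbs existing fixtures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import PixelGrid

__all__ = [
    "SyntheticScene",
    "WormlikeChainSet",
    "FlowScene",
    "CellSheetScene",
    "make_wormlike_chains",
    "make_labyrinth",
    "make_flow_scene",
    "make_zstack",
    "make_cell_sheet",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SyntheticScene:
    """A rendered ridge pattern with its generating masks and parameters."""

    image: PixelGrid                 # grayscale, values in [0, 1]
    ridge_mask: np.ndarray           # binary {0,1} stencil of the ridges
    membrane_mask: np.ndarray        # binary {0,1} cell-membrane stencil
    cell_centroids: list             # [(x_um, y_um), ...]
    params: dict
    seed: int

    def __post_init__(self):
        if self.image.shape != self.ridge_mask.shape or self.image.shape != self.membrane_mask.shape:
            raise ValueError("image and masks must share shape")


@dataclass
class WormlikeChainSet:
    """2D worm-like chains with known persistence length.

    Per-step turn angles are i.i.d. Normal(0, step/lp_true) — the standard
    discretization of a 2D worm-like chain whose tangent correlations decay
    over ``lp_true``.
    """

    chains: list                     # each an (n_points, 2) array, µm
    lp_true: float                   # µm
    step: float                      # µm
    n_chains: int
    n_points: int
    seed: int


@dataclass
class FlowScene:
    """Image frames advected by a known analytic velocity field."""

    frames: list                     # ordered PixelGrids
    v_true: tuple                    # (vx, vy) arrays, µm/min, on the grid
    dt: float                        # frame interval, min
    field: str
    magnitude: float
    seed: int


@dataclass
class CellSheetScene:
    """A sheet of polygonal cells delimited by bright membranes.

    ``interior_centroids`` are the ground-truth centroids (pixel units,
    (x, y)) of cells that do not touch the image border; ``labels`` is the
    full cell-label image (0 on membranes).
    """

    image: PixelGrid
    membrane_mask: np.ndarray
    labels: np.ndarray
    interior_centroids: list
    border_centroids: list
    params: dict
    seed: int


# ---------------------------------------------------------------------------
# worm-like chains
# ---------------------------------------------------------------------------

def make_wormlike_chains(lp_true: float, step: float, n_points: int,
                         n_chains: int, seed: int) -> WormlikeChainSet:
    """Sample 2D worm-like chains of persistence length ``lp_true``.

    The chain is built by a cumulative heading: the first segment points in a
    uniformly random direction and every subsequent segment turns by
    phi ~ Normal(0, sigma^2) with sigma^2 = step / lp_true.  In the stiff
    limit (lp_true -> infinity) all turn angles vanish and the chain is a
    straight line.

    Parameters
    ----------
    lp_true : persistence length, µm (> 0)
    step : segment length, µm (> 0)
    n_points : points per chain (>= 10)
    n_chains : number of chains
    seed : RNG seed
    """
    if not lp_true > 0:
        raise ValueError(f"lp_true must be positive, got {lp_true}")
    if not step > 0:
        raise ValueError(f"step must be positive, got {step}")
    if n_points < 10:
        raise ValueError("chains need at least 10 coordinate points")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(step / lp_true)
    chains = []
    for _ in range(n_chains):
        theta0 = rng.uniform(-np.pi, np.pi)
        phi = rng.normal(0.0, sigma, size=n_points - 2)
        headings = theta0 + np.concatenate([[0.0], np.cumsum(phi)])
        dxy = step * np.column_stack([np.cos(headings), np.sin(headings)])
        coords = np.vstack([[0.0, 0.0], np.cumsum(dxy, axis=0)])
        chains.append(coords)
    return WormlikeChainSet(chains, lp_true, step, n_chains, n_points, seed)


# ---------------------------------------------------------------------------
# ridge patterns
# ---------------------------------------------------------------------------

def _render_ridges(mask: np.ndarray, ridge_sigma_px: float,
                   noise: float, rng) -> np.ndarray:
    """Grayscale rendering: stencil blurred by a Gaussian ridge profile plus noise."""
    img = ndimage.gaussian_filter(mask.astype(float), ridge_sigma_px)
    peak = img.max()
    if peak > 0:
        img = img / peak
    if noise > 0:
        img = img + rng.normal(0.0, noise, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def make_labyrinth(period: float = 0.66, shape: tuple = (256, 256),
                   pixel_size: float = 0.098, mode: str = "labyrinth",
                   seed: int = 0, *, noise: float = 0.05,
                   ridge_sigma_um: float = 0.15, orientation: float = 0.0,
                   phase: float = 0.0) -> SyntheticScene:
    """A striped or labyrinthine ridge pattern of known spatial period.

    ``stripes`` thresholds a sinusoid of exact period ``period`` (µm);
    ``labyrinth`` thresholds band-pass filtered noise whose radial power
    spectrum peaks at wave number 2π/period, giving the isotropic, maze-like
    crowding typical of yolk-cell patterns.

    The grayscale image is the binary stencil convolved with a Gaussian ridge
    profile (``ridge_sigma_um``) plus additive Gaussian noise of amplitude
    ``noise`` (so SNR ≈ 1/noise for a peak-normalized rendering).
    """
    if period <= 2 * pixel_size:
        raise ValueError(
            f"period {period} µm is at/below the Nyquist limit 2*pixel_size={2*pixel_size} µm")
    if mode not in ("stripes", "labyrinth"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    ny, nx = shape
    if mode == "stripes":
        X, Y = np.meshgrid(np.arange(nx) * pixel_size, np.arange(ny) * pixel_size)
        u = np.cos(orientation) * X + np.sin(orientation) * Y
        mask = (np.sin(2 * np.pi * u / period + phase) > 0).astype(np.uint8)
    else:
        noise_img = rng.standard_normal(shape)
        f = np.fft.fft2(noise_img)
        ky = 2 * np.pi * np.fft.fftfreq(ny, d=pixel_size)
        kx = 2 * np.pi * np.fft.fftfreq(nx, d=pixel_size)
        kmag = np.sqrt(kx[None, :] ** 2 + ky[:, None] ** 2)
        k0 = 2 * np.pi / period
        band = np.exp(-0.5 * ((kmag - k0) / (0.15 * k0)) ** 2)
        pattern = np.fft.ifft2(f * band).real
        mask = (pattern > 0).astype(np.uint8)
    image = _render_ridges(mask, ridge_sigma_um / pixel_size, noise, rng)
    params = dict(period=period, pixel_size=pixel_size, mode=mode,
                  noise=noise, ridge_sigma_um=ridge_sigma_um)
    return SyntheticScene(PixelGrid(image, pixel_size, pixel_size), mask,
                          np.zeros(shape, dtype=np.uint8), [], params, seed)


# ---------------------------------------------------------------------------
# flow scenes
# ---------------------------------------------------------------------------

_FIELDS = ("translation", "source", "shear", "rotation")


def _analytic_field(field: str, magnitude: float, shape: tuple,
                    pixel_size: float) -> tuple:
    ny, nx = shape
    x = (np.arange(nx) - (nx - 1) / 2.0) * pixel_size
    y = (np.arange(ny) - (ny - 1) / 2.0) * pixel_size
    X, Y = np.meshgrid(x, y)
    c = magnitude
    if field == "translation":
        vx, vy = np.full(shape, c), np.zeros(shape)
    elif field == "source":
        vx, vy = c * X, c * Y
    elif field == "shear":
        vx, vy = c * Y, np.zeros(shape)
    elif field == "rotation":
        vx, vy = c * Y, -c * X
    else:
        raise ValueError(f"unknown field {field!r}; expected one of {_FIELDS}")
    return vx, vy


def make_flow_scene(field: str, magnitude: float, shape: tuple = (96, 96),
                    dt: float = 0.5, seed: int = 0, *, n_frames: int = 2,
                    pixel_size: float = 0.2, blob_sigma_px: float = 1.5,
                    blob_density: float = 0.13) -> FlowScene:
    """Frames advected by a named analytic velocity field.

    The first frame is a speckle-like texture of many Gaussian blobs
    (emulating fluorescent label granularity); frame t+1 is frame t warped
    backward by ``v_true * dt`` (bilinear interpolation), so brightness
    constancy holds up to interpolation error.  Displacements above 3 px per
    frame violate the small-displacement regime of the flow estimator: the
    magnitude is clamped with a warning.
    """
    if n_frames < 2:
        raise ValueError("a flow scene needs at least 2 frames")
    vx, vy = _analytic_field(field, magnitude, shape, pixel_size)
    max_disp_px = max(np.abs(vx).max(), np.abs(vy).max()) * dt / pixel_size
    if max_disp_px >= 3.0:
        scale = 2.99 / max_disp_px
        warnings.warn(
            f"flow displacement {max_disp_px:.2f} px/frame exceeds the "
            f"small-displacement regime; clamping magnitude by x{scale:.3f}")
        magnitude *= scale
        vx, vy = _analytic_field(field, magnitude, shape, pixel_size)

    rng = np.random.default_rng(seed)
    ny, nx = shape
    x = (np.arange(nx) - (nx - 1) / 2.0) * pixel_size
    y = (np.arange(ny) - (ny - 1) / 2.0) * pixel_size
    X, Y = np.meshgrid(x, y)
    n_blobs = max(10, int(blob_density * ny * nx))
    margin = 3 * blob_sigma_px * pixel_size
    bx = rng.uniform(x.min() - margin, x.max() + margin, n_blobs)
    by = rng.uniform(y.min() - margin, y.max() + margin, n_blobs)
    amp = rng.uniform(0.3, 1.0, n_blobs)
    s2 = 2.0 * (blob_sigma_px * pixel_size) ** 2
    base = np.zeros(shape)
    for p, q, a in zip(bx, by, amp):
        base += a * np.exp(-((X - p) ** 2 + (Y - q) ** 2) / s2)
    base = base / base.max()

    rows, cols = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    # backward warp: value at pixel p comes from p - v*dt (in pixel units)
    src_r = rows - vy * dt / pixel_size
    src_c = cols - vx * dt / pixel_size
    frames = [base]
    for _ in range(n_frames - 1):
        frames.append(ndimage.map_coordinates(frames[-1], [src_r, src_c],
                                              order=1, mode="reflect"))
    grids = [PixelGrid(f, pixel_size, pixel_size) for f in frames]
    return FlowScene(grids, (vx, vy), dt, field, magnitude, seed)


# ---------------------------------------------------------------------------
# z-stacks for entropy filtering
# ---------------------------------------------------------------------------

def make_zstack(n_periderm: int, n_basal: int, n_cells: int = 9,
                shape: tuple = (96, 96), seed: int = 0,
                n_timepoints: int = 1):
    """An XYZT stack of low-entropy periderm and high-entropy basal slices.

    Periderm slices render a sparse striped ridge pattern on a dark
    background (intensity histogram concentrated -> low Shannon entropy);
    basal slices render dense uniform speckle (flat histogram -> high
    entropy).  Returns ``(stack, labels)`` with ``stack`` of shape
    (T, Z, ny, nx) and ``labels`` a boolean array marking periderm slices.
    """
    if n_periderm < 1:
        raise ValueError("need at least one periderm slice")
    if len(shape) != 2:
        raise ValueError(f"shape must be 2D, got {shape}")
    rng = np.random.default_rng(seed)
    nz = n_periderm + n_basal
    stack = np.zeros((n_timepoints, nz, *shape), dtype=float)
    labels = np.zeros(nz, dtype=bool)
    labels[:n_periderm] = True
    x = np.arange(shape[1])
    for t in range(n_timepoints):
        for z in range(nz):
            if labels[z]:
                stripe_period = max(8, shape[1] // max(n_cells, 1))
                stripes = (np.sin(2 * np.pi * x / stripe_period) > 0.85)
                img = np.broadcast_to(stripes, shape).astype(float) * 0.8
                img = img + rng.normal(0, 0.01, shape)
            else:
                img = rng.uniform(0, 1, shape)
            stack[t, z] = np.clip(img, 0, 1)
    return stack, labels


# ---------------------------------------------------------------------------
# cell sheets for membrane segmentation and tracking
# ---------------------------------------------------------------------------

def make_cell_sheet(n_x: int = 5, n_y: int = 5, cell_px: int = 40,
                    jitter: float = 0.15, seed: int = 0, *,
                    pixel_size: float = 0.1977, membrane_intensity: float = 1.0,
                    ridge_intensity: float = 0.0, noise: float = 0.01) -> CellSheetScene:
    """A sheet of ``n_x x n_y`` polygonal cells with bright membranes.

    Cells are nearest-seed (Voronoi) regions of a jittered lattice of seeds;
    the membrane is the set of pixels adjacent to a different cell, dilated
    to ~2 px width.  Ground-truth centroids of interior (non-border) cells
    are the pixel means of their label regions.  Optionally an interior
    stripe texture of amplitude ``ridge_intensity`` emulates microridges.
    """
    rng = np.random.default_rng(seed)
    ny, nx = n_y * cell_px, n_x * cell_px
    gx, gy = np.meshgrid(np.arange(n_x), np.arange(n_y))
    seeds = np.column_stack([
        (gx.ravel() + 0.5 + rng.uniform(-jitter, jitter, n_x * n_y)) * cell_px,
        (gy.ravel() + 0.5 + rng.uniform(-jitter, jitter, n_x * n_y)) * cell_px,
    ])  # (x, y) pixel coords
    cols, rows = np.meshgrid(np.arange(nx), np.arange(ny))
    d2 = (cols[..., None] - seeds[:, 0]) ** 2 + (rows[..., None] - seeds[:, 1]) ** 2
    labels = np.argmin(d2, axis=-1) + 1

    membrane = np.zeros((ny, nx), dtype=bool)
    membrane[:-1, :] |= labels[:-1, :] != labels[1:, :]
    membrane[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    membrane = ndimage.binary_dilation(membrane, iterations=1)
    # the sheet boundary is not membrane: border cells stay open/clipped
    cell_labels = np.where(membrane, 0, labels)

    interior, border = [], []
    for lab in range(1, n_x * n_y + 1):
        region = cell_labels == lab
        if not region.any():
            continue
        rr, cc = np.nonzero(region)
        centroid = (cc.mean(), rr.mean())
        touches = rr.min() == 0 or cc.min() == 0 or rr.max() == ny - 1 or cc.max() == nx - 1
        (border if touches else interior).append(centroid)

    img = membrane.astype(float) * membrane_intensity
    if ridge_intensity > 0:
        stripe = (np.sin(2 * np.pi * cols / 8.0) > 0).astype(float)
        img = np.maximum(img, stripe * ridge_intensity * (~membrane))
    img = np.clip(img + rng.normal(0, noise, img.shape), 0, 1)
    params = dict(n_x=n_x, n_y=n_y, cell_px=cell_px, jitter=jitter,
                  pixel_size=pixel_size, ridge_intensity=ridge_intensity, noise=noise)
    return CellSheetScene(PixelGrid(img, pixel_size, pixel_size),
                          membrane.astype(np.uint8), cell_labels,
                          interior, border, params, seed)
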