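"""Entropy-based z-slice selection and mean projection of XYZT stacks.

Periderm (outer epidermal) slices of a confocal stack show sparse, bright
ridge patterns on dark background and therefore have lower Shannon entropy
than the densely textured basal-epidermis slices beneath them.  Slices are
kept when their global entropy stays below a per-movie threshold; within the
kept slices, pixels whose local (3x3) entropy exceeds a second threshold are
zeroed out to remove basal signal bleeding into the periderm plane.  The kept
slices are then mean-projected per time point.

Entropy convention: base-2 Shannon entropy of a 256-bin histogram of the
image after min-max scaling to [0, 255] (a constant image scales to a single
bin and has zero entropy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import PixelGrid, as_grid

__all__ = ["SliceSelection", "shannon_entropy", "local_entropy_map",
           "select_and_project"]


@dataclass
class SliceSelection:
    """Per-timepoint kept z indices and the (movie-constant) thresholds."""

    kept_indices: list        # list (per timepoint) of lists of z indices
    global_threshold: float   # bits
    local_threshold: float    # bits
    window: int = 3


def _quantize256(values: np.ndarray) -> np.ndarray:
    """Min-max scale to [0, 255] and round to integer gray levels."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros(values.shape, dtype=np.uint8)
    return np.clip(np.round((values - lo) / (hi - lo) * 255), 0, 255).astype(np.uint8)


def shannon_entropy(img) -> float:
    """Global Shannon information content of an image, in bits.

    -sum p log2 p over the 256-bin intensity histogram, with 0*log0 := 0.
    """
    img = as_grid(img)
    if img.values.size == 0:
        raise ValueError("cannot compute entropy of an empty image")
    q = _quantize256(img.values)
    counts = np.bincount(q.ravel(), minlength=256).astype(float)
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def local_entropy_map(img, window: int = 3) -> PixelGrid:
    """Per-pixel Shannon entropy (bits) of the ``window x window`` neighborhood.

    Borders are replicate-padded so the map has the same shape as the input.
    The image is quantized to 256 gray levels once, globally, before the
    local histograms are formed.
    """
    img = as_grid(img)
    if min(img.shape) < window:
        raise ValueError(f"image must be at least {window}x{window}")
    if window % 2 != 1:
        raise ValueError("window must be odd")
    q = _quantize256(img.values)
    pad = window // 2
    padded = np.pad(q, pad, mode="edge")
    win = np.lib.stride_tricks.sliding_window_view(padded, (window, window))
    flat = win.reshape(-1, window * window).astype(np.int16)
    # count, for each element, how many window elements equal it; then
    # H = -sum_unique p log2 p = -(1/n) sum_elements log2(count/n)
    n = window * window
    eq = (flat[:, :, None] == flat[:, None, :])
    counts = eq.sum(axis=-1)
    ent = -np.sum(np.log2(counts / n), axis=-1) / n
    return img.with_values(ent.reshape(img.shape))


def select_and_project(stack: np.ndarray, global_threshold: float,
                       local_threshold: float, *, dx: float = 1.0,
                       dy: float = 1.0, window: int = 3):
    """Entropy-filter an XYZT stack and mean-project the kept periderm slices.

    Parameters
    ----------
    stack
        Array of shape (T, Z, ny, nx) or (Z, ny, nx) for a single timepoint.
    global_threshold
        Keep slices with global entropy <= this value (bits).  Held constant
        across all time points of a movie.
    local_threshold
        Zero out pixels whose 3x3 local entropy exceeds this value (bits).
        ``np.inf`` disables pixel masking.

    Returns
    -------
    (projections, selection)
        ``projections`` is a list of per-timepoint :class:`PixelGrid` mean
        projections; ``selection`` records the kept z indices per timepoint.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 3:
        stack = stack[None]
    if stack.ndim != 4:
        raise ValueError(f"expected a (T, Z, ny, nx) stack, got shape {stack.shape}")
    projections = []
    kept_per_t = []
    for t in range(stack.shape[0]):
        entropies = [shannon_entropy(PixelGrid(stack[t, z], dx, dy))
                     for z in range(stack.shape[1])]
        kept = [z for z, h in enumerate(entropies) if h <= global_threshold]
        if not kept:
            raise ValueError(
                f"no slice passed the global entropy threshold "
                f"{global_threshold} bits at timepoint {t} "
                f"(slice entropies: {np.round(entropies, 3).tolist()})")
        planes = []
        for z in kept:
            plane = stack[t, z].copy()
            if np.isfinite(local_threshold):
                lem = local_entropy_map(PixelGrid(plane, dx, dy), window=window)
                plane[lem.values > local_threshold] = 0.0
            planes.append(plane)
        projections.append(PixelGrid(np.mean(planes, axis=0), dx, dy))
        kept_per_t.append(kept)
    return projections, SliceSelection(kept_per_t, global_threshold,
                                       local_threshold, window)
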