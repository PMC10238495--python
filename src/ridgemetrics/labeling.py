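"""Conventional microridge masking: the training-label generator.

For one extracted patterned cell, the label is produced by: Gaussian
smoothing (sigma = 0.7 px) -> intensity gradient by derivative-of-Gaussian
(sigma_g = 0.7 px) -> Laplacian as the trace of the Hessian of the smoothed
image -> rectification keeping only non-positive values (bright ridges are
intensity crests, where the Laplacian is negative) -> logistic sigmoid of
sqrt(|L|), mapping background to 0.5 and ridge crests toward 1 -> Otsu
binarization, yielding the binary ridge label B.

Because the chain starts from image derivatives, the label is invariant to
constant intensity offsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .grid import PixelGrid, as_grid
from .cells import gaussian_smooth

__all__ = ["LabeledPair", "gauss_gradient", "rectified_laplacian",
           "sigmoid_mask", "label_cell"]


@dataclass
class LabeledPair:
    """A smoothed grayscale cell image and its binary ridge label."""

    gray: PixelGrid
    label: np.ndarray

    def __post_init__(self):
        if self.gray.shape != self.label.shape:
            raise ValueError("gray image and label must share shape")
        if not np.isin(self.label, (0, 1)).all():
            raise ValueError("label must be binary {0, 1}")


def gauss_gradient(img, sigma_g: float = 0.7):
    """Image gradient by convolution with the derivative of a Gaussian.

    Returns ``(gx, gy)`` as PixelGrids; for a linear ramp a*x the interior of
    gx is a (the derivative-of-Gaussian kernel has unit first moment).
    """
    if sigma_g <= 0:
        raise ValueError(f"sigma_g must be positive, got {sigma_g}")
    img = as_grid(img)
    gx = ndimage.gaussian_filter(img.values, sigma_g, order=(0, 1), mode="reflect")
    gy = ndimage.gaussian_filter(img.values, sigma_g, order=(1, 0), mode="reflect")
    return img.with_values(gx), img.with_values(gy)


def rectified_laplacian(gx, gy, sigma_g: float = 0.7) -> PixelGrid:
    """Negative-rectified Laplacian from the Gauss-gradient image.

    The second derivatives are taken by applying the derivative-of-Gaussian
    operator to the gradient components (sigma_g each), so
    La = d2 IM/dx2 + d2 IM/dy2 at a combined smoothing scale; the output L
    keeps La where La <= 0 and is zero elsewhere.
    """
    gx, gy = as_grid(gx), as_grid(gy)
    lxx = ndimage.gaussian_filter(gx.values, sigma_g, order=(0, 1), mode="reflect")
    lyy = ndimage.gaussian_filter(gy.values, sigma_g, order=(1, 0), mode="reflect")
    la = lxx + lyy
    return gx.with_values(np.where(la <= 0, la, 0.0))


def sigmoid_mask(L) -> PixelGrid:
    """Logistic sigmoid of sqrt(|L|): S = 1 / (1 + exp(-sqrt(|L|))).

    Background (L = 0) maps to exactly 0.5; increasingly negative Laplacian
    (sharper ridge crests) maps monotonically toward 1.
    """
    L = as_grid(L)
    return L.with_values(1.0 / (1.0 + np.exp(-np.sqrt(np.abs(L.values)))))


def label_cell(patterned_image, *, sigma: float = 0.7,
               sigma_g: float = 0.7) -> LabeledPair:
    """Full labeling chain for one extracted cell image.

    Smoothing -> Gauss gradient -> rectified Laplacian -> sigmoid -> Otsu.
    An image with no usable foreground (flat sigmoid response) yields an
    all-zero label with a warning.
    """
    img = as_grid(patterned_image)
    smooth = gaussian_smooth(img, sigma=sigma)
    gx, gy = gauss_gradient(smooth, sigma_g=sigma_g)
    L = rectified_laplacian(gx, gy, sigma_g=sigma_g)
    S = sigmoid_mask(L)
    if np.ptp(S.values) < 1e-12:
        warnings.warn("flat sigmoid response: no ridge foreground found")
        return LabeledPair(smooth, np.zeros(img.shape, dtype=np.uint8))
    thresh = threshold_otsu(S.values)
    B = (S.values > thresh).astype(np.uint8)
    return LabeledPair(smooth, B)
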