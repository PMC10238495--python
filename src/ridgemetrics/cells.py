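"""Periderm cell-membrane segmentation and single-cell extraction.

The membrane pipeline runs: Gaussian denoising (sigma = 0.7 px) -> Butterworth
high-pass in the frequency domain (order n = 1, cutoff D0 = 3) to momentarily
suppress the low-frequency content and leave membranes -> Otsu binarization ->
morphological closing (disk, configurable radius) to seal membrane gaps.
Complementing the closed membrane mask yields enclosed cell regions; regions
touching the image border or failing area/solidity cutoffs are dropped, and
each surviving cell is extracted as the bounding-box crop of the grayscale
image masked by the region's convex image (Hadamard product), giving the
"patterned cell" that feeds ridge labeling and the CNN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sklabel, regionprops
from skimage.morphology import closing, disk

from .grid import PixelGrid, as_grid

__all__ = ["CellRegion", "ButterworthFilter", "gaussian_smooth",
           "butterworth_highpass", "close_membranes", "extract_cells"]


@dataclass
class CellRegion:
    """One segmented cell with its extracted patterned image.

    ``patterned_image`` is crop(gray, bbox) * convex_image: exactly zero
    outside the convex mask.
    """

    area: float                  # px^2
    solidity: float              # (0, 1]
    bbox: tuple                  # (x, y, w, h) in px
    convex_image: np.ndarray     # binary, bbox-shaped
    centroid: tuple              # (x, y) px
    patterned_image: PixelGrid

    def __post_init__(self):
        if not (0 < self.solidity <= 1):
            raise ValueError(f"solidity must be in (0, 1], got {self.solidity}")
        if self.convex_image.shape != (self.bbox[3], self.bbox[2]):
            raise ValueError("convex_image shape must equal bbox (h, w)")


@dataclass
class ButterworthFilter:
    """High-pass transfer function H = 1 / (1 + (D0/D)^(2n)) on an r x c grid."""

    n: int = 1
    D0: float = 3.0
    r: int = 0   # image width, px
    c: int = 0   # image height, px

    def __post_init__(self):
        if self.n < 1 or self.D0 <= 0:
            raise ValueError("need order n >= 1 and cutoff D0 > 0")

    def transfer(self) -> np.ndarray:
        """H evaluated on the centered (r x c) frequency grid; H(0) = 0."""
        x = np.arange(self.r) - self.r / 2.0
        y = np.arange(self.c) - self.c / 2.0
        D = np.sqrt(x[None, :] ** 2 + y[:, None] ** 2)
        with np.errstate(divide="ignore"):
            H = 1.0 / (1.0 + (self.D0 / D) ** (2 * self.n))
        H[D == 0] = 0.0
        return H


def gaussian_smooth(img, sigma: float = 0.7) -> PixelGrid:
    """Low-pass Gaussian smoothing, g(x, y; sigma), unit DC gain.

    Reflective borders conserve total intensity; a constant image is a fixed
    point.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    img = as_grid(img)
    return img.with_values(ndimage.gaussian_filter(img.values, sigma, mode="reflect"))


def butterworth_highpass(img, n: int = 1, D0: float = 3.0) -> PixelGrid:
    """Butterworth high-pass filtering in the frequency domain.

    The centered spectrum is multiplied by H = 1/(1 + (D0/D)^(2n)) with D the
    distance from the spectrum center; H(D0) = 1/2, H -> 1 at high frequency
    and H -> 0 at DC, so a constant image maps to ~0.
    """
    img = as_grid(img)
    rows, cols = img.shape
    H = ButterworthFilter(n=n, D0=D0, r=cols, c=rows).transfer()
    F = np.fft.fftshift(np.fft.fft2(img.values))
    out = np.fft.ifft2(np.fft.ifftshift(F * H)).real
    return img.with_values(out)


def close_membranes(img_hp, close_radius: int = 2) -> np.ndarray:
    """Binarize a high-passed image (Otsu) and close membrane gaps.

    Closing uses a disk structuring element of the given radius (radius 0 is
    the identity on the binarized image).  Raises if binarization yields no
    foreground at all.
    """
    img_hp = as_grid(img_hp)
    values = img_hp.values
    thresh = threshold_otsu(values)
    bw = values > thresh
    if not bw.any():
        raise ValueError("binarization produced an all-background image")
    if close_radius > 0:
        bw = closing(bw, disk(close_radius))
    return bw.astype(np.uint8)


def extract_cells(membrane_mask: np.ndarray, gray_img, min_area: float = 0.0,
                  min_solidity: float = 0.0) -> list:
    """Label enclosed regions of the complemented membrane mask as cells.

    Regions touching the image border (partially visible cells) are dropped,
    as are regions below the area or solidity cutoffs.  Each surviving cell
    is returned as a :class:`CellRegion` with its patterned image
    (bounding-box crop of ``gray_img`` masked by the region's convex image).
    """
    gray = as_grid(gray_img)
    mask = np.asarray(membrane_mask).astype(bool)
    if mask.shape != gray.shape:
        raise ValueError("membrane mask and grayscale image must share shape")
    interior = ~mask
    labels = sklabel(interior, connectivity=1)
    ny, nx = mask.shape
    cells = []
    for prop in regionprops(labels):
        minr, minc, maxr, maxc = prop.bbox
        if minr == 0 or minc == 0 or maxr == ny or maxc == nx:
            continue  # border-touching: incomplete boundary
        if prop.area < min_area or prop.solidity < min_solidity:
            continue
        convex = prop.image_convex.astype(np.uint8)
        crop = gray.values[minr:maxr, minc:maxc]
        patterned = crop * convex
        cells.append(CellRegion(
            area=float(prop.area),
            solidity=float(prop.solidity),
            bbox=(minc, minr, maxc - minc, maxr - minr),
            convex_image=convex,
            centroid=(float(prop.centroid[1]), float(prop.centroid[0])),
            patterned_image=PixelGrid(patterned, gray.dx, gray.dy),
        ))
    if not cells:
        warnings.warn("no cell region survived the border/area/solidity cuts")
    cells.sort(key=lambda c: (c.centroid[1], c.centroid[0]))
    return cells
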