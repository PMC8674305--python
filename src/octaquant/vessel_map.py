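"""En-face angiogram preprocessing and vessel-map extraction.

Turns a grayscale OCTA en-face image into a binary perfusion map, a
1-px-wide skeleton, per-centerline-pixel calibers (μm), and the
micro / macro / total vessel decomposition used for TMI / MIR / MAR
density metrics.

Conventions (used package-wide):
  * rasters are square, pixel centers at integer coordinates;
  * the field (fovea) center is at ((grid_px-1)/2, (grid_px-1)/2);
  * 8-connectivity for components and skeleton topology;
  * default pixel pitch 3 mm / 512 px.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize as _sk_skeletonize

DEFAULT_FIELD_MM = 3.0
DEFAULT_GRID_PX = 512
DEFAULT_PITCH_MM = DEFAULT_FIELD_MM / DEFAULT_GRID_PX
#: macro/micro caliber cutoff in μm
DEFAULT_CALIBER_CUTOFF_UM = 25.0
#: radius (mm) of the structuring window for background removal
DEFAULT_BACKGROUND_RADIUS_MM = 0.25


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class EnFaceImage:
    """One 3x3 mm en-face angiogram raster plus acquisition metadata.

    Parameters
    ----------
    pixels
        Square 2-D array of non-negative finite intensities.
    pixel_pitch_mm
        Physical size of one pixel (field_mm / grid_px).
    laterality
        ``"OD"`` (right eye) or ``"OS"`` (left eye); may be ``None`` for
        purely synthetic rasters that never enter laterality handling.
    layer
        ``"SRL"`` | ``"DRL"`` | ``"CONJ"``.
    oriented
        True once the raster is in right-eye orientation (OS mirrored).
    """

    pixels: np.ndarray
    pixel_pitch_mm: float = DEFAULT_PITCH_MM
    laterality: str | None = None
    layer: str | None = None
    subject_id: str = ""
    group: str = ""
    oriented: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError(f"raster must be square 2-D, got {self.pixels.shape}")
        if not self.pixel_pitch_mm > 0:
            raise ValueError("pixel_pitch_mm must be > 0")
        if not np.all(np.isfinite(self.pixels)) or self.pixels.min() < 0:
            raise ValueError("intensities must be finite and >= 0")
        if self.laterality is not None and self.laterality not in ("OD", "OS"):
            raise ValueError(f"laterality must be 'OD' or 'OS', got {self.laterality!r}")

    @property
    def grid_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def field_mm(self) -> float:
        return self.grid_px * self.pixel_pitch_mm

    def with_pixels(self, pixels: np.ndarray, **meta) -> "EnFaceImage":
        """Copy of this image with new pixel data (metadata preserved)."""
        out = replace(self, **meta)
        out.pixels = np.asarray(pixels, dtype=float)
        return out


@dataclass
class VesselMaps:
    """Aligned binary vessel maps and the calibrated skeleton.

    ``micro`` and ``macro`` are disjoint and their union is ``total``
    (the TMI = MIR + MAR decomposition).  ``caliber_um`` holds the vessel
    diameter in μm at each skeleton pixel and NaN elsewhere.
    """

    total: np.ndarray
    micro: np.ndarray
    macro: np.ndarray
    skeleton: np.ndarray
    caliber_um: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        for name in ("total", "micro", "macro", "skeleton"):
            arr = np.asarray(getattr(self, name), dtype=bool)
            setattr(self, name, arr)
        if np.any(self.micro & self.macro):
            raise ValueError("micro and macro maps overlap")
        if not np.array_equal(self.micro | self.macro, self.total):
            raise ValueError("micro | macro must equal total")
        if np.any(self.skeleton & ~self.total):
            raise ValueError("skeleton must be a subset of the total map")
        on_skel = self.caliber_um[self.skeleton]
        if on_skel.size and (not np.all(np.isfinite(on_skel)) or on_skel.min() <= 0):
            raise ValueError("caliber must be finite and > 0 on skeleton pixels")

    def class_mask(self, vessel_class: str) -> np.ndarray:
        """Binary map for a vessel class: TMI (total), MIR (micro), MAR (macro)."""
        try:
            return {"TMI": self.total, "MIR": self.micro, "MAR": self.macro}[vessel_class]
        except KeyError:
            raise ValueError(f"unknown vessel class {vessel_class!r}") from None

    def class_skeleton(self, vessel_class: str) -> np.ndarray:
        return self.skeleton & self.class_mask(vessel_class)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def preprocess(
    img: EnFaceImage,
    invert: bool = False,
    background_radius_mm: float = DEFAULT_BACKGROUND_RADIUS_MM,
    stretch_percentiles: tuple[float, float] = (1.0, 99.0),
) -> EnFaceImage:
    """Normalize an angiogram: optional inversion, contrast balance,
    background removal.

    Contrast is balanced by mapping the 1st-99th intensity percentiles to
    [0, 1] (clipped).  The slowly varying background is then estimated by a
    grey-level opening with a square window spanning ``background_radius_mm``
    on each side of a pixel and subtracted (floored at 0).  Opening is
    idempotent, so on an already-normalized raster a second pass is a no-op.
    """
    x = img.pixels
    if np.ptp(x) == 0:
        warnings.warn("constant image: percentile stretch undefined, returned unchanged")
        return img.with_pixels(x.copy())
    if invert:
        x = x.max() - x
    lo, hi = np.percentile(x, stretch_percentiles)
    if hi > lo:
        x = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
    else:  # degenerate histogram: fall back to min-max
        x = (x - x.min()) / np.ptp(x)
    win = 2 * max(1, round(background_radius_mm / img.pixel_pitch_mm)) + 1
    background = ndi.grey_opening(x, size=(win, win), mode="nearest")
    x = np.clip(x - background, 0.0, None)
    return img.with_pixels(x)


def binarize(
    img: EnFaceImage,
    method: str = "otsu",
    fixed_threshold: float | None = None,
) -> np.ndarray:
    """Threshold a preprocessed image into a binary perfusion map.

    A pixel is perfusion (1) iff its intensity strictly exceeds the
    threshold; Otsu's global threshold is the default.
    """
    x = img.pixels
    if method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed thresholding requires fixed_threshold")
        thr = float(fixed_threshold)
    elif method == "otsu":
        if np.ptp(x) == 0:
            # constant raster: nothing separable, call everything background
            return np.zeros_like(x, dtype=bool)
        thr = threshold_otsu(x)
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return x > thr


def min_component_px_for_caliber(
    pixel_pitch_mm: float, caliber_um: float = DEFAULT_CALIBER_CUTOFF_UM
) -> int:
    """Area (px) of a disk of the given diameter at the given pitch.

    Used as the default size cutoff for non-vascular speckle removal: any
    component smaller than a 25 μm-diameter dot cannot be a vessel.
    """
    radius_px = (caliber_um / 2.0) / (pixel_pitch_mm * 1000.0)
    return int(np.ceil(np.pi * radius_px**2))


def remove_nonvascular(
    mask: np.ndarray,
    min_component_px: int | None = None,
    pixel_pitch_mm: float = DEFAULT_PITCH_MM,
) -> np.ndarray:
    """Delete 8-connected components smaller than ``min_component_px``."""
    mask = np.asarray(mask, dtype=bool)
    if min_component_px is None:
        min_component_px = min_component_px_for_caliber(pixel_pitch_mm)
    if min_component_px <= 0:
        return mask.copy()
    labels, _ = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_component_px
    keep[0] = False
    return keep[labels]


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Topology-preserving thinning to 1-px-wide centerlines."""
    mask = np.asarray(mask, dtype=bool)
    skel = _sk_skeletonize(mask)
    return skel & mask


def estimate_caliber(
    mask: np.ndarray, skeleton: np.ndarray, pixel_pitch_mm: float = DEFAULT_PITCH_MM
) -> np.ndarray:
    """Vessel diameter (μm) at each skeleton pixel.

    Caliber = 2 x Euclidean distance from the centerline pixel to the
    nearest background pixel, converted to μm.  A skeleton pixel adjacent
    to background therefore reads 2 x pitch, never 0.
    """
    mask = np.asarray(mask, dtype=bool)
    skeleton = np.asarray(skeleton, dtype=bool)
    if np.any(skeleton & ~mask):
        raise ValueError("skeleton must be a subset of the mask")
    caliber = np.full(mask.shape, np.nan)
    if skeleton.any():
        edt_px = ndi.distance_transform_edt(mask)
        caliber[skeleton] = 2.0 * edt_px[skeleton] * pixel_pitch_mm * 1000.0
    return caliber


def classify_vessels(
    mask: np.ndarray,
    skeleton: np.ndarray,
    caliber_um: np.ndarray,
    threshold_um: float = DEFAULT_CALIBER_CUTOFF_UM,
    macro_above: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Split the perfusion map into (micro, macro) by centerline caliber.

    Every mask pixel inherits the caliber of its nearest skeleton pixel;
    macrovessels are those with caliber strictly above ``threshold_um``
    (set ``macro_above=False`` to flip the direction of the cut).
    Returns disjoint rasters whose union is exactly ``mask``.
    """
    mask = np.asarray(mask, dtype=bool)
    skeleton = np.asarray(skeleton, dtype=bool)
    if not skeleton.any():
        if mask.any():
            warnings.warn("empty skeleton with non-empty mask: all pixels classified micro")
        return mask.copy(), np.zeros_like(mask)
    _, (ri, ci) = ndi.distance_transform_edt(~skeleton, return_indices=True)
    nearest_caliber = caliber_um[ri, ci]
    if macro_above:
        macro = mask & (nearest_caliber > threshold_um)
    else:
        macro = mask & (nearest_caliber <= threshold_um)
    micro = mask & ~macro
    return micro, macro


def build_vessel_maps(
    img: EnFaceImage,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    min_component_px: int | None = None,
    caliber_cutoff_um: float = DEFAULT_CALIBER_CUTOFF_UM,
    run_preprocess: bool = True,
    invert: bool = False,
) -> VesselMaps:
    """Full single-image chain: preprocess -> binarize -> clean ->
    skeletonize -> caliber -> micro/macro classification."""
    work = preprocess(img, invert=invert) if run_preprocess else img
    mask = binarize(work, method=method, fixed_threshold=fixed_threshold)
    mask = remove_nonvascular(mask, min_component_px, pixel_pitch_mm=img.pixel_pitch_mm)
    skel = skeletonize(mask)
    caliber = estimate_caliber(mask, skel, img.pixel_pitch_mm)
    micro, macro = classify_vessels(mask, skel, caliber, caliber_cutoff_um)
    return VesselMaps(total=mask, micro=micro, macro=macro, skeleton=skel, caliber_um=caliber)
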