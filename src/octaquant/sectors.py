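"""Macular sector geometry and eye-laterality handling.

Builds the region masks used for sectorized density analysis:

* ``annuli`` — six concentric rings C1..C6 between the 0.6 mm foveal
  avascular zone and the 2.5 mm circle (total radial bandwidth
  (2.5 - 0.6)/2 = 0.95 mm, each ring 0.95/6 ~ 0.158 mm wide);
* ``hemisphere`` — SR / SL / IL / IR quadrants split by the horizontal and
  vertical lines through the fovea;
* ``etdrs`` — S / I / L / R wedges split by the two 45-degree diagonals;
* ``whole`` — the full field (the conjunctival 3x3 mm ROI uses only this).

All names follow right-eye (OD) orientation; left-eye images are mirrored
first (``orient_to_right_eye``).  Pixel centers sit at integer coordinates
and the fovea at ((grid_px-1)/2, (grid_px-1)/2); a pixel belongs to the
region containing its center, with boundary ties broken deterministically
(toward superior then right for hemisphere lines, clockwise for diagonals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .vessel_map import DEFAULT_GRID_PX, DEFAULT_PITCH_MM, EnFaceImage

DEFAULT_FAZ_DIAMETER_MM = 0.6
DEFAULT_ANNULUS_OUTER_MM = 2.5
DEFAULT_N_RINGS = 6

HEMISPHERE_MIRROR = {"SR": "SL", "SL": "SR", "IR": "IL", "IL": "IR"}
ETDRS_MIRROR = {"S": "S", "I": "I", "L": "R", "R": "L"}


@dataclass
class SectorScheme:
    """A named partition of the analysis area into region masks."""

    name: str
    regions: dict[str, np.ndarray]
    geometry_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        stacked = np.zeros(next(iter(self.regions.values())).shape, dtype=int)
        for key, mask in self.regions.items():
            self.regions[key] = np.asarray(mask, dtype=bool)
            stacked += self.regions[key]
        if stacked.max() > 1:
            raise ValueError(f"regions of scheme {self.name!r} overlap")

    @property
    def analysis_mask(self) -> np.ndarray:
        """Union of all regions (the scheme's declared analysis area)."""
        out = np.zeros(next(iter(self.regions.values())).shape, dtype=bool)
        for mask in self.regions.values():
            out |= mask
        return out

    def region_names(self) -> list[str]:
        return list(self.regions)


def _center_offsets(grid_px: int) -> tuple[np.ndarray, np.ndarray]:
    c = (grid_px - 1) / 2.0
    rows, cols = np.mgrid[0:grid_px, 0:grid_px]
    return rows - c, cols - c


def _radius_mm(grid_px: int, pixel_pitch_mm: float) -> np.ndarray:
    dy, dx = _center_offsets(grid_px)
    return np.hypot(dy, dx) * pixel_pitch_mm


def annulus_mask(
    grid_px: int,
    pixel_pitch_mm: float,
    inner_d_mm: float,
    outer_d_mm: float,
) -> np.ndarray:
    """Pixels with inner_d/2 <= r < outer_d/2 from the field center."""
    r = _radius_mm(grid_px, pixel_pitch_mm)
    return (r >= inner_d_mm / 2.0) & (r < outer_d_mm / 2.0)


def make_whole(grid_px: int = DEFAULT_GRID_PX, pixel_pitch_mm: float = DEFAULT_PITCH_MM) -> SectorScheme:
    """Whole-field ROI (single region), e.g. the conjunctival 3x3 mm field."""
    return SectorScheme(
        name="whole",
        regions={"whole": np.ones((grid_px, grid_px), dtype=bool)},
        geometry_params={"pixel_pitch_mm": pixel_pitch_mm},
    )


def make_annuli(
    grid_px: int = DEFAULT_GRID_PX,
    pixel_pitch_mm: float = DEFAULT_PITCH_MM,
    faz_d_mm: float = DEFAULT_FAZ_DIAMETER_MM,
    outer_d_mm: float = DEFAULT_ANNULUS_OUTER_MM,
    n_rings: int = DEFAULT_N_RINGS,
) -> SectorScheme:
    """Concentric rings C1 (innermost) .. C<n_rings> between the FAZ and the
    outer circle.

    Ring i covers radii r_in + (i-1)w <= r < r_in + i*w with
    r_in = faz_d_mm/2 and w = (outer_d_mm - faz_d_mm) / (2*n_rings); the
    rings are disjoint and their union is the full annulus.
    """
    if faz_d_mm >= outer_d_mm:
        raise ValueError("faz_d_mm must be smaller than outer_d_mm")
    if outer_d_mm > grid_px * pixel_pitch_mm:
        raise ValueError("outer diameter exceeds the imaged field")
    if n_rings < 1:
        raise ValueError("n_rings must be >= 1")
    r_in = faz_d_mm / 2.0
    width = (outer_d_mm - faz_d_mm) / (2.0 * n_rings)
    r = _radius_mm(grid_px, pixel_pitch_mm)
    regions = {}
    for i in range(1, n_rings + 1):
        lo = r_in + (i - 1) * width
        hi = r_in + i * width
        regions[f"C{i}"] = (r >= lo) & (r < hi)
    return SectorScheme(
        name="annuli",
        regions=regions,
        geometry_params={
            "faz_diameter_mm": faz_d_mm,
            "annulus_outer_mm": outer_d_mm,
            "n_rings": n_rings,
            "radial_bandwidth_mm": (outer_d_mm - faz_d_mm) / 2.0,
            "ring_width_mm": width,
            "pixel_pitch_mm": pixel_pitch_mm,
        },
    )


def _within_mask(
    grid_px: int, pixel_pitch_mm: float, within: str, faz_d_mm: float, outer_d_mm: float
) -> np.ndarray:
    if within == "annulus":
        return annulus_mask(grid_px, pixel_pitch_mm, faz_d_mm, outer_d_mm)
    if within == "whole":
        return np.ones((grid_px, grid_px), dtype=bool)
    raise ValueError(f"within must be 'annulus' or 'whole', got {within!r}")


def make_hemisphere_quadrants(
    grid_px: int = DEFAULT_GRID_PX,
    pixel_pitch_mm: float = DEFAULT_PITCH_MM,
    within: str = "annulus",
    faz_d_mm: float = DEFAULT_FAZ_DIAMETER_MM,
    outer_d_mm: float = DEFAULT_ANNULUS_OUTER_MM,
) -> SectorScheme:
    """SR / SL / IL / IR quadrants split by the horizontal and vertical lines
    through the field center (image rows increase downward, so superior means
    smaller row index).  Ties on the lines go toward superior, then right.
    """
    dy, dx = _center_offsets(grid_px)
    superior = dy <= 0  # tie -> superior
    right = dx >= 0  # tie -> right
    area = _within_mask(grid_px, pixel_pitch_mm, within, faz_d_mm, outer_d_mm)
    regions = {
        "SR": superior & right & area,
        "SL": superior & ~right & area,
        "IL": ~superior & ~right & area,
        "IR": ~superior & right & area,
    }
    return SectorScheme(
        name="hemisphere",
        regions=regions,
        geometry_params={
            "within": within,
            "faz_diameter_mm": faz_d_mm,
            "annulus_outer_mm": outer_d_mm,
            "pixel_pitch_mm": pixel_pitch_mm,
        },
    )


def make_etdrs_quadrants(
    grid_px: int = DEFAULT_GRID_PX,
    pixel_pitch_mm: float = DEFAULT_PITCH_MM,
    within: str = "annulus",
    faz_d_mm: float = DEFAULT_FAZ_DIAMETER_MM,
    outer_d_mm: float = DEFAULT_ANNULUS_OUTER_MM,
) -> SectorScheme:
    """S / I / L / R wedges split by the two 45-degree diagonals through the
    center.  With theta measured counterclockwise from the +x (right) axis
    and superior up: R = (-45, 45], S = (45, 135], L = (135, 180] u
    [-180, -135], I = (-135, -45] — each boundary ray belongs to the wedge
    clockwise of it.
    """
    dy, dx = _center_offsets(grid_px)
    theta = np.degrees(np.arctan2(-dy, dx))  # up is positive
    area = _within_mask(grid_px, pixel_pitch_mm, within, faz_d_mm, outer_d_mm)
    regions = {
        "S": (theta > 45) & (theta <= 135) & area,
        "R": (theta > -45) & (theta <= 45) & area,
        "I": (theta > -135) & (theta <= -45) & area,
        "L": ((theta > 135) | (theta <= -135)) & area,
    }
    return SectorScheme(
        name="etdrs",
        regions=regions,
        geometry_params={
            "within": within,
            "faz_diameter_mm": faz_d_mm,
            "annulus_outer_mm": outer_d_mm,
            "pixel_pitch_mm": pixel_pitch_mm,
        },
    )


def default_schemes_for_layer(
    layer: str,
    grid_px: int = DEFAULT_GRID_PX,
    pixel_pitch_mm: float = DEFAULT_PITCH_MM,
    faz_d_mm: float = DEFAULT_FAZ_DIAMETER_MM,
    outer_d_mm: float = DEFAULT_ANNULUS_OUTER_MM,
    n_rings: int = DEFAULT_N_RINGS,
) -> list[SectorScheme]:
    """The sectorizations analyzed for a layer: retinal layers get annuli,
    hemisphere and ETDRS quadrants plus the whole field; the conjunctiva uses
    only the whole 3x3 mm ROI."""
    if layer == "CONJ":
        return [make_whole(grid_px, pixel_pitch_mm)]
    common = dict(faz_d_mm=faz_d_mm, outer_d_mm=outer_d_mm)
    return [
        make_annuli(grid_px, pixel_pitch_mm, n_rings=n_rings, **common),
        make_hemisphere_quadrants(grid_px, pixel_pitch_mm, **common),
        make_etdrs_quadrants(grid_px, pixel_pitch_mm, **common),
        make_whole(grid_px, pixel_pitch_mm),
    ]


def flip_horizontal(pixels: np.ndarray) -> np.ndarray:
    """Mirror a raster about its vertical axis (an involution)."""
    return np.asarray(pixels)[:, ::-1].copy()


def orient_to_right_eye(img: EnFaceImage) -> EnFaceImage:
    """Mirror OS (left-eye) images to right-eye orientation; OD unchanged.

    Pooling both eyes requires a common anatomical frame, so left-eye data
    are flipped about the vertical axis before sectorized analysis.
    """
    if img.laterality is None:
        raise ValueError("cannot orient an image without laterality metadata")
    if img.oriented or img.laterality == "OD":
        return img.with_pixels(img.pixels.copy(), oriented=True)
    return img.with_pixels(flip_horizontal(img.pixels), oriented=True)


def mirror_region_name(scheme_name: str, region: str) -> str:
    """Region label that a horizontal mirror maps onto (identity for
    annuli/whole, SR<->SL IL<->IR for hemisphere, L<->R for ETDRS)."""
    if scheme_name == "hemisphere":
        return HEMISPHERE_MIRROR[region]
    if scheme_name == "etdrs":
        return ETDRS_MIRROR[region]
    return region
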