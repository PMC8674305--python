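"""Synthetic en-face angiograms with known ground truth.

No public OCTA dataset accompanies the study conditions this package
targets, so every downstream stage is validated against simulated
angiograms whose vessel geometry, perfusion fraction and caliber mix are
known exactly.

The generator grows a branching vascular network with seeded, biased
random walkers: each walker lays down a stroke of a caliber sampled from
the spec's caliber mixture, may spawn branches, and avoids re-entering
already-perfused tissue.  Strokes accumulate until the rasterized
perfusion fraction (outside the foveal avascular zone) reaches the target
within +/-0.02.  Because the walker sequence depends only on the RNG seed
— never on the target — raising the target with the same seed only extends
the same network, so realized perfusion is monotone in the target and a
given (spec, seed) pair is bitwise reproducible.

Cohorts draw per-subject latent (deep-retinal, conjunctival) density pairs
from a bivariate normal with a configurable (negative) correlation, then
rasterize one image per eye per layer, mirroring left eyes in construction
so laterality handling is exercised end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sectors import annulus_mask, flip_horizontal
from .vessel_map import DEFAULT_FIELD_MM, DEFAULT_GRID_PX, EnFaceImage

#: achieved-density tolerance (absolute perfusion fraction)
DENSITY_TOL = 0.02
#: caliber mixture (diameter μm, weight) for retinal layers: capillaries
#: straddling the 25 μm macro/micro cutoff plus a few arteriole-scale trunks
RETINAL_CALIBERS = ((12.0, 0.30), (16.0, 0.30), (20.0, 0.20), (35.0, 0.15), (60.0, 0.05))
#: conjunctival plexus: denser fine calibers, no trunks, no FAZ
CONJ_CALIBERS = ((10.0, 0.35), (14.0, 0.35), (18.0, 0.20), (28.0, 0.10))

LAYERS = ("SRL", "DRL", "CONJ")
GROUPS = ("control", "case")


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic angiogram."""

    target_perfusion: float
    field_mm: float = DEFAULT_FIELD_MM
    grid_px: int = DEFAULT_GRID_PX
    caliber_dist: tuple[tuple[float, float], ...] = RETINAL_CALIBERS
    faz_diameter_mm: float = 0.6
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_perfusion <= 1.0:
            raise ValueError("target_perfusion must be in [0, 1]")
        if self.grid_px < 64:
            raise ValueError("grid_px must be >= 64")
        weights = [w for _, w in self.caliber_dist]
        if any(w < 0 for w in weights) or not math.isclose(sum(weights), 1.0, abs_tol=1e-9):
            raise ValueError("caliber weights must be >= 0 and sum to 1")
        if any(d <= 0 for d, _ in self.caliber_dist):
            raise ValueError("caliber diameters must be > 0")
        if not self.faz_diameter_mm < self.field_mm:
            raise ValueError("faz_diameter_mm must be smaller than field_mm")
        if not 0.0 <= self.noise < 1.0:
            raise ValueError("noise amplitude must be in [0, 1)")

    @property
    def pixel_pitch_mm(self) -> float:
        return self.field_mm / self.grid_px


@dataclass
class GroundTruth:
    """Exact geometry behind one synthetic angiogram."""

    vessel_mask: np.ndarray
    #: list of (polyline array of (row, col) px, diameter μm)
    centerlines: list[tuple[np.ndarray, float]]
    #: region name -> true perfusion fraction, by pixel counting
    per_region_density: dict[str, float]


@dataclass
class CohortSpec:
    """Structure of a simulated two-group, two-eye cohort.

    ``group_means`` maps (group, layer) to the mean target perfusion of that
    group's subjects in that layer; ``conj_retina_rho`` is the latent
    correlation between a subject's conjunctival and deep-retinal densities
    (negative to emulate the compensatory-perfusion pattern of interest).
    """

    n_per_group: int = 12
    group_means: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_MEANS))
    between_subject_sd: float = 0.04
    conj_retina_rho: float = -0.9
    eyes_per_subject: int = 2
    seed: int = 0
    grid_px: int = DEFAULT_GRID_PX
    field_mm: float = DEFAULT_FIELD_MM
    noise: float = 0.1

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2 (statistics undefined below)")
        if abs(self.conj_retina_rho) > 1:
            raise ValueError("|conj_retina_rho| must be <= 1")
        for key, mean in self.group_means.items():
            if not 0.0 <= mean <= 1.0:
                raise ValueError(f"group mean for {key} outside [0, 1]")
        if self.eyes_per_subject not in (1, 2):
            raise ValueError("eyes_per_subject must be 1 or 2")

    @property
    def layers(self) -> list[str]:
        seen = []
        for _, layer in self.group_means:
            if layer not in seen:
                seen.append(layer)
        return seen


#: study conditions emulated by default: deep-retinal perfusion deficit of
#: 1.5 between-subject SDs in cases, conjunctival excess of the same size,
#: no superficial-layer group difference
DEFAULT_GROUP_MEANS = {
    ("control", "SRL"): 0.45,
    ("case", "SRL"): 0.45,
    ("control", "DRL"): 0.40,
    ("case", "DRL"): 0.34,
    ("control", "CONJ"): 0.30,
    ("case", "CONJ"): 0.36,
}


# ---------------------------------------------------------------------------
# single-image generation
# ---------------------------------------------------------------------------

def _disk_offsets(radius_px: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(math.ceil(radius_px))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy * dy + dx * dx <= radius_px * radius_px
    return dy[keep], dx[keep]


def _stamp(mask, valid, points, offsets, grid_px):
    """Stamp disk offsets at integer points; returns newly set pixel count."""
    dy, dx = offsets
    new = 0
    for r, c in points:
        rr = dy + r
        cc = dx + c
        keep = (rr >= 0) & (rr < grid_px) & (cc >= 0) & (cc < grid_px)
        rr, cc = rr[keep], cc[keep]
        fresh = valid[rr, cc] & ~mask[rr, cc]
        mask[rr, cc] |= valid[rr, cc]
        new += int(fresh.sum())
    return new


def generate_tree(
    spec: SyntheticSpec, max_walkers: int = 200_000
) -> tuple[EnFaceImage, GroundTruth]:
    """Grow one branching vascular network and render its angiogram.

    Returns the speckled grayscale image (background ~0.1, vessels ~0.9
    before noise) and the exact ground truth.  Raises ``RuntimeError`` if
    the target perfusion cannot be packed within the ``max_walkers`` budget.
    """
    rng = np.random.default_rng(spec.seed)
    g = spec.grid_px
    pitch_um = spec.pixel_pitch_mm * 1000.0

    if spec.faz_diameter_mm > 0:
        valid = ~annulus_mask(g, spec.pixel_pitch_mm, 0.0, spec.faz_diameter_mm)
    else:
        valid = np.ones((g, g), dtype=bool)
    n_valid = int(valid.sum())

    mask = np.zeros((g, g), dtype=bool)
    centerlines: list[tuple[np.ndarray, float]] = []
    diameters = np.array([d for d, _ in spec.caliber_dist])
    weights = np.array([w for _, w in spec.caliber_dist])
    offsets_cache = {d: _disk_offsets(max(d / 2.0 / pitch_um, 0.5)) for d in diameters}

    count = 0
    if spec.target_perfusion > 0:
        stop_frac = spec.target_perfusion - DENSITY_TOL / 4.0
        reached = False
        for _ in range(max_walkers):
            if count / n_valid >= stop_frac:
                reached = True
                break
            diameter = float(rng.choice(diameters, p=weights))
            offsets = offsets_cache[diameter]
            # walker state: position, heading, steps left
            pos = rng.uniform(0, g - 1, size=2)
            theta = rng.uniform(0.0, 2.0 * math.pi)
            n_steps = int(rng.integers(30, 90))
            branch_p = 0.02
            stack = [(pos, theta, n_steps)]
            while stack:
                pos, theta, steps = stack.pop()
                path = [pos.copy()]
                for _ in range(steps):
                    theta += rng.normal(0.0, 0.25)
                    pos = pos + np.array([-math.sin(theta), math.cos(theta)])
                    # reflect at the field border
                    for ax in (0, 1):
                        if pos[ax] < 0:
                            pos[ax] = -pos[ax]
                            theta = -theta if ax == 0 else math.pi - theta
                        elif pos[ax] > g - 1:
                            pos[ax] = 2 * (g - 1) - pos[ax]
                            theta = -theta if ax == 0 else math.pi - theta
                    head = (int(round(pos[0])), int(round(pos[1])))
                    # self-avoidance: mostly stop on re-entering perfused tissue
                    if mask[head] and rng.random() < 0.5:
                        break
                    path.append(pos.copy())
                    if rng.random() < branch_p and len(stack) < 6:
                        stack.append(
                            (pos.copy(), theta + rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.2),
                             max(steps // 2, 10))
                        )
                pts = np.rint(np.array(path)).astype(int)
                count += _stamp(mask, valid, pts, offsets, g)
                centerlines.append((np.array(path), diameter))
        if not reached and count / n_valid < stop_frac:
            raise RuntimeError(
                f"target perfusion {spec.target_perfusion} unreachable: "
                f"stalled at {count / n_valid:.3f} after {max_walkers} walkers"
            )

    image = 0.1 + 0.8 * mask.astype(float)
    if spec.noise > 0:
        image = image * (1.0 + spec.noise * rng.standard_normal(image.shape))
    image = np.clip(image, 0.0, 1.0)

    per_region = {
        "whole": float(mask.mean()),
        "analysis": float(mask[valid].sum() / n_valid),
    }
    gt = GroundTruth(vessel_mask=mask, centerlines=centerlines, per_region_density=per_region)
    return (
        EnFaceImage(image, pixel_pitch_mm=spec.pixel_pitch_mm),
        gt,
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def draw_cohort_latents(cohort: CohortSpec) -> pd.DataFrame:
    """Per-subject latent true densities, before any rasterization.

    One row per subject per layer with columns subject_id, group, layer,
    true_density.  DRL and CONJ densities come from a correlated bivariate
    normal (correlation ``conj_retina_rho``); any other layer is an
    independent normal.  All values are clipped to [0.05, 0.95].
    """
    rng = np.random.default_rng(cohort.seed)
    rho = cohort.conj_retina_rho
    rows = []
    for group in GROUPS:
        for i in range(cohort.n_per_group):
            sid = f"{group[:3]}{i + 1:03d}"
            z_ret = rng.standard_normal()
            z_conj = rho * z_ret + math.sqrt(max(1.0 - rho * rho, 0.0)) * rng.standard_normal()
            for layer in cohort.layers:
                if (group, layer) not in cohort.group_means:
                    continue
                mean = cohort.group_means[(group, layer)]
                if layer == "DRL":
                    z = z_ret
                elif layer == "CONJ":
                    z = z_conj
                else:
                    z = rng.standard_normal()
                density = float(np.clip(mean + cohort.between_subject_sd * z, 0.05, 0.95))
                rows.append({"subject_id": sid, "group": group, "layer": layer,
                             "true_density": density})
    return pd.DataFrame(rows)


def generate_cohort(
    cohort: CohortSpec,
) -> tuple[list[tuple[EnFaceImage, GroundTruth]], pd.DataFrame]:
    """Rasterize a full cohort: one image per subject per eye per layer.

    Left-eye (OS) images are horizontal mirrors by construction, so the
    laterality-handling path is exercised downstream.  Returns the list of
    (image, ground truth) pairs and the latent-density table from
    :func:`draw_cohort_latents` (the generator's own truth).
    """
    latents = draw_cohort_latents(cohort)
    rng = np.random.default_rng(cohort.seed + 1)
    pairs: list[tuple[EnFaceImage, GroundTruth]] = []
    eyes = ["OD", "OS"][: cohort.eyes_per_subject]
    for row in latents.itertuples(index=False):
        layer = row.layer
        for eye in eyes:
            spec = SyntheticSpec(
                target_perfusion=row.true_density,
                field_mm=cohort.field_mm,
                grid_px=cohort.grid_px,
                caliber_dist=CONJ_CALIBERS if layer == "CONJ" else RETINAL_CALIBERS,
                faz_diameter_mm=0.0 if layer == "CONJ" else 0.6,
                noise=cohort.noise,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            img, gt = generate_tree(spec)
            pixels = img.pixels
            if eye == "OS":  # mirrored in construction
                pixels = flip_horizontal(pixels)
                gt = GroundTruth(
                    vessel_mask=flip_horizontal(gt.vessel_mask),
                    centerlines=gt.centerlines,
                    per_region_density=gt.per_region_density,
                )
            pairs.append(
                (
                    EnFaceImage(
                        pixels,
                        pixel_pitch_mm=img.pixel_pitch_mm,
                        laterality=eye,
                        layer=layer,
                        subject_id=row.subject_id,
                        group=row.group,
                    ),
                    gt,
                )
            )
    return pairs, latents


def write_cohort(
    pairs: list[tuple[EnFaceImage, GroundTruth]],
    latents: pd.DataFrame,
    outdir: str | Path,
) -> Path:
    """Write cohort images (8-bit grayscale PNG), a manifest CSV and the
    per-image ground-truth densities; returns the manifest path."""
    from PIL import Image

    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    truth_rows = []
    for img, gt in pairs:
        name = f"{img.subject_id}_{img.laterality}_{img.layer}.png"
        path = outdir / "images" / name
        Image.fromarray(np.round(img.pixels * 255).astype(np.uint8), mode="L").save(path)
        rows.append(
            {
                "subject_id": img.subject_id,
                "group": img.group,
                "eye": img.laterality,
                "layer": img.layer,
                "path": str(Path("images") / name),
            }
        )
        for region, value in gt.per_region_density.items():
            truth_rows.append(
                {"subject_id": img.subject_id, "eye": img.laterality,
                 "layer": img.layer, "region": region, "true_density": value}
            )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    pd.DataFrame(truth_rows).to_csv(outdir / "ground_truth.csv", index=False)
    latents.to_csv(outdir / "latents.csv", index=False)
    return manifest
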