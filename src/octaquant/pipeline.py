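"""End-to-end orchestration: manifest in, density records and statistics out.

Also carries the OCTA scan-protocol arithmetic (B-scans per volume, total
A-scans) used to sanity-check acquisition settings.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd

from . import density as dens
from . import sectors as sect
from . import stats as st
from . import vessel_map as vm

logger = logging.getLogger("octaquant")

RETINAL_LAYERS = ("SRL", "DRL")


@dataclass(frozen=True)
class ScanProtocol:
    """Acquisition protocol of a 3x3 mm OCTA scan.

    Defaults mirror a swept-raster protocol with 216 y raster positions,
    five repeated B-scans per position, 216 A-scans per B-scan, four volume
    scans (two horizontal + two vertical rasters), 270 B-scans/s and a
    3.9 s acquisition.
    """

    y_positions: int = 216
    repeats_per_position: int = 5
    a_scans_per_b: int = 216
    volumes: int = 4
    frame_rate: float = 270.0
    acquisition_s: float = 3.9

    def __post_init__(self) -> None:
        for name in ("y_positions", "repeats_per_position", "a_scans_per_b", "volumes"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.frame_rate <= 0 or self.acquisition_s <= 0:
            raise ValueError("frame_rate and acquisition_s must be positive")


def validate_protocol(p: ScanProtocol) -> dict[str, int]:
    """Derived acquisition counts.

    b_scans_per_volume = y_positions x repeats; total_a_scans = volumes x
    b_scans_per_volume x a_scans_per_b.  The frame-rate/acquisition-time
    identity is deliberately not enforced: reported protocols are often
    rounded and internally inconsistent, so only the exact multiplicative
    counts are derived.
    """
    b_per_vol = p.y_positions * p.repeats_per_position
    return {
        "b_scans_per_volume": int(b_per_vol),
        "total_a_scans": int(p.volumes * b_per_vol * p.a_scans_per_b),
    }


@dataclass
class RunConfig:
    """One quantification run: manifest-driven, fully reproducible."""

    manifest: str | Path
    outdir: str | Path
    field_mm: float = vm.DEFAULT_FIELD_MM
    faz_diameter_mm: float = sect.DEFAULT_FAZ_DIAMETER_MM
    annulus_outer_mm: float = sect.DEFAULT_ANNULUS_OUTER_MM
    n_rings: int = sect.DEFAULT_N_RINGS
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    caliber_cutoff_um: float = vm.DEFAULT_CALIBER_CUTOFF_UM
    analysis_level: str = "subject"  # 'subject' (eyes averaged) or 'eye'
    t_variant: str = "welch"
    adjust: str | None = None
    seed: int = 0
    schemes: tuple[str, ...] = ("annuli", "hemisphere", "etdrs", "whole")

    def __post_init__(self) -> None:
        if self.caliber_cutoff_um <= 0:
            raise ValueError("caliber cutoff must be > 0")
        if self.analysis_level not in ("subject", "eye"):
            raise ValueError("analysis_level must be 'subject' or 'eye'")


REQUIRED_MANIFEST_COLUMNS = ("subject_id", "group", "eye", "layer", "path")


def load_image(path: Path, field_mm: float = vm.DEFAULT_FIELD_MM, **meta) -> vm.EnFaceImage:
    """Read an 8/16-bit grayscale PNG or TIFF into an EnFaceImage in [0, 1];
    the pixel pitch follows from the raster width and the physical field."""
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        arr = np.asarray(tifffile.imread(path), dtype=float)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("I"), dtype=float)
    if arr.max() > 0:
        arr = arr / (255.0 if arr.max() <= 255 else 65535.0)
    return vm.EnFaceImage(arr, pixel_pitch_mm=field_mm / arr.shape[0], **meta)


def quantify_image(img: vm.EnFaceImage, cfg: RunConfig) -> list[dens.DensityRecord]:
    """Single-image chain: orient -> vessel maps -> sectorize -> densities."""
    img = sect.orient_to_right_eye(img)
    maps = vm.build_vessel_maps(
        img,
        method=cfg.threshold_method,
        fixed_threshold=cfg.fixed_threshold,
        caliber_cutoff_um=cfg.caliber_cutoff_um,
    )
    schemes = [
        s
        for s in sect.default_schemes_for_layer(
            img.layer or "SRL",
            grid_px=img.grid_px,
            pixel_pitch_mm=img.pixel_pitch_mm,
            faz_d_mm=cfg.faz_diameter_mm,
            outer_d_mm=cfg.annulus_outer_mm,
            n_rings=cfg.n_rings,
        )
        if s.name in cfg.schemes or (img.layer == "CONJ" and s.name == "whole")
    ]
    return dens.compute_all(
        maps,
        schemes,
        subject_id=img.subject_id,
        group=img.group,
        eye=img.laterality or "OD",
        layer=img.layer or "",
        pixel_pitch_mm=img.pixel_pitch_mm,
    )


def run_pipeline(cfg: RunConfig) -> Path:
    """Process every manifest row and write density records, subject-level
    averages, comparison tables and a run log.  Returns the output directory.

    Unreadable images are skipped and logged; the run aborts only if a whole
    group ends up empty.  Reruns with the same config are bit-identical.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = Path(cfg.manifest)
    manifest = pd.read_csv(manifest_path)
    missing = [c for c in REQUIRED_MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest lacks required columns: {missing}")

    records: list[dens.DensityRecord] = []
    log_rows = []
    for row in manifest.itertuples(index=False):
        img_path = Path(row.path)
        if not img_path.is_absolute():
            img_path = manifest_path.parent / img_path
        try:
            img = load_image(
                img_path,
                field_mm=cfg.field_mm,
                laterality=row.eye,
                layer=row.layer,
                subject_id=str(row.subject_id),
                group=row.group,
            )
            records.extend(quantify_image(img, cfg))
            log_rows.append({"path": str(row.path), "status": "processed", "reason": ""})
        except (OSError, ValueError) as exc:
            logger.warning("skipping %s: %s", row.path, exc)
            log_rows.append({"path": str(row.path), "status": "skipped", "reason": str(exc)})

    eye_df = dens.records_to_frame(records)
    if eye_df.empty or eye_df["group"].nunique() < 2:
        _write_log(outdir, cfg, log_rows)
        raise RuntimeError("a group is empty after filtering; no statistics possible")

    eye_df.to_csv(outdir / "density_eye.csv", index=False)
    subj_df = dens.subject_average(eye_df)
    subj_df.to_csv(outdir / "density_subject.csv", index=False)

    analysed = subj_df if cfg.analysis_level == "subject" else eye_df
    table = st.region_comparison_table(
        analysed, level=cfg.analysis_level, variant=cfg.t_variant, adjust=cfg.adjust
    )
    table.to_csv(outdir / "region_comparison.csv", index=False)
    for metric in dens.METRICS:
        dens.pivot_region_table(analysed, metric).to_csv(outdir / f"region_means_{metric}.csv")

    _write_log(outdir, cfg, log_rows)
    return outdir


def _write_log(outdir: Path, cfg: RunConfig, log_rows: list[dict]) -> None:
    try:
        version = metadata.version("octaquant")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    payload = {
        "config": {k: str(v) if isinstance(v, Path) else v for k, v in asdict(cfg).items()},
        "seed": cfg.seed,
        "version": version,
        "images": log_rows,
    }
    (outdir / "run_log.json").write_text(json.dumps(payload, indent=2, default=str))
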