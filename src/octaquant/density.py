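"""Perfusion (area) and skeleton (length) density metrics.

Perfusion density is the fraction of a region's area occupied by perfused
vessel pixels; skeleton density is the total centerline length per unit
region area (mm/mm^2).  Both are computed per region of a sector scheme
and per vessel class (TMI = total, MIR = micro, MAR = macro), then
aggregated from eye level to subject level by averaging the two eyes.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .sectors import SectorScheme
from .vessel_map import VesselMaps

VESSEL_CLASSES = ("TMI", "MIR", "MAR")
METRICS = ("perfusion", "skeleton")
#: eye marker for subject-level (both-eyes-averaged) records
BOTH_EYES = "OU"

RECORD_KEY = ["subject_id", "group", "eye", "layer", "scheme", "region",
              "vessel_class", "metric"]


@dataclass(frozen=True)
class DensityRecord:
    """One (subject, eye, layer, scheme, region, class, metric) -> value row."""

    subject_id: str
    group: str
    eye: str
    layer: str
    scheme: str
    region: str
    vessel_class: str
    metric: str
    value: float

    def __post_init__(self) -> None:
        if self.metric == "perfusion" and not 0.0 <= self.value <= 1.0:
            raise ValueError(f"perfusion density {self.value} outside [0, 1]")
        if self.value < 0:
            raise ValueError("density values must be >= 0")


def perfusion_density(mask: np.ndarray, region: np.ndarray) -> float:
    """|mask AND region| / |region| — perfused-area fraction of the region."""
    mask = np.asarray(mask, dtype=bool)
    region = np.asarray(region, dtype=bool)
    if mask.shape != region.shape:
        raise ValueError("mask and region shapes differ")
    n_region = int(region.sum())
    if n_region == 0:
        raise ValueError("empty region: perfusion density undefined")
    return float((mask & region).sum() / n_region)


def skeleton_density(
    skeleton: np.ndarray,
    region: np.ndarray,
    pixel_pitch_mm: float,
    diagonal_correction: bool = False,
) -> float:
    """Centerline length per region area, in mm per mm^2.

    Default length is skeleton-pixel count x pixel pitch (pure pixel-distance
    scaling).  With ``diagonal_correction`` the length is instead summed over
    centerline adjacencies (pitch for axial steps, sqrt(2) x pitch for
    diagonal steps), which undercounts isolated pixels but respects geometry.
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    region = np.asarray(region, dtype=bool)
    if skeleton.shape != region.shape:
        raise ValueError("skeleton and region shapes differ")
    n_region = int(region.sum())
    if n_region == 0:
        raise ValueError("empty region: skeleton density undefined")
    s = skeleton & region
    if not diagonal_correction:
        length_mm = float(s.sum()) * pixel_pitch_mm
    else:
        axial = np.count_nonzero(s[:, :-1] & s[:, 1:]) + np.count_nonzero(s[:-1, :] & s[1:, :])
        diag = np.count_nonzero(s[:-1, :-1] & s[1:, 1:]) + np.count_nonzero(s[:-1, 1:] & s[1:, :-1])
        length_mm = (axial + np.sqrt(2.0) * diag) * pixel_pitch_mm
    area_mm2 = n_region * pixel_pitch_mm**2
    return length_mm / area_mm2


def compute_all(
    maps: VesselMaps,
    schemes: list[SectorScheme],
    subject_id: str = "",
    group: str = "",
    eye: str = "",
    layer: str = "",
    pixel_pitch_mm: float | None = None,
    diagonal_correction: bool = False,
) -> list[DensityRecord]:
    """One DensityRecord per region x vessel class x metric, in a fixed
    deterministic order (scheme, region, class, metric)."""
    if pixel_pitch_mm is None:
        raise ValueError("pixel_pitch_mm is required for skeleton densities")
    records = []
    for scheme in schemes:
        for region_name, region in scheme.regions.items():
            for vc in VESSEL_CLASSES:
                vmask = maps.class_mask(vc)
                vskel = maps.class_skeleton(vc)
                for metric in METRICS:
                    if metric == "perfusion":
                        value = perfusion_density(vmask, region)
                    else:
                        value = skeleton_density(
                            vskel, region, pixel_pitch_mm,
                            diagonal_correction=diagonal_correction,
                        )
                    records.append(
                        DensityRecord(
                            subject_id=subject_id, group=group, eye=eye, layer=layer,
                            scheme=scheme.name, region=region_name,
                            vessel_class=vc, metric=metric, value=value,
                        )
                    )
    return records


def records_to_frame(records: list[DensityRecord]) -> pd.DataFrame:
    """Tidy DataFrame of density records (one row per record)."""
    df = pd.DataFrame([asdict(r) for r in records])
    if not df.empty and df.duplicated(subset=RECORD_KEY).any():
        raise ValueError("duplicate (subject, eye, layer, scheme, region, class, metric) rows")
    return df


def subject_average(records: pd.DataFrame | list[DensityRecord]) -> pd.DataFrame:
    """Average the two eyes of each subject into one value per
    subject/layer/scheme/region/class/metric (eye marked ``OU``).

    Eye-level records must already be in right-eye orientation so that
    mirrored regions correspond anatomically.  Single-eye subjects pass
    through with a warning.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    key = [c for c in RECORD_KEY if c != "eye"]
    n_eyes = df.groupby(key, sort=False)["eye"].nunique()
    if (n_eyes < 2).any():
        n_single = df.loc[:, ["subject_id", "layer"]].drop_duplicates().shape[0]
        warnings.warn(
            f"some of the {n_single} subject/layer cells have a single eye; "
            "their values pass through unaveraged"
        )
    out = df.groupby(key, sort=False, as_index=False)["value"].mean()
    out.insert(2, "eye", BOTH_EYES)
    return out


def pivot_region_table(df: pd.DataFrame, metric: str = "perfusion") -> pd.DataFrame:
    """Wide per-region table (rows = layer/scheme/region, columns = group x
    vessel class mean) mirroring the per-sector layout of cohort reports."""
    sub = df[df["metric"] == metric]
    return sub.pivot_table(
        index=["layer", "scheme", "region"],
        columns=["group", "vessel_class"],
        values="value",
        aggfunc="mean",
    )
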