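"""Stack and measurement-table I/O.

Stacks are multi-page TIFFs with the two channels interleaved per slice
(slice 0 / pre-synaptic, slice 0 / end-plate, slice 1 / pre-synaptic,
...), 12-bit data in a 16-bit container.  A JSON sidecar next to the
TIFF records voxel size, channel roles, the generator seed, and — for
synthetic stacks — the scalar ground truth.

Measurement tables are plain CSV, one row per NMJ.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .datamodel import (
    AnimalRecord,
    CHANNEL_ROLES,
    DEFAULT_VOXEL_SIZE,
    FormatError,
    ImageStack,
    IntegrityError,
    MAX_INTENSITY,
    NMJRecord,
)

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = [
    "animal_id",
    "sex",
    "treatment",
    "age_months",
    "body_mass_pre",
    "body_mass_post",
    "nmj_id",
    "pre_volume",
    "endplate_volume",
    "planar_area",
    "axes_area",
    "relative_planar_area",
    "apposition_pct",
    "category",
    "valid",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(stack: ImageStack, path, sidecar: Optional[dict] = None) -> Path:
    """Write a two-channel stack as an interleaved multi-page TIFF plus a
    JSON sidecar with the physical metadata."""
    path = Path(path)
    pages = np.empty((2 * stack.n_slices,) + stack.voxels.shape[2:], dtype=np.uint16)
    for ch in range(2):
        pages[ch::2] = stack.voxels[ch].astype(np.uint16)
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "voxel_size_um": list(stack.voxel_size),
        "channel_roles": list(stack.channel_roles),
        **(stack.metadata or {}),
        **(sidecar or {}),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_stack(path) -> ImageStack:
    """Read an interleaved two-channel multi-page TIFF.

    Voxel size and channel roles come from the JSON sidecar when
    present; otherwise the defaults are used with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise FormatError(f"{path}: expected a flat page series, got shape {pages.shape}")
    if pages.shape[0] % 2 != 0:
        raise FormatError(
            f"{path}: odd page count {pages.shape[0]}; two interleaved channels expected"
        )
    if pages.dtype != np.uint16:
        raise FormatError(f"{path}: 16-bit container required, got dtype {pages.dtype}")
    if pages.max(initial=0) > MAX_INTENSITY:
        raise FormatError(
            f"{path}: intensities exceed the 12-bit range (max {pages.max()})"
        )
    voxels = np.stack([pages[0::2], pages[1::2]])

    voxel_size = DEFAULT_VOXEL_SIZE
    roles = CHANNEL_ROLES
    metadata: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        metadata = json.loads(sidecar.read_text())
        voxel_size = tuple(metadata.pop("voxel_size_um", voxel_size))
        roles = tuple(metadata.pop("channel_roles", roles))
    else:
        logger.warning("%s: no sidecar; assuming voxel size %s µm", path, DEFAULT_VOXEL_SIZE)
    return ImageStack(
        voxels=voxels, voxel_size=voxel_size, channel_roles=roles, metadata=metadata
    )


def records_to_frame(animals: Sequence[AnimalRecord]) -> pd.DataFrame:
    """Flatten animal records into one row per NMJ."""
    rows = []
    for animal in animals:
        seen = set()
        for rec in animal.nmjs:
            if rec.nmj_id in seen:
                raise IntegrityError(
                    f"duplicate nmj_id {rec.nmj_id!r} within animal {animal.animal_id!r}"
                )
            seen.add(rec.nmj_id)
            rows.append(
                {
                    "animal_id": animal.animal_id,
                    "sex": animal.sex,
                    "treatment": animal.treatment,
                    "age_months": animal.age_months,
                    "body_mass_pre": animal.body_mass_pre,
                    "body_mass_post": animal.body_mass_post,
                    "nmj_id": rec.nmj_id,
                    "pre_volume": rec.pre_volume,
                    "endplate_volume": rec.endplate_volume,
                    "planar_area": rec.planar_area,
                    "axes_area": rec.axes_area,
                    "relative_planar_area": rec.relative_planar_area,
                    "apposition_pct": rec.apposition_pct,
                    "category": rec.category,
                    "valid": rec.valid,
                }
            )
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list:
    """Inverse of :func:`records_to_frame`."""
    animals = []
    for animal_id, sub in frame.groupby("animal_id", sort=False):
        first = sub.iloc[0]
        nmjs = [
            NMJRecord(
                nmj_id=row.nmj_id,
                pre_volume=float(row.pre_volume),
                endplate_volume=float(row.endplate_volume),
                planar_area=float(row.planar_area),
                axes_area=float(row.axes_area),
                relative_planar_area=float(row.relative_planar_area),
                apposition_pct=float(row.apposition_pct),
                category=row.category,
                valid=bool(row.valid),
            )
            for row in sub.itertuples()
        ]
        animals.append(
            AnimalRecord(
                animal_id=animal_id,
                sex=first.sex,
                treatment=first.treatment,
                age_months=float(first.age_months),
                body_mass_pre=float(first.body_mass_pre),
                body_mass_post=float(first.body_mass_post),
                nmjs=nmjs,
            )
        )
    return animals


def write_measurements(animals: Sequence[AnimalRecord], path) -> Path:
    """Write the per-NMJ measurement table as CSV (header always
    present, even for an empty cohort)."""
    path = Path(path)
    records_to_frame(animals).to_csv(path, index=False)
    return path


def read_measurements(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(
        path, dtype={"animal_id": str, "nmj_id": str, "category": str, "valid": bool}
    )
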