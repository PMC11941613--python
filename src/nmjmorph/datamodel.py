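"""Core data containers for the NMJ morphometry pipeline.

Conventions used throughout the package:

* 3D arrays are indexed ``(z, y, x)``; multi-channel stacks are
  ``(channel, z, y, x)``.
* Physical sizes are micrometres; voxel size is the ``(dz, dy, dx)``
  triple, default ``(1.0, 0.5, 0.5)`` µm (confocal z-step 1 µm, pixel
  0.5 µm).
* Intensities live in the 12-bit range 0–4095 inside a 16-bit container.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

MAX_INTENSITY = 4095
DEFAULT_VOXEL_SIZE = (1.0, 0.5, 0.5)

PRE_SYNAPTIC = "pre_synaptic"
END_PLATE = "end_plate"
CHANNEL_ROLES = (PRE_SYNAPTIC, END_PLATE)

INNERVATED = "innervated"
PARTIALLY_DENERVATED = "partially_denervated"
FULLY_DENERVATED = "fully_denervated"
CATEGORIES = (INNERVATED, PARTIALLY_DENERVATED, FULLY_DENERVATED)

VEHICLE = "vehicle"
CHLOROQUINE = "chloroquine"
TREATMENTS = (VEHICLE, CHLOROQUINE)


class FormatError(ValueError):
    """A file or array violates the stack/table format contract."""


class IntegrityError(ValueError):
    """Records are internally inconsistent (e.g. duplicate ids)."""


class GenerationError(RuntimeError):
    """A synthetic target is not realizable inside the stack bounds."""


def _positive_triple(name: str, value: Sequence[float]) -> tuple:
    triple = tuple(float(v) for v in value)
    if len(triple) != 3 or any(v <= 0 or not np.isfinite(v) for v in triple):
        raise ValueError(f"{name} must be a positive finite (z, y, x) triple, got {value!r}")
    return triple


@dataclass
class ImageStack:
    """A two-channel 3D confocal stack with physical voxel dimensions.

    ``voxels`` has shape ``(2, n_slices, ny, nx)``.  Channel order follows
    ``channel_roles`` (pre-synaptic terminal, motor end-plate by default).
    """

    voxels: np.ndarray
    voxel_size: tuple = DEFAULT_VOXEL_SIZE
    channel_roles: tuple = CHANNEL_ROLES
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise FormatError(
                f"stack must be (channel, z, y, x), got ndim={self.voxels.ndim}"
            )
        if self.voxels.shape[0] != 2:
            raise FormatError(
                f"exactly 2 channels required, got {self.voxels.shape[0]}"
            )
        if len(self.channel_roles) != 2 or len(set(self.channel_roles)) != 2:
            raise FormatError(f"two distinct channel roles required, got {self.channel_roles!r}")
        if self.voxels.size and (self.voxels.min() < 0 or self.voxels.max() > MAX_INTENSITY):
            raise FormatError(
                f"intensities must lie in [0, {MAX_INTENSITY}], got "
                f"[{self.voxels.min()}, {self.voxels.max()}]"
            )
        self.voxel_size = _positive_triple("voxel_size", self.voxel_size)

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[1]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def channel(self, role: str) -> np.ndarray:
        """Return the 3D intensity array for a channel role."""
        try:
            idx = self.channel_roles.index(role)
        except ValueError:
            raise KeyError(f"channel role {role!r} not in {self.channel_roles}") from None
        return self.voxels[idx]


@dataclass
class BinaryVolume:
    """A segmented 3D mask that knows its voxel size, so voxel counts
    convert to µm³."""

    mask: np.ndarray
    voxel_size: tuple = DEFAULT_VOXEL_SIZE
    channel_role: Optional[str] = None

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={self.mask.ndim}")
        self.voxel_size = _positive_triple("voxel_size", self.voxel_size)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def with_mask(self, mask: np.ndarray) -> "BinaryVolume":
        return replace(self, mask=mask)


@dataclass
class BinaryMask2D:
    """A segmented 2D mask (typically from a maximum-intensity
    projection) with pixel size ``(dy, dx)`` in µm."""

    mask: np.ndarray
    pixel_size: tuple = (0.5, 0.5)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError(f"mask must be 2D, got ndim={self.mask.ndim}")
        pair = tuple(float(v) for v in self.pixel_size)
        if len(pair) != 2 or any(v <= 0 or not np.isfinite(v) for v in pair):
            raise ValueError(f"pixel_size must be a positive (dy, dx) pair, got {self.pixel_size!r}")
        self.pixel_size = pair

    @property
    def pixel_area(self) -> float:
        return self.pixel_size[0] * self.pixel_size[1]


@dataclass
class NMJRecord:
    """Measurements for a single neuromuscular junction.

    Volumes in µm³, areas in µm², relative planar area and apposition in
    percent.  ``valid`` is False when both channels segmented empty and
    the record must be excluded from statistics.
    """

    nmj_id: str
    pre_volume: float = float("nan")
    endplate_volume: float = float("nan")
    planar_area: float = float("nan")
    axes_area: float = float("nan")
    relative_planar_area: float = float("nan")
    apposition_pct: float = float("nan")
    category: str = INNERVATED
    valid: bool = True

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}, got {self.category!r}")
        for name in ("pre_volume", "endplate_volume", "planar_area", "axes_area"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if np.isfinite(self.apposition_pct) and not (0.0 <= self.apposition_pct <= 100.0):
            raise ValueError(f"apposition_pct must be in [0, 100], got {self.apposition_pct}")


@dataclass
class AnimalRecord:
    """One animal: metadata plus its per-NMJ measurements."""

    animal_id: str
    sex: str
    treatment: str
    age_months: float = float("nan")
    body_mass_pre: float = float("nan")
    body_mass_post: float = float("nan")
    nmjs: list = field(default_factory=list)

    def __post_init__(self):
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}, got {self.treatment!r}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        seen = set()
        for rec in self.nmjs:
            if rec.nmj_id in seen:
                raise IntegrityError(
                    f"duplicate nmj_id {rec.nmj_id!r} within animal {self.animal_id!r}"
                )
            seen.add(rec.nmj_id)

    @property
    def valid_nmjs(self) -> list:
        return [r for r in self.nmjs if r.valid]
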