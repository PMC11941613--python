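"""Synthetic two-channel NMJ stacks with exact ground truth.

The generator emulates en face diaphragm neuromuscular junctions: a
branched ("pretzel") motor end-plate of ~1800 µm³ lying on a gently
curved surface patch, an overlying pre-synaptic terminal of
~1250–1400 µm³ covering a controllable fraction of its own volume
against the end-plate, stray axonal label in the pre-synaptic channel,
Gaussian PSF blur, Poisson photon noise, and 12-bit quantization.

Geometry is constructed in physical units on the voxel grid:

1. ``branch_count`` smooth random-walk arms radiate from a centre point
   on a shallow bowl surface, giving a curved branched skeleton.
2. The end-plate mask is the set of the N nearest voxels to the skeleton
   (Euclidean distance transform with anisotropic sampling), where N is
   the target volume in voxels — so the realized volume matches the
   target to within one voxel.
3. The terminal mask is built the same way from a translated copy of the
   skeleton; the translation magnitude is bisected until the voxel
   overlap fraction with the end-plate matches the target apposition.
4. An optional thin axon filament is added to the pre-synaptic channel,
   kept clear of both structures so that reference-based mask cleaning
   can remove it.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import binary_dilation, distance_transform_edt, gaussian_filter

from .datamodel import (
    CATEGORIES,
    CHANNEL_ROLES,
    DEFAULT_VOXEL_SIZE,
    END_PLATE,
    GenerationError,
    ImageStack,
    MAX_INTENSITY,
    NMJRecord,
    PRE_SYNAPTIC,
    AnimalRecord,
)

logger = logging.getLogger(__name__)

#: body-mass distributions (grams) by sex, and the 7-day mass change,
#: matching an adult C57BL/6 × 129J cohort at 5–8 months
MASS_BY_SEX = {"male": (32.0, 3.0), "female": (22.7, 1.5)}
MASS_POST_DELTA = (-0.3, 1.0)


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not np.isfinite(v):
            raise ValueError(f"configuration error: {name} contains non-finite value {v!r}")


@dataclass(frozen=True)
class NMJParams:
    """Generative parameters for a single synthetic NMJ."""

    target_endplate_volume: float  # µm³
    target_pre_volume: float  # µm³
    target_apposition: float  # fraction of pre volume apposed, in [0, 1]
    branch_count: int = 5
    depth_offset: float = 30.0  # µm below the tissue surface (metadata)
    noise_level: float = 1.0  # 0 disables photon noise
    seed: int = 0

    def __post_init__(self):
        _require_finite(
            "NMJParams",
            self.target_endplate_volume,
            self.target_pre_volume,
            self.target_apposition,
            self.depth_offset,
            self.noise_level,
        )
        if self.target_endplate_volume <= 0 or self.target_pre_volume <= 0:
            raise ValueError("target volumes must be > 0")
        if not 0.0 <= self.target_apposition <= 1.0:
            raise ValueError(f"target_apposition must be in [0, 1], got {self.target_apposition}")
        if self.branch_count < 1:
            raise ValueError("branch_count must be a positive integer")
        if self.depth_offset > 60.0:
            raise ValueError("depth_offset must be <= 60 µm (superficial NMJs only)")


@dataclass(frozen=True)
class GroupConfig:
    """Population distributions for one treatment group.

    Moments are the per-NMJ means ± SD; ``category_probs`` is the
    (innervated, partially denervated, fully denervated) probability
    triple used for the per-NMJ category draw.
    """

    label: str
    n_animals: int = 6
    nmj_per_animal_mean: float = 40.0
    nmj_per_animal_sd: float = 11.0
    endplate_volume_mean: float = 1800.0
    endplate_volume_sd: float = 260.0
    pre_volume_mean: float = 1330.0
    pre_volume_sd: float = 255.0
    apposition_mean: float = 61.0  # percent
    apposition_sd: float = 10.5
    category_probs: tuple = (0.93, 0.07, 0.0)
    relative_planar_area_mean: float = 44.0  # percent, fast mode only
    relative_planar_area_sd: float = 7.5

    def __post_init__(self):
        _require_finite(
            f"GroupConfig[{self.label}]",
            self.nmj_per_animal_mean,
            self.nmj_per_animal_sd,
            self.endplate_volume_mean,
            self.endplate_volume_sd,
            self.pre_volume_mean,
            self.pre_volume_sd,
            self.apposition_mean,
            self.apposition_sd,
            self.relative_planar_area_mean,
            self.relative_planar_area_sd,
            *self.category_probs,
        )
        if self.n_animals <= 0:
            raise ValueError("n_animals must be > 0")
        for name in (
            "nmj_per_animal_sd",
            "endplate_volume_sd",
            "pre_volume_sd",
            "apposition_sd",
            "relative_planar_area_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        probs = tuple(float(p) for p in self.category_probs)
        if len(probs) != 3 or any(p < 0 for p in probs):
            raise ValueError("category_probs must be 3 nonnegative probabilities")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(f"category_probs must sum to 1, got {sum(probs)}")
        object.__setattr__(self, "category_probs", probs)


@dataclass(frozen=True)
class RenderConfig:
    """Rendering geometry and optics.

    ``shape_xy`` is the (rows, cols) canvas matching the nominal
    800 × 600 acquisition array; ``None`` shrinks the canvas to the
    working crop around the NMJ, which is convenient for large batches.
    """

    voxel_size: tuple = DEFAULT_VOXEL_SIZE  # (dz, dy, dx) µm
    shape_xy: Optional[tuple] = (600, 800)
    n_slices: Optional[int] = None  # None: drawn in [12, 16] per NMJ
    sigma_lateral: float = 0.6  # PSF σ, µm
    sigma_axial: float = 1.2
    background: float = 100.0
    amplitude: float = 3000.0
    nominal_tube_radius: float = 2.6  # µm, sets total skeleton length
    turn_rate: float = 0.07  # rad/µm arm curl
    turn_jitter: float = 0.15
    bowl_curvature: float = 0.004  # µm⁻¹, gentle surface curvature
    rho_max: float = 26.0  # µm, maximal arm radius from the centre
    crop_margin: float = 10.0  # µm of clear border around the structure
    axon: bool = True
    axon_gap: float = 8.0  # µm between end-plate extent and axon path
    axon_length: float = 28.0
    axon_clearance: float = 4.5  # µm kept clear of both structures

    @classmethod
    def compact(cls, **overrides) -> "RenderConfig":
        """Canvas cropped to the NMJ neighbourhood; same optics."""
        overrides.setdefault("shape_xy", None)
        return cls(**overrides)


@dataclass
class GroundTruth:
    """Exact noiseless truth for one rendered NMJ.

    Realized volumes are voxel counts of the noiseless masks times the
    voxel volume — exactly.
    """

    params: NMJParams
    true_endplate_volume: float
    true_pre_volume: float
    true_apposition_pct: float
    endplate_mask: np.ndarray
    pre_mask: np.ndarray
    axon_mask: Optional[np.ndarray] = None
    n_slices: int = 0

    def scalars(self) -> dict:
        """JSON-serializable summary (for the sidecar file)."""
        return {
            "true_endplate_volume_um3": self.true_endplate_volume,
            "true_pre_volume_um3": self.true_pre_volume,
            "true_apposition_pct": self.true_apposition_pct,
            "target_endplate_volume_um3": self.params.target_endplate_volume,
            "target_pre_volume_um3": self.params.target_pre_volume,
            "target_apposition": self.params.target_apposition,
            "branch_count": self.params.branch_count,
            "depth_offset_um": self.params.depth_offset,
            "noise_level": self.params.noise_level,
            "seed": self.params.seed,
            "n_slices": self.n_slices,
        }


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _truncated_normal_positive(rng, mean, sd) -> float:
    """Normal draw truncated at zero (redraw; the study moments put
    essentially no mass below zero)."""
    if sd == 0:
        return float(mean)
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > 0:
            return float(v)
    raise ValueError(f"configuration error: cannot draw positive value at mean={mean}, sd={sd}")


def sample_nmj_params(group: GroupConfig, rng_seed) -> NMJParams:
    """Draw one NMJ's generative parameters from the group distributions.

    Volumes use zero-truncated normals; apposition is a normal draw (in
    percent) clamped to [0, 100].  Deterministic given the seed.
    """
    rng = _as_rng(rng_seed)
    ep = _truncated_normal_positive(rng, group.endplate_volume_mean, group.endplate_volume_sd)
    pre = _truncated_normal_positive(rng, group.pre_volume_mean, group.pre_volume_sd)
    if group.apposition_sd == 0:
        app = group.apposition_mean / 100.0
    else:
        app = rng.normal(group.apposition_mean, group.apposition_sd) / 100.0
    app = float(np.clip(app, 0.0, 1.0))
    return NMJParams(
        target_endplate_volume=ep,
        target_pre_volume=pre,
        target_apposition=app,
        branch_count=int(rng.integers(4, 7)),
        depth_offset=float(rng.uniform(5.0, 55.0)),
        noise_level=1.0,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# rendering internals


def _rasterize(points_um: np.ndarray, shape: tuple, voxel_size: tuple) -> np.ndarray:
    idx = np.rint(points_um / np.asarray(voxel_size)).astype(int)
    np.clip(idx, 0, np.asarray(shape) - 1, out=idx)
    m = np.zeros(shape, dtype=bool)
    m[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return m


def _nearest_n_voxels(dist: np.ndarray, n: int) -> np.ndarray:
    """Mask of exactly the n grid voxels nearest to a structure (EDT);
    distance ties are broken in flat index order, deterministically."""
    flat = dist.ravel()
    if n >= flat.size:
        raise GenerationError("target volume exceeds the stack bounds")
    idx = np.argpartition(flat, n - 1)[:n]
    mask = np.zeros(flat.size, dtype=bool)
    mask[idx] = True
    return mask.reshape(dist.shape)


def _skeleton_points(params: NMJParams, render: RenderConfig, rng, crop_um: float, z0: float):
    """Branched random-walk skeleton on a shallow bowl, in µm (z, y, x).

    Returns the per-arm point lists (so a sub-length of every arm can be
    reused for the pre-synaptic terminal) and the patch centre."""
    cy = cx = crop_um / 2.0
    n_branches = params.branch_count
    total_len = params.target_endplate_volume / (math.pi * render.nominal_tube_radius**2)
    weights = rng.dirichlet(np.full(n_branches, 8.0))
    ds = 0.4
    arms = []
    for i in range(n_branches):
        theta = 2 * math.pi * i / n_branches + rng.uniform(-0.4, 0.4)
        curl = render.turn_rate * (1.0 if i % 2 == 0 else -1.0)
        y, x = cy, cx
        n_steps = max(4, int(total_len * weights[i] / ds))
        arm = []
        for _ in range(n_steps):
            ny_, nx_ = y + ds * math.sin(theta), x + ds * math.cos(theta)
            rho = math.hypot(ny_ - cy, nx_ - cx)
            if rho > render.rho_max:
                # steer back toward the centre instead of leaving the patch
                theta = math.atan2(cy - y, cx - x) + rng.uniform(-0.5, 0.5)
                continue
            y, x = ny_, nx_
            z = z0 + render.bowl_curvature * rho * rho
            arm.append((z, y, x))
            theta += curl * ds + rng.normal(0.0, render.turn_jitter * math.sqrt(ds))
        if arm:
            arms.append(np.asarray(arm))
    if sum(len(a) for a in arms) < 4:
        raise GenerationError("end-plate skeleton degenerate (too few points)")
    return arms, (cy, cx)


def render_nmj_stack(params: NMJParams, render: Optional[RenderConfig] = None):
    """Render one synthetic NMJ.

    Returns ``(ImageStack, GroundTruth)``.  The noiseless binary masks in
    the truth are aligned voxel-for-voxel with the stack; realized
    volumes match the targets to within one voxel, and realized
    apposition matches ``target_apposition`` to ~1 point wherever the
    geometry permits.
    """
    render = render or RenderConfig()
    rng = np.random.default_rng(params.seed)
    vs = np.asarray(render.voxel_size, dtype=float)
    dz, dy, dx = vs
    voxvol = float(vs.prod())

    n_slices = render.n_slices or int(rng.integers(12, 17))
    crop_um = 2.0 * (render.rho_max + render.crop_margin)
    crop_shape = (n_slices, int(round(crop_um / dy)), int(round(crop_um / dx)))
    z0 = 0.55 * n_slices * dz

    arms, (cy, cx) = _skeleton_points(params, render, rng, crop_um, z0)
    pts = np.concatenate(arms)

    # --- end-plate: N nearest voxels to the skeleton
    n_ep = max(1, int(round(params.target_endplate_volume / voxvol)))
    skel = _rasterize(pts, crop_shape, vs)
    d_ep = distance_transform_edt(~skel, sampling=vs)
    if n_ep >= 0.5 * skel.size:
        raise GenerationError(
            f"end-plate target {params.target_endplate_volume} µm³ not realizable in bounds"
        )
    ep_mask = _nearest_n_voxels(d_ep, n_ep)
    r_ep = float(d_ep[ep_mask].max())
    if r_ep > 8.0:
        raise GenerationError("end-plate dilation radius implausible; volume target too large")

    # --- pre-synaptic terminal: a sub-length of every arm (so the tube
    # keeps the end-plate's thickness at the smaller volume), translated
    # by a shift bisected to hit the target apposition fraction
    n_pre = max(1, int(round(params.target_pre_volume / voxvol)))
    f_len = float(
        np.clip(params.target_pre_volume / params.target_endplate_volume, 0.15, 1.0)
    )
    pre_pts = np.concatenate(
        [arm[: max(2, int(math.ceil(f_len * len(arm))))] for arm in arms]
    )
    sy, sx = rng.choice([-1.0, 1.0]), rng.choice([-1.0, 1.0])
    direction = np.array([-0.55, sy * 0.57, sx * 0.61])
    direction /= np.linalg.norm(direction)
    s_max = min(9.0, (z0 - 2.0) / abs(direction[0]))

    def build(shift):
        shifted = pre_pts + shift * direction
        m = _rasterize(shifted, crop_shape, vs)
        d = distance_transform_edt(~m, sampling=vs)
        pre = _nearest_n_voxels(d, n_pre)
        frac = np.count_nonzero(pre & ep_mask) / np.count_nonzero(pre)
        return pre, d, frac

    target = params.target_apposition
    lo, hi = 0.0, s_max
    pre_lo = build(lo)
    best = min([pre_lo], key=lambda t: abs(t[2] - target))
    if target < pre_lo[2] - 1e-9:
        pre_hi = build(hi)
        best = min([best, pre_hi], key=lambda t: abs(t[2] - target))
        if target > pre_hi[2]:
            for _ in range(14):
                mid = 0.5 * (lo + hi)
                cand = build(mid)
                if abs(cand[2] - target) < abs(best[2] - target):
                    best = cand
                if abs(cand[2] - target) <= 0.01:
                    break
                if cand[2] > target:
                    lo = mid
                else:
                    hi = mid
    pre_mask, d_pre, realized_frac = best
    if abs(realized_frac - target) > 0.05:
        logger.warning(
            "apposition target %.2f only realized as %.2f for seed %d",
            target,
            realized_frac,
            params.seed,
        )

    # --- stray axon filament (pre-synaptic channel only), kept clear of
    # both structures so reference-linked cleaning can discard it
    axon_mask = None
    if render.axon:
        rho_ext = float(np.hypot(pts[:, 1] - cy, pts[:, 2] - cx).max())
        rad = min(rho_ext + render.axon_gap, crop_um / 2.0 - 3.0)
        phi0 = rng.uniform(0.0, 2 * math.pi)
        phis = phi0 + np.arange(0.0, render.axon_length / rad, 0.3 / rad)
        z_ax = max(z0 - 1.5, 1.0)
        ax_pts = np.column_stack(
            [np.full_like(phis, z_ax), cy + rad * np.sin(phis), cx + rad * np.cos(phis)]
        )
        m = _rasterize(ax_pts, crop_shape, vs)
        m = binary_dilation(m, structure=np.ones((1, 3, 3), bool))
        clear = render.axon_clearance
        m &= d_ep > r_ep + clear
        m &= d_pre > float(d_pre[pre_mask].max()) + clear
        axon_mask = m if m.any() else None

    # --- render channels: blur the crop, embed into the canvas, add noise
    if render.shape_xy is None:
        canvas_shape = crop_shape
        oy = ox = 0
    else:
        canvas_shape = (n_slices, int(render.shape_xy[0]), int(render.shape_xy[1]))
        if canvas_shape[1] < crop_shape[1] or canvas_shape[2] < crop_shape[2]:
            raise GenerationError(
                f"canvas {render.shape_xy} smaller than working crop {crop_shape[1:]}"
            )
        max_jitter = 20
        oy = (canvas_shape[1] - crop_shape[1]) // 2
        ox = (canvas_shape[2] - crop_shape[2]) // 2
        oy += int(rng.integers(-min(max_jitter, oy), min(max_jitter, oy) + 1)) if oy else 0
        ox += int(rng.integers(-min(max_jitter, ox), min(max_jitter, ox) + 1)) if ox else 0

    sigma_vox = (render.sigma_axial / dz, render.sigma_lateral / dy, render.sigma_lateral / dx)

    def render_channel(mask):
        signal = render.amplitude * mask.astype(float)
        if any(s > 0 for s in sigma_vox) and (
            render.sigma_lateral > 0 or render.sigma_axial > 0
        ):
            signal = gaussian_filter(signal, sigma=sigma_vox)
        img = np.full(canvas_shape, render.background, dtype=float)
        img[:, oy : oy + crop_shape[1], ox : ox + crop_shape[2]] += signal
        if params.noise_level > 0:
            img = img + params.noise_level * (rng.poisson(np.clip(img, 0, None)) - img)
        return np.clip(np.rint(img), 0, MAX_INTENSITY).astype(np.uint16)

    pre_render_mask = pre_mask if axon_mask is None else (pre_mask | axon_mask)
    pre_channel = render_channel(pre_render_mask)
    ep_channel = render_channel(ep_mask)

    def embed(mask):
        full = np.zeros(canvas_shape, dtype=bool)
        full[:, oy : oy + crop_shape[1], ox : ox + crop_shape[2]] = mask
        return full

    ep_full, pre_full = embed(ep_mask), embed(pre_mask)
    axon_full = embed(axon_mask) if axon_mask is not None else None

    stack = ImageStack(
        voxels=np.stack([pre_channel, ep_channel]),
        voxel_size=tuple(vs),
        channel_roles=(PRE_SYNAPTIC, END_PLATE),
        metadata={"seed": params.seed},
    )
    truth = GroundTruth(
        params=params,
        true_endplate_volume=float(np.count_nonzero(ep_full)) * voxvol,
        true_pre_volume=float(np.count_nonzero(pre_full)) * voxvol,
        true_apposition_pct=100.0 * realized_frac,
        endplate_mask=ep_full,
        pre_mask=pre_full,
        axon_mask=axon_full,
        n_slices=n_slices,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class SyntheticNMJ:
    """One generated NMJ: parameters, drawn category/complexity, and —
    in image mode — the rendered stack with its ground truth."""

    nmj_id: str
    params: NMJParams
    category: str
    relative_planar_area: float
    stack: Optional[ImageStack] = None
    truth: Optional[GroundTruth] = None

    def truth_record(self) -> NMJRecord:
        """Measurement record taken directly from the generative truth
        (fast mode) or the realized noiseless masks (image mode)."""
        if self.truth is not None:
            pre = self.truth.true_pre_volume
            ep = self.truth.true_endplate_volume
            app = self.truth.true_apposition_pct
        else:
            pre = self.params.target_pre_volume
            ep = self.params.target_endplate_volume
            app = 100.0 * self.params.target_apposition
        return NMJRecord(
            nmj_id=self.nmj_id,
            pre_volume=pre,
            endplate_volume=ep,
            relative_planar_area=self.relative_planar_area,
            apposition_pct=app,
            category=self.category,
        )


@dataclass
class SyntheticAnimal:
    animal_id: str
    sex: str
    treatment: str
    age_months: float
    body_mass_pre: float
    body_mass_post: float
    nmjs: list = field(default_factory=list)

    def truth_animal_record(self) -> AnimalRecord:
        return AnimalRecord(
            animal_id=self.animal_id,
            sex=self.sex,
            treatment=self.treatment,
            age_months=self.age_months,
            body_mass_pre=self.body_mass_pre,
            body_mass_post=self.body_mass_post,
            nmjs=[n.truth_record() for n in self.nmjs],
        )


def generate_cohort(
    groups: Sequence[GroupConfig],
    seed: int,
    mode: str = "fast",
    render: Optional[RenderConfig] = None,
    min_nmj_per_animal: int = 35,
) -> list:
    """Generate a full synthetic cohort.

    Sexes alternate within each group; the per-animal NMJ count is a
    normal draw floored at ``min_nmj_per_animal``.  In ``fast`` mode the
    per-NMJ measurements are the distribution draws themselves (no
    imaging); in ``image`` mode every NMJ is rendered as a stack with
    ground truth.  Deterministic given the seed.
    """
    if mode not in ("fast", "image"):
        raise ValueError(f"mode must be 'fast' or 'image', got {mode!r}")
    root = np.random.SeedSequence(seed)
    animals = []
    for g_idx, group in enumerate(groups):
        group_ss = root.spawn(len(groups))[g_idx]
        animal_seeds = group_ss.spawn(group.n_animals)
        for a_idx in range(group.n_animals):
            rng = np.random.default_rng(animal_seeds[a_idx])
            sex = "male" if a_idx % 2 == 0 else "female"
            mass_mu, mass_sd = MASS_BY_SEX[sex]
            mass_pre = rng.normal(mass_mu, mass_sd)
            mass_post = mass_pre + rng.normal(*MASS_POST_DELTA)
            if group.nmj_per_animal_sd == 0:
                n_nmj = int(round(group.nmj_per_animal_mean))
            else:
                n_nmj = int(round(rng.normal(group.nmj_per_animal_mean, group.nmj_per_animal_sd)))
            n_nmj = max(min_nmj_per_animal, n_nmj)
            animal = SyntheticAnimal(
                animal_id=f"{group.label}_{a_idx + 1:02d}",
                sex=sex,
                treatment=group.label,
                age_months=float(rng.uniform(5.5, 8.0)),
                body_mass_pre=float(mass_pre),
                body_mass_post=float(mass_post),
            )
            for j in range(n_nmj):
                params = sample_nmj_params(group, rng)
                category = str(rng.choice(CATEGORIES, p=group.category_probs))
                if group.relative_planar_area_sd == 0:
                    rpa = group.relative_planar_area_mean
                else:
                    rpa = rng.normal(
                        group.relative_planar_area_mean, group.relative_planar_area_sd
                    )
                rpa = float(np.clip(rpa, 0.0, 100.0))
                nmj = SyntheticNMJ(
                    nmj_id=f"{animal.animal_id}_nmj{j + 1:03d}",
                    params=params,
                    category=category,
                    relative_planar_area=rpa,
                )
                if mode == "image":
                    nmj.stack, nmj.truth = render_nmj_stack(params, render)
                animal.nmjs.append(nmj)
            animals.append(animal)
    return animals
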