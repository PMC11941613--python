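"""End-to-end study orchestration.

``run_study`` generates (or ingests) a two-group cohort — vehicle vs
chloroquine — measures every NMJ, aggregates per animal, runs the
statistical battery, derives effect sizes, and checks them against
configured target brackets.  Bracket checks (value ± tolerance) rather
than equality are used throughout because cohorts are stochastic.

The default :data:`REFERENCE_STUDY` carries the calibration the package
replicates: 6 animals per group (sexes balanced), ~270 vs ~221 NMJs,
pre-synaptic volume 1411 ± 236 vs 1248 ± 274 µm³, end-plate volume
1792 ± 259 vs 1804 ± 269 µm³, apposition 66 ± 11 vs 56 ± 10 %, and
denervation-category probabilities (0.93, 0.07, 0) vs (0.78, 0.19, 0.03).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    AnimalRecord,
    CATEGORIES,
    CHLOROQUINE,
    FULLY_DENERVATED,
    INNERVATED,
    PARTIALLY_DENERVATED,
    VEHICLE,
)
from .image_io import records_to_frame
from .morphometry import MorphometryConfig, measure_nmj
from .stats import (
    EffectSizes,
    StatsResult,
    chi_square_independence,
    effect_sizes,
    one_way_anova,
    paired_t_test,
    two_way_anova,
)
from .synthetic import GroupConfig, RenderConfig, generate_cohort

logger = logging.getLogger(__name__)

#: default replication targets: central value and bracket half-width
DEFAULT_TARGETS = {
    "pct_change_pre_volume": {"value": 12.0, "tol": 4.0},
    "pct_change_apposition": {"value": 15.0, "tol": 4.0},
    "pct_change_innervated": {"value": 16.0, "tol": 6.0},
    "fold_partial_denervation": {"value": 2.7, "tol": 1.2},
    "pct_sex_mass_difference": {"value": 41.0, "tol": 10.0},
    "pct_change_endplate_volume": {"value": 0.0, "tol": 5.0},
}


@dataclass(frozen=True)
class StudyConfig:
    """Full configuration of a replication run."""

    vehicle: GroupConfig
    chloroquine: GroupConfig
    seed: int = 0
    mode: str = "fast"
    render: Optional[RenderConfig] = None
    morphometry: MorphometryConfig = field(default_factory=MorphometryConfig)
    min_nmj_per_animal: int = 35
    targets: dict = field(default_factory=lambda: dict(DEFAULT_TARGETS))

    def __post_init__(self):
        if self.vehicle.label == self.chloroquine.label:
            raise ValueError("group labels must be distinct")

    def scaled(
        self, n_animals: int, nmj_mean: float, nmj_sd: float = 0.0, min_nmj: int = 1
    ) -> "StudyConfig":
        """A reduced-scale copy (fewer animals/NMJs), e.g. for image mode."""
        return replace(
            self,
            vehicle=replace(
                self.vehicle,
                n_animals=n_animals,
                nmj_per_animal_mean=nmj_mean,
                nmj_per_animal_sd=nmj_sd,
            ),
            chloroquine=replace(
                self.chloroquine,
                n_animals=n_animals,
                nmj_per_animal_mean=nmj_mean,
                nmj_per_animal_sd=nmj_sd,
            ),
            min_nmj_per_animal=min_nmj,
        )


#: calibration of the replicated study: printed group moments and scale
REFERENCE_STUDY = StudyConfig(
    vehicle=GroupConfig(
        label=VEHICLE,
        n_animals=6,
        nmj_per_animal_mean=45.0,
        nmj_per_animal_sd=11.0,
        endplate_volume_mean=1792.0,
        endplate_volume_sd=259.0,
        pre_volume_mean=1411.0,
        pre_volume_sd=236.0,
        apposition_mean=66.0,
        apposition_sd=11.0,
        category_probs=(0.93, 0.07, 0.0),
        relative_planar_area_mean=45.0,
        relative_planar_area_sd=8.0,
    ),
    chloroquine=GroupConfig(
        label=CHLOROQUINE,
        n_animals=6,
        nmj_per_animal_mean=37.0,
        nmj_per_animal_sd=11.0,
        endplate_volume_mean=1804.0,
        endplate_volume_sd=269.0,
        pre_volume_mean=1248.0,
        pre_volume_sd=274.0,
        apposition_mean=56.0,
        apposition_sd=10.0,
        category_probs=(0.78, 0.19, 0.03),
        relative_planar_area_mean=43.0,
        relative_planar_area_sd=7.0,
    ),
)


def aggregate_by_animal(animals: Sequence[AnimalRecord]) -> pd.DataFrame:
    """Per-animal denervation-category proportions and morphometric means.

    Invalid NMJs are dropped; an animal with zero valid NMJs is excluded
    with a warning.  Proportions sum to 1 per animal.
    """
    rows = []
    for animal in animals:
        recs = animal.valid_nmjs
        if not recs:
            logger.warning("animal %s has no valid NMJs; excluded", animal.animal_id)
            continue
        n = len(recs)
        cats = [r.category for r in recs]
        row = {
            "animal_id": animal.animal_id,
            "sex": animal.sex,
            "treatment": animal.treatment,
            "body_mass_pre": animal.body_mass_pre,
            "body_mass_post": animal.body_mass_post,
            "n_nmjs": n,
            "prop_innervated": cats.count(INNERVATED) / n,
            "prop_partially_denervated": cats.count(PARTIALLY_DENERVATED) / n,
            "prop_fully_denervated": cats.count(FULLY_DENERVATED) / n,
        }
        for name in ("pre_volume", "endplate_volume", "apposition_pct", "relative_planar_area"):
            vals = np.asarray([getattr(r, name) for r in recs], dtype=float)
            vals = vals[np.isfinite(vals)]
            row[f"mean_{name}"] = float(vals.mean()) if vals.size else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ReplicationReport:
    scale: dict
    group_means: dict
    analyses: dict
    effects: EffectSizes
    per_animal: pd.DataFrame
    verdicts: dict

    def to_dict(self) -> dict:
        def conv(obj):
            if isinstance(obj, StatsResult):
                return dataclasses.asdict(obj)
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return {
            "scale": conv(self.scale),
            "group_means": conv(self.group_means),
            "analyses": conv(self.analyses),
            "effects": dataclasses.asdict(self.effects),
            "effects_rounded": self.effects.rounded(),
            "per_animal": self.per_animal.to_dict(orient="records"),
            "verdicts": conv(self.verdicts),
        }

    @property
    def all_pass(self) -> bool:
        return all(v["pass"] for v in self.verdicts.values())


def _measure_cohort(synthetic_animals, morph: MorphometryConfig) -> list:
    animals = []
    for sa in synthetic_animals:
        rec = sa.truth_animal_record()
        measured = []
        for nmj in sa.nmjs:
            measured.append(measure_nmj(nmj.stack, morph, nmj_id=nmj.nmj_id))
        rec.nmjs = measured
        animals.append(rec)
    return animals


def run_study(config: StudyConfig) -> ReplicationReport:
    """Execute the full study and return the replication report.

    Fast mode analyses the distribution draws directly (statistics-only,
    deterministic given the seed); image mode renders every NMJ and runs
    the measurement chain first.
    """
    synthetic = generate_cohort(
        [config.vehicle, config.chloroquine],
        seed=config.seed,
        mode=config.mode,
        render=config.render,
        min_nmj_per_animal=config.min_nmj_per_animal,
    )
    if config.mode == "image":
        animals = _measure_cohort(synthetic, config.morphometry)
    else:
        animals = [sa.truth_animal_record() for sa in synthetic]
    return analyze_cohort(animals, config)


def analyze_cohort(animals: Sequence[AnimalRecord], config: StudyConfig) -> ReplicationReport:
    """Statistics + effect sizes + verdicts for an already-measured cohort."""
    frame = records_to_frame(animals)
    frame = frame[frame["valid"]]
    veh_label, chl_label = config.vehicle.label, config.chloroquine.label
    per_animal = aggregate_by_animal(animals)

    analyses: dict = {}
    group_means: dict = {}

    # per-NMJ one-way ANOVAs, treatment as the fixed effect
    for col in ("pre_volume", "endplate_volume", "apposition_pct", "relative_planar_area"):
        sub = frame[np.isfinite(frame[col])]
        if sub.empty or sub["treatment"].nunique() < 2:
            continue
        analyses[f"anova_{col}"] = one_way_anova(sub[col].to_numpy(), sub["treatment"].to_numpy())
        group_means[col] = {
            t: float(g.mean()) for t, g in sub.groupby("treatment")[col]
        }

    # per-animal category proportions: two-way ANOVA and chi-square
    long = per_animal.melt(
        id_vars=["animal_id", "treatment"],
        value_vars=["prop_innervated", "prop_partially_denervated", "prop_fully_denervated"],
        var_name="category",
        value_name="proportion",
    )
    analyses["two_way_proportions"] = two_way_anova(
        long["proportion"], long["treatment"], long["category"]
    )

    counts = pd.crosstab(frame["treatment"], frame["category"]).reindex(
        index=[veh_label, chl_label], columns=list(CATEGORIES), fill_value=0
    )
    nonzero_cols = counts.columns[(counts.sum(axis=0) > 0)]
    if len(nonzero_cols) < counts.shape[1]:
        logger.warning(
            "dropping empty denervation categories from the chi-square table: %s",
            sorted(set(counts.columns) - set(nonzero_cols)),
        )
    analyses["chi_square_categories"] = chi_square_independence(
        counts[nonzero_cols].to_numpy()
    )

    # body mass: matched pre/post within each group; sex difference
    for label in (veh_label, chl_label):
        sub = per_animal[per_animal["treatment"] == label]
        if len(sub) >= 2:
            analyses[f"paired_t_mass_{label}"] = paired_t_test(
                sub["body_mass_pre"], sub["body_mass_post"]
            )
    if per_animal["sex"].nunique() == 2:
        analyses["anova_mass_by_sex"] = one_way_anova(
            per_animal["body_mass_pre"], per_animal["sex"]
        )

    # effect sizes from group means
    props = per_animal.groupby("treatment")[
        ["prop_innervated", "prop_partially_denervated"]
    ].mean()
    mass_by_sex = per_animal.groupby("sex")["body_mass_pre"].mean()
    summaries = {
        "pre_volume": (
            group_means["pre_volume"][veh_label],
            group_means["pre_volume"][chl_label],
        ),
        "apposition": (
            group_means["apposition_pct"][veh_label],
            group_means["apposition_pct"][chl_label],
        ),
        "innervated_pct": (
            100.0 * props.loc[veh_label, "prop_innervated"],
            100.0 * props.loc[chl_label, "prop_innervated"],
        ),
    }
    if props.loc[veh_label, "prop_partially_denervated"] > 0:
        summaries["partial_pct"] = (
            100.0 * props.loc[veh_label, "prop_partially_denervated"],
            100.0 * props.loc[chl_label, "prop_partially_denervated"],
        )
    if {"male", "female"} <= set(mass_by_sex.index):
        summaries["mass_by_sex"] = (mass_by_sex["male"], mass_by_sex["female"])
    effects = effect_sizes(summaries)

    if "endplate_volume" in group_means:
        ep = group_means["endplate_volume"]
        pct_change_endplate = 100.0 * (ep[veh_label] - ep[chl_label]) / ep[veh_label]
    else:
        pct_change_endplate = float("nan")

    observed = {
        "pct_change_pre_volume": effects.pct_change_pre_volume,
        "pct_change_apposition": effects.pct_change_apposition,
        "pct_change_innervated": effects.pct_change_innervated,
        "fold_partial_denervation": effects.fold_partial_denervation,
        "pct_sex_mass_difference": effects.pct_sex_mass_difference,
        "pct_change_endplate_volume": pct_change_endplate,
    }
    verdicts = {}
    for name, spec in config.targets.items():
        value = observed.get(name, float("nan"))
        ok = bool(np.isfinite(value) and abs(value - spec["value"]) <= spec["tol"])
        verdicts[name] = {
            "value": float(value),
            "target": spec["value"],
            "tol": spec["tol"],
            "pass": ok,
        }

    scale = {
        "mode": config.mode,
        "seed": config.seed,
        "n_animals": int(len(per_animal)),
        "total_nmjs": int(len(frame)),
    }
    return ReplicationReport(
        scale=scale,
        group_means=group_means,
        analyses=analyses,
        effects=effects,
        per_animal=per_animal,
        verdicts=verdicts,
    )
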