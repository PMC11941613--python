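# Replication calibration: the two-group chloroquine vs vehicle diaphragm
# NMJ study this package models.  Group moments are the published
# per-NMJ means ± SD; category_probs are the (innervated, partially
# denervated, fully denervated) per-animal proportions.  The per-group
# NMJ-count means reproduce the ~270 / ~221 NMJ totals at 6 animals per
# group with at least 35 en face NMJs analyzed per animal.
seed: 0
mode: fast
min_nmj_per_animal: 35
groups:
  vehicle:
    n_animals: 6
    nmj_per_animal_mean: 45.0
    nmj_per_animal_sd: 11.0
    endplate_volume_mean: 1792.0   # µm³
    endplate_volume_sd: 259.0
    pre_volume_mean: 1411.0        # µm³
    pre_volume_sd: 236.0
    apposition_mean: 66.0          # percent of pre-synaptic volume
    apposition_sd: 11.0
    category_probs: [0.93, 0.07, 0.0]
    relative_planar_area_mean: 45.0  # percent
    relative_planar_area_sd: 8.0
  chloroquine:
    n_animals: 6
    nmj_per_animal_mean: 37.0
    nmj_per_animal_sd: 11.0
    endplate_volume_mean: 1804.0
    endplate_volume_sd: 269.0
    pre_volume_mean: 1248.0
    pre_volume_sd: 274.0
    apposition_mean: 56.0
    apposition_sd: 10.0
    category_probs: [0.78, 0.19, 0.03]
    relative_planar_area_mean: 43.0
    relative_planar_area_sd: 7.0
# Bracket targets the replication report checks (value ± tol)
targets:
  pct_change_pre_volume: {value: 12.0, tol: 4.0}
  pct_change_apposition: {value: 15.0, tol: 4.0}
  pct_change_innervated: {value: 16.0, tol: 6.0}
  fold_partial_denervation: {value: 2.7, tol: 1.2}
  pct_sex_mass_difference: {value: 41.0, tol: 10.0}
  pct_change_endplate_volume: {value: 0.0, tol: 5.0}
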