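# nmjmorph

3D morphometry of neuromuscular junctions (NMJs) from two-channel
confocal z-stacks, plus the cohort-level statistics used in treatment
studies of diaphragm muscle denervation — with a synthetic stack
generator that provides exact ground truth for validating every stage.

The package targets the standard design of rodent NMJ morphology
studies: whole-mount diaphragm muscle with motor end-plates labeled by
α-bungarotoxin and pre-synaptic terminals by anti-synaptophysin, imaged
en face as 12-bit two-channel stacks (0.5 × 0.5 µm pixels, 1 µm steps,
10–18 slices). It is written for muscle/neurophysiology labs who want a
reproducible, scriptable replacement for interactive per-stack analysis.

## What it computes

Per NMJ, from the binarized channels:

* **pre-synaptic terminal volume** and **motor end-plate volume** —
  foreground voxels × voxel volume (µm³);
* **planar area** of the end-plate on the maximum-intensity projection
  (MIP), and the area of its **main orthogonal axes** box
  (principal-axes-aligned bounding box of the pixel cloud);
* **relative planar area** = 100 · planar / axes area (%) — an inverse
  complexity index: branchier, more fragmented end-plates fill less of
  their axes box;
* **apposition** = 100 · |pre ∩ post| / |pre| (%) on the 3D masks — the
  fraction of the terminal directly opposing the end-plate;
* a **denervation category** (innervated / partially denervated / fully
  denervated) from the MIP overlap fraction f = |pre ∩ post| / |post|,
  with configurable cutpoints (default: f ≥ 0.80 innervated,
  f ≥ 0.10 partial, else fully denervated).

Per cohort: per-animal aggregation, one-way ANOVA (treatment effect on
per-NMJ morphometrics), two-way ANOVA with interaction (treatment ×
denervation category on per-animal proportions, Type-II sums of
squares), Pearson chi-square on the category table, Tukey–Kramer HSD
post hocs, matched pre/post body-mass t-tests, derived effect sizes,
and a Monte-Carlo power check for the nested design.

## Worked example

Run the full replication study in fast mode (statistics on the
generative draws; deterministic given the seed):

```bash
nmjmorph replicate --config configs/replication.yaml --seed 5 --out report.json
```

prints

```
[PASS] verdicts:
  ok  pct_change_pre_volume: 13.23 (target 12.0 ± 4.0)
  ok  pct_change_apposition: 14.72 (target 15.0 ± 4.0)
  ok  pct_change_innervated: 13.37 (target 16.0 ± 6.0)
  ok  fold_partial_denervation: 2.21 (target 2.7 ± 1.2)
  ok  pct_sex_mass_difference: 50.23 (target 41.0 ± 10.0)
  ok  pct_change_endplate_volume: -1.13 (target 0.0 ± 5.0)
```

Each line is a derived effect size from this simulated cohort compared
to its bracket target: the chloroquine arm shows a ~13 % lower mean
pre-synaptic volume and ~15 % lower apposition than vehicle, with no
end-plate volume change, ~13 % fewer innervated NMJs and a 2.2-fold rise
in partial denervation — the expected pattern at this cohort size, where
proportions of rare categories fluctuate between seeds. `report.json`
holds the underlying test statistics (F, χ², t), degrees of freedom,
p-values, per-animal tables, and group summaries.

The image-based path works the same way from Python:

```python
from nmjmorph import measure_nmj
from nmjmorph.synthetic import NMJParams, RenderConfig, render_nmj_stack

params = NMJParams(target_endplate_volume=1800, target_pre_volume=1350,
                   target_apposition=0.66, seed=7)
stack, truth = render_nmj_stack(params, RenderConfig.compact())
rec = measure_nmj(stack, nmj_id="demo")
# rec.pre_volume ≈ truth.true_pre_volume (within the segmentation
# tolerance; exact when rendered without blur and noise)
```

Other CLI entry points: `nmjmorph generate` (write a synthetic cohort as
TIFF + JSON sidecars), `nmjmorph measure` (stacks → measurement CSV),
`nmjmorph stats` (CSV → statistics report).

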