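# pleuraseg

Anatomically constrained training for pneumothorax segmentation on chest
radiographs — a complete, desk-scale implementation of the four-phase
pipeline, exercised end to end on synthetic chest phantoms.

## The problem

Pneumothorax (air in the pleural space) can only appear in the
**lung + space**: the lungs plus the pleural band, inside the thoracic
cavity and outside the mediastinum. End-to-end segmentation models ignore
this location prior and happily predict lesions in anatomically impossible
places — especially under domain shift, and especially where lucent mimics
(skin folds, bowel gas) resemble pneumothorax. `pleuraseg` is for
researchers in medical image analysis who want to study, extend or reuse
location-constrained training without GPU-scale infrastructure or access to
clinical datasets.

## The method

Training minimises a Dice loss plus a differentiable location penalty:

    L = mean_i [ ℓ_Dice(Y_i, S_i) + λ · P(Y_i, C_i) ],
    P(Y, C) = 1 − |Y ∩ C| / |Y|        (soft, probability-mass counts)

where C_i is a per-image binary mask of the admissible region. C_i is
produced without extra annotation by a four-phase pipeline:

1. **Auxiliary lung segmenter** trained on a separate lung-annotated domain;
2. **Morphological refinement** of its predictions into lung + space:
   top-2 connected components → closing (19×19 ellipse) → dilation (15×15
   ellipse);
3. **Reliability discriminator**: constraints are labelled by the coverage
   rate R = |C∩S|/|S| (reliable iff R ≥ 0.99), a CNN classifier is trained
   on channel-fused (image, constraint, masked image) inputs, and a
   specificity-anchored score cutoff decides which constraints to keep —
   rejected samples fall back to an all-ones mask, which nullifies the
   penalty exactly;
4. **Constrained segmenter training** with λ grid-selected on validation.

Everything runs on synthetic phantoms with paired lung / lung+space /
lesion masks, controllable domain shift, and pneumothorax mimics outside
the admissible region, so every phase is testable with no external data.
I/O utilities also read/write real-data dialects (8/16-bit PNG, 0/255 PNG
masks, and SIIM-style column-major run-length-encoded CSV masks).

## Worked example

```python
from pleuraseg import pipeline

cfg = pipeline.ExperimentConfig()          # 64x64 phantoms, 120/20/40 target split
paths = pipeline.run_all(cfg, seed=1, outdir="out")
```

This writes `out/discriminator_report.csv`,

```
 specificity_target  cutoff  auroc  specificity  sensitivity      ppv  npv
               0.80    0.03    1.0     0.857143          1.0 0.928571  1.0
               0.85    0.03    1.0     0.857143          1.0 0.928571  1.0
               0.90    0.24    1.0     1.000000          1.0 1.000000  1.0
               0.95    0.24    1.0     1.000000          1.0 1.000000  1.0
```

showing the constraint-reliability discriminator separating reliable from
corrupted constraints (validation AUROC 1.0 at this seed), with adjacent
specificity targets resolving to the same score cutoff — and
`out/phase4_comparison.csv` with the baseline-vs-constrained test metrics
for this single seed (here IoU 0.711 → 0.717, DSC 0.823 → 0.826; single-seed
differences sit inside run-to-run noise, which is why the benchmark protocol
averages three seeds). The per-sample coverage ledger (R, label, score,
kept) lands in `out/coverage_records.csv`.

The method's own evaluation protocol is the three-seed ablation over
constraint sources (`pleuraseg ablate --seed 0`), whose mean rows were:

```
                   variant seed      iou      dsc        hd
                  baseline mean 0.698923 0.815306 12.776458
      raw_lung_constraints mean 0.668366 0.789991 12.374910
       refined_constraints mean 0.690387 0.808675 10.773435
refined_plus_discriminator mean 0.707301 0.823157 10.091491
```

Reading: raw transferred lung masks *hurt* (they exclude the pleural rim
where pneumothorax lives), morphological refinement roughly recovers the
baseline, and adding the reliability discriminator yields the best mean
IoU/DSC and a large Hausdorff improvement — the qualitative pattern the
constraint pipeline is designed to produce.

The command-line interface mirrors the library:

```bash
pleuraseg all    --seed 1 --outdir out      # full pipeline
pleuraseg ablate --seed 0 --outdir out      # constraint-source ablation
pleuraseg sweep  --seed 0 --outdir out      # element-size / cover-rate sweeps
```

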