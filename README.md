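# prostriage

Triage of prostate core-needle-biopsy whole-slide images (WSIs) into
**benign**, **indolent** (candidate for active surveillance) and
**aggressive** (candidate for definitive therapy), for computational
pathology researchers and engineers building slide-screening pipelines.

Pathologists grade prostate adenocarcinoma by Gleason patterns: GP3
(well-formed glands) is low risk, GP4/GP5 (fused/poorly formed glands,
sheets and cords) is high risk. The slide-level rule implemented here is an
area-fraction cutoff over annotated carcinoma,

    label(WSI) = benign      if no carcinoma
                 aggressive  if area(GP4+GP5) / area(GP3+GP4+GP5) >= 0.20
                 indolent    otherwise,

with the 20% boundary inclusive. Slides are scored by a tile classifier
with two *independent* sigmoid heads,

    p_indolent(t), p_aggressive(t)  for each tissue tile t,
    S_L = max_t p_L(t)              (max aggregation per label L),

and a head enters the slide's label set when `S_L >= 0.5`. Both heads may
fire at once — a *double-label* slide, typical of mixed GP3/GP4 morphology
near the cutoff. Training is weakly supervised hard-example mining (the k
highest-scoring tiles per slide join the training pool; mined tiles from
benign slides supervise both heads negative, suppressing false positives),
optionally preceded by fully supervised sampling from pathologist
annotation polygons (FS+WS mode). Evaluation provides per-head ROC-AUC,
log loss, accuracy/sensitivity/specificity with percentile-bootstrap 95%
CIs, a double-label acceptance scoring mode, and rater-agreement
statistics (multi-rater Bennett S, intra-rater weighted kappa).

Because clinical WSIs of this kind are not redistributable, the package
ships a seeded synthetic-slide generator (three separable procedural
textures composed as biopsy-like fragments on white, with annotation
polygons and labels derived through the same 20% rule) so the entire
pipeline is testable end to end on a laptop. See `docs/methods.md` for the
model, parameters and limitations.

## Worked example

```python
from prostriage.synthetic_wsi import generate_dataset
from prostriage.training_engine import TrainingConfig, run_training
from prostriage.wsi_inference import score_slide, aggregate_wsi
from prostriage.evaluation import evaluate_set
from prostriage.wsi_io import read_slide

manifest = generate_dataset(10, "demo_data", split_fractions=(0.4, 0.2, 0.4), seed=7)
config = TrainingConfig(tile_size=128, stride=128, draws_per_epoch=8,
                        warmup_epochs=2, max_epochs=20, patience=10, seed=7)
classifier, history = run_training(manifest, config, mode="FS+WS")

predictions, truths = [], []
for _, row in manifest.subset("test").iterrows():
    slide = read_slide(row["path"], slide_id=row["slide_id"])
    pred = aggregate_wsi(score_slide(classifier, slide, tile_size=128, stride=128))
    predictions.append(pred)
    truths.append(row["label"])

one = predictions[-1]
print(f"slide {one.slide_id} (truth: {truths[-1]})")
print(f"  score_indolent   = {one.score_indolent:.3f}")
print(f"  score_aggressive = {one.score_aggressive:.3f}")
print(f"  label_set        = {sorted(one.label_set)}")

report = evaluate_set(predictions, truths, mode="exclusive", n_bootstrap=1000, seed=7)
agg = report.heads["aggressive"].roc_auc
print(f"aggressive ROC-AUC = {agg.point:.3f} [{agg.ci_low:.3f} - {agg.ci_high:.3f}]")
```

Output:

```
slide aggressive_009 (truth: aggressive)
  score_indolent   = 0.934
  score_aggressive = 0.947
  label_set        = ['aggressive', 'indolent']
aggressive ROC-AUC = 1.000 [1.000 - 1.000]
```

The test slide is called *both* indolent and aggressive: its GP4/5 regions
drive the aggressive head while its GP3 regions legitimately drive the
indolent head — the double-label phenomenon the acceptance scoring mode
(`mode="double_label_accept"`) is designed for. The aggressive head ranks
the 12 held-out synthetic test slides perfectly; on the fully separable
synthetic textures that is the expected ceiling, not a claim about real
histology.

A command-line interface mirrors the library:

```sh
triage generate --n-per-label 4 --out data/ --seed 7
triage train --manifest data/manifest.csv --mode fs+ws --seed 7 --out ckpt/
triage predict --ckpt ckpt/model.npz --slide data/slides/aggressive_000.tiff \
    --out pred.json --heatmap heat.png
triage label --annotations data/annotations/indolent_000.geojson --out label.json
triage rater-stats --ratings ratings.csv --mode s-score
```

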