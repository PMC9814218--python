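# Methods

## Problem and model

`prostriage` triages prostate core-needle-biopsy whole-slide images (WSIs)
into three management-oriented classes: **benign**, **indolent** (candidate
for active surveillance) and **aggressive** (candidate for definitive
therapy). The clinical ground truth is an area-fraction rule over Gleason
patterns: a slide whose Gleason pattern 4 + 5 area is at least 20% of the
total annotated carcinoma area is aggressive; carcinoma below that cutoff is
indolent; no carcinoma is benign. The boundary is inclusive (exactly 20% is
aggressive). For tile-level supervision, GP3 regions supervise the
*indolent* head and GP4/GP5 regions the *aggressive* head.

Scoring is a two-stage pipeline:

1. **Tile scoring.** The slide is cut into fixed-size tiles on a stride
   grid restricted to tissue (Otsu threshold on ITU-R 601 luminance; tissue
   is the dark side, the scanner background is near-white). A convolutional
   classifier maps each tile to two *independent* sigmoid probabilities,
   `p_indolent` and `p_aggressive`. There is deliberately no softmax
   coupling: a tile of mixed morphology may score high on both heads, and
   benign is the absence of both.
2. **Max aggregation.** Each head's slide score is the maximum tile
   probability. A head whose score reaches the decision threshold (default
   0.5) enters the slide's label set; both heads firing yields a
   *double-label* slide, an empty set is benign. `exclusive_label` collapses
   the set by taking the larger score (ties toward aggressive).

## Training

Two supervision modes share one loop:

* **WS** (weakly supervised): slide labels only.
* **FS+WS**: warm-up draws carcinoma tiles only from annotation polygons of
  the matching class (tile centre inside the polygon), then continues like WS.

The loop starts with `warmup_epochs` (default 2) of balanced random
sampling: each draw picks one slide per label and an equal number of tiles
per slide. After warm-up it alternates inference and **hard-example
mining**: for each sampled slide the k (default 8) tiles with the highest
relevant-head probability join a training pool; when the pool holds N
(default 256) tiles it is consumed in batches of 32 (leftovers persist —
tiles are never dropped). Mined-tile weak labels: benign slides are
negative for both heads (false-positive suppression — the reason mining
helps at all); an indolent slide is positive for the indolent head and
*masked* for the aggressive head; an aggressive slide the converse. The
masking matters: aggressive slides legitimately contain GP3 regions, so a
cross-head negative would inject label noise.

The loss is mean binary cross-entropy over unmasked (tile, head) pairs,
optimized with Adam (lr 0.001, beta1 0.9, beta2 0.999). After each epoch
the validation loss is the mean per-head BCE of max-aggregated slide scores
against the slide label's head indicators (indolent slide -> (1, 0),
aggressive -> (0, 1), benign -> (0, 0)). Training stops when this loss has
not improved for `patience` (default 10) epochs, and the best-epoch
parameters are returned.

### Backbone and the fine-tuning policy

The backbone is pluggable; the built-in `tinyconv` network (mean-pool to
32x32, two 3x3-conv + batch-norm + ReLU + pool stages of 8 and 16 channels,
global average pooling, a 2-unit linear head; ~1.5k parameters) is written
directly on numpy with explicit backward passes, so it trains in seconds on
one CPU and is bit-reproducible under a seed. `trainable_policy="partial"`
freezes everything except the batch-normalization affine parameters and the
final classification layer — the standard efficient-transfer recipe when
starting from pretrained weights. Because this package ships no pretrained
backbone, the training default is `"all"`: from random initialization,
partial training leaves the frozen random convolutions as the only feature
extractor and separates weakly. The partial policy remains fully supported
and contract-tested (frozen parameters stay bit-identical across a run).

## Evaluation

Each head is evaluated one-vs-rest: truth binarized as `truth == head`,
score is the head's slide score. ROC curves sweep all distinct scores;
AUC is trapezoidal and equals the Mann-Whitney pair-ranking probability
with ties counted one half. Log loss clips probabilities at 1e-15.
Accuracy/sensitivity/specificity come from hard calls in one of two modes:

* `exclusive` — compare `exclusive_label` with the truth;
* `double_label_accept` — a double-label call whose set contains the truth
  is resolved *to* the truth. This formalizes "accepting" a double call as
  correct when either member matches the consensus; since it only ever
  moves calls toward the truth, accept-mode accuracy is never below
  exclusive-mode accuracy (a tested invariant). The naive alternative
  (call head L positive iff L is in the label set) does not have this
  property — a double call on a benign-truth slide would manufacture a
  false positive — which is why it was not adopted. AUC is call-free and
  identical in both modes.

95% confidence intervals are percentile bootstrap over slides (1000
resamples by default); degenerate resamples (e.g. single-class AUC) are
skipped, and an interval is refused if more than half degenerate.
Bootstrap coverage is verified by simulation (N(0,1) vs N(1,1) scores,
true AUC = Phi(1/sqrt 2), 200 repetitions at n = 100).

## Rater agreement

Inter-rater agreement across two or more raters uses **Bennett's S**:
mean pairwise percent agreement per item, chance-corrected with the uniform
baseline 1/c, S = (c·Po − 1)/(c − 1) with c = 3. The multi-rater
generalization (average pairwise agreement, then one chance correction) is
the standard one and is oracle-tested against explicit pair enumeration.
Intra-rater (test-retest) agreement uses **weighted kappa** over the
ordered categories benign < indolent < aggressive with linear weights
|i−j|/(c−1) by default (quadratic by flag); the weighting scheme is a
convention choice, so both are exposed. Verbal interpretation bands are
left-open/right-closed (≤0 poor, (0,0.2] slight, (0.2,0.4] fair, (0.4,0.6]
moderate, (0.6,0.8] substantial, (0.8,1] almost perfect) so every value up
to 1 maps to exactly one band, including values inside the printed gaps of
the conventional scale.

## Synthetic data

Real biopsy WSIs are gigapixel files with restricted access; the generator
emulates their *statistical structure* at desk scale (default 1536x1024,
three elongated rectangular fragments on pure white). Three procedural
textures stand in for tissue classes: a smooth pink benign field with pale
voids, a regular small-ring motif for GP3 (the well-formed-gland look), and
a dark fused-blob field for GP4/5. Design constraints, in order:

* **Separable by a small classifier** — the textures differ in hue,
  luminance and spatial frequency; the pipeline-level test is that training
  recovers aggressive-head AUC >= 0.95 on held-out slides, and a
  label-shuffled control stays at chance.
* **Otsu-consistent** — all tissue sits in a narrow luminance band
  (roughly 110-185) far below the 255 background, so the global Otsu
  threshold falls in the tissue/background gap rather than splitting dark
  carcinoma from pale stroma; geometry snaps to the 16-px mask grid so the
  majority-rule tissue mask covers fragments exactly.
* **Label-consistent by construction** — carcinoma textures are painted in
  rectangular bands, each wrapped in a matching annotation polygon, and the
  emitted slide label is *derived from those annotations* through the same
  20% rule the labeling module implements. Requested GP4/5 fractions are
  realized within band-quantization error (about +/-2% of carcinoma area);
  near-boundary slides (GP4/5 share 0.15-0.25) are included deliberately to
  exercise double-label behaviour.

What the generator does **not** emulate: stain variation, scanner
artifacts, pen/ink marks, nuclear-level morphology, multi-resolution
pyramids, or the ambiguous GP3/GP4 transition zones that drive human
disagreement on real slides. Passing the end-to-end tests therefore shows
the pipeline's machinery is correct and can recover a clean signal; it says
nothing about accuracy on real histology.

## Problem sizes and numerical choices

Tests and the acceptance script run the full pipeline at desk scale as the
package's own study conditions: 30 synthetic slides (12 train / 6
validation / 12 test, balanced), 128-px tiles with stride 128, the
`tinyconv` backbone, k = 8, N = 256, batch 32, 2 warm-up epochs, 8 draws
per epoch, at most 20 epochs with patience 10. The label-shuffled control
runs 5 independent seeds at 4 epochs each and evaluates the 18 held-out
slides; its null standard deviation (~0.06 on the mean AUC) is set by the
evaluation-set size. All randomness flows from explicit
`numpy.random.Generator` seeds; training, generation and bootstrap results
are exactly reproducible under a fixed seed. Ties: Otsu takes the smallest
maximizing threshold; hard mining breaks score ties in row-major tile
order; exclusive-label ties go to aggressive. Degenerate inputs (single-bin
histograms, empty tile grids, all-masked batches, single-class AUC) raise
typed errors rather than returning silent defaults.

## Known limitations

* The 20% rule needs annotated carcinoma area; without annotations only
  slide-level weak supervision (WS) is possible.
* Max aggregation makes slide scores sensitive to a single false-positive
  tile; hard mining mitigates but does not eliminate this.
* The indolent head's one-vs-rest AUC is intrinsically limited because
  aggressive slides usually contain GP3 regions too, so their indolent
  score is legitimately high; this is the same phenomenon that produces
  double-label calls and is the motivation for the acceptance scoring mode.
* The tiny backbone is a test-scale stand-in; swapping in a stronger
  backbone changes capacity, not mechanics.
* Vendor formats (SVS/JPEG2000) are not decoded; convert to tiled TIFF or
  PNG first, or adapt a reader to `SlideImage`.
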