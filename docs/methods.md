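# Methods

This note documents the models and procedures implemented in `pathomil`, the
assumptions behind them, the parameters that matter, and what the synthetic
benchmark does and does not establish.

## Problem setting

A colon histopathology case couples a whole-slide image (WSI) with a
free-text diagnostic report. The package targets the annotation-free
training regime: no pathologist labels anything. Weak multilabel diagnoses
are extracted from the report text and used as slide-level supervision for
an image classifier over five classes, in fixed canonical order: cancer,
high-grade dysplasia (HGD), low-grade dysplasia (LGD), hyperplastic polyp,
normal. A report or slide may carry several classes at once.

## Weak-label extraction from report text

The labeler is a rule-based concept-extraction pipeline:

1. **Normalization** — lowercase, Unicode NFKC folding, whitespace collapse
   (newline runs keep a newline because newlines scope sentences). An offset
   map preserves the link back to original character positions.
2. **Recognition** — greedy longest-match, left-to-right, over token
   n-grams of gazetteer terms and synonyms. Tokens split on whitespace *and*
   hyphens, so "hyperplasia-adenomatous" exposes "hyperplasia" to matching
   while "high-grade dysplasia" still matches as a three-token term. Matches
   never overlap and never cross a sentence boundary ({".", ";", newline}).
   The recognizer is a pluggable callable; the shipped default is the
   gazetteer matcher, and a neural biomedical NER model can be substituted
   without touching the rest of the pipeline.
3. **Linking** — exact normalized equality (score 1.0), then curated ad-hoc
   patterns (e.g. grade adjectives next to "dysplas-"), then best normalized
   Levenshtein ratio over all terms, accepted at or above the configurable
   threshold (default 0.85). Ties break by higher score, then
   lexicographically smallest concept id, so linking is deterministic. The
   ad-hoc rule set is a reconstruction — the original hand-tuned rules of
   clinical deployments are unpublished — and is versioned with the package.
4. **Negation** — a cue ("no", "not", "without", "absence of", "free of",
   "negative for") ending within `negation_window` (default 5) tokens before
   a mention, in the same sentence, marks the concept negated; negated
   concepts contribute no class. Negation is on by default because missing
   it is the main documented failure mode of affirmative-only extraction;
   disabling it reproduces that failure for study.
5. **Context rules** — a hyperplasia- or adenoma-type concept inside a
   resection-margin clause ("margin of resection on hyperplasia-adenomatous
   mucosa") describes the margin, not a finding, and is suppressed. The
   switch is separate from negation so the documented false positive can be
   reproduced or mitigated independently.
6. **Grade resolution** — grade-sensitive concepts (bare "dysplasia",
   adenoma types) take their class from the nearest grade adjective in the
   sentence ({severe, marked, high(-grade)} → HGD; {mild, moderate, slight,
   low(-grade)} → LGD), searching both directions with ties preferring the
   preceding adjective; with no adjective the configurable default applies
   (LGD, the most prevalent dysplasia grade in screening corpora). The
   sentence-scope search is a design choice: it lets "tubulovillous adenoma
   with severe dysplasia" resolve the adenoma to HGD even though the
   adjective follows the mention.
7. **Fallback** — a report in which no class survives is labeled `normal`,
   applied per report. Labels are therefore never empty.

Unmatched tokens (length ≥ 5, alphabetic, not stopwords) get a fuzzy-linking
pass so single-character typos ("adenocarcnoma") still link. The labeler
asserts English input; a translator hook (a `text -> text` callable) can be
registered for other languages but none ships.

## Slide preprocessing

Slides are split into 224 × 224 patches at 10× magnification. Pyramid
handling picks the level with the smallest magnification at or above the
target and rescales exactly; single-level rasters rescale directly; slides
without magnification metadata assume 20× (logged). Upscaling is off by
default and raises.

Tissue/background separation thresholds the HSV saturation channel with
Otsu's method, then applies morphological opening and closing (disk radius
2) and hole filling. This is a deliberately simple, documented stand-in for
dedicated slide-QC tooling; it assumes a bright background and stained
tissue and does not detect pen marks, blur or folds. Patches lie on a
non-overlapping grid (stride = patch size; overlap is configurable), border
cells smaller than a patch are dropped rather than padded, and a patch is
retained iff its tissue fraction reaches the threshold (default 0.5, a
sensitivity knob the underlying protocol leaves open).

Training-time augmentation operates at WSI level: per slide and epoch, a
transform is sampled with three independent inclusion decisions at
probability 0.5 each — rotation (90/180/270), horizontal/vertical flips, and
colour jitter in HSV (hue ±20, saturation ±30, value ±20 on the 8-bit
scale) — and applied identically to every patch of that slide, so
within-slide consistency is preserved. The pipeline is fully seeded.

## The attention-MIL classifier

A WSI is a bag X_n of p patches. The model is instance-level MIL:

- a **frozen backbone** encodes each patch into a feature vector. The
  `paper` preset is a 34-layer residual network layout (7×7/2 stem, stages
  [3,4,6,3] at 64/128/256/512 channels, global average pool → 512 features),
  forward-only in NumPy, with random seeded weights or weights loaded from
  an `.npz` file; the `tiny` preset is a two-layer random-filter
  convolutional net summarized by channel statistics (54 features), fast
  enough to featurize thousands of patches per minute on one CPU.
- an **input standardization layer** (per-dimension mean/scale, fitted on
  the training bags' features, frozen and stored with the checkpoint). This
  is part of the architecture: backbone feature scales vary by orders of
  magnitude across dimensions, and without standardization Adam conditions
  so poorly that slide-label recovery stalls well below its attainable
  accuracy.
- an **embedding layer** (affine, default 512 → 128) with ReLU.
- a **patch classifier** (affine, 128 → 5 logits z[p, c]): patch-level
  prediction is multiclass softmax/argmax, ties to the lowest class index.
- a **per-class attention network** (affine, 128 → 5 scores; a
  shared-attention variant is a config switch). Attention weights are
  a[c, ·] = softmax over patches of class c's scores, so every class row
  sums to one. The slide logit for class c is Σ_p a[c, p] · z[p, c], and the
  slide probability its logistic transform — multilabel by construction.

The composition — attention applied to patch *logits*, then a sigmoid — is
one of several aggregations consistent with instance-level MIL plus
attention pooling; it keeps patch predictions independently meaningful
(each patch has its own class posterior) while producing multilabel slide
probabilities, and it is isolated behind `attention_pool` so alternatives
can be swapped in one place.

**Prediction rule**: a class is set iff its probability exceeds the decision
threshold (default 0.5); if none does, the argmax class is set — a
diagnosis is always emitted.

**Training** minimizes the unweighted mean over the five classes of binary
cross-entropy between slide probabilities and the weak label, with Adam
(default learning rate 1e-3, weight decay 1e-3 as coupled L2, 15 epochs),
one bag per gradient step, bags shuffled per epoch, the backbone frozen
throughout. No class re-weighting is applied despite imbalance. Gradients
are derived in closed form and implemented directly in NumPy; they are
verified against finite differences in the test suite. Within a fold the
epoch checkpoint with the lowest validation loss is kept.

**Model selection** is grid search (learning rate and weight decay over
{1e-2 … 1e-5}, embedding width over {32, 64, 128, 256}) by lowest mean
validation loss across folds; ties break toward smaller embedding and
smaller learning rate for parsimony, making the search invariant to
enumeration order.

**Cross-validation** is k-fold (default k = 10) at patient level: all bags
of a patient stay in one fold, fold sizes differ by at most one patient, and
metrics are reported as mean ± sample standard deviation over the k models.
One master seed fans out per-fold and per-epoch streams, so folds are
independently reproducible.

## Evaluation

- **Slide/image level (multilabel)**: micro-accuracy pooled over all
  (sample, class) indicator cells, and support-weighted macro F1 with the
  zero convention (a class never predicted but present scores F1 = 0;
  zero-support classes carry zero weight). A per-sample exact-match accuracy
  is logged but never reported as the headline.
- **Patch level (multiclass)**: Cohen's κ; 0.40–0.60 is conventionally the
  "moderate agreement" band.
- **Per class**: precision, recall, F1, support; one-vs-rest ROC curves and
  trapezoidal AUC, with degenerate classes flagged as undefined rather than
  scored 0.
- **Label-source comparison**: two-sided Wilcoxon rank-sum, exact by
  enumeration for combined n ≤ 12, tie- and continuity-corrected normal
  approximation otherwise (the branches agree within 0.02 at the switch
  point).
- **Mislabeled-subset protocol**: cases whose automatic label disagrees with
  ground truth in at least one class form the mislabel set; metrics can then
  be computed on exactly that subset.
- **External datasets**: predictions aggregate onto each public dataset's
  scheme by OR over the scheme's membership sets (e.g. HGD and LGD both map
  to "Dysplasia" on AIDA; cancer and HGD to "High-risk" on IMP-CRC).
  Unmapped internal classes are dropped (logged at debug level). A slide
  whose mapped prediction set is empty is scored as the empty set — wrong
  against any positive ground truth. Scheme-level accuracy is micro over the
  scheme's external classes.
- **Interpretability**: attention heatmaps paint per-patch weights into
  patch footprints (min-max normalized per slide — a monotone map, so the
  weight ranking is conserved) alpha-blended over the slide; the latent
  export keeps patches whose top class probability exceeds 0.5 and projects
  their 128-d embeddings to 2-D with seeded t-SNE.

## Synthetic benchmark

The generator produces paired cases with known truth so every component is
testable without clinical data.

**Slides**: class regions are elliptical blobs (one vertical band per set
class, non-overlapping) painted with procedural gland textures on a white
background. Texture parameters follow the morphology gradient pathologists
describe — gland deformation and epithelial solidity increase strictly from
normal through hyperplastic polyp, LGD and HGD to cancer — with lattice
jitter, azimuthal ring deformation and per-pixel colour jitter so classes
are distinguishable by construction but not constant. Ground truth is
recorded per pixel (region mask) and per grid cell (the class covering at
least half the cell's tissue, else none). Default slide size is 1120 × 1120
(a 5 × 5 patch grid) for desk-scale speed, configurable upward.

**Reports**: each set class contributes one affirmative template phrase
drawn from variants the bundled gazetteer covers; pure-normal cases omit
findings with probability 0.5, exercising the fallback path as well as the
explicit mention path. Optional noise: with the configured rates, a negated
phrase for an *unset* class is appended ("no high-grade dysplasia"), and the
resection-margin distractor clause is appended when hyperplastic polyp is
unset.

**Corpus**: label sets are drawn from a configurable prevalence distribution
whose default mirrors a screening workflow (normal 0.30, LGD 0.22,
hyperplastic 0.14, cancer 0.12, HGD 0.08, plus rare two-class combinations);
patients are assigned round-robin with a configurable bags-per-patient
count. Label-noise injection corrupts exactly ⌊rate · n⌋ cases by flipping
one uniformly chosen class indicator (keeping at least one class set) — the
minimal corruption unit under the "one or more classes differ" definition of
a mislabel — and records every corruption in a manifest. Rates of 0.15–0.25
emulate the error range reported for automatic report labeling on real
hospital corpora.

**What passing tests show, and what they do not.** The synthetic textures
are far more separable than real histology; stain variability across
centers, scanner differences, artifacts, and block-level report structure
are not emulated. Recovery results on this benchmark validate the
*machinery* — that the MIL objective, attention pooling, fold handling and
label plumbing are correct and that the pipeline learns what its weak labels
encode — not clinical performance. Conversely, because texture separability
is itself asserted by a test (a standardized logistic regression on patch
features exceeds 0.9 accuracy), a recovery failure indicts the MIL
machinery rather than the data.

## Study sizes and numerical choices

- The scaled-down recovery and robustness studies use 200 cases (160
  training bags, 40 held out by patient), 5 × 5 patch grids, the tiny
  backbone, and k = 2 cross-validation; these sizes make the full studies
  reproducible in minutes on one CPU core. They train with augmentation
  off: per-epoch slide-level augmentation forces re-featurization of every
  bag each epoch, which dominates runtime at these sizes, and the synthetic
  textures already carry colour jitter at generation. Augmentation remains
  on by default in `TrainConfig` and has its own tests.
- The attention-localization study trains on a corpus whose label-set
  prevalence includes lesion + normal combinations (a lesion region inside
  benign mucosa on one slide). Attention weights can only be evaluated for
  contrasts the training bags contain: a model trained exclusively on
  single-lesion slides has never had to rank lesion against normal patches
  within one bag, so its heatmaps on such slides are uninformative — and
  real screening WSIs are precisely lesions embedded in benign tissue. The
  recovery and robustness studies keep the default screening-imbalance
  prevalence.
- Softmax and binary cross-entropy are computed in shifted/stable forms;
  attention rows are validated to sum to 1 within 1e-6.
- Ties: patch argmax → lowest class index; grid search → smaller embedding,
  then smaller learning rate; linking → higher score, then smallest concept
  id; grade adjectives → nearest, preceding on distance ties.
- Degenerate inputs: single-colour slides yield an empty or full tissue mask
  (no exception); slides smaller than one patch yield an empty bag with a
  warning; an all-below-threshold slide prediction falls back to argmax;
  AUC on a degenerate class raises an explicit undefined-metric error.
- Checkpoints are self-describing `.npz` archives (head weights including
  the standardizer, backbone spec, training config, class order, version).

## Known limitations

- The rule-based labeler is a reconstruction tuned on synthetic phrasing
  plus the documented failure modes; on real clinical text its ad-hoc rule
  set would need extension, and non-English reports require a translator.
- Block-level reports (one report covering several slides) are not split;
  the normal fallback applies per report.
- The NumPy backbones are forward-only; pretrained convolutional weights
  can be loaded from `.npz` but no converter from framework checkpoints is
  bundled.
- Embedding-level MIL (aggregating embeddings rather than predictions) is
  out of scope, as are stain normalization and self-supervised pretraining.
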