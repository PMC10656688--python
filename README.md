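# birads-video

A toolkit for automatic BI-RADS assessment of breast-ultrasound sweep
videos. It implements the full classical pipeline

```
sweep video ──► lesion frame selection + segmentation
            ──► per-frame lexicon features (shape, orientation, margin,
                echo pattern, posterior acoustic features, calcification)
            ──► frame-proportion score fusion
            ──► BI-RADS category (2 / 3 / 4a / 4b / 4c / 5) + benign/malignant call
```

plus the statistics used to evaluate such a system against human
readers (confusion metrics, tie-aware ordinal ROC/AUC with DeLong
variance and paired test, Cohen's kappa with interpretation bins,
McNemar's test, percent/conditional agreement), and a synthetic
speckle-phantom generator so every stage is testable end-to-end without
clinical data.

## Package layout

| module                 | contents |
|------------------------|----------|
| `birads.phantom`       | `PhantomSpec`, ellipsoidal sweep model, speckle rendering, ground truth, archetype/battery specs |
| `birads.video_io`      | `FrameSequence`, PNG-directory and (optional) MP4/AVI readers, rating-CSV parser, JSON reports |
| `birads.segmentation`  | classical lesion segmenter, SimAM attention weights, BCE/focal/CIoU losses, Dice/IoU + detection counts |
| `birads.features`      | the six lexicon extractors (15 levels) with all thresholds in `FeatureConfig` |
| `birads.fusion`        | frame-proportion aggregation, level selection, weighted score table, rank thresholds, simple-cyst override |
| `birads.evalstats`     | confusion metrics, AUC/DeLong, kappa, McNemar, agreement rates |
| `birads.cli`           | the `birads` command-line app and `RunConfig` |

## CLI

A single `birads` entry point with subcommands:

```bash
# render a synthetic sweep (PNG frames + masks + ground-truth JSON)
birads phantom --config spec.yaml --out video_dir/ --seed 3

# segment a video (a directory of zero-padded PNG frames, or MP4/AVI
# when an imageio ffmpeg plugin is installed)
birads segment video_dir/ --out masks/

# per-frame lexicon features from frames + masks
birads features --frames video_dir/ --masks masks/ --out features.json

# full pipeline to a JSON assessment report
birads classify video_dir/ --out report.json

# reader-agreement statistics from a rating table
birads eval ratings.csv --pairs auto:expA --pairs auto:junA --out stats.json

# phantom label-recovery benchmark
birads benchmark --seeds 5 --out bench.json
```

The ratings CSV has header
`lesion_id,truth,rating_auto,rating_expA,rating_expB,rating_junA,rating_junB`
with BI-RADS tokens `2,3,4a,4b,4c,5` and truth `benign`/`malignant`.
Every report embeds a hash of the configuration actually applied, the
package version and the seed, and repeat runs are byte-identical.

All thresholds — segmentation (`SegConfig`), feature extraction
(`FeatureConfig`) and the fusion score table (`ScoreTable`: per-level
weights, frame-proportion thresholds, rank thresholds, malignancy cut,
simple-cyst override) — are plain dataclasses serializable to YAML.

## Conventions

- 0-based `(row, col)` indexing; row 0 is the skin side, depth grows
  with the row index; bounding boxes are half-open
  `(row0, col0, row1, col1)`.
- Frames are grayscale float arrays in `[0, 1]`; directories of frames
  are read in lexicographic order (zero-pad the names).
- Empty-vs-empty mask overlap is defined as Dice = IoU = 1.
- The segmenter assumes hypoechoic (dark) lesions by default; use
  `threshold_method="fixed"` with `invert=True` for hyperechoic ones.
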