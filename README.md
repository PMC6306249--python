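# shapebias

Do contour classifiers recognize objects by **global shape** or by **local
contour features**? This package provides everything needed to ask that
question of any image classifier under controlled conditions:

- **`shapebias.geometry`** — contour primitives: subpixel contour
  extraction, arc-length resampling and smoothing, turning-angle curvature
  profiles and histograms, elliptic Fourier descriptors (Kuhl–Giardina)
  with invariance normalization, and the global/local distance measures.
- **`shapebias.stimuli`** — stimulus constructions: silhouettes, outline
  drawings, texture chimeras (cue conflict), **part scrambling** (destroys
  global configuration, preserves local contour statistics) and
  **serration** (destroys local contour statistics, preserves global
  shape), each with a quantitative `ManipulationReport`.
- **`shapebias.synth`** — seeded synthetic catalogs: smooth "blob" classes
  (radial Fourier outlines) and polygon classes, exemplar jitter,
  procedural textures, disjoint train/test splits.
- **`shapebias.classify`** — the classifier contract (`validate_probs`,
  adapter interface) and two scikit-learn-style toy classifiers that
  *embody* the competing hypotheses: a curvature-histogram
  (local-feature) classifier and an elliptic-Fourier (global-shape)
  classifier.
- **`shapebias.metrics`** — analysis statistics: competition label ranks,
  top-k correctness, chance level, shape-vs-texture preference, grouped
  summary tables, human-response scoring, pooled two-sample t test.
- **`shapebias.experiment` / `shapebias.cli`** — an end-to-end pipeline
  (`generate → classify → analyze → report`) with deterministic, resumable
  runs.

## Quick start

```python
from shapebias import (build_catalog, ToyShapeClassifier, part_scramble,
                       serrate)
import numpy as np

cat = build_catalog(10, 20, seed=42, blob_fraction=1.0)
X = [m for v in cat.vocabulary for m in cat.train[v]]
y = [v for v in cat.vocabulary for _ in cat.train[v]]

local_clf = ToyShapeClassifier(feature_kind="curvature").fit(X, y)
global_clf = ToyShapeClassifier(feature_kind="efd").fit(X, y)

test = [m for v in cat.vocabulary for m in cat.test[v]]
scrambled = [part_scramble(m, n_parts=3, seed=i)[0] for i, m in enumerate(test)]
serrated = [serrate(m)[0] for m in test]
```

The two classifiers double-dissociate: scrambling barely touches the
curvature classifier but destroys the EFD classifier, and serration does
the reverse.

### CLI

```sh
shapebias generate --seed 3 --classes 10 --exemplars 20 --out catalog/
shapebias classify --catalog catalog/ --classifier curvature --out results/
shapebias run --experiment scramble --seed 5 --out run/ --classifier both
shapebias compare --report-a run/report_curvature.csv --report-b run/report_efd.csv
```

`run` accepts a YAML/JSON config via `--config`; flags override config
values. Exit codes distinguish configuration (2), data (3) and adapter (4)
failures.

## Verification

```sh
pytest                                            # unit + property + acceptance tests
python scripts/acceptance.py --seed 1 --out acceptance.json
```

See `docs/methods.md` for the measurement conventions (smoothing scales,
curvature binning, corner discounting, descriptor gauges, catalog design)
and known limitations.
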