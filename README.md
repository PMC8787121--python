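# mmiqa

A full-reference image-quality metric for pool/underwater-style scenes,
plus the tooling around it: JPEG distortion-database construction,
subjective-score (DMOS) processing, and a metric-evaluation harness.

The metric ("MM-IQA") fuses three per-pixel feature similarities between a
reference and a distorted image — local luminance, local contrast, and
Scharr gradient magnitude — with a spectral-residual saliency stage: the
saliency maps of both images give a contour-similarity term and the
positional weights used to pool everything into one score in (0, 1]
(1 = identical images).

## Library quick start

```python
from mmiqa import (FixtureSpec, MMIQAParams, build_distortion_set,
                   generate_pool_fixture, mm_iqa_score)

ref = generate_pool_fixture(FixtureSpec(seed=7, height=288, width=512))
ds = build_distortion_set(ref, [50, 40, 30, 20, 10], "scene7")
params = MMIQAParams()
for level, dist in zip(ds.levels, ds.distorted):
    print(level, mm_iqa_score(ref, dist, params).value)
```

`MMIQAParams` exposes every free constant (stabilizers C1–C4, fusion
weight `w1`, exponents `theta`/`psi`, saliency working width, window
settings) and round-trips through a flat YAML config; unknown keys are
rejected. Note the saliency stage runs on a downscaled copy of the image
(`working_width`, default 256); for small inputs choose a working width a
few times smaller than the image so block artifacts are averaged out.

## CLI

One entry point, `mmiqa`, with subcommands:

```bash
mmiqa fixtures --n 10 --seed 7 --out refs/            # synthetic references
mmiqa distort --ref refs/ --out db/ --levels 10,20,30,40,50
mmiqa saliency --in img.png --out sal.png             # saliency heat map
mmiqa featuremaps --ref a.png --dist b.png --out maps/
mmiqa score --ref a.png --dist b.png --json [--config mmiqa.yaml]
mmiqa batch --manifest db/manifest.csv --out scores.csv
mmiqa simulate-ratings --quality quality.csv --subjects 16 --seed 3 \
      --out-ratings ratings.csv --out-refs refmap.csv
mmiqa dmos --ratings ratings.csv --refs refmap.csv --k 2 --out dmos.csv
mmiqa benchmark --scores scores.csv --dmos dmos.csv --out report.json
```

`distort` writes `db/<ref_id>/q<level>.jpg` plus `manifest.csv`
(`reference_id,level,path,reference_path`). Rating CSVs are
subjects-as-rows, image-ids-as-columns, with a sidecar CSV mapping each
distorted image id to its reference id. `benchmark` emits the five
indices (SROCC, KROCC, PLCC, RMSE, MAE — the last is the mean absolute
error) together with the fitted five-parameter logistic curve.

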