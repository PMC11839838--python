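# promptseg

Automated evaluation of **interactive point-prompt 2D segmentation** on
volumetric tumor MRI.

Promptable foundation segmentation models return candidate masks for a 2D
image conditioned on user clicks (foreground/background points). For
radiotherapy-style tumor contouring, the practical questions are: how good
does the contour get as an expert keeps clicking, which of the model's
candidate masks should be kept, how well do stacked 2D contours approximate
a 3D segmentation, and for which slices does the approach break down. This
package implements the full evaluation pipeline that answers those questions
against ground-truth labels, for anyone benchmarking a promptable model
(or a mock of one) on brain-tumor-like volumes:

- **Prompt simulation.** Per tumor-containing slice: the first foreground
  point is placed at the ground-truth distance-transform argmax (the tumor
  "center"); each corrective point goes at the center of the set difference
  between ground truth G and prediction P — a foreground point in G∖P when
  |G| ≥ |P|, else a background point in P∖G — up to nine points. The
  per-iteration IoU (J = |G∩P| / |G∪P|) of the selected mask is recorded;
  the primary per-slice metric is the **best IoU** over iterations.
- **Triple-mask selection.** The predictor returns three candidates with
  confidence scores; the *oracle* strategy keeps the candidate with the
  highest calculated IoU (an expert choosing the best suggestion), the
  *suggested* strategy keeps the highest-confidence one, and the
  *prev-slice* strategy keeps the one most similar to the previous slice's
  segmentation (sequential slice-wise workflow).
- **3D stacking and fusion.** Best per-slice masks are stacked per
  orientation (transverse / sagittal / coronal) and fused by per-voxel
  2-of-3 majority vote; volumetric Dice D = 2|A∩B|/(|A|+|B|) scores the
  result (D = 2J/(1+J)).
- **ROI cropping.** Experiments optionally run on a cuboid region of
  interest fitted to the 3D tumor extent with a 2-cm margin.
- **Area statistics.** Spearman correlation of best IoU with ground-truth
  tumor area, and the optimal area cutpoint by **maximally selected
  Wilcoxon rank statistics** with a seeded-permutation adjustment for
  cutpoint selection.

Everything runs fully self-contained on **synthetic phantoms** (bright-rim /
necrotic-core tumors on a noisy brain-like background, spanning a sharp
high-grade-like to diffuse low-grade-like contrast axis) with a **mock
promptable predictor** whose candidate quality responds to prompt count and
image contrast — no downloads or model weights. The same pipeline runs
unchanged on real NIfTI image/label pairs with any predictor implementing
the `PromptablePredictor` contract (a callable mapping a 3-channel 2D image
and a prompt list to three masks plus confidences).

## Worked example

```sh
python analysis/01_generate_phantoms.py   # cohort -> results/phantoms/
python analysis/02_simulate_prompts.py    # prompt loops -> results/traces.csv
python analysis/03_fuse_orientations.py   # 3D fusion -> results/fusion.csv
python analysis/04_threshold_stats.py     # area stats -> results/threshold.json
```

Output of the simulation step (20 phantoms, seed 0):

```
simulated 2196 slice traces over 20 phantoms
  oracle   : mean best IoU 0.820 (IQR 0.741-1.000), mean prompts to best 7.2
      HGG_like: 0.860 (n=269)
      LGG_like: 0.726 (n=114)
  suggested: mean best IoU 0.794 (IQR 0.726-0.849), mean prompts to best 6.8
  oracle mean best-so-far IoU by prompt count:
    0.581 0.637 0.672 0.702 0.722 0.738 0.757 0.778 0.820
```

Reading this: with a single prompt the best candidate reaches IoU 0.58 on
average and climbs monotonically to 0.82 by nine prompts; sharp
high-contrast (HGG-like) lesions segment substantially better than diffuse
low-contrast (LGG-like) ones; picking the model's most-confident candidate
instead of the objectively best one costs accuracy. Fusion and threshold
steps then report:

```
  mean Dice transverse: 0.911   mean Dice fused: 0.953  (p = 8.9e-05)
  Spearman rho = 0.402 (p = 2.8e-16)
  optimal area cutpoint 126 mm^2 (permutation-adjusted p = 0.000999)
  mean best IoU 0.744 below vs 0.854 above the cutpoint
```

i.e. majority-voting the three orientations removes orientation-specific
errors, and low accuracy concentrates on slices with small tumor
cross-sections, with a data-driven area threshold separating the regimes.

The same pipeline is scriptable via the `promptseg` CLI
(`generate`, `simulate`, `fuse`, `stats`, `report`, `all`), configured by a
YAML file; see `promptseg all --help`.

## Layout

- `src/promptseg/` — library: `phantoms` (synthetic volumes + mock
  predictor), `volume_prep` (normalization, slice extraction, ROI, NIfTI
  IO), `prompt_sim` (the interactive loop and study driver), `fusion3d`
  (stacking, majority vote, Dice), `metrics_stats` (summaries, Wilcoxon
  tests, maximally selected rank statistics), `config`/`cli` (experiment
  orchestration).
- `analysis/` — numbered narrative drivers over the library.
- `docs/methods.md` — models, parameters, numerical choices, limitations.
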