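# seedshape

Geometric models, average silhouettes and J-index quantification for seed
shape in the Cactaceae.

Seed outlines in cacti are poorly served by verbal categories ("lenticular",
"mussel-shaped", "hat-shaped"): the groups overlap and nothing is
quantifiable. `seedshape` instead describes a seed by its similarity to a
geometric model curve and quantifies the fit. It is aimed at seed
morphometricians and taxonomists working from flatbed/macro photographs of
seed lots, and at anyone needing a reproducible, scriptable version of this
workflow.

## The models and the statistic

Four curve families cover the main outline types:

* **Superellipse** `|x/a|^p + |y/b|^p = 1` — symmetric, squarish seeds
  (*Rebutia*; e.g. `p = 2.3, a = 1.5, b = 2` for *R. heliosa*);
* **paired semi-ellipses** with a flattened lower lobe — symmetric seeds
  with a straight hilum cup (*Echinopsis* type);
* **generalized Archimedean spiral** `r = t^(-1/3)` on an angle interval,
  closed into a polygon — asymmetric seeds (*Hylocereus* `t∈[0.3,5]`,
  *Pachycereus* `[0.5,5]`, *Ferocactus*/*Echinocactus* `[1,5]`,
  *Pereskia* `[1,6]`);
* **Opuntia curve** `r = 1/t + 1 − cos t`, `t∈[2,6]` — a cardioid plus a
  hyperbolic spiral.

Fit quality is the **J index**,

```
J = 100 · S / T
```

with S the area shared between seed silhouette and model and T the total
area covered by both after superimposing them for maximum similarity
(translation, rotation, uniform scale, optional mirror). J is 100 × the
Jaccard/IoU similarity; J > 90 is the conventional threshold for a good
adjustment. Alongside J, each seed gets the seven ImageJ-convention
descriptors — area A, perimeter P, length L, width W (moment-equivalent
ellipse axes), aspect ratio AR = L/W, circularity C = 4πA/P², roundness
R = 4A/(πL²) — and lots get mean/sd/min/max/CV tables, one-way ANOVA and
Scheffé letter groups. A lot's *average silhouette* (the region where an
occupancy fraction ≥ θ of the aligned masks coincide, default θ = 0.9) can
be extracted and used to close spiral-arc models.

Because real seed photographs of this kind are rarely archived, the package
includes a calibrated synthetic-photograph generator (`seedshape simulate` /
`seedshape.synth`) producing ground-truthed lots whose size, shape and
J-index statistics match published lot tables. See `docs/methods.md` for
the full model description and design choices.

## Worked example

Simulate a 20-seed *Hylocereus*-type lot, segment it, and score it against
its own source model:

```
$ seedshape simulate --model HYLO1 --n 20 --seed 42 --out lot
rendered 20 seeds to lot/image.png
$ seedshape segment --image lot/image.png --mm-per-px 0.01 --out seg
20 seeds segmented
$ seedshape jindex --seeds seg --model HYLO1 --mm-per-px 0.01 --out j
mean J = 91.3 over 20 seeds
```

`j/j_summary.csv` then reads (abridged):

```
mean,91.29
sd,2.25
min,86.71
max,95.98
cv,2.47
```

i.e. this lot fits its model like a published lot does: mean J ≈ 91 with
most seeds above the J > 90 adequacy line, and a J-index CV of ~2.5%.
`j/results.csv` holds the per-seed J values with the fitted transform
(dx, dy, rotation, scale, mirror) for each seed. Measuring the same masks
(`seedshape measure --masks seg --mm-per-px 0.01 --out meas`) gives the
per-seed descriptor table and a lot summary; for this lot the summary row
`mean` is A = 3.67 mm², L = 2.72 mm, W = 1.80 mm, AR = 1.52 — the model's
own aspect ratio, as expected for a lot drawn from it.

The same functions are importable:

```python
from seedshape import get_model, render_population, model_lot_spec, batch_j, segment_seeds

spec = model_lot_spec("HYLO1", mean_length_mm=2.69, cv_length_pct=4.4, rng_seed=42)
img, truth = render_population(spec)
masks = segment_seeds(img, scale=spec.mm_per_px)
results, summary = batch_j(masks, get_model("HYLO1"))
```

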