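# milt

Weakly supervised PD-L1 tumor proportion scoring from whole-slide images.

The tumor proportion score (TPS) — the percentage of viable tumor cells
with partial or complete membranous PD-L1 staining,

```
TPS = 100 × (PD-L1-positive tumor cells) / (viable tumor cells),
```

valid only when ≥ 100 viable tumor cells are present — guides
immunotherapy eligibility in lung cancer, but manual scoring varies
between pathologists. `milt` predicts a slide's TPS from the
slide-level label alone (no cell or pixel annotations) using multiple
instance learning, and ships the full agreement-statistics suite used
to validate such a scorer against pathologist truth.

The pipeline:

1. **Tissue detection & tiling** — Otsu thresholding on the greyscale
   slide, then non-overlapping 256×256 patches over tissue.
2. **Tumor-patch classification** — a compact CNN keeps tumor patches so
   the downstream model never fits stroma or immune infiltrate.
3. **MIL scoring** — per-patch feature vectors squashed into [0,1]
   (extractor CNN), gated-attention weights per patch, *distribution
   pooling* (the attention-weighted marginal distribution of each
   feature over bins of the unit interval, a smoothed histogram), and a
   fully connected head over the `num_features × n_bins` bag
   representation giving a distribution over 12 discrete TPS labels
   spanning 0–0.9. A bag's prediction is the expected TPS; a slide's
   TPS-AI is the mean over 100 resampled inference bags.
4. **Evaluation** — ICC(2,1) with 95% CI, Cohen's kappa at the clinical
   1% and 50% cutoffs, Bland–Altman limits of agreement, and one-vs-rest
   rates over the three expression subgroups (<1%, 1–49%, ≥50%).
5. **Heatmaps** — per-patch predictions (averaged over the bags each
   patch was sampled into) rendered as a thresholded overlay.

Because real PD-L1 cohorts are private, the package includes a synthetic
IHC slide generator with ground truth exact by construction: tissue
blobs, tumor cells with hematoxylin-blue nuclei, brown membranous rings
on a controlled fraction of them, and brown-stained distractor immune
cells that a correct scorer must ignore. Every stage of the pipeline is
validated against these slides.

All neural components are compact NumPy networks with hand-derived
gradients (checked against finite differences in the test suite); no
deep-learning framework is required.

## Worked example

```python
from milt.pipeline import desk_config, run_all

cfg = desk_config("milt_out", seed=0)      # 60 synthetic 1024×1024 slides
result = run_all(cfg, ("simulate", "tile", "train-classifier",
                       "extract-tumor", "train-mil", "predict", "evaluate"))
rep = result["report"]
print(f"n={rep.n} ICC={rep.icc:.3f} "
      f"CI=({rep.icc_ci_low:.3f}, {rep.icc_ci_high:.3f}) "
      f"kappa@50%={rep.kappa_at_50pct:.3f}")
```

On the 24 held-out slides of the seed-0 cohort this prints

```
n=24 ICC=0.971 CI=(0.893, 0.989) kappa@50%=0.913
```

meaning: the predicted TPS agrees with the generator's true TPS with an
intraclass correlation of 0.971 (absolute agreement, so a systematic
offset would lower it), and at the clinical 50% cutoff the predicted
high/low stratification agrees with truth at kappa 0.913 ("almost
perfect" on the conventional interpretation bands). The evaluation
stage also writes `milt_out/evaluation/agreement.json` and scatter /
Bland–Altman plots.

The same stages are available from the shell:

```
milt simulate --out milt_out --seed 0
milt tile --out milt_out
...
milt evaluate --out milt_out
```

with an optional YAML config (`--config`) that CLI flags override; every
run writes back its resolved configuration and a per-stage provenance
record (config hash, seed, input hashes).

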