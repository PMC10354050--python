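# kapurseg

Breast-lesion segmentation in T2-weighted DCE-MRI slices by
entropy-optimal multilevel thresholding, with the thresholds found by
the Gorilla Troops Optimizer (GTO) and by its rotation-based-learning
hybrid (GTORBL).

The package is aimed at medical-image-analysis researchers who want a
reproducible, fully scripted implementation of this segmentation family:
the optimizers, the preprocessing and postprocessing around them, the
evaluation metrics, and the statistical / multi-criteria apparatus used
to compare segmentation methods.  Because clinical DCE-MRI archives
cannot ship with a package, a phantom generator produces synthetic
breast slices with exact ground truth so every stage is testable
offline.

## Method

A gray image with levels 0..255 is partitioned by M thresholds
`th_1 < ... < th_M` into M+1 classes, `Class(j) = {th_j, ..., th_{j+1}-1}`
(a threshold starts the next class).  Kapur's criterion scores a
threshold set by the sum of the within-class Shannon entropies

    F(th_1..th_M) = Σ_j E_j,
    E_j = − Σ_{i∈Class(j)} (P_i/w_j) ln(P_i/w_j),   w_j = Σ_{i∈Class(j)} P_i,

where `P_i = f(i)/N` is the normalized histogram.  Maximizing F favours
homogeneous intensity classes; the brightest class(es) of the optimal
partition are the hyperintense lesion candidates.

F is maximized over the continuous box `[1, 255]^M` by

* **GTO** — a population metaheuristic with three exploration moves
  (random migration with probability p, move towards a random troop
  member, repulsion from a random candidate) and two exploitation moves
  (follow the silverback when the adaptive coefficient
  `C = (cos 2r + 1)(1 − t/T)` is at least W, competition around it
  otherwise), with greedy replacement;
* **GTORBL** — GTO plus rotation-based learning: each candidate `T_i`
  in the population's bounding box `[a_i, b_i]` is rotated about the box
  centre by a deflection angle `φ ~ 180° · N(1, 0.25)`,

      T*_i = (a_i+b_i)/2 + u_i cos φ − v_i sin φ,
      u_i = T_i − (a_i+b_i)/2,   v_i = sqrt((T_i−a_i)(b_i−T_i)),

  which at φ = 180° reduces exactly to opposition-based learning
  `a + b − T`.  The rotated population is merged with the original and
  the best N agents are kept, at initialization and, with
  generation-jumping rate `P_gj = 0.3`, after any GTO iteration.

The full pipeline is: anisotropic-diffusion denoising → max-filter
intensity-inhomogeneity correction → Kapur threshold search →
multilevel labelling → extraction of the top-k brightest classes →
hole filling → overlay on the original slice.  Defaults follow the
published setup: 30 agents, 100 iterations, β = 3, W = 0.8, p = 0.03.

The statistics module provides one-way ANOVA with Tukey's HSD, paired
Wilcoxon signed-rank tests with Bonferroni correction, and TOPSIS
ranking of a methods × criteria decision matrix (FPR as the sole cost
criterion).

## Worked example

```python
import numpy as np
import kapurseg as ks

pair = ks.generate_phantom(ks.PhantomSpec(), np.random.default_rng(4))
cfg = ks.PipelineConfig(optimizer="gtorbl", n_thresholds=2, top_k=1)
res = ks.segment_image(pair.image, cfg, np.random.default_rng(10_004))
rep = ks.evaluate_masks(res.lesion_mask, pair.gt_mask)
print(list(res.thresholds), round(res.entropy, 4))
print(round(rep.dsc, 4), round(rep.sensitivity, 4), round(rep.accuracy, 4))
```

prints

```
[42, 144] 9.2285
0.9476 1.0 0.9978
```

i.e. on this phantom the optimizer selects thresholds 42 and 144
(entropy 9.2285 nats over three classes: background, breast tissue,
hyperintense lesion); the extracted top class overlaps the known lesion
mask with Dice 0.948 at sensitivity 1.0 and pixel accuracy 0.998.

The same pipeline is available from the shell:

```sh
kapurseg simulate --seed 4 --out sim/
kapurseg segment --input sim/phantom.png --m 2 --seed 17 --out seg/
kapurseg evaluate --pred seg/mask.png --gt sim/gt.png
```

`kapurseg batch` repeats the stochastic segmentation (default 10
repeats per image, deterministic per-run child seeds) and writes a
per-run results table plus a mean (sd) summary per metric;
`kapurseg stats anova|topsis` reproduce the comparison tables.

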