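"""Batch orchestration: the repeated-runs experimental protocol.

The stochastic optimizers start from random populations, so each image
is segmented `repeats` times (default 10) and metrics are summarized as
mean (sd) per measure.  A master seed deterministically spawns an
independent child seed per (image, repeat) pair, so the whole table is
reproducible while repeats stay statistically independent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import RunConfig
from .metrics import METRIC_NAMES, evaluate_masks
from .segment import segment_image


def child_rng(master_seed: int, image_index: int, repeat_index: int) -> np.random.Generator:
    """Deterministic, independent stream for one (image, repeat) cell."""
    ss = np.random.SeedSequence([int(master_seed), int(image_index), int(repeat_index)])
    return np.random.default_rng(ss)


def run_batch(images, config: RunConfig, gt_masks=None,
              image_names=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment every image `repeats` times and tabulate the metrics.

    Parameters
    ----------
    images : sequence of 2-D uint8 arrays
    config : RunConfig
    gt_masks : optional sequence of boolean masks (None entries allowed);
        images without ground truth get NaN metric columns.
    image_names : optional labels for the result rows.

    Returns
    -------
    (rows, summary)
        `rows` has one record per image x repeat with thresholds,
        entropy and the eight metrics; `summary` holds mean and sd per
        metric over all scored rows.
    """
    gt_masks = gt_masks if gt_masks is not None else [None] * len(images)
    image_names = image_names or [f"image{i}" for i in range(len(images))]
    records = []
    for i, (img, gt, name) in enumerate(zip(images, gt_masks, image_names)):
        for r in range(config.repeats):
            rng = child_rng(config.seed, i, r)
            result = segment_image(img, config.pipeline, rng)
            rec = {"image": name, "repeat": r,
                   "thresholds": " ".join(map(str, result.thresholds)),
                   "entropy": result.entropy}
            if gt is not None:
                rec.update(evaluate_masks(result.lesion_mask, gt).as_dict())
            else:
                rec.update({m: np.nan for m in METRIC_NAMES})
            records.append(rec)
    rows = pd.DataFrame(records)
    summary = pd.DataFrame({
        "mean": rows[list(METRIC_NAMES)].mean(),
        "std": rows[list(METRIC_NAMES)].std(ddof=1),
    })
    return rows, summary
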