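"""End-to-end lesion segmentation pipeline.

Stages: anisotropic-diffusion denoising -> intensity-inhomogeneity
correction -> Kapur-entropy threshold search (GTO or GTORBL over the
continuous box [1, 255]^M, candidates rounded/sorted/deduplicated into
integer threshold sets) -> multilevel labelling -> extraction of the
hyperintense top classes -> hole filling -> colour overlay on the
original slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .gto import Bounds, GTOParams, OptimizerResult, gto_optimize
from .kapur import KapurObjective, compute_histogram, to_probabilities
from .preprocess import ADFParams, anisotropic_diffusion, correct_iih
from .rbl import RBLParams, gtorbl_optimize

OVERLAY_COLOR = (255, 64, 64)  # bright marker for localized lesions


@dataclass
class PipelineConfig:
    """Everything :func:`segment_image` needs besides the image itself.

    n_thresholds is the number M of thresholds (M + 1 intensity
    classes); top_k selects how many of the brightest classes form the
    lesion mask.
    """

    optimizer: str = "gtorbl"
    n_thresholds: int = 4
    top_k: int = 1
    gto_params: GTOParams = field(default_factory=GTOParams)
    rbl_params: RBLParams = field(default_factory=RBLParams)
    adf_params: ADFParams = field(default_factory=ADFParams)
    iih_window: int = 127
    iih_sigma: float = 224.0

    def __post_init__(self) -> None:
        if self.optimizer not in ("gto", "gtorbl"):
            raise ValueError("optimizer must be 'gto' or 'gtorbl'")
        if not 1 <= self.top_k <= self.n_thresholds:
            raise ValueError("need 1 <= top_k <= n_thresholds")


@dataclass
class SegmentationResult:
    thresholds: np.ndarray
    labels: np.ndarray
    lesion_mask: np.ndarray
    overlay: np.ndarray
    entropy: float
    optimizer_result: OptimizerResult


def decode_thresholds(position: np.ndarray, m: int) -> np.ndarray | None:
    """Real-valued agent -> strictly increasing integer threshold set.

    Round to nearest integer, clip into [1, 255], sort ascending and
    resolve duplicates by shifting upwards by 1; if the shift would
    overflow 255 the encoding is unrepairable and None is returned
    (the objective then scores it -inf).
    """
    th = np.sort(np.clip(np.rint(np.asarray(position)), 1, 255).astype(np.int64))
    for i in range(1, m):
        if th[i] <= th[i - 1]:
            th[i] = th[i - 1] + 1
    if th[-1] > 255:
        return None
    return th


def make_threshold_objective(p: np.ndarray, m: int):
    """Kapur-entropy objective over real-valued threshold encodings."""
    kapur = KapurObjective(p)

    def objective(x: np.ndarray) -> float:
        th = decode_thresholds(x, m)
        if th is None:
            return -np.inf
        return kapur(th)

    return objective


def apply_thresholds(image: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Label each pixel with the index of its intensity class.

    A threshold value starts the next class: intensity 99 under
    th=[100] is label 0, intensity 100 is label 1.
    """
    th = np.asarray(thresholds, dtype=np.int64)
    return np.digitize(np.asarray(image), th).astype(np.int64)


def extract_lesion_mask(labels: np.ndarray, n_thresholds: int, top_k: int = 1) -> np.ndarray:
    """Hyperintense-class mask: pixels in the `top_k` brightest classes."""
    if not 1 <= top_k <= n_thresholds:
        raise ValueError("need 1 <= top_k <= n_thresholds")
    return np.asarray(labels) >= (n_thresholds + 1 - top_k)


def fill_regions(mask: np.ndarray) -> np.ndarray:
    """Fill interior holes (4-connectivity); border-touching background stays."""
    return ndimage.binary_fill_holes(np.asarray(mask).astype(bool))


def localize(original: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """RGB overlay of the lesion mask on the original grayscale slice."""
    img = np.asarray(original)
    mask = np.asarray(mask).astype(bool)
    if img.shape != mask.shape:
        raise ValueError("image and mask must share a shape")
    overlay = np.stack([img] * 3, axis=-1).astype(np.uint8)
    overlay[mask] = OVERLAY_COLOR
    return overlay


def segment_image(image: np.ndarray, config: PipelineConfig | None = None,
                  rng: np.random.Generator | int | None = None) -> SegmentationResult:
    """Run the full pipeline on one 8-bit grayscale slice.

    Deterministic under a fixed seed and config.  Raises if the
    preprocessed histogram occupies fewer levels than the requested
    number of classes.
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng(rng)
    image = np.asarray(image)

    denoised = anisotropic_diffusion(image, config.adf_params)
    corrected = correct_iih(denoised, window=config.iih_window,
                            smooth_sigma=config.iih_sigma)

    hist = compute_histogram(corrected)
    m = config.n_thresholds
    if np.count_nonzero(hist) < m + 1:
        raise ValueError(
            f"histogram has fewer occupied levels than M+1 = {m + 1}")
    p = to_probabilities(hist)
    objective = make_threshold_objective(p, m)
    bounds = Bounds(np.full(m, 1.0), np.full(m, 255.0))
    if config.optimizer == "gtorbl":
        opt = gtorbl_optimize(objective, bounds, config.gto_params,
                              config.rbl_params, rng)
    else:
        opt = gto_optimize(objective, bounds, config.gto_params, rng)

    thresholds = decode_thresholds(opt.best_position, m)
    if thresholds is None:  # pragma: no cover - unreachable for m <= 251
        raise RuntimeError("optimizer returned an unrepairable threshold set")
    labels = apply_thresholds(corrected, thresholds)
    mask = fill_regions(extract_lesion_mask(labels, m, config.top_k))
    overlay = localize(image, mask)
    return SegmentationResult(thresholds=thresholds, labels=labels,
                              lesion_mask=mask, overlay=overlay,
                              entropy=opt.best_fitness, optimizer_result=opt)
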