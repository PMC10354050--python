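"""Synthetic breast-MRI phantoms with known ground truth.

The generator emulates T2-weighted fat-suppressed breast DCE-MRI slices
at desk scale: a large elliptical tissue region on dark background,
zero or more non-overlapping elliptical hyperintense lesions of varying
size, per-pixel Gaussian texture, a smooth multiplicative bias field
(linear ramp of random orientation, 1 +/- bias_amplitude) emulating
intensity inhomogeneity, and additive Gaussian acquisition noise
(Rician optional).  Every phantom ships with its exact lesion mask and
bias field, so segmentation accuracy can be scored against a known gold
standard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kapur import N_LEVELS


@dataclass
class PhantomSpec:
    """Generation parameters; defaults are the package's study conditions.

    Intensity means (background 30, tissue 120, lesion 220) with texture
    sd 10 give three well-separated tissue classes; the mild default
    bias (amplitude 0.2) and noise (sd 8) mirror the multiplicative
    inhomogeneity + additive noise corruption model of real slices.
    """

    size: tuple[int, int] = (256, 256)
    n_lesions: int = 2
    lesion_radius_range: tuple[float, float] = (6.0, 20.0)
    intensity_means: tuple[float, float, float] = (30.0, 120.0, 220.0)
    intensity_sd: float = 10.0
    bias_amplitude: float = 0.2
    noise_sd: float = 8.0
    noise_model: str = "gaussian"

    def __post_init__(self) -> None:
        bg, tissue, lesion = self.intensity_means
        if not bg < tissue < lesion:
            raise ValueError("need background < tissue < lesion means")
        if min(tissue - bg, lesion - tissue) < 3 * self.intensity_sd:
            import warnings
            warnings.warn("class means closer than 3 sd; classes may merge")
        if self.n_lesions < 0 or self.bias_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("counts/amplitudes must be non-negative")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")


@dataclass
class PhantomPair:
    image: np.ndarray      # uint8 slice as observed
    gt_mask: np.ndarray    # bool lesion ground truth
    bias_truth: np.ndarray # the multiplicative field actually applied


def _ellipse_mask(shape, cy, cx, ry, rx, angle=0.0):
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    y, x = yy - cy, xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = x * ca + y * sa
    v = -x * sa + y * ca
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _bias_field(shape, amplitude, rng):
    """Linear multiplicative ramp of random orientation, range 1 +/- amplitude."""
    if amplitude == 0:
        return np.ones(shape)
    theta = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    ramp = ((xx / (shape[1] - 1) - 0.5) * np.cos(theta)
            + (yy / (shape[0] - 1) - 0.5) * np.sin(theta))
    ramp = ramp / max(abs(ramp.min()), abs(ramp.max()), 1e-12)
    return 1.0 + amplitude * ramp


def generate_phantom(spec: PhantomSpec | None = None,
                     rng: np.random.Generator | int | None = None) -> PhantomPair:
    """One reproducible phantom slice plus ground truth.

    Lesions are placed fully inside the tissue ellipse, mutually
    disjoint with a 3-pixel separation margin; placement failure after
    bounded retries raises.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(rng)
    h, w = spec.size
    bg_mean, tissue_mean, lesion_mean = spec.intensity_means

    tissue = _ellipse_mask((h, w), h / 2, w / 2, 0.40 * h, 0.34 * w)
    ideal = np.full((h, w), bg_mean, dtype=np.float64)
    ideal[tissue] = tissue_mean

    gt = np.zeros((h, w), dtype=bool)
    placed: list[np.ndarray] = []
    r_lo, r_hi = spec.lesion_radius_range
    for _ in range(spec.n_lesions):
        for attempt in range(200):
            ry = rng.uniform(r_lo, r_hi)
            rx = rng.uniform(r_lo, r_hi)
            angle = rng.uniform(0, np.pi)
            cy = rng.uniform(h / 2 - 0.40 * h, h / 2 + 0.40 * h)
            cx = rng.uniform(w / 2 - 0.34 * w, w / 2 + 0.34 * w)
            lesion = _ellipse_mask((h, w), cy, cx, ry, rx, angle)
            margin = _ellipse_mask((h, w), cy, cx, ry + 3, rx + 3, angle)
            inside = not np.any(lesion & ~tissue)
            disjoint = all(not np.any(margin & prev) for prev in placed)
            if inside and disjoint and lesion.any():
                placed.append(lesion)
                gt |= lesion
                ideal[lesion] = lesion_mean
                break
        else:
            raise RuntimeError("could not place non-overlapping lesions")

    if spec.intensity_sd > 0:
        ideal = ideal + rng.normal(0.0, spec.intensity_sd, size=(h, w))
    bias = _bias_field((h, w), spec.bias_amplitude, rng)
    observed = ideal * bias
    if spec.noise_sd > 0:
        if spec.noise_model == "gaussian":
            observed = observed + rng.normal(0.0, spec.noise_sd, size=(h, w))
        else:  # Rician: magnitude of complex Gaussian corruption
            re = observed + rng.normal(0.0, spec.noise_sd, size=(h, w))
            im = rng.normal(0.0, spec.noise_sd, size=(h, w))
            observed = np.hypot(re, im)
    image = np.clip(np.rint(observed), 0, 255).astype(np.uint8)
    return PhantomPair(image=image, gt_mask=gt, bias_truth=bias)


def generate_histogram_fixture(n_modes: int, weights=None,
                               rng: np.random.Generator | int | None = None,
                               n_pixels: int = 65536) -> np.ndarray:
    """Mixture-of-discretized-Gaussians probability vector over 256 levels.

    Mode centres are drawn well apart (>= 30 levels); widths are uniform
    in [5, 12].  The mixture is quantized to integer counts over
    `n_pixels` (default 256 x 256) so the vector is realizable as an
    actual image histogram: far tails are exactly zero rather than
    carrying astronomically small mass, which would otherwise let the
    entropy criterion reward physically meaningless micro-classes.
    Drives threshold-search tests without any image.
    """
    if not 2 <= n_modes <= 6:
        raise ValueError("n_modes must be in [2, 6]")
    rng = np.random.default_rng(rng)
    if weights is None:
        weights = rng.dirichlet(np.full(n_modes, 5.0))
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (n_modes,) or np.any(weights < 0) or abs(weights.sum() - 1) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")

    # rejection-sample well-separated centres
    for _ in range(1000):
        centers = np.sort(rng.uniform(15, 240, size=n_modes))
        if n_modes == 1 or np.all(np.diff(centers) >= 30):
            break
    else:
        raise RuntimeError("could not separate mode centres")
    levels = np.arange(N_LEVELS, dtype=np.float64)
    p = np.zeros(N_LEVELS)
    for wgt, c in zip(weights, centers):
        sd = rng.uniform(5.0, 12.0)
        comp = np.exp(-0.5 * ((levels - c) / sd) ** 2)
        p += wgt * comp / comp.sum()
    counts = np.rint(p / p.sum() * n_pixels)
    return counts / counts.sum()
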