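"""Reading and writing images and result tables (PNG/TIFF via Pillow)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image


def read_gray(path: str | Path) -> np.ndarray:
    """Load a PNG/TIFF image as an 8-bit grayscale array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)


def read_mask(path: str | Path) -> np.ndarray:
    """Load a 0/255 binary mask image as a boolean array."""
    return read_gray(path) > 127


def write_gray(path: str | Path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="L").save(path)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    write_gray(path, np.asarray(mask, dtype=bool).astype(np.uint8) * 255)


def write_rgb(path: str | Path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)


def write_trace_csv(path: str | Path, trace) -> None:
    """Convergence trace as CSV with columns evals,best_fitness."""
    with open(path, "w") as fh:
        fh.write("evals,best_fitness\n")
        for evals, best in trace:
            fh.write(f"{int(evals)},{best!r}\n")


def write_histogram_csv(path: str | Path, counts: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("level,count\n")
        for level, count in enumerate(np.asarray(counts)):
            fh.write(f"{level},{int(count)}\n")
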