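"""Image reading/writing and run manifests.

Images are exchanged with disk as 8-bit (or, on input, 16-bit) PNG/PPM
rasters and processed in memory as float intensities in [0, 1].  Export
clips to [0, 1] and quantises with round-half-up so golden-image tests are
stable.  A :class:`RunManifest` records every parameter of a CLI run as a
flat key-value text file that round-trips losslessly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np

from .tensor import as_image

__all__ = ["load_image", "save_image", "RunManifest"]


def load_image(path) -> np.ndarray:
    """Read a PNG or PPM/PGM image as float ``(H, W, C)`` in [0, 1].

    8-bit values map 255 -> 1.0 and 16-bit 65535 -> 1.0; an alpha channel,
    if present, is dropped.  Greyscale stays single-channel.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # imageio raises various backend errors
        raise ValueError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(raw)
    if arr.dtype == np.uint8:
        values = arr / 255.0
    elif arr.dtype == np.uint16:
        values = arr / 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        values = arr.astype(float)
    else:
        raise ValueError(f"{path}: unsupported sample type {arr.dtype}")
    if values.ndim == 3 and values.shape[2] in (2, 4):  # LA / RGBA
        values = values[:, :, :-1]
        if values.shape[2] == 1:
            values = values[:, :, 0]
    return as_image(values)


def save_image(image: np.ndarray, path) -> None:
    """Clip to [0, 1], quantise to 8 bits (round-half-up) and write.

    The format follows the extension: .png, or binary PPM/PGM (.ppm/.pgm).
    Single-channel images are written as greyscale.
    """
    u = as_image(image)
    q = np.floor(np.clip(u, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)
    if q.shape[2] == 1:
        q = q[:, :, 0]
    path = Path(path)
    try:
        iio.imwrite(path, q)
    except Exception as exc:
        raise ValueError(f"cannot write image {path}: {exc}") from exc


@dataclass(frozen=True)
class RunManifest:
    """Flat, losslessly serialisable record of one processing run."""

    input: str
    output: str
    mode: str
    solver: str
    a: Optional[float] = None
    gamma: Optional[float] = None
    K: Optional[float] = None
    dt: float = 0.2
    iterations: int = 1000
    tol: Optional[float] = None
    seed: int = 0
    timestamp: str = ""

    def to_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if value is None:
                continue
            lines.append(f"{f.name} = {value!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunManifest":
        import ast

        known = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"manifest line {lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in known:
                raise ValueError(f"manifest line {lineno}: unknown key {key!r}")
            kwargs[key] = ast.literal_eval(value.strip())
        return cls(**kwargs)

    def save(self, path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls.from_text(Path(path).read_text())
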