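"""Seeded synthetic test images with known structure.

Every solver and target constructor in this package is exercised on images
from this generator, so the full test suite runs without any external data.
Available kinds:

``constant``        flat image at a given amplitude;
``ramp``            linear ramp along x between two levels;
``step_edge``       two-level vertical edge (the halo-measurement fixture);
``disk``            filled disk on a flat background;
``red_green_chart`` smooth patch chart whose patches differ mainly along
                    the red-green direction (1, -1, 0), the worst case for
                    protan observers and hence the daltonisation fixture;
``smooth_random``   seeded low-frequency colour field in [0.1, 0.9], made
                    by separable binomial smoothing of uniform noise.
"""

from __future__ import annotations

import numpy as np

from .tensor import as_image

__all__ = ["FIXTURE_KINDS", "generate", "halo_metric"]

FIXTURE_KINDS = (
    "constant",
    "ramp",
    "step_edge",
    "disk",
    "red_green_chart",
    "smooth_random",
)

_BINOMIAL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def _smooth_axis(arr: np.ndarray, axis: int, passes: int) -> np.ndarray:
    """Repeated 5-tap binomial smoothing along one axis, edge-replicated."""
    out = arr
    for _ in range(passes):
        padded = np.pad(
            out, [(2, 2) if ax == axis else (0, 0) for ax in range(out.ndim)], mode="edge"
        )
        acc = np.zeros_like(out)
        for k, wk in enumerate(_BINOMIAL):
            sl = [slice(None)] * out.ndim
            sl[axis] = slice(k, k + out.shape[axis])
            acc += wk * padded[tuple(sl)]
        out = acc
    return out


def generate(
    kind: str,
    height: int = 64,
    width: int = 64,
    channels: int = 3,
    seed: int = 0,
    amplitude: float = 0.5,
    levels: tuple[float, float] = (0.2, 0.8),
    edge_position: int | None = None,
    patch: int = 16,
    smooth_passes: int = 2,
) -> np.ndarray:
    """Generate a deterministic ``(height, width, channels)`` fixture.

    ``amplitude`` is the constant level (``constant``) or the chromatic
    patch offset (``red_green_chart``); ``levels`` are the low/high values
    of ``ramp``, ``step_edge`` and ``disk``; ``edge_position`` the step
    column (defaults to the middle); ``patch`` the chart patch size in
    pixels and ``smooth_passes`` the binomial smoothing applied to the
    chart so its edges span a few pixels.  The same arguments and seed
    always return an identical array.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    if height < 1 or width < 1:
        raise ValueError("fixture dimensions must be positive")
    if channels not in (1, 3):
        raise ValueError("fixtures support 1 or 3 channels")
    lo, hi = levels

    if kind == "constant":
        u = np.full((height, width, channels), float(amplitude))
    elif kind == "ramp":
        row = np.linspace(lo, hi, width)
        u = np.broadcast_to(row[None, :, None], (height, width, channels)).copy()
    elif kind == "step_edge":
        c = width // 2 if edge_position is None else int(edge_position)
        if not 0 < c < width:
            raise ValueError(f"edge_position must lie inside the image, got {c}")
        row = np.where(np.arange(width) < c, lo, hi)
        u = np.broadcast_to(row[None, :, None], (height, width, channels)).copy()
    elif kind == "disk":
        yy, xx = np.mgrid[0:height, 0:width]
        r = min(height, width) / 4.0
        inside = (yy - (height - 1) / 2.0) ** 2 + (xx - (width - 1) / 2.0) ** 2 <= r**2
        u = np.where(inside[..., None], hi, lo) * np.ones((1, 1, channels))
    elif kind == "red_green_chart":
        if channels != 3:
            raise ValueError("red_green_chart is a colour fixture (channels=3)")
        yy, xx = np.mgrid[0:height, 0:width]
        checker = ((yy // patch) + (xx // patch)) % 2
        offset = float(amplitude) * (2.0 * checker - 1.0) / np.sqrt(2.0)
        u = 0.5 + offset[..., None] * np.array([1.0, -1.0, 0.0])
        u = _smooth_axis(_smooth_axis(u, 0, smooth_passes), 1, smooth_passes)
    else:  # smooth_random
        rng = np.random.default_rng(seed)
        u = rng.uniform(size=(height, width, channels))
        u = _smooth_axis(_smooth_axis(u, 0, 4), 1, 4)
        span = u.max() - u.min()
        if span > 0:
            u = 0.1 + 0.8 * (u - u.min()) / span
        else:
            u = np.full_like(u, 0.5)

    return as_image(np.clip(u, 0.0, 1.0))


def halo_metric(result: np.ndarray, source: np.ndarray) -> float:
    """Worst per-channel overshoot of ``result`` beyond the value range of
    ``source`` — 0 means no halo.

    Unconstrained Poisson reintegration of amplified gradients drives
    pixel values past the original range near strong edges (the visible
    halo/ringing); this measures that excursion directly.
    """
    r = as_image(result)
    s = as_image(source)
    if r.shape != s.shape:
        raise ValueError(f"shape mismatch: {r.shape} vs {s.shape}")
    over = np.max(r.reshape(-1, r.shape[2]), axis=0) - np.max(
        s.reshape(-1, s.shape[2]), axis=0
    )
    under = np.min(s.reshape(-1, s.shape[2]), axis=0) - np.min(
        r.reshape(-1, r.shape[2]), axis=0
    )
    return float(max(np.max(over), np.max(under), 0.0))
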