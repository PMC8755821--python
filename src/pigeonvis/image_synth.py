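"""Stimulus generation: sine gratings, 1/f naturalistic surrogates, and
grid scrambling.

The study's stimuli were grayscale photographs of human and pigeon faces,
their grid-scrambled controls, and sine gratings.  The photographs cannot
be redistributed, so the naturalistic surrogate here is a random-phase
field with a power-law amplitude spectrum (``1/f`` by default) — it shares
the two properties the spectral analysis relies on: spectral energy
concentrated at low spatial frequencies, and high low-frequency similarity
between exemplars.

Scrambling divides the image into a grid of tiles (15 columns x 32 rows by
default), permutes tile positions uniformly at random, and re-orients each
tile independently.  Every operation is a permutation of pixels, so the
intensity multiset — and hence the mean luminance — is conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import imageio.v3 as iio
import numpy as np

__all__ = [
    "StimulusImage",
    "make_sine_grating",
    "make_naturalistic",
    "scramble_image",
    "write_png",
    "read_png",
]


class ImageError(ValueError):
    """Raised for degenerate stimulus parameters."""


@dataclass(frozen=True)
class StimulusImage:
    """A grayscale stimulus with intensities in [0, 1] plus provenance."""

    pixels: np.ndarray
    label: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ImageError("pixels must be a 2-D grayscale array")
        if px.size and (px.min() < -1e-12 or px.max() > 1 + 1e-12):
            raise ImageError("intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def make_sine_grating(
    frequency: float,
    size: int = 512,
    orientation: Literal["horizontal", "vertical"] = "horizontal",
) -> StimulusImage:
    """Sine grating at ``frequency`` cycles per image width.

    ``orientation`` names the axis along which intensity varies:
    ``"horizontal"`` varies along x (vertical bars).  Frequency must be at
    least 1 cycle/image and below the Nyquist limit (``size / 2``).
    """
    if not (1 <= frequency < size / 2):
        raise ImageError("frequency must satisfy 1 <= f < size/2 (Nyquist)")
    x = np.arange(size) / size
    wave = 0.5 + 0.5 * np.sin(2 * np.pi * frequency * x)
    if orientation == "horizontal":
        px = np.tile(wave, (size, 1))
    elif orientation == "vertical":
        px = np.tile(wave[:, None], (1, size))
    else:
        raise ImageError(f"unknown orientation {orientation!r}")
    return StimulusImage(
        px,
        label="grating",
        provenance={"kind": "grating", "frequency": frequency,
                    "orientation": orientation},
    )


def make_naturalistic(
    seed: int, size: int = 512, spectral_exponent: float = 2.0
) -> StimulusImage:
    """Random-phase surrogate with amplitude spectrum ~ 1/f^(exponent/2).

    With the default exponent of 2 the power spectrum falls as 1/f^2, the
    canonical statistic of natural scenes, so almost all spectral energy
    sits at low spatial frequencies.  ``spectral_exponent=0`` gives white
    noise.  Deterministic in ``seed``; output rescaled to [0, 1].
    """
    if size < 32:
        raise ImageError("size must be >= 32")
    rng = np.random.default_rng(seed)
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = 1.0  # DC handled separately
    amplitude = f ** (-spectral_exponent / 2.0)
    amplitude[0, 0] = 0.0
    phase = rng.uniform(0, 2 * np.pi, size=(size, size))
    spectrum = amplitude * np.exp(1j * phase)
    img = np.real(np.fft.ifft2(spectrum))
    lo, hi = img.min(), img.max()
    if hi - lo < 1e-15:
        px = np.full_like(img, 0.5)
    else:
        px = (img - lo) / (hi - lo)
    return StimulusImage(
        px,
        label="naturalistic",
        provenance={"kind": "naturalistic", "seed": int(seed),
                    "spectral_exponent": spectral_exponent},
    )


def _orient_tile(tile: np.ndarray, op: int, square: bool) -> np.ndarray:
    """Apply one of the tile re-orientations; all are pixel permutations.

    Square tiles use the 8 dihedral operations (4 rotations x optional
    flip); non-square tiles are restricted to the 4 that preserve shape
    (identity, 180 deg, horizontal flip, vertical flip).
    """
    if square:
        rot, flip = op % 4, op // 4
        out = np.rot90(tile, rot)
        return np.fliplr(out) if flip else out
    return [tile, tile[::-1, ::-1], tile[:, ::-1], tile[::-1, :]][op]


def scramble_image(
    img: StimulusImage,
    grid: tuple[int, int] = (15, 32),
    seed: int = 0,
    allow_flips: bool = True,
    permutation: np.ndarray | None = None,
    orientations: np.ndarray | None = None,
) -> StimulusImage:
    """Grid-scramble ``img``: permute tile positions and re-orient tiles.

    ``grid`` is (columns, rows); the image dimensions must be divisible by
    the grid.  Each of the ``cols * rows`` tiles is moved to a uniformly
    random position and independently re-oriented.  Square tiles draw from
    rotations {0, 90, 180, 270} degrees (plus flips when ``allow_flips``);
    non-square tiles from {0, 180} degrees plus flips, which keep the tile
    shape.  The pixel multiset, and therefore the mean luminance, is
    conserved exactly.

    ``permutation`` and ``orientations`` override the seeded draws with an
    explicit tile permutation / per-tile orientation code (0 = unchanged),
    e.g. to build a deterministic control.
    """
    cols, rows = grid
    h, w = img.pixels.shape
    if cols < 1 or rows < 1 or cols > w or rows > h:
        raise ImageError("grid larger than image")
    if w % cols or h % rows:
        raise ImageError(
            f"image {w}x{h} not divisible by grid {cols}x{rows}; crop or pad first"
        )
    tw, th = w // cols, h // rows
    square = tw == th
    n_ops = (8 if allow_flips else 4) if square else (4 if allow_flips else 2)

    rng = np.random.default_rng(seed)
    n_tiles = cols * rows
    perm = rng.permutation(n_tiles) if permutation is None else np.asarray(permutation)
    ops = (
        rng.integers(0, n_ops, size=n_tiles)
        if orientations is None
        else np.asarray(orientations)
    )
    if sorted(perm) != list(range(n_tiles)) or len(ops) != n_tiles:
        raise ImageError("permutation/orientations must cover every tile")
    if ops.min() < 0 or ops.max() >= n_ops:
        raise ImageError(f"orientation codes must lie in [0, {n_ops})")

    tiles = [
        img.pixels[r * th:(r + 1) * th, c * tw:(c + 1) * tw]
        for r in range(rows)
        for c in range(cols)
    ]
    out = np.empty_like(img.pixels)
    for dest, (src, op) in enumerate(zip(perm, ops)):
        r, c = divmod(dest, cols)
        out[r * th:(r + 1) * th, c * tw:(c + 1) * tw] = _orient_tile(
            tiles[src], int(op), square
        )
    return StimulusImage(
        out,
        label=f"scrambled:{img.label}",
        provenance={
            "kind": "scrambled",
            "parent": img.provenance,
            "grid": [cols, rows],
            "seed": int(seed),
            "allow_flips": allow_flips,
        },
    )


def write_png(img: StimulusImage, path) -> None:
    """Write as 8-bit grayscale PNG."""
    iio.imwrite(path, np.round(img.pixels * 255).astype(np.uint8))


def read_png(path, label: str = "") -> StimulusImage:
    """Read a PNG as a [0, 1] grayscale stimulus (RGB averaged if needed)."""
    px = np.asarray(iio.imread(path), dtype=float)
    if px.ndim == 3:
        px = px[..., :3].mean(axis=-1)
    return StimulusImage(px / 255.0, label=label, provenance={"kind": "file",
                                                              "path": str(path)})
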