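"""Rendering fixed windows as 320 x 240 RGB spectrogram images.

Each fixed window becomes a borderless 320 x 240 x 3 image — 230,400
values — which is the input of the convolutional branch.  The rendering is
a dB-scaled mel spectrogram (128 bands, 80 dB dynamic range) mapped
through the perceptual "viridis" colormap and bilinearly resized; the
exact parameterization is encapsulated here so it can be swapped without
touching the models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from PIL import Image

from . import _dsp
from .audio_io import AudioSegment

WIDTH = 320
HEIGHT = 240
N_MELS = 128
TOP_DB = 80.0
COLORMAP = "viridis"


@dataclass
class Spectrogram:
    """An 8-bit RGB image of a window's time-frequency energy.

    `pixels` has shape (240, 320, 3) with values in [0, 255]; row 0 is the
    top of the image, i.e. the highest frequency.
    """

    pixels: np.ndarray
    source: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.shape != (HEIGHT, WIDTH, 3):
            raise ValueError(
                f"spectrogram image must be {HEIGHT}x{WIDTH}x3, got {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)

    @property
    def n_values(self) -> int:
        return self.pixels.size  # 230,400 at the contract resolution


def render_spectrogram(segment: AudioSegment, n_mels: int = N_MELS) -> Spectrogram:
    """Render one fixed window as a borderless RGB spectrogram image.

    Deterministic: identical segments produce identical pixel arrays.  The
    dB floor (`TOP_DB` below the maximum) makes silence well-defined: a
    silent window renders as a spatially constant image.
    """
    mel = _dsp.mel_spectrogram(segment.samples, segment.rate, n_mels)
    db = _dsp.power_to_db(mel, top_db=TOP_DB)
    span = db.max() - db.min()
    norm = (db - db.min()) / span if span > 0 else np.zeros_like(db)
    rgba = colormaps[COLORMAP](norm)  # (n_mels, n_frames, 4) floats
    rgb = (rgba[..., :3] * 255.0).round().astype(np.uint8)
    rgb = rgb[::-1]  # row 0 = highest frequency (image convention)
    img = Image.fromarray(rgb, mode="RGB").resize((WIDTH, HEIGHT), Image.BILINEAR)
    return Spectrogram(pixels=np.asarray(img), source=segment.source)


def write_png(spec: Spectrogram, path) -> None:
    """Write the image as an 8-bit RGB PNG (lossless)."""
    try:
        Image.fromarray(spec.pixels, mode="RGB").save(path, format="PNG")
    except OSError as exc:
        raise IOError(f"cannot write PNG to {path}: {exc}") from exc


def read_png(path) -> Spectrogram:
    """Read a PNG written by :func:`write_png`; round-trips bit-exactly."""
    try:
        img = Image.open(path).convert("RGB")
    except OSError as exc:
        raise IOError(f"cannot read PNG from {path}: {exc}") from exc
    return Spectrogram(pixels=np.asarray(img), source=str(path))
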