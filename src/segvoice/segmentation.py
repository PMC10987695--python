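"""Fixed-duration windowing of recordings and streams.

Every recording is forced to a uniform window (default 1.5 s) before
feature extraction: longer inputs are trimmed symmetrically around their
center, shorter ones are symmetrically padded with silence.  Longer audio
streams are cut into potentially overlapping windows at a fixed stride so a
classifier can score emotion continuously along the stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio_io import DEFAULT_RATE, AudioSegment

DEFAULT_DURATION = 1.5


@dataclass(frozen=True)
class WindowSpec:
    """Window geometry: duration and stride in seconds at a given rate.

    stride defaults to the duration (non-overlapping windows); stride below
    the duration overlaps windows, stride above it leaves gaps.
    """

    duration: float = DEFAULT_DURATION
    stride: float | None = None
    rate: int = DEFAULT_RATE

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("window duration must be positive")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.stride is None:
            object.__setattr__(self, "stride", self.duration)
        if self.stride <= 0:
            raise ValueError("stride must be positive")

    @property
    def target_len(self) -> int:
        return int(round(self.duration * self.rate))

    @property
    def stride_len(self) -> int:
        return int(round(self.stride * self.rate))


def fix_window(segment: AudioSegment, spec: WindowSpec | None = None) -> AudioSegment:
    """Force a segment to exactly the window length by symmetric trim/pad.

    Excess samples are removed equally from both ends (the odd one from the
    end); missing samples are added as zeros equally at both ends (the odd
    one at the start).  An input already at the target length is returned
    unchanged.
    """
    spec = spec or WindowSpec(rate=segment.rate)
    x = segment.samples
    n, target = x.size, spec.target_len
    if n == 0:
        raise ValueError("cannot fix an empty segment")
    if n == target:
        return segment
    if n > target:
        excess = n - target
        start = excess // 2  # floor at the start, ceil at the end
        out = x[start : start + target]
    else:
        deficit = target - n
        pre = (deficit + 1) // 2  # extra zero goes at the start
        out = np.concatenate([np.zeros(pre), x, np.zeros(deficit - pre)])
    return AudioSegment(
        samples=out,
        rate=segment.rate,
        label=segment.label,
        source=segment.source,
        offset=segment.offset,
    )


def stream_windows(segment: AudioSegment, spec: WindowSpec | None = None) -> list[AudioSegment]:
    """Cut a stream into fixed windows at offsets 0, stride, 2*stride, ...

    Every offset strictly inside the stream yields a window; a tail shorter
    than the window is symmetrically zero-padded rather than dropped, so
    any non-empty stream yields at least one window.  Each output carries
    its source offset in seconds.
    """
    spec = spec or WindowSpec(rate=segment.rate)
    x = segment.samples
    n, target, stride = x.size, spec.target_len, spec.stride_len
    windows: list[AudioSegment] = []
    start = 0
    while start == 0 or start < n:
        chunk = x[start : start + target]
        if chunk.size == 0:
            break
        win = AudioSegment(
            samples=chunk,
            rate=segment.rate,
            label=segment.label,
            source=segment.source,
            offset=segment.offset + start / segment.rate,
        )
        windows.append(fix_window(win, spec))
        start += stride
    return windows
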