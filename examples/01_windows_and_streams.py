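"""Fixed-window segmentation: trim/pad one recording, window a stream.

Generates a synthetic 'anger' utterance, shows the symmetric trim/pad
rule, then cuts a 4 s stream into overlapping 1.5 s windows.
"""

import numpy as np

import segvoice as sv
from segvoice.segmentation import WindowSpec, fix_window, stream_windows

seg = sv.synth_segment("anger", sv.SynthConfig(seed=7), 0)
print(f"generated segment: {len(seg)} samples at {seg.rate} Hz = {seg.duration} s")

short = sv.AudioSegment(samples=seg.samples[:16_000], rate=16_000)
fixed = fix_window(short, WindowSpec())
pad = np.sum(fixed.samples[:5_000] == 0)
print(f"a 1.0 s input is padded back to {len(fixed)} samples "
      f"({pad} leading zeros: silence split evenly between the ends)")

stream = sv.AudioSegment(samples=np.tile(seg.samples, 3)[:64_000], rate=16_000)
windows = stream_windows(stream, WindowSpec(duration=1.5, stride=0.5))
print(f"a {stream.duration:.1f} s stream at stride 0.5 s yields {len(windows)} windows "
      f"at offsets {[w.offset for w in windows]}")
print("each window is classification-ready: same length, zero-padded tail included")
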