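"""Render a window as the 320x240 RGB spectrogram the CNN consumes.

Writes a PNG and verifies the lossless round-trip.
"""

import numpy as np

import segvoice as sv

seg = sv.synth_segment("joy", sv.SynthConfig(seed=1), 0)
img = sv.render_spectrogram(seg)
print(f"image shape {img.pixels.shape} = {img.n_values} data points")

sv.write_png(img, "joy_spectrogram.png")
back = sv.read_png("joy_spectrogram.png")
print("PNG round-trip bit-exact:", bool(np.array_equal(back.pixels, img.pixels)))
print("brightest rows sit where the harmonic stack concentrates energy; "
      "row 0 is the highest frequency")
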