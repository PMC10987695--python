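"""The acoustic feature battery: 17 feature families, 14,244 entries.

Every fixed 1.5 s window at 16 kHz is described by an ordered, named
feature vector.  The battery deliberately over-generates — the intent is
to hand the classifiers as much information as possible and let them
select what matters — so no feature selection happens here.

Block ledger at the default window (24,000 samples, n_fft 2,048, hop 512,
hence 47 centered frames and 1,025 spectral bins):

==============  =====  =============================================
block           size   contents
==============  =====  =============================================
raw_variance    1,200  variance of the raw signal in 20-sample windows
hpss_variance   2,400  same, for harmonic then percussive components
flatness           47  per-frame spectral flatness
centroid           47  per-frame spectral centroid (Hz)
f0                 47  per-frame fundamental frequency (0 = unvoiced)
voiced             94  per-frame voiced flag, then voiced probability
rolloff            94  per-frame rolloff at 85%, then at 15%
bandwidth          47  per-frame spectral bandwidth (Hz)
zcr                47  per-frame zero-crossing rate
rms                47  per-frame root-mean-square amplitude
contrast          188  4 spectral-contrast bands x 47 frames
tonnetz           282  6 tonal-centroid dims x 47 frames
chroma            564  12 pitch classes x 47 frames
pitch_track     2,050  per-bin variance then mean of pitch candidates
pitch_mag       2,050  per-bin variance then mean of candidate magnitudes
magnitude       2,050  per-bin variance then mean of |STFT|
phase           2,050  per-bin variance then mean of the phase angle
mfcc              940  20 mel-cepstral coefficients x 47 frames
==============  =====  =============================================

Total: 14,244.  Matrix blocks are flattened coefficient-major (row-major).
All variances are population variances; NaN never leaves this module.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _dsp
from .audio_io import AudioSegment, DatasetManifest, load_audio
from .segmentation import WindowSpec, fix_window

RAW_VAR_WIN = 20  # samples per raw-signal variance window (24,000 / 20 = 1,200)
ROLLOFF_PERCENTS = (0.85, 0.15)
N_CONTRAST_BANDS = 4  # 3 octave sub-bands + residual top band
N_MFCC = 20

BLOCK_ORDER = (
    "raw_variance", "hpss_variance", "flatness", "centroid", "f0", "voiced",
    "rolloff", "bandwidth", "zcr", "rms", "contrast", "tonnetz", "chroma",
    "pitch_track", "pitch_mag", "magnitude", "phase", "mfcc",
)


@dataclass(frozen=True)
class FrameSpec:
    """Short-time analysis geometry shared by all framewise features."""

    rate: int = 16_000
    n_fft: int = _dsp.N_FFT
    hop: int = _dsp.HOP

    @property
    def n_bins(self) -> int:
        return self.n_fft // 2 + 1

    def n_frames(self, n_samples: int) -> int:
        return _dsp.n_frames_for(n_samples, self.hop)


def expected_block_sizes(n_samples: int, spec: FrameSpec | None = None) -> dict[str, int]:
    """Block sizes implied by the battery's formulas for a window length.

    At the default window this reproduces the ledger above (total 14,244);
    at other durations the same formulas scale the blocks consistently.
    """
    spec = spec or FrameSpec()
    if n_samples % RAW_VAR_WIN != 0:
        raise ValueError(
            f"window of {n_samples} samples is not divisible by the "
            f"{RAW_VAR_WIN}-sample variance window"
        )
    nf = spec.n_frames(n_samples)
    nb = spec.n_bins
    return {
        "raw_variance": n_samples // RAW_VAR_WIN,
        "hpss_variance": 2 * (n_samples // RAW_VAR_WIN),
        "flatness": nf,
        "centroid": nf,
        "f0": nf,
        "voiced": 2 * nf,
        "rolloff": 2 * nf,
        "bandwidth": nf,
        "zcr": nf,
        "rms": nf,
        "contrast": N_CONTRAST_BANDS * nf,
        "tonnetz": 6 * nf,
        "chroma": 12 * nf,
        "pitch_track": 2 * nb,
        "pitch_mag": 2 * nb,
        "magnitude": 2 * nb,
        "phase": 2 * nb,
        "mfcc": N_MFCC * nf,
    }


@dataclass
class FeatureVector:
    """Ordered named blocks of real-valued features."""

    blocks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, values in self.blocks.items():
            arr = np.asarray(values, dtype=np.float64).ravel()
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"block {name!r} contains non-finite values")
            self.blocks[name] = arr

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.blocks[name] for name in self.blocks])

    @property
    def names(self) -> list[str]:
        return [f"{blk}.{i}" for blk, arr in self.blocks.items() for i in range(arr.size)]

    def __len__(self) -> int:
        return sum(arr.size for arr in self.blocks.values())


# --- individual feature families -------------------------------------------


def windowed_variance(samples: np.ndarray, win: int = RAW_VAR_WIN) -> np.ndarray:
    """Population variance of consecutive non-overlapping `win`-sample windows."""
    samples = np.asarray(samples, dtype=np.float64)
    if samples.size % win != 0:
        raise ValueError(
            f"signal length {samples.size} is not divisible by window {win}"
        )
    return samples.reshape(-1, win).var(axis=1)


def hpss_variance(segment: AudioSegment, win: int = RAW_VAR_WIN) -> np.ndarray:
    """Windowed variance of the harmonic then the percussive component."""
    harmonic, percussive = _dsp.hpss(segment.samples)
    return np.concatenate([windowed_variance(harmonic, win), windowed_variance(percussive, win)])


def _spectral_contrast(S: np.ndarray, freqs: np.ndarray, quantile: float = 0.2) -> np.ndarray:
    """Per-band peak-to-valley contrast in dB, shape (N_CONTRAST_BANDS, n_frames).

    Bands are octave-spaced from 200 Hz (0-200, 200-400, 400-800) with the
    remaining spectrum as the final band.  Contrast is the dB difference
    between the mean of the top and bottom `quantile` of bin energies.
    """
    edges = [0.0, 200.0, 400.0, 800.0, freqs[-1] + 1.0]
    power = S**2
    out = np.zeros((len(edges) - 1, S.shape[1]))
    for b in range(len(edges) - 1):
        rows = (freqs >= edges[b]) & (freqs < edges[b + 1])
        band = power[rows]
        if band.shape[0] == 0:
            continue
        k = max(1, int(round(quantile * band.shape[0])))
        band_sorted = np.sort(band, axis=0)
        valley = band_sorted[:k].mean(axis=0)
        peak = band_sorted[-k:].mean(axis=0)
        out[b] = 10.0 * (np.log10(np.maximum(peak, 1e-10)) - np.log10(np.maximum(valley, 1e-10)))
    return out


def framewise_scalars(segment: AudioSegment, spec: FrameSpec | None = None) -> dict[str, np.ndarray]:
    """Per-frame scalar descriptors: flatness, centroid, rolloff, bandwidth, zcr, rms.

    Rolloff is computed at both an upper (0.85) and a lower (0.15) energy
    percentage and concatenated high-first, giving two curves per window.
    """
    spec = spec or FrameSpec(rate=segment.rate)
    x = segment.samples
    S, _ = _dsp.magphase(_dsp.stft(x, spec.n_fft, spec.hop))
    power = S**2
    freqs = _dsp.fft_frequencies(spec.rate, spec.n_fft)
    total = power.sum(axis=0)
    safe_total = np.maximum(total, 1e-10)

    flatness = np.exp(np.mean(np.log(np.maximum(power, 1e-10)), axis=0)) / np.maximum(
        power.mean(axis=0), 1e-10
    )
    flatness = np.where(total > 1e-10, flatness, 1.0)  # silence: flat by convention

    centroid = (freqs[:, None] * power).sum(axis=0) / safe_total
    centroid = np.where(total > 1e-10, centroid, 0.0)

    cum = np.cumsum(power, axis=0)
    rolloffs = []
    for pct in ROLLOFF_PERCENTS:
        idx = np.argmax(cum >= pct * safe_total, axis=0)
        rolloffs.append(np.where(total > 1e-10, freqs[idx], 0.0))
    rolloff = np.concatenate(rolloffs)

    bandwidth = np.sqrt(
        ((freqs[:, None] - centroid[None, :]) ** 2 * power).sum(axis=0) / safe_total
    )
    bandwidth = np.where(total > 1e-10, bandwidth, 0.0)

    frames = _dsp.frame_signal(x, spec.n_fft, spec.hop)
    signs = np.signbit(frames)
    zcr = np.mean(signs[:, 1:] != signs[:, :-1], axis=1)
    rms = np.sqrt(np.mean(frames**2, axis=1))

    return {
        "flatness": flatness,
        "centroid": centroid,
        "rolloff": rolloff,
        "bandwidth": bandwidth,
        "zcr": zcr,
        "rms": rms,
    }


def f0_and_voiced(segment: AudioSegment, spec: FrameSpec | None = None) -> dict[str, np.ndarray]:
    """Per-frame F0 (Hz, 0 when unvoiced) and voiced flag + probability."""
    spec = spec or FrameSpec(rate=segment.rate)
    f0, flag, prob = _dsp.f0_autocorr(segment.samples, spec.rate, spec.n_fft, spec.hop)
    return {"f0": f0, "voiced": np.concatenate([flag, prob])}


def binwise_var_mean(matrix: np.ndarray, n_bins: int = 1025) -> np.ndarray:
    """Per-frequency-bin population variance across frames, then per-bin mean.

    Summarizes a (n_bins x n_frames) matrix into 2 * n_bins values,
    variance half first.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2 or matrix.shape[0] != n_bins:
        raise ValueError(
            f"expected a matrix with {n_bins} frequency-bin rows, got shape {matrix.shape}"
        )
    return np.concatenate([matrix.var(axis=1), matrix.mean(axis=1)])


def tonal_blocks(segment: AudioSegment, spec: FrameSpec | None = None) -> dict[str, np.ndarray]:
    """Spectral contrast, tonnetz, chroma and MFCC matrices, flattened row-major."""
    spec = spec or FrameSpec(rate=segment.rate)
    x = segment.samples
    S, _ = _dsp.magphase(_dsp.stft(x, spec.n_fft, spec.hop))
    freqs = _dsp.fft_frequencies(spec.rate, spec.n_fft)
    contrast = _spectral_contrast(S, freqs)
    chroma_m = _dsp.chroma(x, spec.rate, spec.n_fft, spec.hop)
    tonnetz_m = _dsp.tonnetz(chroma_m)
    mfcc_m = _dsp.mfcc(x, spec.rate, N_MFCC, n_fft=spec.n_fft, hop=spec.hop)
    return {
        "contrast": contrast.ravel(),
        "tonnetz": tonnetz_m.ravel(),
        "chroma": chroma_m.ravel(),
        "mfcc": mfcc_m.ravel(),
    }


def extract_feature_vector(segment: AudioSegment, spec: FrameSpec | None = None) -> FeatureVector:
    """Assemble the full battery for one fixed window.

    The segment must already have the configured window length (use
    :func:`segvoice.segmentation.fix_window` first); a wrong length raises
    rather than silently re-windowing.  Any NaN produced by a numerically
    degenerate input is replaced by 0 before assembly.
    """
    spec = spec or FrameSpec(rate=segment.rate)
    n = segment.samples.size
    sizes = expected_block_sizes(n, spec)  # validates divisibility

    x = segment.samples
    blocks: dict[str, np.ndarray] = {}
    blocks["raw_variance"] = windowed_variance(x)
    blocks["hpss_variance"] = hpss_variance(segment)
    scalars = framewise_scalars(segment, spec)
    voicing = f0_and_voiced(segment, spec)
    blocks["flatness"] = scalars["flatness"]
    blocks["centroid"] = scalars["centroid"]
    blocks["f0"] = voicing["f0"]
    blocks["voiced"] = voicing["voiced"]
    blocks["rolloff"] = scalars["rolloff"]
    blocks["bandwidth"] = scalars["bandwidth"]
    blocks["zcr"] = scalars["zcr"]
    blocks["rms"] = scalars["rms"]
    tonal = tonal_blocks(segment, spec)
    blocks["contrast"] = tonal["contrast"]
    blocks["tonnetz"] = tonal["tonnetz"]
    blocks["chroma"] = tonal["chroma"]
    blocks["mfcc"] = tonal["mfcc"]

    D = _dsp.stft(x, spec.n_fft, spec.hop)
    S, P = _dsp.magphase(D)
    pitches, mags = _dsp.pitch_track(x, spec.rate, spec.n_fft, spec.hop)
    blocks["pitch_track"] = binwise_var_mean(pitches, spec.n_bins)
    blocks["pitch_mag"] = binwise_var_mean(mags, spec.n_bins)
    blocks["magnitude"] = binwise_var_mean(S, spec.n_bins)
    blocks["phase"] = binwise_var_mean(P, spec.n_bins)

    ordered: dict[str, np.ndarray] = {}
    for name in BLOCK_ORDER:
        arr = np.nan_to_num(blocks[name], nan=0.0, posinf=0.0, neginf=0.0)
        if arr.size != sizes[name]:
            raise AssertionError(
                f"block {name!r} produced {arr.size} values, expected {sizes[name]}"
            )
        ordered[name] = arr
    return FeatureVector(blocks=ordered)


def feature_time_map(n_samples: int, spec: FrameSpec | None = None,
                     n_segments: int = 48) -> np.ndarray:
    """Map every feature index to a time-segment index in [0, n_segments).

    Features with a temporal axis (raw/HPSS variance windows, framewise
    curves, flattened coefficient-x-frame matrices) are assigned to the
    segment containing their window or frame center.  The bin-wise
    variance/mean summaries have no time location and get -1; they act as
    always-present context when attributions are grouped by time.
    """
    spec = spec or FrameSpec()
    sizes = expected_block_sizes(n_samples, spec)
    seg_len = n_samples // n_segments  # remainder lands in the final segment

    def seg_of_sample(s: np.ndarray) -> np.ndarray:
        return np.minimum(s // seg_len, n_segments - 1)

    nf = spec.n_frames(n_samples)
    frame_centers = np.minimum(np.arange(nf) * spec.hop, n_samples - 1)
    frame_seg = seg_of_sample(frame_centers)
    n_raw = sizes["raw_variance"]
    raw_seg = seg_of_sample(np.arange(n_raw) * RAW_VAR_WIN + RAW_VAR_WIN // 2)

    pieces = []
    for name in BLOCK_ORDER:
        size = sizes[name]
        if name == "raw_variance":
            pieces.append(raw_seg)
        elif name == "hpss_variance":
            pieces.append(np.concatenate([raw_seg, raw_seg]))
        elif name in ("pitch_track", "pitch_mag", "magnitude", "phase"):
            pieces.append(np.full(size, -1))
        else:  # framewise curves and coefficient-major matrices
            pieces.append(np.tile(frame_seg, size // nf))
    out = np.concatenate(pieces)
    assert out.size == sum(sizes.values())
    return out


def feature_matrix(
    manifest: DatasetManifest,
    window: WindowSpec | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Extract the battery for every manifest entry into one table.

    Row order follows the manifest; columns are `block.index` names plus a
    final `label` column.  Per-file failures are collected and reported
    together so one bad file does not silently truncate the table.
    """
    window = window or WindowSpec()
    rows, names, failures = [], None, []
    t0 = time.monotonic()
    for i, rec in enumerate(manifest):
        try:
            seg = load_audio(rec.path, target_rate=window.rate)
            seg = fix_window(seg, window)
            fv = extract_feature_vector(seg, FrameSpec(rate=window.rate))
        except Exception as exc:
            failures.append(f"{rec.path}: {exc}")
            continue
        if names is None:
            names = fv.names
        rows.append(fv.values)
        if progress and (i + 1) % 50 == 0:
            print(f"  features: {i + 1}/{len(manifest)} ({time.monotonic() - t0:.0f}s)")
    if failures:
        detail = "\n  ".join(failures)
        raise IOError(f"feature extraction failed for {len(failures)} file(s):\n  {detail}")
    data = np.vstack(rows)
    df = pd.DataFrame(data, columns=names)
    df["label"] = [rec.label for rec in manifest]
    return df
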