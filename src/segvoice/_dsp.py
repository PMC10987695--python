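"""Short-time signal-processing primitives used by the feature battery.

Conventions (shared by every consumer in this package):

* frames are *centered*: the signal is reflection-padded by n_fft//2 on
  both sides before framing, so a signal of N samples with hop h yields
  exactly 1 + floor(N / h) frames;
* the analysis window is a periodic Hann window of length n_fft;
* spectra are one-sided, n_fft//2 + 1 bins.

Everything here is deterministic and allocation-light; no randomness.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import dct, irfft, rfft
from scipy.ndimage import median_filter

N_FFT = 2048
HOP = 512

_EPS = 1e-10


def n_frames_for(n_samples: int, hop: int = HOP) -> int:
    """Frame-count law for centered framing: 1 + floor(N / hop)."""
    return 1 + n_samples // hop


def frame_signal(x: np.ndarray, n_fft: int = N_FFT, hop: int = HOP) -> np.ndarray:
    """Centered frames of `x`, shape (n_frames, n_fft); reflection padded."""
    pad = n_fft // 2
    xp = np.pad(x, pad, mode="reflect") if x.size > 1 else np.pad(x, pad)
    frames = sliding_window_view(xp, n_fft)[::hop]
    return frames[: n_frames_for(x.size, hop)]


def stft(x: np.ndarray, n_fft: int = N_FFT, hop: int = HOP) -> np.ndarray:
    """Complex one-sided STFT, shape (n_fft//2 + 1, n_frames)."""
    frames = frame_signal(x, n_fft, hop)
    window = np.hanning(n_fft + 1)[:-1]  # periodic Hann
    return rfft(frames * window, axis=1).T


def istft(S: np.ndarray, n_samples: int, n_fft: int = N_FFT, hop: int = HOP) -> np.ndarray:
    """Invert a centered one-sided STFT back to `n_samples` samples.

    Weighted overlap-add with the same periodic Hann window; the squared
    window sum normalizes the overlap, and the center padding is trimmed.
    """
    window = np.hanning(n_fft + 1)[:-1]
    frames = irfft(S.T, n=n_fft, axis=1) * window
    n_padded = n_samples + 2 * (n_fft // 2)
    out = np.zeros(n_padded)
    norm = np.zeros(n_padded)
    w2 = window**2
    for i in range(frames.shape[0]):
        start = i * hop
        out[start : start + n_fft] += frames[i]
        norm[start : start + n_fft] += w2
    out = out / np.maximum(norm, _EPS)
    pad = n_fft // 2
    return out[pad : pad + n_samples]


def magphase(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a complex spectrogram D into magnitude S and phase angle (radians)."""
    return np.abs(S), np.angle(S)


def fft_frequencies(rate: int, n_fft: int = N_FFT) -> np.ndarray:
    return np.fft.rfftfreq(n_fft, d=1.0 / rate)


def power_to_db(power: np.ndarray, top_db: float = 80.0) -> np.ndarray:
    """10*log10 with floor: values below (max - top_db) dB are clamped."""
    db = 10.0 * np.log10(np.maximum(power, _EPS))
    return np.maximum(db, db.max() - top_db)


# --- mel filterbank / MFCC --------------------------------------------------


def hz_to_mel(f: np.ndarray | float) -> np.ndarray:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(rate: int, n_fft: int = N_FFT, n_mels: int = 128,
                   fmin: float = 0.0, fmax: float | None = None) -> np.ndarray:
    """Triangular mel filterbank, shape (n_mels, n_fft//2 + 1), area-normalized."""
    fmax = fmax or rate / 2.0
    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    freqs = fft_frequencies(rate, n_fft)
    fb = np.zeros((n_mels, freqs.size))
    for i in range(n_mels):
        lo, mid, hi = hz_pts[i : i + 3]
        rising = (freqs - lo) / max(mid - lo, _EPS)
        falling = (hi - freqs) / max(hi - mid, _EPS)
        fb[i] = np.clip(np.minimum(rising, falling), 0.0, None)
        width = max(hi - lo, _EPS)
        fb[i] *= 2.0 / width  # Slaney-style area normalization
    return fb


def mel_spectrogram(x: np.ndarray, rate: int, n_mels: int = 128,
                    n_fft: int = N_FFT, hop: int = HOP) -> np.ndarray:
    S, _ = magphase(stft(x, n_fft, hop))
    fb = mel_filterbank(rate, n_fft, n_mels)
    return fb @ (S**2)


def mfcc(x: np.ndarray, rate: int, n_mfcc: int = 20, n_mels: int = 128,
         n_fft: int = N_FFT, hop: int = HOP) -> np.ndarray:
    """MFCC matrix, shape (n_mfcc, n_frames): DCT-II of the log-mel spectrum."""
    logmel = power_to_db(mel_spectrogram(x, rate, n_mels, n_fft, hop))
    return dct(logmel, type=2, axis=0, norm="ortho")[:n_mfcc]


# --- chroma / tonnetz -------------------------------------------------------


def chroma(x: np.ndarray, rate: int, n_fft: int = N_FFT, hop: int = HOP,
           tuning_a: float = 440.0) -> np.ndarray:
    """12-row chromagram: spectral power folded onto pitch classes.

    Each STFT bin is assigned to the pitch class of its nearest equal-
    tempered semitone; per-frame columns are normalized to unit maximum.
    Silent frames stay all-zero.
    """
    S, _ = magphase(stft(x, n_fft, hop))
    power = S**2
    freqs = fft_frequencies(rate, n_fft)
    valid = freqs > 25.0  # discard DC / sub-audio bins
    midi = 69.0 + 12.0 * np.log2(np.maximum(freqs, _EPS) / tuning_a)
    pitch_class = np.mod(np.round(midi).astype(int), 12)
    out = np.zeros((12, power.shape[1]))
    for pc in range(12):
        rows = valid & (pitch_class == pc)
        out[pc] = power[rows].sum(axis=0)
    peak = out.max(axis=0)
    nonzero = peak > _EPS
    out[:, nonzero] /= peak[nonzero]
    return out


# Tonal-centroid transform: projects a 12-bin chroma vector onto three
# circles (fifths r=1, minor thirds r=1, major thirds r=0.5).
def _tonnetz_basis() -> np.ndarray:
    pc = np.arange(12)
    basis = np.stack(
        [
            np.sin(pc * 7.0 * np.pi / 6.0),
            np.cos(pc * 7.0 * np.pi / 6.0),
            np.sin(pc * 3.0 * np.pi / 2.0),
            np.cos(pc * 3.0 * np.pi / 2.0),
            0.5 * np.sin(pc * 2.0 * np.pi / 3.0),
            0.5 * np.cos(pc * 2.0 * np.pi / 3.0),
        ]
    )
    return basis


def tonnetz(chroma_matrix: np.ndarray) -> np.ndarray:
    """6-row tonal centroid of an L1-normalized chromagram."""
    norms = chroma_matrix.sum(axis=0)
    c = chroma_matrix / np.maximum(norms, _EPS)
    return _tonnetz_basis() @ c


# --- harmonic / percussive separation ---------------------------------------


def hpss(x: np.ndarray, n_fft: int = N_FFT, hop: int = HOP,
         kernel: int = 31, power: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Median-filtering harmonic/percussive separation in the time domain.

    Harmonic energy is smooth along time (horizontal median filter),
    percussive energy smooth along frequency (vertical); soft Wiener-style
    masks split the complex spectrogram and each part is inverted back to
    a waveform of the input length.
    """
    D = stft(x, n_fft, hop)
    S = np.abs(D)
    harm = median_filter(S, size=(1, kernel), mode="reflect")
    perc = median_filter(S, size=(kernel, 1), mode="reflect")
    hp, pp = harm**power, perc**power
    total = np.maximum(hp + pp, _EPS)
    mask_h = hp / total
    mask_p = pp / total
    n = x.size
    return istft(D * mask_h, n, n_fft, hop), istft(D * mask_p, n, n_fft, hop)


# --- pitch ------------------------------------------------------------------


def pitch_track(x: np.ndarray, rate: int, n_fft: int = N_FFT, hop: int = HOP,
                fmin: float = 50.0, fmax: float = 2000.0,
                threshold: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Sparse per-bin pitch candidates from local spectral peaks.

    Returns (pitches, magnitudes), each (n_bins, n_frames).  A bin holds a
    parabolically interpolated peak frequency (and the peak magnitude) when
    the magnitude spectrum has a local maximum there exceeding `threshold`
    times the frame maximum; all other cells are zero.
    """
    S, _ = magphase(stft(x, n_fft, hop))
    n_bins, n_cols = S.shape
    freqs = fft_frequencies(rate, n_fft)
    bin_hz = rate / n_fft

    prev = np.vstack([S[:1], S[:-1]])
    nxt = np.vstack([S[1:], S[-1:]])
    is_peak = (S > prev) & (S >= nxt)
    frame_max = S.max(axis=0, keepdims=True)
    is_peak &= S > threshold * np.maximum(frame_max, _EPS)
    in_range = ((freqs >= fmin) & (freqs <= fmax))[:, None]
    is_peak &= in_range

    # parabolic interpolation around each peak bin
    denom = prev - 2 * S + nxt
    shift = np.where(np.abs(denom) > _EPS, 0.5 * (prev - nxt) / np.where(np.abs(denom) > _EPS, denom, 1.0), 0.0)
    shift = np.clip(shift, -0.5, 0.5)
    pitches = np.where(is_peak, (np.arange(n_bins)[:, None] + shift) * bin_hz, 0.0)
    mags = np.where(is_peak, S, 0.0)
    return pitches, mags


def f0_autocorr(x: np.ndarray, rate: int, n_fft: int = N_FFT, hop: int = HOP,
                fmin: float = 50.0, fmax: float = 500.0,
                voicing_threshold: float = 0.45) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame F0 via normalized autocorrelation, with voicing decision.

    Returns (f0, voiced_flag, voiced_prob), each of length n_frames.
    Within the admissible lag range the candidate period is the *shortest*
    lag whose autocorrelation reaches 80% of the range maximum, which
    suppresses sub-octave errors on strongly periodic frames.  The
    normalized peak value acts as the periodicity score: frames score 0 on
    silence, near 1 on a pure harmonic tone.
    """
    frames = frame_signal(x, n_fft, hop)
    window = np.hanning(n_fft + 1)[:-1]
    fw = (frames - frames.mean(axis=1, keepdims=True)) * window
    # autocorrelation via rFFT (Wiener-Khinchin)
    spec = rfft(fw, n=2 * n_fft, axis=1)
    ac = irfft(spec * np.conj(spec), axis=1)[:, :n_fft]
    r0 = ac[:, 0]

    lag_min = max(2, int(np.floor(rate / fmax)))
    lag_max = min(n_fft - 1, int(np.ceil(rate / fmin)))
    n = frames.shape[0]
    f0 = np.zeros(n)
    prob = np.zeros(n)
    for i in range(n):
        if r0[i] < _EPS:
            continue
        seg = ac[i, lag_min : lag_max + 1] / r0[i]
        peak_val = seg.max()
        if peak_val <= 0:
            continue
        candidates = np.nonzero(seg >= 0.8 * peak_val)[0]
        # local maxima only: drop candidates on a rising slope edge
        best = None
        for c in candidates:
            left = seg[c - 1] if c > 0 else -np.inf
            right = seg[c + 1] if c < seg.size - 1 else -np.inf
            if seg[c] >= left and seg[c] >= right:
                best = c
                break
        if best is None:
            best = int(np.argmax(seg))
        lag = lag_min + best
        score = float(np.clip(seg[best], 0.0, 1.0))
        prob[i] = score
        if score >= voicing_threshold:
            f0[i] = rate / lag
    voiced = (prob >= voicing_threshold).astype(np.float64)
    f0 = np.where(voiced > 0, f0, 0.0)
    return f0, voiced, prob
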