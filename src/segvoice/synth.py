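"""Synthetic emotional-utterance generator.

Real emotional-speech corpora cannot ship with the package, so every
downstream stage (segmentation, features, spectrograms, classifiers,
evaluation) is exercised on generated vocal-like audio instead.  Each
emotion class is a point in a small acoustic parameter space — fundamental
frequency mean and range, energy, amplitude-modulation rate, noise floor —
loosely following the arousal/valence folk wisdom (anger: high pitch, loud,
fast modulation; sadness: low pitch, quiet, slow).  These profiles are test
fixtures, not claims about real emotion acoustics.

A `separation` knob in [0, 1] linearly interpolates every class profile
between the neutral profile (separation 0: labels carry no information)
and its full value (separation 1), which gives the evaluation machinery a
controllable effect size.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .audio_io import AudioSegment, DatasetManifest, ManifestRecord, save_wav
from .labels import EMOTIONS, LABEL_TO_INT, check_label


@dataclass(frozen=True)
class EmotionProfile:
    """Acoustic parameters of one synthetic emotion class."""

    f0_mean: float  # Hz
    f0_range: float  # Hz, peak-to-peak pitch movement
    energy: float  # relative RMS amplitude in [0, 1]
    am_rate: float  # Hz, amplitude-modulation (syllable-like) rate
    noise_frac: float  # fraction of signal power that is broadband noise

    def __post_init__(self) -> None:
        if self.f0_mean <= 0:
            raise ValueError("f0_mean must be positive")
        for name in ("energy", "noise_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


#: Default per-class profiles (declared fixtures; see module docstring).
PROFILES: dict[str, EmotionProfile] = {
    "anger": EmotionProfile(f0_mean=220.0, f0_range=80.0, energy=0.90, am_rate=6.0, noise_frac=0.20),
    "disgust": EmotionProfile(f0_mean=140.0, f0_range=40.0, energy=0.55, am_rate=3.0, noise_frac=0.30),
    "fear": EmotionProfile(f0_mean=260.0, f0_range=60.0, energy=0.60, am_rate=8.0, noise_frac=0.15),
    "joy": EmotionProfile(f0_mean=240.0, f0_range=100.0, energy=0.80, am_rate=5.0, noise_frac=0.05),
    "neutral": EmotionProfile(f0_mean=120.0, f0_range=20.0, energy=0.50, am_rate=2.0, noise_frac=0.10),
    "sadness": EmotionProfile(f0_mean=100.0, f0_range=15.0, energy=0.30, am_rate=1.5, noise_frac=0.08),
}

# Per-utterance jitter SDs, as fractions of the profile value.
_JITTER = {"f0_mean": 0.05, "f0_range": 0.15, "energy": 0.10, "am_rate": 0.15, "noise_frac": 0.15}

_N_HARMONICS = 8
_N_SPEAKERS = 10


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters for one synthetic dataset."""

    n_per_class: int = 10
    separation: float = 1.0
    duration: float = 1.5
    rate: int = 16_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if not 0.0 <= self.separation <= 1.0:
            raise ValueError("separation must lie in [0, 1]")
        if self.duration <= 0 or self.rate <= 0:
            raise ValueError("duration and rate must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.rate))


def _blend_profile(label: str, separation: float) -> EmotionProfile:
    """Interpolate a class profile toward neutral by 1 - separation."""
    base, neutral = PROFILES[label], PROFILES["neutral"]
    mix = lambda a, b: b + separation * (a - b)  # noqa: E731
    return EmotionProfile(
        f0_mean=mix(base.f0_mean, neutral.f0_mean),
        f0_range=mix(base.f0_range, neutral.f0_range),
        energy=mix(base.energy, neutral.energy),
        am_rate=mix(base.am_rate, neutral.am_rate),
        noise_frac=mix(base.noise_frac, neutral.noise_frac),
    )


def _utterance_rng(config: SynthConfig, label: str, index: int) -> np.random.Generator:
    # Index-keyed substream: utterance i of class c is reproducible on its
    # own, so parallel or partial generation yields identical audio.
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, LABEL_TO_INT[label], index])
    )


def synth_segment(label: str, config: SynthConfig, index: int = 0) -> AudioSegment:
    """Generate one emotion-conditioned vocal-like segment.

    The waveform is a harmonic stack (8 partials, 1/k amplitude rolloff)
    whose F0 contour drifts and oscillates inside the class's pitch range,
    shaped by an attack/decay envelope with class-rate amplitude
    modulation, plus a broadband noise floor.  Deterministic given
    (label, seed, index).
    """
    check_label(label)
    if index < 0 or index >= config.n_per_class:
        raise ValueError(f"index {index} outside [0, {config.n_per_class})")
    rng = _utterance_rng(config, label, index)
    prof = _blend_profile(label, config.separation)

    jit = {
        name: max(1e-6, getattr(prof, name) * (1.0 + _JITTER[name] * rng.standard_normal()))
        for name in _JITTER
    }
    jit["energy"] = min(jit["energy"], 1.0)
    jit["noise_frac"] = float(np.clip(jit["noise_frac"], 0.0, 0.95))

    n = config.n_samples
    t = np.arange(n) / config.rate

    # F0 contour: slow drift plus a vibrato-like oscillation, bounded to
    # stay within the (jittered) pitch range around the mean.
    drift = np.linspace(-0.5, 0.5, n) * jit["f0_range"] * rng.uniform(-1, 1)
    vibrato = 0.5 * jit["f0_range"] * np.sin(2 * np.pi * rng.uniform(3.0, 7.0) * t + rng.uniform(0, 2 * np.pi))
    f0 = np.maximum(40.0, jit["f0_mean"] + drift + vibrato)
    phase = 2 * np.pi * np.cumsum(f0) / config.rate

    voiced = np.zeros(n)
    for k in range(1, _N_HARMONICS + 1):
        voiced += (1.0 / k) * np.sin(k * phase + rng.uniform(0, 2 * np.pi))
    voiced /= np.sqrt(np.mean(voiced**2)) + 1e-12

    # Energy envelope: attack/decay ramps with syllable-like modulation.
    attack = int(0.1 * n)
    env = np.ones(n)
    env[:attack] = np.linspace(0.0, 1.0, attack)
    env[-attack:] = np.linspace(1.0, 0.0, attack)
    am = 1.0 + 0.6 * np.sin(2 * np.pi * jit["am_rate"] * t + rng.uniform(0, 2 * np.pi))
    env *= am / 1.6

    noise = rng.standard_normal(n)
    noise /= np.sqrt(np.mean(noise**2)) + 1e-12

    nf = jit["noise_frac"]
    x = np.sqrt(1.0 - nf) * voiced * env + np.sqrt(nf) * noise * env
    x *= 0.5 * jit["energy"] / (np.sqrt(np.mean(x**2)) + 1e-12)
    x = np.clip(x, -1.0, 1.0)
    return AudioSegment(samples=x, rate=config.rate, label=label, source=f"synthetic:{label}:{index}")


def make_dataset(config: SynthConfig, out_dir: str | Path) -> DatasetManifest:
    """Write a balanced synthetic dataset (WAVs + manifest.csv) to `out_dir`.

    Produces n_per_class x 6 16-bit PCM WAV files with one manifest row
    each; pseudo-speaker ids cycle so speakers span all classes.  The same
    config (seed included) always reproduces identical files.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out_dir}: {exc}") from exc
    records = []
    for label in EMOTIONS:
        for i in range(config.n_per_class):
            seg = synth_segment(label, config, i)
            path = out_dir / f"{label}_{i:04d}.wav"
            save_wav(seg, path)
            records.append(
                ManifestRecord(
                    path=str(path),
                    label=label,
                    speaker=f"spk{i % _N_SPEAKERS:02d}",
                    language="synthetic",
                    corpus="synthetic",
                )
            )
    manifest = DatasetManifest(records=records)
    manifest.save(out_dir / "manifest.csv")
    return manifest


def make_arrays(config: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Generate a balanced dataset directly as (waveform matrix, int labels).

    Convenience for in-memory pipelines and tests; row order is class-major
    then index, identical to :func:`make_dataset`'s manifest order.
    """
    X = np.empty((6 * config.n_per_class, config.n_samples))
    y = np.empty(6 * config.n_per_class, dtype=np.int64)
    row = 0
    for label in EMOTIONS:
        for i in range(config.n_per_class):
            X[row] = synth_segment(label, config, i).samples
            y[row] = LABEL_TO_INT[label]
            row += 1
    return X, y
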