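"""Audio and manifest I/O plus corpus filename parsing.

All downstream processing happens at a single configured sample rate
(default 16 kHz): any input is resampled on load, and stereo recordings are
averaged to mono.  Corpus support covers the RAVDESS audio-speech filename
code and the Emo-DB filename code, each mapped onto the six-class label set
in :mod:`segvoice.labels`.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from .labels import EXCLUDED, LABEL_TO_INT, check_label

DEFAULT_RATE = 16_000

MANIFEST_COLUMNS = ("path", "label", "speaker", "language", "corpus")


@dataclass
class AudioSegment:
    """A mono waveform with its sample rate and provenance.

    `samples` are float amplitudes in [-1, 1]; `offset` is the start time
    of this segment within its source recording, in seconds.
    """

    samples: np.ndarray
    rate: int
    label: str | None = None
    source: str | None = None
    offset: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("AudioSegment requires a non-empty 1-D waveform")
        if self.rate <= 0:
            raise ValueError(f"sample rate must be positive, got {self.rate}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class ManifestRecord:
    path: str
    label: str
    speaker: str
    language: str
    corpus: str


@dataclass
class DatasetManifest:
    """Ordered list of labeled recordings; paths are unique."""

    records: list[ManifestRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        paths = [r.path for r in self.records]
        if len(set(paths)) != len(paths):
            raise ValueError("manifest paths must be unique")
        for r in self.records:
            check_label(r.label)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.label] = counts.get(r.label, 0) + 1
        return counts

    def save(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(MANIFEST_COLUMNS)
            for r in self.records:
                writer.writerow([r.path, r.label, r.speaker, r.language, r.corpus])

    @classmethod
    def load(cls, path: str | Path) -> "DatasetManifest":
        records = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            missing = set(MANIFEST_COLUMNS) - set(reader.fieldnames or ())
            if missing:
                raise ValueError(f"manifest {path} missing columns {sorted(missing)}")
            for row in reader:
                records.append(
                    ManifestRecord(
                        path=row["path"],
                        label=row["label"],
                        speaker=row["speaker"],
                        language=row["language"],
                        corpus=row["corpus"],
                    )
                )
        return cls(records=records)


def load_audio(path: str | Path, target_rate: int = DEFAULT_RATE) -> AudioSegment:
    """Read a WAV file as a mono float waveform at `target_rate`.

    Integer PCM is scaled to [-1, 1]; stereo channels are averaged;
    resampling uses a polyphase filter at the exact rational rate ratio.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt/empty files
        raise IOError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise IOError(f"WAV file {path} contains no samples")
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max) + 1.0
        samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    if rate != target_rate:
        ratio = Fraction(target_rate, int(rate))
        samples = resample_poly(samples, ratio.numerator, ratio.denominator)
    samples = np.clip(samples, -1.0, 1.0)
    return AudioSegment(samples=samples, rate=target_rate, source=str(path))


def save_wav(segment: AudioSegment, path: str | Path) -> None:
    """Write a segment as 16-bit PCM mono WAV, clipping to [-1, 1]."""
    clipped = np.clip(segment.samples, -1.0, 1.0)
    # scale by 2^15 and clip the top code so load()'s /2^15 round-trips
    # within one quantization step
    pcm = np.clip(np.round(clipped * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(Path(path), segment.rate, pcm)


# --- RAVDESS filename convention -------------------------------------------
#
# 7 hyphenated 2-digit fields: modality-channel-emotion-intensity-statement-
# repetition-actor.  Emotion codes: 01 neutral, 02 calm, 03 happy, 04 sad,
# 05 angry, 06 fearful, 07 disgust, 08 surprised.  Calm and surprised fall
# outside the six-class target set and are excluded.

_RAVDESS_RE = re.compile(r"^(\d{2})-(\d{2})-(\d{2})-(\d{2})-(\d{2})-(\d{2})-(\d{2})$")

RAVDESS_EMOTIONS = {
    "01": "neutral",
    "02": EXCLUDED,  # calm
    "03": "joy",
    "04": "sadness",
    "05": "anger",
    "06": "fear",
    "07": "disgust",
    "08": EXCLUDED,  # surprised
}


def parse_ravdess_name(filename: str) -> tuple[str, str]:
    """Parse a RAVDESS filename into (label-or-excluded, speaker id)."""
    stem = Path(filename).stem
    m = _RAVDESS_RE.match(stem)
    if not m:
        raise ValueError(f"not a RAVDESS filename code: {filename!r}")
    emotion_code, actor = m.group(3), m.group(7)
    if emotion_code not in RAVDESS_EMOTIONS:
        raise ValueError(f"unknown RAVDESS emotion code {emotion_code!r} in {filename!r}")
    return RAVDESS_EMOTIONS[emotion_code], actor


# --- Emo-DB filename convention --------------------------------------------
#
# <2-digit speaker><text code><emotion letter><version>, e.g. "03a01Wa".
# German emotion letters: W Wut/anger, A Angst/fear, F Freude/joy,
# T Trauer/sadness, E Ekel/disgust, N neutral, L Langeweile/boredom.
# Boredom is the corpus's seventh category outside the target set.

_EMODB_RE = re.compile(r"^(\d{2})([ab]\d{2})([WAFTENL])([a-z]\d?)?$")

EMODB_EMOTIONS = {
    "W": "anger",
    "A": "fear",
    "F": "joy",
    "T": "sadness",
    "E": "disgust",
    "N": "neutral",
    "L": EXCLUDED,  # boredom
}


def parse_emodb_name(filename: str) -> tuple[str, str]:
    """Parse an Emo-DB filename into (label-or-excluded, speaker id)."""
    stem = Path(filename).stem
    m = _EMODB_RE.match(stem)
    if not m:
        raise ValueError(f"not an Emo-DB filename code: {filename!r}")
    speaker, letter = m.group(1), m.group(3)
    return EMODB_EMOTIONS[letter], speaker


_PARSERS = {"ravdess": parse_ravdess_name, "emodb": parse_emodb_name}
_LANGUAGES = {"ravdess": "en", "emodb": "de", "synthetic": "synthetic"}


def scan_corpus(directory: str | Path, corpus: str) -> DatasetManifest:
    """Build a manifest from a directory of corpus-named WAV files.

    Files whose code parses to an out-of-scope category are skipped; files
    that do not parse at all raise, so directory mix-ups fail loudly.
    For `corpus="synthetic"` the directory's own manifest.csv is loaded.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise IOError(f"not a directory: {directory}")
    if corpus == "synthetic":
        return DatasetManifest.load(directory / "manifest.csv")
    if corpus not in _PARSERS:
        raise ValueError(f"unknown corpus {corpus!r}; expected ravdess|emodb|synthetic")
    parse = _PARSERS[corpus]
    records = []
    for wav in sorted(directory.rglob("*.wav")):
        label, speaker = parse(wav.name)
        if label == EXCLUDED:
            continue
        records.append(
            ManifestRecord(
                path=str(wav),
                label=label,
                speaker=speaker,
                language=_LANGUAGES[corpus],
                corpus=corpus,
            )
        )
    return DatasetManifest(records=records)


def labels_to_int(labels) -> np.ndarray:
    return np.array([LABEL_TO_INT[check_label(l)] for l in labels], dtype=np.int64)
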