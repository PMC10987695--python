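"""The six emotion categories used as classification targets.

The label set is the intersection of the categories annotated in the two
public emotional-speech corpora this package supports (RAVDESS, Emo-DB):
fear, joy, anger, disgust, sadness, plus neutral speech.  Integer codes are
assigned in alphabetical order of the English names so that encodings are
stable across runs and machines.
"""

from __future__ import annotations

EMOTIONS: tuple[str, ...] = ("anger", "disgust", "fear", "joy", "neutral", "sadness")

LABEL_TO_INT: dict[str, int] = {name: i for i, name in enumerate(EMOTIONS)}
INT_TO_LABEL: dict[int, str] = {i: name for i, name in enumerate(EMOTIONS)}

N_CLASSES: int = len(EMOTIONS)

#: Sentinel returned by corpus filename parsers for recordings whose
#: annotated category is outside the six-class target set (e.g. RAVDESS
#: "calm"/"surprised", Emo-DB "boredom").
EXCLUDED = "excluded"


def check_label(label: str) -> str:
    """Validate an emotion label, returning it unchanged.

    Raises
    ------
    ValueError
        If `label` is not one of the six admissible emotion names.
    """
    if label not in LABEL_TO_INT:
        raise ValueError(
            f"unknown emotion label {label!r}; expected one of {EMOTIONS}"
        )
    return label
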