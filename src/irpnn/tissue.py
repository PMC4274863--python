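"""Tissue-class labels for the three-way pancreatic classification task."""

from __future__ import annotations

import enum


class TissueClass(enum.IntEnum):
    """Histological class of a tissue sample.

    The integer ordinals (normal=1, early=2, advanced=3) are fixed: they
    define the output encoding of the classifier and the tie-breaking order
    of its argmax decision (lower ordinal wins an exact tie).
    """

    NORMAL = 1
    EARLY = 2
    ADVANCED = 3

    @property
    def label(self) -> str:
        return _LABELS[self]

    @classmethod
    def from_label(cls, text: str) -> "TissueClass":
        """Parse a class from its short name ('normal'/'early'/'advanced').

        Also accepts the integer ordinals as strings and a few common
        synonyms ('early carcinoma', 'advanced carcinoma').
        """
        key = str(text).strip().lower()
        for tc, lab in _LABELS.items():
            if key in (lab, str(int(tc)), f"{lab} carcinoma"):
                return tc
        raise ValueError(
            f"unknown tissue class {text!r}; expected one of "
            f"{[lab for lab in _LABELS.values()]}"
        )


_LABELS = {
    TissueClass.NORMAL: "normal",
    TissueClass.EARLY: "early",
    TissueClass.ADVANCED: "advanced",
}

#: Canonical class ordering used everywhere a per-class sequence is built.
CLASS_ORDER = (TissueClass.NORMAL, TissueClass.EARLY, TissueClass.ADVANCED)
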