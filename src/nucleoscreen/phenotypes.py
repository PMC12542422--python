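"""Canonical per-cell phenotype vocabulary for the translocation screen.

Eight classes describe where the reporter signal sits in a cell (nucleoli,
nucleoplasm, cytoplasm) plus the states that are excluded from hit-rate
denominators (mitotic, apoptotic, signal-free, and missegmented cells).
The tuple order below is the canonical order used everywhere: class-count
columns, probability vectors, classifier posteriors and tie-breaking.
"""

from __future__ import annotations

PHENOTYPE_CLASSES: tuple[str, ...] = (
    "nucleolar",
    "nucleolar_nucleoplasmic",
    "nucleoplasmic",
    "cytoplasmic",
    "mitotic",
    "apoptotic",
    "no_signal",
    "missegmented",
)

#: Classes with an intact interphase nucleus and a scoreable reporter signal.
INTERPHASE_CLASSES: tuple[str, ...] = PHENOTYPE_CLASSES[:4]

#: Classes never counted in hit-rate denominators.
EXCLUDED_CLASSES: tuple[str, ...] = PHENOTYPE_CLASSES[4:]

N_CLASSES = len(PHENOTYPE_CLASSES)

_CLASS_INDEX = {name: i for i, name in enumerate(PHENOTYPE_CLASSES)}


def class_index(label: str) -> int:
    """Position of *label* in the canonical class order."""
    try:
        return _CLASS_INDEX[label]
    except KeyError:
        raise ValueError(
            f"unknown phenotype class {label!r}; expected one of {PHENOTYPE_CLASSES}"
        ) from None


def validate_classes(labels) -> None:
    """Raise ``ValueError`` if any label is not one of the eight classes."""
    bad = sorted(set(labels) - set(PHENOTYPE_CLASSES))
    if bad:
        raise ValueError(f"unknown phenotype class labels: {bad}")
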