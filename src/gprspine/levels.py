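"""Canonical vertebral level labels, ordered caudal (S1) to cephalad (T1)."""

from __future__ import annotations

CANONICAL_LEVELS: tuple[str, ...] = (
    "S1",
    "L5", "L4", "L3", "L2", "L1",
    "T12", "T11", "T10", "T9", "T8", "T7",
    "T6", "T5", "T4", "T3", "T2", "T1",
)

LEVEL_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(CANONICAL_LEVELS)}

LUMBAR_LEVELS: tuple[str, ...] = ("L5", "L4", "L3", "L2", "L1")
THORACIC_LEVELS: tuple[str, ...] = CANONICAL_LEVELS[6:]

N_LEVELS = len(CANONICAL_LEVELS)


def is_thoracic(label: str) -> bool:
    return label.startswith("T")


def is_lumbar(label: str) -> bool:
    return label.startswith("L")
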