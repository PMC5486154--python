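"""Electrode montage handling for 10-20 system recordings.

Left/right hemisphere membership is encoded in 10-20 labels: an odd
trailing digit marks a left-hemisphere electrode, an even digit its
right-hemisphere mirror, and a trailing ``z`` the midline.  Hemispheric
asymmetry features need the ordered list of left-right symmetric channel
pairs; for the standard 30-channel montage that list has exactly 12 pairs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import yaml

logger = logging.getLogger(__name__)

#: Standard 30-channel 10-20 montage (older temporal nomenclature kept as
#: recorded; T3/T4/T5/T6 are aliases of T7/T8/P7/P8).
DEFAULT_30_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8",
    "T3", "C3", "Cz", "C4", "T4",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "Oz", "O2",
)

#: Old 10-20 temporal labels and their modern equivalents.
NOMENCLATURE_ALIASES: dict[str, str] = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}

_LABEL_RE = re.compile(r"^([A-Za-z]+?)(\d+)$")


def canonical_name(label: str) -> str:
    """Map old temporal nomenclature (T3/T4/T5/T6) to the modern label."""
    return NOMENCLATURE_ALIASES.get(label, label)


def is_midline(label: str) -> bool:
    return label.lower().endswith("z")


def _split(label: str) -> tuple[str, int] | None:
    m = _LABEL_RE.match(canonical_name(label))
    if m is None:
        return None
    return m.group(1), int(m.group(2))


def derive_symmetric_pairs(channel_names: list[str]) -> list[tuple[str, str]]:
    """Derive the ordered left-right symmetric pairs from 10-20 labels.

    Two channels pair when their labels differ only in the parity of the
    trailing digit (F3/F4, T7/T8, ...).  Midline channels (trailing ``z``)
    never pair.  Channels without a partner are silently excluded (count
    logged).  Pair order follows the left channel's position in
    ``channel_names``; the result is deterministic and idempotent for a
    fixed channel list.
    """
    canon = {canonical_name(c): c for c in channel_names}
    pairs: list[tuple[str, str]] = []
    unpaired = 0
    for name in channel_names:
        if is_midline(name):
            continue
        parts = _split(name)
        if parts is None:
            unpaired += 1
            continue
        base, digit = parts
        if digit % 2 == 0:  # right-hemisphere channel; handled via its left mirror
            continue
        partner = canon.get(f"{base}{digit + 1}")
        if partner is None:
            unpaired += 1
            continue
        pairs.append((name, partner))
    if unpaired:
        logger.info("derive_symmetric_pairs: %d channel(s) without a partner excluded", unpaired)
    return pairs


@dataclass(frozen=True)
class Montage:
    """Ordered channel labels plus the left-right symmetric pair list.

    Invariants (checked at construction): every pair member is a montage
    channel, no channel sits in two pairs, and midline channels never
    appear in a pair.
    """

    channel_names: tuple[str, ...]
    symmetric_pairs: tuple[tuple[str, str], ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.symmetric_pairs is None:
            object.__setattr__(
                self, "symmetric_pairs", tuple(derive_symmetric_pairs(list(self.channel_names)))
            )
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        object.__setattr__(
            self, "symmetric_pairs", tuple(tuple(p) for p in self.symmetric_pairs)
        )
        names = set(self.channel_names)
        seen: set[str] = set()
        for left, right in self.symmetric_pairs:
            for ch in (left, right):
                if ch not in names:
                    raise ValueError(f"pair channel {ch!r} not in montage")
                if ch in seen:
                    raise ValueError(f"channel {ch!r} appears in two pairs")
                if is_midline(ch):
                    raise ValueError(f"midline channel {ch!r} cannot be in a pair")
                seen.add(ch)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    @property
    def n_pairs(self) -> int:
        return len(self.symmetric_pairs)

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_names.index(label)
        except ValueError:
            # tolerate old/new nomenclature mismatches
            canon = [canonical_name(c) for c in self.channel_names]
            return canon.index(canonical_name(label))

    def pair_indices(self) -> list[tuple[int, int]]:
        """(left_index, right_index) per pair, in pair order."""
        return [
            (self.channel_index(left), self.channel_index(right))
            for left, right in self.symmetric_pairs
        ]

    @classmethod
    def default_30(cls) -> "Montage":
        return cls(channel_names=DEFAULT_30_CHANNELS)

    @classmethod
    def from_yaml(cls, path) -> "Montage":
        """Load ``{channels: [...], pairs: [[L, R], ...]}``; pairs optional."""
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        channels = tuple(doc["channels"])
        pairs = doc.get("pairs")
        if pairs is None:
            return cls(channel_names=channels)
        return cls(channel_names=channels, symmetric_pairs=tuple((p[0], p[1]) for p in pairs))

    def to_yaml(self, path) -> None:
        doc = {
            "channels": list(self.channel_names),
            "pairs": [list(p) for p in self.symmetric_pairs],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)
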