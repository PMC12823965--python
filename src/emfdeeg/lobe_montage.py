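"""Electrode-to-lobe grouping under the 10-20 system.

Two presets cover the 19-channel (500 Hz) and 14-channel (128 Hz)
montages used for the task-vs-rest contrast.  Lobe assignment follows
10-20 nomenclature: F*/AF*/FP* frontal, C* central, T* temporal,
P* parietal, O* occipital; midline electrodes go to their letter's lobe.
FC5/FC6 are fronto-central but grouped frontal because the 14-channel
montage declares no central lobe — this is an inference from standard
nomenclature, overridable with a custom mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .entropy_features import META_COLUMNS

LOBE_NAMES = ("frontal", "central", "temporal", "parietal", "occipital")

_MAT19 = {
    "frontal": {"FP1", "FP2", "F3", "F4", "F7", "F8", "FZ"},
    "central": {"C3", "C4", "CZ"},
    "temporal": {"T3", "T4", "T5", "T6"},
    "parietal": {"P3", "P4", "PZ"},
    "occipital": {"O1", "O2"},
}

_STEW14 = {
    "frontal": {"AF3", "AF4", "F3", "F4", "F7", "F8", "FC5", "FC6"},
    "temporal": {"T7", "T8"},
    "parietal": {"P7", "P8"},
    "occipital": {"O1", "O2"},
}


@dataclass(frozen=True)
class LobeMontage:
    """Disjoint lobe -> electrode-set mapping covering a full montage."""

    mapping: dict[str, frozenset[str]]
    montage_id: str = "custom"

    def __post_init__(self):
        mapping = {lobe: frozenset(ch.upper() for ch in chans)
                   for lobe, chans in self.mapping.items()}
        object.__setattr__(self, "mapping", mapping)
        for lobe in mapping:
            if lobe not in LOBE_NAMES:
                raise ValueError(f"unknown lobe name {lobe!r}; expected one of {LOBE_NAMES}")
        seen: dict[str, str] = {}
        for lobe, chans in mapping.items():
            if not chans:
                raise ValueError(f"lobe {lobe!r} declared but empty")
            for ch in chans:
                if ch in seen:
                    raise ValueError(f"channel {ch} assigned to both {seen[ch]} and {lobe}")
                seen[ch] = lobe

    @property
    def lobes(self) -> list[str]:
        return [l for l in LOBE_NAMES if l in self.mapping]

    @property
    def channels(self) -> frozenset[str]:
        out: set[str] = set()
        for chans in self.mapping.values():
            out |= chans
        return frozenset(out)

    def lobe_of(self, channel: str) -> str:
        ch = channel.upper()
        for lobe, chans in self.mapping.items():
            if ch in chans:
                return lobe
        raise KeyError(f"channel {channel!r} not in montage {self.montage_id}")


def build_montage(montage_id: str = "mat19",
                  mapping: dict[str, set[str]] | None = None,
                  channels: list[str] | None = None) -> LobeMontage:
    """Construct a preset or custom montage.

    Presets: ``mat19`` (5 lobes / 19 channels) and ``stew14`` (4 lobes /
    14 channels).  A custom ``mapping`` must cover ``channels`` exactly
    when a channel list is given.
    """
    if mapping is not None:
        montage = LobeMontage(mapping, montage_id="custom")
        if channels is not None:
            want = {c.upper() for c in channels}
            missing = sorted(want - montage.channels)
            extra = sorted(montage.channels - want)
            if missing:
                raise ValueError(f"custom montage omits channels: {missing}")
            if extra:
                raise ValueError(f"custom montage has unknown channels: {extra}")
        return montage
    if montage_id == "mat19":
        return LobeMontage(_MAT19, "mat19")
    if montage_id == "stew14":
        return LobeMontage(_STEW14, "stew14")
    raise ValueError(f"unknown montage_id {montage_id!r}")


def _column_channel(name: str) -> str | None:
    parts = name.split("__")
    return parts[0].upper() if len(parts) == 3 else None


def select_lobe_features(matrix: pd.DataFrame, montage: LobeMontage,
                         lobe: str) -> pd.DataFrame:
    """Submatrix of feature columns whose channel belongs to one lobe.

    Metadata columns (condition, subject id) are preserved.
    """
    if lobe not in montage.mapping:
        raise KeyError(f"lobe {lobe!r} not declared in montage {montage.montage_id} "
                       f"(has {montage.lobes})")
    wanted = montage.mapping[lobe]
    cols = [c for c in matrix.columns
            if _column_channel(c) in wanted or c in META_COLUMNS]
    return matrix[cols]
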