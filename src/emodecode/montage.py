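"""Electrode montage: 10-10 channel set, scalp regions, homologous pairs.

Every feature stage keys off this structure: band powers are computed per
channel, frontal alpha asymmetry per homologous left/right frontal pair, and
the pooled-feature topography is tallied per (region, hemisphere).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

REGIONS = ("frontal", "temporal", "central_parietal", "occipital", "midline")

# 10-10 subset used by the experiment's cap, grouped by scalp region.
# Left/right columns are aligned so that row i of the left list is the
# homologue of row i of the right list (odd vs. even index convention).
_REGION_CHANNELS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "frontal": (
        ("Fp1", "AF3", "AF7", "F1", "F3", "F5", "F7"),
        ("Fp2", "AF4", "AF8", "F2", "F4", "F6", "F8"),
    ),
    "temporal": (
        ("FT7", "FT9", "T7", "TP7", "TP9"),
        ("FT8", "FT10", "T8", "TP8", "TP10"),
    ),
    "central_parietal": (
        ("FC1", "FC3", "FC5", "C1", "C3", "C5", "CP1", "CP3", "CP5",
         "P1", "P3", "P5", "P7"),
        ("FC2", "FC4", "FC6", "C2", "C4", "C6", "CP2", "CP4", "CP6",
         "P2", "P4", "P6", "P8"),
    ),
    "occipital": (
        ("PO3", "PO7", "O1"),
        ("PO4", "PO8", "O2"),
    ),
}

_MIDLINE = ("FPz", "Fz", "Cz", "CPz", "POz", "Oz")


@dataclass(frozen=True)
class Montage:
    """Channel names plus region/hemisphere assignment and homologous pairs.

    Invariants (checked at construction): channel names are unique, every
    non-midline channel belongs to exactly one homologous pair, and the two
    members of a pair share a region while sitting on opposite hemispheres.
    """

    channel_names: tuple[str, ...]
    region: dict[str, str] = field(repr=False)
    hemisphere: dict[str, str] = field(repr=False)
    homologous_pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        names = self.channel_names
        if len(set(names)) != len(names):
            raise ValueError("duplicate channel names in montage")
        for ch in names:
            if ch not in self.region or ch not in self.hemisphere:
                raise ValueError(f"channel {ch!r} missing region/hemisphere")
            if self.region[ch] not in REGIONS:
                raise ValueError(f"unknown region {self.region[ch]!r}")
        paired: list[str] = []
        for left, right in self.homologous_pairs:
            if self.hemisphere[left] != "left" or self.hemisphere[right] != "right":
                raise ValueError(f"pair ({left}, {right}) not left/right")
            if self.region[left] != self.region[right]:
                raise ValueError(f"pair ({left}, {right}) spans regions")
            paired.extend((left, right))
        if len(set(paired)) != len(paired):
            raise ValueError("channel appears in more than one pair")
        lateral = {ch for ch in names if self.hemisphere[ch] != "midline"}
        if set(paired) != lateral:
            missing = lateral - set(paired)
            raise ValueError(f"unpaired lateral channels: {sorted(missing)}")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, channel: str) -> int:
        return self.channel_names.index(channel)

    def channels_in(self, region: str, hemisphere: str | None = None) -> list[str]:
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        out = [ch for ch in self.channel_names if self.region[ch] == region]
        if hemisphere is not None:
            out = [ch for ch in out if self.hemisphere[ch] == hemisphere]
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "channel_names": list(self.channel_names),
            "region": self.region,
            "hemisphere": self.hemisphere,
            "homologous_pairs": [list(p) for p in self.homologous_pairs],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Montage":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        payload = json.loads(text)
        return cls(
            channel_names=tuple(payload["channel_names"]),
            region=dict(payload["region"]),
            hemisphere=dict(payload["hemisphere"]),
            homologous_pairs=tuple(tuple(p) for p in payload["homologous_pairs"]),
        )


def default_montage(extra_midline: str | None = "Pz") -> Montage:
    """The experiment's 62-channel cap, optionally completed to 63 channels.

    The published channel table enumerates 62 electrodes (7+7 frontal, 5+5
    temporal, 13+13 central-parietal, 3+3 occipital, 6 midline) yet the
    correlation analysis runs on a 63 x 63 channel matrix; the missing 63rd
    channel is never named.  By default ``Pz`` (a standard 10-10 midline site
    absent from the table) is appended to reach 63; pass ``None`` to keep the
    literal 62-channel set.
    """
    names: list[str] = []
    region: dict[str, str] = {}
    hemisphere: dict[str, str] = {}
    pairs: list[tuple[str, str]] = []
    for reg, (left, right) in _REGION_CHANNELS.items():
        for lch, rch in zip(left, right, strict=True):
            names.extend((lch, rch))
            region[lch] = region[rch] = reg
            hemisphere[lch] = "left"
            hemisphere[rch] = "right"
            pairs.append((lch, rch))
    midline = list(_MIDLINE)
    if extra_midline is not None:
        if extra_midline in names or extra_midline in midline:
            raise ValueError(f"extra midline channel {extra_midline!r} already present")
        midline.append(extra_midline)
    for ch in midline:
        names.append(ch)
        region[ch] = "midline"
        hemisphere[ch] = "midline"
    return Montage(tuple(names), region, hemisphere, tuple(pairs))


def homologous_pairs(montage: Montage, region: str) -> list[tuple[str, str]]:
    """Left/right pairs restricted to one scalp region (midline has none)."""
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    return [p for p in montage.homologous_pairs if montage.region[p[0]] == region]
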