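"""Packaged frontoparietal fNIRS montage (schematic 10-10 layout).

Two 8-source/8-detector systems — one frontal, one parietal — giving 16
sources, 16 detectors and 40 channels.  Positions are 10-10 electrode labels
and region tags are approximate anatomical annotations; the layout is
schematic (intended for naming and bookkeeping, not for image
reconstruction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources


@dataclass(frozen=True)
class Montage:
    """Source/detector 10-10 positions and the channel list."""

    sources: dict[str, str]  # e.g. "S11" -> 10-10 label
    detectors: dict[str, str]
    channels: list[dict]  # {"source": "S11", "detector": "D13", "region": ...}

    def __post_init__(self) -> None:
        for ch in self.channels:
            if ch["source"] not in self.sources:
                raise ValueError(f"channel references unknown source {ch['source']}")
            if ch["detector"] not in self.detectors:
                raise ValueError(f"channel references unknown detector {ch['detector']}")

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    @property
    def n_detectors(self) -> int:
        return len(self.detectors)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def channel_names(self) -> list[str]:
        return [f"{c['source']}-{c['detector']}" for c in self.channels]

    @classmethod
    def from_json(cls, text: str) -> "Montage":
        cfg = json.loads(text)
        return cls(
            sources=cfg["sources"],
            detectors=cfg["detectors"],
            channels=cfg["channels"],
        )


def load_default_montage() -> Montage:
    """Load the packaged 40-channel frontoparietal montage."""
    text = (
        resources.files("urnbid.fnirs").joinpath("data/montage_1010.json").read_text()
    )
    return Montage.from_json(text)
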