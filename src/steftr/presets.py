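"""Species presets for recording/analysis conditions.

Each preset fixes the time frame length, the moving-average window (None
disables smoothing) and the maximum cluster number used during model
selection. Values are in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class SpeciesPreset:
    name: str
    time_unit: float
    window: float | None
    max_clusters: int
    length_unit: str


PRESETS: dict[str, SpeciesPreset] = {
    "worm": SpeciesPreset("worm", 1.0, 12.0, 20, "mm"),
    "penguin": SpeciesPreset("penguin", 60.0, 20 * 60.0, 5, "m"),
    "seabird": SpeciesPreset("seabird", 60.0, 10 * 60.0, 5, "km"),
    "rat": SpeciesPreset("rat", 1.0, 20.0, 5, "cm"),
    "fly": SpeciesPreset("fly", 0.25, None, 5, "a.u."),
    "bat": SpeciesPreset("bat", 0.008, None, 5, "m"),
}
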