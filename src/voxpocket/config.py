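"""Run configuration with the pinned pipeline defaults.

Defaults trace either to a recommended method parameter (6 A solid-angle
sphere, top 20% candidates, 20 A cluster linkage, 10 A volume probe, >= 4 of
7 interior directions) or to a documented artifact decision (1 A spacing,
0.1*4*pi solid-angle band, equal ranking weights, 4.5 A contact cutoff).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass


@dataclass(frozen=True)
class RunConfig:
    spacing: float = 1.0
    padding: float = 10.0
    sa_radius: float = 6.0
    candidate_fraction: float = 0.20
    cluster_distance: float = 20.0
    sa_band: float = 0.1 * 4.0 * math.pi
    volume_radius: float = 10.0
    interior_direction_min: int = 4
    w1: float = 0.5
    w2: float = 0.5
    chains: tuple[str, ...] = ()
    match_distance: float = 4.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.padding < max(self.sa_radius, self.volume_radius):
            raise ValueError("padding must cover the largest virtual-sphere radius")
        if not 0 < self.candidate_fraction <= 1:
            raise ValueError("candidate_fraction must lie in (0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["chains"] = list(self.chains)
        return d
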