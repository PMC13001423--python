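"""Geometric detection rules for the six non-covalent interaction classes.

Each interaction type carries a distance window ``[d_min, d_cut]`` and, where
physically meaningful, an angular filter. Distances inside the window are
converted to a strength in ``[1e-6, 1]`` by a piecewise-linear decay:
full strength at or below ``d_min``, the floor value exactly at ``d_cut``,
and zero (no contact) beyond the cutoff.

The default windows follow common interaction-profiler practice and are fully
configurable; every annotation run records the rule set it used.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

INTERACTION_TYPES = ("hbond", "salt_bridge", "vdw", "hydrophobic", "pipi", "cation_pi")

#: floor strength assigned at the cutoff distance
STRENGTH_FLOOR = 1e-6

#: van der Waals radii (Å) for elements seen in protein/ligand heavy atoms
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}
DEFAULT_VDW_RADIUS = 1.70


@dataclass(frozen=True)
class TypeRule:
    """Distance window and optional angular filter for one interaction type."""

    d_min: float
    d_cut: float
    angle_min: Optional[float] = None  # degrees; meaning depends on type
    angle_max: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 < self.d_min < self.d_cut:
            raise ValueError(
                f"require 0 < d_min < d_cut, got d_min={self.d_min}, d_cut={self.d_cut}"
            )


@dataclass(frozen=True)
class RuleConfig:
    """Full rule set for the annotator.

    ``vdw`` is special-cased: its window is defined relative to the sum of the
    two atoms' van der Waals radii (``sum - vdw_slack`` to ``sum + vdw_slack``),
    and by default a residue-atom cell already explained by a more specific
    interaction type is excluded from the vdW map (``vdw_fallback_only``).
    """

    hbond: TypeRule = field(default_factory=lambda: TypeRule(2.5, 3.5, angle_min=120.0))
    salt_bridge: TypeRule = field(default_factory=lambda: TypeRule(3.0, 5.5))
    hydrophobic: TypeRule = field(default_factory=lambda: TypeRule(3.3, 4.0))
    pipi: TypeRule = field(default_factory=lambda: TypeRule(3.5, 5.5, angle_min=30.0, angle_max=60.0))
    cation_pi: TypeRule = field(default_factory=lambda: TypeRule(3.5, 6.0))
    vdw_slack: float = 0.5
    vdw_fallback_only: bool = True
    his_is_cationic: bool = True
    floor: float = STRENGTH_FLOOR

    def window(self, itype: str, radius_a: float = 0.0, radius_b: float = 0.0) -> tuple[float, float]:
        """Distance window (d_min, d_cut) for ``itype``; vdW needs the two radii."""
        if itype == "vdw":
            s = radius_a + radius_b
            return max(s - self.vdw_slack, 0.1), s + self.vdw_slack
        rule: TypeRule = getattr(self, itype)
        return rule.d_min, rule.d_cut

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "RuleConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            kwargs[f.name] = TypeRule(**v) if isinstance(v, dict) else v
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path) -> "RuleConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def decay_strength(d: float, d_min: float, d_cut: float, floor: float = STRENGTH_FLOOR) -> float:
    """Piecewise-linear distance-to-strength decay.

    Returns 1 for ``d <= d_min``, ``floor`` exactly at ``d_cut``, a linear
    interpolation in between, and 0 beyond the cutoff (no contact).
    """
    if d < 0:
        raise ValueError(f"distance must be non-negative, got {d}")
    if not d_min < d_cut:
        raise ValueError("require d_min < d_cut")
    if d > d_cut:
        return 0.0
    if d <= d_min:
        return 1.0
    return 1.0 + (d - d_min) * (floor - 1.0) / (d_cut - d_min)


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW_RADIUS)
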