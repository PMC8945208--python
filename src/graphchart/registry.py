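"""Substructure vocabulary for barcode-like timelines.

A fetal cardiac screening sweep is summarised per frame by which of 18
anatomical substructures an upstream object detector found.  The registry
fixes the channel order used everywhere downstream (file columns are
canonicalised to it on load) and partitions the channels into the three
groups the cascade encoder operates on:

* ``vessels`` — the 4 great-vessel substructures (three-vessel trachea view),
* ``heart`` — the 8 intracardiac substructures (four-chamber view),
* ``others`` — the remaining 6 landmark structures.

It also carries the plane-visibility table: which channels are visible in an
ideally acquired four-chamber view (4CV) and three-vessel trachea view
(3VTV).  These sets drive both the synthesised view-proxy inputs and the
sweep simulator, and can be overridden from a YAML/JSON config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "SubstructureRegistry",
    "default_registry",
    "DEFAULT_CHANNELS",
    "DEFAULT_GROUPS",
    "DEFAULT_PLANE_VISIBILITY",
    "ABDOMINAL_VISIBILITY",
]

#: Canonical channel order (crux ... ductus arteriosus).
DEFAULT_CHANNELS: tuple[str, ...] = (
    "crux",
    "ventricular septum",
    "right atrium",
    "tricuspid valve",
    "right ventricle",
    "left atrium",
    "mitral valve",
    "left ventricle",
    "pulmonary artery",
    "ascending aorta",
    "superior vena cava",
    "descending aorta",
    "stomach",
    "spine",
    "umbilical vein",
    "inferior vena cava",
    "pulmonary vein",
    "ductus arteriosus",
)

DEFAULT_GROUPS: dict[str, str] = {
    "crux": "heart",
    "ventricular septum": "heart",
    "right atrium": "heart",
    "tricuspid valve": "heart",
    "right ventricle": "heart",
    "left atrium": "heart",
    "mitral valve": "heart",
    "left ventricle": "heart",
    "pulmonary artery": "vessels",
    "ascending aorta": "vessels",
    "superior vena cava": "vessels",
    "ductus arteriosus": "vessels",
    "descending aorta": "others",
    "stomach": "others",
    "spine": "others",
    "umbilical vein": "others",
    "inferior vena cava": "others",
    "pulmonary vein": "others",
}

#: Channels visible in an ideal acquisition of each diagnostic plane.  The
#: 4CV shows the full intracardiac anatomy with the descending aorta and
#: spine as posterior landmarks; the 3VTV shows the great vessels with the
#: same landmarks.
DEFAULT_PLANE_VISIBILITY: dict[str, frozenset[str]] = {
    "FOUR_CV": frozenset(
        [c for c, g in DEFAULT_GROUPS.items() if g == "heart"]
        + ["descending aorta", "spine"]
    ),
    "THREE_VTV": frozenset(
        [c for c, g in DEFAULT_GROUPS.items() if g == "vessels"]
        + ["descending aorta", "spine"]
    ),
}

#: Channels visible at the abdominal start of the sweep (stomach plane).
ABDOMINAL_VISIBILITY: frozenset[str] = frozenset(
    ["stomach", "spine", "umbilical vein", "descending aorta", "inferior vena cava"]
)

_GROUP_SIZES = {"vessels": 4, "heart": 8, "others": 6}


@dataclass(frozen=True)
class SubstructureRegistry:
    """Ordered 18-channel vocabulary with its vessels/heart/others partition."""

    names: tuple[str, ...] = DEFAULT_CHANNELS
    groups: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    plane_visibility: dict[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_PLANE_VISIBILITY)
    )

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(names) != 18 or len(set(names)) != 18:
            raise ValueError(f"registry needs 18 unique channels, got {len(names)}")
        if set(self.groups) != set(names):
            raise ValueError("group assignment must cover exactly the channel set")
        for group, size in _GROUP_SIZES.items():
            members = [n for n in names if self.groups[n] == group]
            if len(members) != size:
                raise ValueError(
                    f"group {group!r} must have {size} members, got {len(members)}"
                )
        unknown = set(self.groups.values()) - set(_GROUP_SIZES)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        for plane, visible in self.plane_visibility.items():
            extra = set(visible) - set(names)
            if extra:
                raise ValueError(f"plane {plane}: unknown channels {sorted(extra)}")
            object.__setattr__(
                self,
                "plane_visibility",
                {**self.plane_visibility, plane: frozenset(visible)},
            )

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def group_members(self, group: str) -> tuple[str, ...]:
        """Channels of ``group`` in registry order."""
        return tuple(n for n in self.names if self.groups[n] == group)

    def group_indices(self, group: str) -> tuple[int, ...]:
        return tuple(i for i, n in enumerate(self.names) if self.groups[n] == group)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def visibility_indices(self, plane: str) -> tuple[int, ...]:
        try:
            visible = self.plane_visibility[plane]
        except KeyError:
            raise ValueError(f"unknown plane {plane!r}") from None
        return tuple(i for i, n in enumerate(self.names) if n in visible)

    @classmethod
    def from_config(cls, path: str | Path) -> "SubstructureRegistry":
        """Load a registry (channel order, groups, plane sets) from YAML/JSON."""
        with open(path, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
        return cls(
            names=tuple(cfg["names"]),
            groups=dict(cfg["groups"]),
            plane_visibility={
                k: frozenset(v) for k, v in cfg.get("plane_visibility", {}).items()
            }
            or dict(DEFAULT_PLANE_VISIBILITY),
        )

    def to_config(self, path: str | Path) -> None:
        cfg = {
            "names": list(self.names),
            "groups": dict(self.groups),
            "plane_visibility": {k: sorted(v) for k, v in self.plane_visibility.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=False)


def default_registry() -> SubstructureRegistry:
    """The standard 18-channel registry with the 4/8/6 group partition."""
    return SubstructureRegistry()
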