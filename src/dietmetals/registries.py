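"""Component registries for diet scoring.

Two small config-backed registries drive the dietary scoring stage:

* :class:`DIIWeightRegistry` — the 24 dietary components entering the adapted
  dietary inflammatory index, each with a signed inflammatory weight and a
  flag saying whether the intake is energy-adjusted (expressed per 1000 kcal)
  before standardization.
* :class:`ServingRegistry` — a food-code vocabulary mapping coded fruit and
  vegetable records to guideline serving sizes; codes marked ``excluded``
  (fruit-containing sweets and similar) contribute zero servings.

Both ship with editable YAML defaults under ``dietmetals/data``. The default
inflammatory weights are synthetic placeholders with plausible signs; the
registry format lets users substitute literature-derived weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "DIIComponent",
    "DIIWeightRegistry",
    "ServingEntry",
    "ServingRegistry",
]


def _packaged(name: str) -> str:
    return (resources.files("dietmetals") / "data" / name).read_text()


@dataclass(frozen=True)
class DIIComponent:
    """One dietary component of the inflammatory index."""

    name: str
    weight: float
    energy_adjust: bool = True
    unit: str = ""


class DIIWeightRegistry:
    """Ordered registry of dietary components and inflammatory weights.

    Weights are oriented so that a positive contribution to the total score
    is anti-inflammatory, matching the adapted-index sign convention in which
    a positive score indicates an anti-inflammatory diet.
    """

    def __init__(self, components: Iterable[DIIComponent]):
        components = tuple(components)
        names = [c.name for c in components]
        if len(set(names)) != len(names):
            raise ValueError("component names must be unique")
        if not components:
            raise ValueError("registry needs at least one component")
        for c in components:
            if not np.isfinite(c.weight):
                raise ValueError(f"non-finite weight for component {c.name!r}")
        self.components = components

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.components]

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components], dtype=float)

    @property
    def energy_adjust_mask(self) -> np.ndarray:
        return np.array([c.energy_adjust for c in self.components], dtype=bool)

    def __len__(self) -> int:
        return len(self.components)

    def __iter__(self):
        return iter(self.components)

    @classmethod
    def from_mapping(cls, payload: Mapping) -> "DIIWeightRegistry":
        comps = [
            DIIComponent(
                name=str(c["name"]),
                weight=float(c["weight"]),
                energy_adjust=bool(c.get("energy_adjust", True)),
                unit=str(c.get("unit", "")),
            )
            for c in payload["components"]
        ]
        return cls(comps)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DIIWeightRegistry":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "DIIWeightRegistry":
        """The packaged 24-component registry (synthetic placeholder weights)."""
        return cls.from_mapping(yaml.safe_load(_packaged("dii_weights.yaml")))

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "components": [
                {
                    "name": c.name,
                    "weight": float(c.weight),
                    "energy_adjust": bool(c.energy_adjust),
                    "unit": c.unit,
                }
                for c in self.components
            ]
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


@dataclass(frozen=True)
class ServingEntry:
    code: str
    group: str  # fruit | vegetable | excluded
    serving_size_g: float | None
    label: str = ""


class ServingRegistry:
    """Food-code → (group, serving size) lookup for fruit/vegetable records."""

    GROUPS = ("fruit", "vegetable", "excluded")

    def __init__(self, entries: Iterable[ServingEntry]):
        self._entries: dict[str, ServingEntry] = {}
        for e in entries:
            if e.group not in self.GROUPS:
                raise ValueError(f"unknown group {e.group!r} for code {e.code!r}")
            if e.group != "excluded":
                if e.serving_size_g is None or e.serving_size_g <= 0:
                    raise ValueError(f"code {e.code!r}: fruit/vegetable serving size must be positive")
            if e.code in self._entries:
                raise ValueError(f"duplicate food code {e.code!r}")
            self._entries[e.code] = e

    def __contains__(self, code: str) -> bool:
        return str(code) in self._entries

    def __getitem__(self, code: str) -> ServingEntry:
        return self._entries[str(code)]

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def entries(self) -> dict[str, ServingEntry]:
        return dict(self._entries)

    def codes(self, group: str | None = None) -> list[str]:
        if group is None:
            return list(self._entries)
        return [c for c, e in self._entries.items() if e.group == group]

    @classmethod
    def from_mapping(cls, payload: Mapping) -> "ServingRegistry":
        entries = []
        for code, spec in payload["codes"].items():
            size = spec.get("serving_size_g")
            entries.append(
                ServingEntry(
                    code=str(code),
                    group=str(spec["group"]),
                    serving_size_g=None if size is None else float(size),
                    label=str(spec.get("label", "")),
                )
            )
        return cls(entries)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ServingRegistry":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "ServingRegistry":
        """The packaged synthetic food-code vocabulary."""
        return cls.from_mapping(yaml.safe_load(_packaged("fv_servings.yaml")))

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "codes": {
                c: {
                    "group": e.group,
                    "serving_size_g": e.serving_size_g,
                    "label": e.label,
                }
                for c, e in self._entries.items()
            }
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
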