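"""Attribute metadata: names, display labels and valence.

The analysis treats every attribute as "higher is worse".  Attributes
measured in the opposite direction (e.g. well-being, social support) carry
``higher_is_worse=False`` and are reverse-coded during preprocessing so
that the networks are interpretable on a common valence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import yaml

__all__ = ["Attribute", "AttributeSchema", "default_schema"]


@dataclass(frozen=True)
class Attribute:
    name: str
    label: str = ""
    higher_is_worse: bool = True
    group_hint: Optional[str] = None  # cosmetic only, never used in analysis

    def __post_init__(self):
        if not self.name:
            raise ValueError("attribute name must be non-empty")
        if not self.label:
            object.__setattr__(self, "label", self.name)


@dataclass(frozen=True)
class AttributeSchema:
    """Ordered collection of :class:`Attribute` with unique names."""

    attributes: tuple[Attribute, ...] = field(default_factory=tuple)

    def __post_init__(self):
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate attribute names: {dupes}")

    @classmethod
    def from_attributes(cls, attrs: Iterable[Attribute | dict]) -> "AttributeSchema":
        converted = tuple(
            a if isinstance(a, Attribute) else Attribute(**a) for a in attrs
        )
        return cls(converted)

    @classmethod
    def from_names(cls, names: Iterable[str]) -> "AttributeSchema":
        """All-default schema (everything higher-is-worse) for quick use."""
        return cls(tuple(Attribute(n) for n in names))

    @classmethod
    def from_file(cls, path) -> "AttributeSchema":
        """Load from YAML or JSON: a list of attribute mappings, optionally
        under a top-level ``attributes`` key."""
        text = Path(path).read_text()
        data = (
            json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        )
        if isinstance(data, dict):
            data = data.get("attributes", data)
        if not isinstance(data, list):
            raise ValueError("schema file must contain a list of attributes")
        return cls.from_attributes(data)

    def to_file(self, path) -> None:
        payload = {
            "attributes": [
                {
                    "name": a.name,
                    "label": a.label,
                    "higher_is_worse": a.higher_is_worse,
                    **({"group_hint": a.group_hint} if a.group_hint else {}),
                }
                for a in self.attributes
            ]
        }
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(payload, indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(payload, sort_keys=False))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.attributes)

    def __len__(self) -> int:
        return len(self.attributes)

    def __iter__(self) -> Iterator[Attribute]:
        return iter(self.attributes)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __getitem__(self, name: str) -> Attribute:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(name)

    def reversed_names(self) -> tuple[str, ...]:
        """Names of attributes that need reverse coding (higher = better)."""
        return tuple(a.name for a in self.attributes if not a.higher_is_worse)


def default_schema() -> AttributeSchema:
    """The 12-attribute schema of the eating-disorder cohort study.

    Self-efficacy, social support, health-related quality of life,
    well-being, BMI and self-rated health are scored so that higher values
    mean *better* outcomes; they are flagged for reverse coding.  Whether
    self-rated health (a 0-100 "best imaginable health" scale) should be
    reverse-coded is a schema setting, not hard-coded; here it is treated
    like the other health measures.
    """
    return AttributeSchema.from_attributes(
        [
            Attribute("bmi", "BMI", higher_is_worse=False),
            Attribute("social_support", "Social support", higher_is_worse=False),
            Attribute("self_efficacy", "Self-efficacy", higher_is_worse=False),
            Attribute("ed_psychopathology", "ED psychopathology (EDE-Q global)"),
            Attribute("binge_eating", "Objective binge eating"),
            Attribute("vomiting", "Self-induced vomiting"),
            Attribute("laxative_use", "Laxative misuse"),
            Attribute("anxiety", "Anxiety (PHQ-4)"),
            Attribute("depression", "Depression (PHQ-4)"),
            Attribute("well_being", "Well-being (ICECAP-A)", higher_is_worse=False),
            Attribute(
                "quality_of_life",
                "Health-related quality of life (EQ-5D-5L)",
                higher_is_worse=False,
            ),
            Attribute("self_rated_health", "Self-rated health (EQ-VAS)", higher_is_worse=False),
        ]
    )
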