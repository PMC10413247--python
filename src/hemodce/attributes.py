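"""Choice attributes, levels and profile coding.

An :class:`Attribute` is one dimension of a treatment alternative (e.g. annual
bleeding times). Categorical attributes are dummy-coded against a designated
reference level; continuous attributes enter the utility linearly in their
stated units (e.g. inhibitor risk in percentage points). An
:class:`AttributeSet` fixes the column layout of every model matrix in the
package, so the design search, the simulator and the estimators all share one
coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import yaml

__all__ = [
    "Attribute",
    "AttributeSet",
    "Profile",
    "ASC_COLUMN",
    "format_level",
]

#: Name of the alternative-specific constant column (status-quo indicator).
ASC_COLUMN = "ASC"

_CODINGS = ("categorical", "continuous")
_DIRECTIONS = ("higher_better", "lower_better", "none")


def format_level(level) -> str:
    """Render a level value for use in a column name (``4.0`` -> ``"4"``)."""
    if isinstance(level, float) and level == int(level):
        return str(int(level))
    return str(level)


@dataclass(frozen=True)
class Attribute:
    """One choice attribute with its levels and coding.

    Parameters
    ----------
    name : str
        Identifier used in column names.
    coding : {"categorical", "continuous"}
        Categorical levels are dummy-coded against ``reference``; continuous
        levels enter as a single numeric column.
    levels : tuple
        Declared level values (categorical: labels; continuous: numbers,
        strictly increasing).
    reference : level, optional
        Reference level for categorical coding (required for categorical).
    unit : str, optional
        Unit of a continuous attribute (e.g. ``"% points"``).
    direction_hint : {"higher_better", "lower_better", "none"}
        Which direction is unambiguously better; consumed only by the
        dominant-preference diagnostics.
    """

    name: str
    coding: str
    levels: tuple
    reference: object = None
    unit: str | None = None
    direction_hint: str = "none"

    def __post_init__(self):
        object.__setattr__(self, "levels", tuple(self.levels))
        if self.coding not in _CODINGS:
            raise ValueError(f"unknown coding {self.coding!r}")
        if self.direction_hint not in _DIRECTIONS:
            raise ValueError(f"unknown direction_hint {self.direction_hint!r}")
        if len(self.levels) < 2:
            raise ValueError(f"attribute {self.name!r} needs >=2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"attribute {self.name!r} has duplicate levels")
        if self.coding == "categorical":
            if self.reference is None:
                raise ValueError(f"categorical attribute {self.name!r} needs a reference level")
            if self.reference not in self.levels:
                raise ValueError(
                    f"reference {self.reference!r} is not a level of {self.name!r}"
                )
        else:
            vals = [float(v) for v in self.levels]
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError(
                    f"continuous attribute {self.name!r} needs strictly increasing levels"
                )
            if self.reference is not None:
                raise ValueError("continuous attributes take no reference level")

    @property
    def design_columns(self) -> list[str]:
        """Model-matrix columns contributed by this attribute."""
        if self.coding == "continuous":
            return [self.name]
        return [
            f"{self.name}[{format_level(lv)}]" for lv in self.levels if lv != self.reference
        ]

    def encode(self, level) -> dict[str, float]:
        """Map a level to its model-matrix column values."""
        if level not in self.levels:
            raise ValueError(f"{level!r} is not a level of attribute {self.name!r}")
        if self.coding == "continuous":
            return {self.name: float(level)}
        return {
            col: 1.0 if lv == level else 0.0
            for col, lv in zip(
                self.design_columns, (lv for lv in self.levels if lv != self.reference)
            )
        }

    def level_utility(self, level, coefficients: Mapping[str, float]) -> float:
        """Part-worth utility of ``level`` under ``coefficients`` (reference = 0)."""
        return sum(
            coefficients[col] * val for col, val in self.encode(level).items()
        )

    def preference_rank(self, level) -> float:
        """Rank levels for dominance comparisons (numeric value if numeric,
        else declared position); interpreted through ``direction_hint``."""
        try:
            return float(level)
        except (TypeError, ValueError):
            return float(self.levels.index(level))

    def better_level(self, a, b):
        """Return the better of two levels per ``direction_hint``; ``None`` on tie.

        Raises if the attribute has no stated direction.
        """
        if self.direction_hint == "none":
            raise ValueError(
                f"attribute {self.name!r} has no direction_hint; dominance undefined"
            )
        ra, rb = self.preference_rank(a), self.preference_rank(b)
        if ra == rb:
            return None
        if self.direction_hint == "higher_better":
            return a if ra > rb else b
        return a if ra < rb else b


@dataclass(frozen=True)
class AttributeSet:
    """Ordered collection of attributes; fixes the model-matrix column layout."""

    attributes: tuple[Attribute, ...]

    def __post_init__(self):
        object.__setattr__(self, "attributes", tuple(self.attributes))
        if not self.attributes:
            raise ValueError("empty attribute set")
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate attribute names")

    def __iter__(self) -> Iterator[Attribute]:
        return iter(self.attributes)

    def __len__(self) -> int:
        return len(self.attributes)

    def __getitem__(self, name: str) -> Attribute:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.attributes]

    @property
    def design_columns(self) -> list[str]:
        """Attribute columns in declared order (ASC excluded)."""
        cols: list[str] = []
        for a in self.attributes:
            cols.extend(a.design_columns)
        return cols

    def encode_profile(self, profile: "Profile") -> dict[str, float]:
        row: dict[str, float] = {}
        for a in self.attributes:
            row.update(a.encode(profile.levels[a.name]))
        return row

    def encode_profile_array(self, profile: "Profile") -> np.ndarray:
        row = self.encode_profile(profile)
        return np.array([row[c] for c in self.design_columns], dtype=float)

    # ---- configuration I/O -------------------------------------------------

    def to_yaml(self, path) -> None:
        payload = {
            "attributes": [
                {
                    "name": a.name,
                    "coding": a.coding,
                    "levels": list(a.levels),
                    **({"reference": a.reference} if a.reference is not None else {}),
                    **({"unit": a.unit} if a.unit else {}),
                    "direction_hint": a.direction_hint,
                }
                for a in self.attributes
            ]
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AttributeSet":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        attrs = [
            Attribute(
                name=spec["name"],
                coding=spec["coding"],
                levels=tuple(spec["levels"]),
                reference=spec.get("reference"),
                unit=spec.get("unit"),
                direction_hint=spec.get("direction_hint", "none"),
            )
            for spec in payload["attributes"]
        ]
        return cls(tuple(attrs))


@dataclass(frozen=True)
class Profile:
    """A full assignment of one level per attribute (one designed alternative)."""

    levels: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "levels", dict(self.levels))

    @staticmethod
    def validate_against(profile: "Profile", attribute_set: AttributeSet) -> None:
        missing = set(attribute_set.names) - set(profile.levels)
        if missing:
            raise ValueError(f"profile missing attributes: {sorted(missing)}")
        for a in attribute_set:
            if profile.levels[a.name] not in a.levels:
                raise ValueError(
                    f"{profile.levels[a.name]!r} is not a level of {a.name!r}"
                )

    def __hash__(self):
        return hash(tuple(sorted(self.levels.items(), key=lambda kv: kv[0])))

    def __eq__(self, other):
        return isinstance(other, Profile) and dict(self.levels) == dict(other.levels)
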