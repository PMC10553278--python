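"""Attribute/level specifications and profile encoding.

A discrete choice experiment (DCE) describes a service by a small set of
attributes, each taking one of a few levels.  A *profile* is one complete
combination of levels (one hypothetical service).  Categorical attributes
enter the utility function as dummy variables against a reference level
("usual care" by convention); continuous attributes (here: annual cost to
the NHS in euro) enter as a single numeric column so that monetary
trade-offs (willingness-to-accept ratios) are defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AttributeSpec",
    "Profile",
    "InvalidSpecError",
    "coef_names",
    "encode_profile",
    "encode_profiles",
    "validate_profile",
]

#: A profile is a tuple of level indices, one per attribute, in attribute order.
Profile = tuple[int, ...]


class InvalidSpecError(ValueError):
    """Raised for malformed attribute specifications or profiles."""


@dataclass(frozen=True)
class AttributeSpec:
    """One DCE attribute with its ordered levels and coding rule.

    Parameters
    ----------
    name:
        Attribute identifier, e.g. ``"waiting_time"``.
    levels:
        Ordered level labels.  At least two, unique within the attribute.
    coding:
        ``"categorical"`` (dummy coding against ``reference_index``) or
        ``"continuous"`` (a single numeric column taking ``level_values``).
    level_values:
        Numeric value per level; required for continuous attributes
        (e.g. cost levels 0, 30, 51, 76 euro/year).
    reference_index:
        Index of the reference ("usual care") level for categorical coding.
    """

    name: str
    levels: tuple[str, ...]
    coding: str = "categorical"
    level_values: tuple[float, ...] | None = None
    reference_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        if self.level_values is not None:
            object.__setattr__(self, "level_values", tuple(float(v) for v in self.level_values))
        if len(self.levels) < 2:
            raise InvalidSpecError(f"attribute {self.name!r} needs >=2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise InvalidSpecError(f"attribute {self.name!r} has duplicate level labels")
        if self.coding not in ("categorical", "continuous"):
            raise InvalidSpecError(f"attribute {self.name!r}: unknown coding {self.coding!r}")
        if self.coding == "continuous":
            if self.level_values is None or len(self.level_values) != len(self.levels):
                raise InvalidSpecError(
                    f"continuous attribute {self.name!r} needs one numeric value per level"
                )
        if not 0 <= self.reference_index < len(self.levels):
            raise InvalidSpecError(f"attribute {self.name!r}: reference_index out of range")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def column_names(self) -> list[str]:
        """Names of the utility-model columns this attribute contributes."""
        if self.coding == "continuous":
            return [self.name]
        return [
            f"{self.name}:{lab}"
            for i, lab in enumerate(self.levels)
            if i != self.reference_index
        ]

    def encode_level(self, index: int) -> np.ndarray:
        """Covariate sub-vector for one level of this attribute."""
        if not 0 <= index < self.n_levels:
            raise InvalidSpecError(
                f"attribute {self.name!r}: level index {index} outside 0..{self.n_levels - 1}"
            )
        if self.coding == "continuous":
            assert self.level_values is not None
            return np.array([self.level_values[index]], dtype=float)
        out = np.zeros(self.n_levels - 1)
        if index != self.reference_index:
            pos = index if index < self.reference_index else index - 1
            out[pos] = 1.0
        return out

    def to_dict(self) -> dict:
        d: dict = {"name": self.name, "levels": list(self.levels), "coding": self.coding}
        if self.level_values is not None:
            d["level_values"] = list(self.level_values)
        if self.coding == "categorical":
            d["reference_index"] = self.reference_index
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AttributeSpec":
        return cls(
            name=d["name"],
            levels=tuple(d["levels"]),
            coding=d.get("coding", "categorical"),
            level_values=tuple(d["level_values"]) if d.get("level_values") is not None else None,
            reference_index=int(d.get("reference_index", 0)),
        )


def validate_profile(profile: Sequence[int], attrs: Sequence[AttributeSpec]) -> Profile:
    """Check a profile against an attribute list and return it as a tuple."""
    prof = tuple(int(i) for i in profile)
    if len(prof) != len(attrs):
        raise InvalidSpecError(
            f"profile has {len(prof)} entries for {len(attrs)} attributes"
        )
    for idx, attr in zip(prof, attrs):
        if not 0 <= idx < attr.n_levels:
            raise InvalidSpecError(
                f"level index {idx} invalid for attribute {attr.name!r}"
            )
    return prof


def coef_names(attrs: Sequence[AttributeSpec]) -> list[str]:
    """Column order of the encoded design matrix: attribute order, then level order."""
    names: list[str] = []
    for a in attrs:
        names.extend(a.column_names())
    return names


def encode_profile(profile: Sequence[int], attrs: Sequence[AttributeSpec]) -> np.ndarray:
    """Encode one profile into the utility-model covariate vector.

    Categorical attributes become 0/1 dummies (reference level encodes to all
    zeros); continuous attributes contribute their level's numeric value.
    """
    prof = validate_profile(profile, attrs)
    return np.concatenate([a.encode_level(i) for i, a in zip(prof, attrs)])


def encode_profiles(profiles: Iterable[Sequence[int]], attrs: Sequence[AttributeSpec]) -> np.ndarray:
    """Encode many profiles into a (n, p) design matrix."""
    rows = [encode_profile(p, attrs) for p in profiles]
    if not rows:
        return np.empty((0, len(coef_names(attrs))))
    return np.vstack(rows)
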