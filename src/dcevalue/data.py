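"""Long-format choice observations: validation, encoding, persistence, QC.

One :class:`ChoiceObservation` is one row of the long format — a single
alternative shown to a single respondent in a single choice set, with a flag
marking whether it was the chosen one.  A complete two-alternative task
therefore spans two rows, exactly one of them chosen (forced choice, no
opt-out).

The quality-control step screens for *dominant responders*: respondents who
always picked the alternative carrying the best level of one particular
attribute, i.e. who traded on a single attribute.  Such non-trading
behaviour can bias conditional-logit estimates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .attributes import AttributeSpec, Profile, coef_names, encode_profile, validate_profile

__all__ = [
    "ChoiceObservation",
    "ChoiceValidationError",
    "GROUPS",
    "best_levels",
    "detect_dominant_responders",
    "encode_design_matrix",
    "observations_to_frame",
    "read_choices",
    "validate_observations",
    "write_choices",
]

GROUPS = ("intervention", "control")


class ChoiceValidationError(ValueError):
    """Raised when choice observations violate the long-format invariants."""


@dataclass(frozen=True)
class ChoiceObservation:
    """One alternative presented to one respondent in one choice set."""

    respondent_id: str
    group: str
    set_id: int
    alternative: str  # "A" or "B"
    profile: Profile
    chosen: bool
    block: int = 0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ChoiceValidationError(
                f"unknown group {self.group!r}; expected one of {GROUPS}"
            )
        if self.alternative not in ("A", "B"):
            raise ChoiceValidationError(f"alternative must be 'A' or 'B', got {self.alternative!r}")
        object.__setattr__(self, "profile", tuple(int(i) for i in self.profile))


def validate_observations(
    obs: Sequence[ChoiceObservation], attrs: Sequence[AttributeSpec] | None = None
) -> None:
    """Enforce the long-format invariants.

    Within each (respondent, set): exactly two alternatives (A and B) and
    exactly one chosen.  Group must be constant within a respondent.  With
    ``attrs`` given, every profile is checked against the attribute space.
    """
    tasks: dict[tuple[str, int], list[ChoiceObservation]] = {}
    group_of: dict[str, str] = {}
    for i, o in enumerate(obs):
        if attrs is not None:
            try:
                validate_profile(o.profile, attrs)
            except ValueError as exc:
                raise ChoiceValidationError(f"row {i}: {exc}") from exc
        prev = group_of.setdefault(o.respondent_id, o.group)
        if prev != o.group:
            raise ChoiceValidationError(
                f"respondent {o.respondent_id!r} appears in both groups"
            )
        tasks.setdefault((o.respondent_id, o.set_id), []).append(o)
    for (rid, sid), rows in tasks.items():
        alts = sorted(r.alternative for r in rows)
        if alts != ["A", "B"]:
            raise ChoiceValidationError(
                f"respondent {rid!r} set {sid}: expected alternatives A and B, got {alts}"
            )
        n_chosen = sum(r.chosen for r in rows)
        if n_chosen != 1:
            raise ChoiceValidationError(
                f"respondent {rid!r} set {sid}: {n_chosen} alternatives chosen (need exactly 1)"
            )


def encode_design_matrix(
    obs: Sequence[ChoiceObservation], attrs: Sequence[AttributeSpec]
) -> pd.DataFrame:
    """Dummy-code observations into the analysis design matrix.

    Returns one row per alternative with ``respondent_id``, ``set_id``,
    ``chosen`` and one numeric column per utility coefficient (dummies for
    non-reference categorical levels in attribute order, a single numeric
    column per continuous attribute).
    """
    validate_observations(obs, attrs)
    names = coef_names(attrs)
    records = []
    for o in obs:
        x = encode_profile(o.profile, attrs)
        rec = {"respondent_id": o.respondent_id, "set_id": o.set_id, "chosen": o.chosen}
        rec.update(zip(names, x))
        records.append(rec)
    df = pd.DataFrame.from_records(records)
    return df[["respondent_id", "set_id", "chosen", *names]]


def observations_to_frame(
    obs: Sequence[ChoiceObservation], attrs: Sequence[AttributeSpec]
) -> pd.DataFrame:
    rows = []
    for o in obs:
        row = {
            "respondent_id": o.respondent_id,
            "group": o.group,
            "set_id": o.set_id,
            "block": o.block,
            "alternative": o.alternative,
        }
        for a, idx in zip(attrs, o.profile):
            row[a.name] = idx
        row["chosen"] = int(o.chosen)
        rows.append(row)
    return pd.DataFrame(rows)


def write_choices(
    obs: Sequence[ChoiceObservation], attrs: Sequence[AttributeSpec], path: str | Path
) -> None:
    """Write observations as long-format CSV (UTF-8, header row)."""
    validate_observations(obs, attrs)
    observations_to_frame(obs, attrs).to_csv(path, index=False)


def read_choices(path: str | Path, attrs: Sequence[AttributeSpec]) -> list[ChoiceObservation]:
    """Read and validate long-format choice CSV written by :func:`write_choices`."""
    path = Path(path)
    required = {"respondent_id", "group", "set_id", "alternative", "chosen"}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            missing = sorted(required - set(reader.fieldnames or []))
            raise ChoiceValidationError(f"{path}: missing columns {missing}")
        obs: list[ChoiceObservation] = []
        seen: set[tuple[str, int, str]] = set()
        for lineno, row in enumerate(reader, start=2):
            try:
                chosen_raw = row["chosen"].strip()
                if chosen_raw not in ("0", "1"):
                    raise ValueError(f"chosen flag must be 0 or 1, got {chosen_raw!r}")
                profile = validate_profile(
                    [int(row[a.name]) for a in attrs], attrs
                )
                o = ChoiceObservation(
                    respondent_id=row["respondent_id"],
                    group=row["group"],
                    set_id=int(row["set_id"]),
                    alternative=row["alternative"],
                    profile=profile,
                    chosen=chosen_raw == "1",
                    block=int(row.get("block", 0) or 0),
                )
            except (KeyError, ValueError) as exc:
                raise ChoiceValidationError(f"{path}: row {lineno}: {exc}") from exc
            key = (o.respondent_id, o.set_id, o.alternative)
            if key in seen:
                raise ChoiceValidationError(
                    f"{path}: row {lineno}: duplicate (respondent, set, alternative) {key}"
                )
            seen.add(key)
            obs.append(o)
    validate_observations(obs, attrs)
    return obs


def best_levels(attrs: Sequence[AttributeSpec]) -> dict[str, int]:
    """Default "best level" per attribute for dominance screening.

    Highest-index level for categorical attributes (levels are ordered from
    usual care upward), and the level with the smallest numeric value for
    continuous cost (least cost to the NHS).
    """
    out: dict[str, int] = {}
    for a in attrs:
        if a.coding == "continuous":
            out[a.name] = int(np.argmin(a.level_values))
        else:
            out[a.name] = a.n_levels - 1
    return out


def detect_dominant_responders(
    obs: Sequence[ChoiceObservation],
    attrs: Sequence[AttributeSpec],
    best: Mapping[str, int] | None = None,
) -> dict[str, list[str]]:
    """Find respondents whose choices are dominated by a single attribute.

    For each attribute, a respondent is flagged when, in every choice set
    where exactly one alternative carried the attribute's best level, they
    chose that alternative.  Sets where both or neither alternative carries
    the best level are uninformative and skipped; respondents with zero
    informative sets are not flagged.
    """
    validate_observations(obs, attrs)
    if best is None:
        best = best_levels(attrs)
    tasks: dict[tuple[str, int], dict[str, ChoiceObservation]] = {}
    for o in obs:
        tasks.setdefault((o.respondent_id, o.set_id), {})[o.alternative] = o
    result: dict[str, list[str]] = {}
    for ai, attr in enumerate(attrs):
        b = best[attr.name]
        informative: dict[str, int] = {}
        consistent: dict[str, bool] = {}
        for (rid, _sid), alts in tasks.items():
            a_best = alts["A"].profile[ai] == b
            b_best = alts["B"].profile[ai] == b
            if a_best == b_best:
                continue  # both or neither carry the best level
            informative[rid] = informative.get(rid, 0) + 1
            chose_best = (alts["A"] if a_best else alts["B"]).chosen
            consistent[rid] = consistent.get(rid, True) and chose_best
        result[attr.name] = sorted(
            rid for rid, ok in consistent.items() if ok and informative[rid] > 0
        )
    return result
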