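"""Synthetic choice data with the exact structure the analysis assumes.

Choices are generated from the random-utility model underlying conditional
logit: each alternative's utility is the linear index ``V = beta . x`` plus
an independent standard Gumbel (type-I extreme value) draw, and the
respondent picks the argmax.  Respondents are randomly assigned to one
questionnaire block and answer every choice set in it, mirroring the trial
exit survey (122 respondents, 78 intervention / 44 control, 4 two-
alternative sets each, drawn from 9 blocks, forced choice).

A configurable fraction of *dominant responders* can be injected per
attribute: their choices are overwritten to always pick the alternative
carrying that attribute's best level whenever the set discriminates on it,
emulating the non-trading behaviour the quality-control screen looks for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .attributes import AttributeSpec, encode_profile
from .data import GROUPS, ChoiceObservation, best_levels
from .design import Design

__all__ = ["SimulationConfig", "inject_dominant_responders", "simulate_choices"]

DEFAULT_COHORT = {"intervention": 78, "control": 44}


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults mirror the trial exit survey conditions."""

    design: Design
    true_beta: Mapping[str, Sequence[float]] | Sequence[float]
    n_respondents: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_COHORT)
    )
    sets_per_respondent: int = 4
    dominant_fraction: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def beta_for(self, group: str) -> np.ndarray:
        if isinstance(self.true_beta, Mapping):
            return np.asarray(self.true_beta[group], dtype=float)
        return np.asarray(self.true_beta, dtype=float)

    def validate(self) -> None:
        if not self.n_respondents or min(self.n_respondents.values()) < 1:
            raise ValueError("each group needs at least one respondent")
        for g in self.n_respondents:
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
        per_block = len(self.design.choice_sets) // self.design.n_blocks
        if not 1 <= self.sets_per_respondent <= per_block:
            raise ValueError(
                f"sets_per_respondent must be in 1..{per_block} (block size)"
            )
        fracs = list(self.dominant_fraction.values())
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) > 1 + 1e-12:
            raise ValueError("dominant fractions must lie in [0,1] and sum to <= 1")
        attr_names = {a.name for a in self.design.attributes}
        unknown = set(self.dominant_fraction) - attr_names
        if unknown:
            raise ValueError(f"dominant_fraction names unknown attributes: {sorted(unknown)}")


def _gumbel(rng: np.random.Generator, size) -> np.ndarray:
    # inverse-CDF: -log(-log(U)) from a seeded uniform stream
    u = rng.uniform(size=size)
    return -np.log(-np.log(u))


def simulate_choices(config: SimulationConfig) -> list[ChoiceObservation]:
    """Draw one synthetic cohort of choice observations.

    Deterministic given ``config.seed``.  Dominant-responder contamination,
    if configured, is applied on top of the Gumbel-choice draws with
    disjoint respondent subsets per attribute.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    attrs = config.design.attributes
    by_block = {
        b: config.design.block(b) for b in range(1, config.design.n_blocks + 1)
    }
    encoded = {
        cs.id: np.vstack([encode_profile(p, attrs) for p in cs.alternatives])
        for cs in config.design.choice_sets
    }
    p = next(iter(encoded.values())).shape[1]
    for group in config.n_respondents:
        if config.beta_for(group).shape != (p,):
            raise ValueError(
                f"true beta for {group!r} has length {len(config.beta_for(group))}, "
                f"encoding has {p} columns"
            )
    obs: list[ChoiceObservation] = []
    counter = 0
    for group in sorted(config.n_respondents):
        beta = config.beta_for(group)
        for _ in range(config.n_respondents[group]):
            counter += 1
            rid = f"r{counter:04d}"
            block = int(rng.integers(1, config.design.n_blocks + 1))
            sets = by_block[block][: config.sets_per_respondent]
            for cs in sets:
                u = encoded[cs.id] @ beta + _gumbel(rng, 2)
                pick = int(np.argmax(u))
                for k, (lab, prof) in enumerate(zip("AB", cs.alternatives)):
                    obs.append(
                        ChoiceObservation(
                            respondent_id=rid,
                            group=group,
                            set_id=cs.id,
                            alternative=lab,
                            profile=prof,
                            chosen=k == pick,
                            block=block,
                        )
                    )
    if config.dominant_fraction:
        # disjoint respondent subsets across attributes, drawn from one shuffle
        respondents = sorted({o.respondent_id for o in obs})
        order = list(rng.permutation(len(respondents)))
        pos = 0
        for attr_name, frac in sorted(config.dominant_fraction.items()):
            k = round(frac * len(respondents))
            chosen_ids = {respondents[i] for i in order[pos : pos + k]}
            pos += k
            obs = _overwrite_dominant(obs, attrs, attr_name, chosen_ids)
    return obs


def _overwrite_dominant(
    obs: list[ChoiceObservation],
    attrs: Sequence[AttributeSpec],
    attribute: str,
    respondents: set[str],
) -> list[ChoiceObservation]:
    names = [a.name for a in attrs]
    if attribute not in names:
        raise ValueError(f"unknown attribute {attribute!r}")
    ai = names.index(attribute)
    best = best_levels(attrs)[attribute]
    tasks: dict[tuple[str, int], list[int]] = {}
    for i, o in enumerate(obs):
        tasks.setdefault((o.respondent_id, o.set_id), []).append(i)
    out = list(obs)
    for (rid, _sid), idxs in tasks.items():
        if rid not in respondents:
            continue
        rows = [obs[i] for i in idxs]
        carries = [r.profile[ai] == best for r in rows]
        if sum(carries) != 1:
            continue  # uninformative set: leave the Gumbel choice in place
        winner = carries.index(True)
        for k, i in enumerate(idxs):
            out[i] = ChoiceObservation(
                respondent_id=rows[k].respondent_id,
                group=rows[k].group,
                set_id=rows[k].set_id,
                alternative=rows[k].alternative,
                profile=rows[k].profile,
                chosen=k == winner,
                block=rows[k].block,
            )
    return out


def inject_dominant_responders(
    obs: Sequence[ChoiceObservation],
    attrs: Sequence[AttributeSpec],
    attribute: str,
    fraction: float,
    seed: int,
) -> list[ChoiceObservation]:
    """Overwrite a random fraction of respondents as single-attribute traders.

    The selected respondents always choose the alternative carrying
    ``attribute``'s best level in every set where exactly one alternative
    does; other sets keep their original choices.  Deterministic given
    ``seed``; ``fraction=0`` returns the observations unchanged.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    names = [a.name for a in attrs]
    if attribute not in names:
        raise ValueError(f"unknown attribute {attribute!r}")
    obs = list(obs)
    if fraction == 0:
        return obs
    rng = np.random.default_rng(seed)
    respondents = sorted({o.respondent_id for o in obs})
    k = round(fraction * len(respondents))
    chosen = set(rng.choice(respondents, size=k, replace=False)) if k else set()
    return _overwrite_dominant(obs, attrs, attribute, chosen)
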