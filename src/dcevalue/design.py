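"""Experimental design for two-alternative discrete choice experiments.

Pipeline: enumerate the full factorial profile space, select an efficient
fraction by Fedorov-style exchange under the D-criterion, randomly pair the
selected profiles into two-alternative choice sets, and allocate the sets
into blocks (questionnaire versions).  Also provides the Johnson–Orme
sample-size rule of thumb.

D-efficiency here is the determinant criterion ``|X'X/N|^(1/p)`` on the
design-generation coding of all alternative profiles — an intercept plus
orthonormal main-effect contrasts with every attribute treated as
qualitative — reported *relative* to the same quantity for the ideal
level-balanced orthogonal design on the same attribute space (attributes
mutually independent, levels uniform).  Under this coding the uniform
product design is D-optimal for main effects, so relative efficiency lies
in (0, 1] and a design whose coded matrix reproduces the ideal moments
exactly scores 1.0.  (The analysis model's dummy/continuous coding is *not*
used for efficiency: the uniform ideal is not D-optimal under dummy coding,
which would let relative "efficiency" exceed 1.)
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .attributes import (
    AttributeSpec,
    InvalidSpecError,
    Profile,
    validate_profile,
)

__all__ = [
    "ChoiceSetDef",
    "Design",
    "SingularDesignError",
    "block_design",
    "count_pairwise_choice_sets",
    "d_efficiency",
    "enumerate_full_factorial",
    "load_design",
    "min_sample_size",
    "pair_profiles",
    "save_design",
    "search_fractional_design",
]


class SingularDesignError(ValueError):
    """Raised when a design's coded matrix is rank deficient."""


@dataclass(frozen=True)
class ChoiceSetDef:
    """One two-alternative choice task (profiles A and B) with a block label."""

    id: int
    block: int
    alternatives: tuple[Profile, Profile]

    def __post_init__(self) -> None:
        if len(self.alternatives) != 2:
            raise InvalidSpecError("a choice set holds exactly two alternatives")
        if self.alternatives[0] == self.alternatives[1]:
            raise InvalidSpecError(f"choice set {self.id}: identical alternative profiles")


@dataclass(frozen=True)
class Design:
    """A blocked two-alternative choice design with its D-efficiency score."""

    attributes: tuple[AttributeSpec, ...]
    choice_sets: tuple[ChoiceSetDef, ...]
    n_blocks: int
    d_efficiency: float
    seed: int
    search_log: tuple[float, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "attributes", tuple(self.attributes))
        object.__setattr__(self, "choice_sets", tuple(self.choice_sets))
        object.__setattr__(self, "search_log", tuple(self.search_log))
        counts: dict[int, int] = {}
        for cs in self.choice_sets:
            counts[cs.block] = counts.get(cs.block, 0) + 1
        if self.choice_sets:
            if len(counts) != self.n_blocks or len(set(counts.values())) != 1:
                raise InvalidSpecError("blocks must be non-empty and equal sized")
        if not 0.0 < self.d_efficiency <= 1.0 + 1e-9:
            raise InvalidSpecError("d_efficiency must lie in (0, 1]")

    @property
    def profiles(self) -> list[Profile]:
        """All alternative profiles, two per choice set, in set order."""
        out: list[Profile] = []
        for cs in self.choice_sets:
            out.extend(cs.alternatives)
        return out

    def block(self, b: int) -> list[ChoiceSetDef]:
        return [cs for cs in self.choice_sets if cs.block == b]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cs in self.choice_sets:
            for lab, prof in zip("AB", cs.alternatives):
                row = {"set_id": cs.id, "block": cs.block, "alternative": lab}
                for attr, idx in zip(self.attributes, prof):
                    row[attr.name] = idx
                rows.append(row)
        return pd.DataFrame(rows)


def enumerate_full_factorial(attrs: Sequence[AttributeSpec]) -> list[Profile]:
    """Cartesian product of level indices over the attribute list."""
    if not attrs:
        raise InvalidSpecError("attribute list is empty")
    for a in attrs:
        if a.n_levels < 2:  # AttributeSpec enforces this, but be explicit
            raise InvalidSpecError(f"attribute {a.name!r} has <2 levels")
    return [tuple(p) for p in itertools.product(*(range(a.n_levels) for a in attrs))]


def count_pairwise_choice_sets(n_profiles: int) -> int:
    """Number of unordered two-alternative choice sets over ``n_profiles``."""
    if n_profiles < 2:
        raise ValueError("need at least 2 profiles to form a pair")
    return n_profiles * (n_profiles - 1) // 2


def min_sample_size(c: int, t: int, a: int) -> int:
    """Johnson–Orme rule-of-thumb minimum respondents: N = ceil(500c/(t*a)).

    ``c`` is the largest number of levels of any attribute, ``t`` the choice
    tasks per respondent, ``a`` the alternatives per task.
    """
    if c <= 0 or t <= 0 or a <= 0:
        raise ValueError("c, t and a must all be positive")
    return math.ceil(500 * c / (t * a))


# --------------------------------------------------------------------------
# D-efficiency


def _contrast_matrix(n_levels: int) -> np.ndarray:
    """Orthonormal main-effect contrasts for a qualitative factor.

    Returns an (L, L-1) matrix with columns orthonormal and orthogonal to
    the all-ones vector (Helmert contrasts, normalized).
    """
    H = np.zeros((n_levels, n_levels - 1))
    for j in range(1, n_levels):
        H[:j, j - 1] = 1.0
        H[j, j - 1] = -j
    return H / np.linalg.norm(H, axis=0)


def design_coding_names(attrs: Sequence[AttributeSpec]) -> list[str]:
    names = ["intercept"]
    for a in attrs:
        names.extend(f"{a.name}.c{k + 1}" for k in range(a.n_levels - 1))
    return names


def design_code_profiles(
    profiles: Sequence[Profile], attrs: Sequence[AttributeSpec]
) -> np.ndarray:
    """Intercept + orthonormal-contrast model matrix, all attributes qualitative."""
    contrasts = [_contrast_matrix(a.n_levels) for a in attrs]
    rows = []
    for prof in profiles:
        prof = validate_profile(prof, attrs)
        rows.append(
            np.concatenate([[1.0]] + [C[i] for i, C in zip(prof, contrasts)])
        )
    return np.vstack(rows)


def _ideal_moment_matrix(attrs: Sequence[AttributeSpec]) -> np.ndarray:
    """X'X/N of the ideal balanced orthogonal design under the contrast coding.

    Uniform levels make each attribute's contrast block I/L; independence
    and zero-mean contrasts kill all cross terms, so the matrix is diagonal.
    """
    diag = [1.0]
    for a in attrs:
        diag.extend([1.0 / a.n_levels] * (a.n_levels - 1))
    return np.diag(diag)


def _d_criterion(M: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0:
        return 0.0
    return math.exp(logdet / M.shape[0])


def d_efficiency(design: Design | Sequence[Profile], attrs: Sequence[AttributeSpec]) -> float:
    """Relative D-efficiency of a design's alternatives, in (0, 1].

    ``|X'X/N|^(1/p)`` of the contrast-coded alternative rows divided by the
    same criterion for the balanced orthogonal ideal.  Row order does not
    matter.  Raises :class:`SingularDesignError` for rank-deficient coded
    matrices, naming the collinear columns.
    """
    profiles = design.profiles if isinstance(design, Design) else list(design)
    if not profiles:
        raise InvalidSpecError("empty design")
    X = design_code_profiles(profiles, attrs)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        names = design_coding_names(attrs)
        # columns involved in the rank deficiency: near-zero R diagonal in a
        # QR factorization stands in for "drop these to restore full rank"
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [names[j] for j in range(len(names)) if diag[j] <= 1e-10 * max(diag.max(), 1.0)]
        raise SingularDesignError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {bad or names}"
        )
    M = X.T @ X / len(X)
    eff = _d_criterion(M) / _d_criterion(_ideal_moment_matrix(attrs))
    return float(min(eff, 1.0)) if eff < 1.0 + 1e-9 else float(eff)


# --------------------------------------------------------------------------
# Fedorov exchange search


def _exchange_once(
    F: np.ndarray,
    cand: np.ndarray,
    rng: np.random.Generator,
    max_swaps: int,
) -> tuple[np.ndarray, list[float]]:
    """Fedorov exchange on row set ``F`` (n, p) over candidates ``cand``.

    Repeatedly performs the single best row-for-candidate swap while it
    increases det(F'F); returns the improved rows and the log-det trace.
    """
    n = len(F)
    M = F.T @ F
    sign, logdet = np.linalg.slogdet(M)
    log: list[float] = [logdet if sign > 0 else -np.inf]
    for _ in range(max_swaps):
        try:
            Minv = np.linalg.inv(M)
        except np.linalg.LinAlgError:
            break
        d_x = np.einsum("ij,jk,ik->i", F, Minv, F)  # leverage of in-design rows
        d_c = np.einsum("ij,jk,ik->i", cand, Minv, cand)
        G = F @ Minv @ cand.T
        # Fedorov delta: det ratio - 1 for swapping row i with candidate j
        delta = d_c[None, :] - d_x[:, None] - (d_x[:, None] * d_c[None, :] - G**2)
        i, j = np.unravel_index(np.argmax(delta), delta.shape)
        if delta[i, j] <= 1e-10:
            break
        F = F.copy()
        F[i] = cand[j]
        M = F.T @ F
        sign, logdet = np.linalg.slogdet(M)
        log.append(logdet)
    return F, log


def search_fractional_design(
    attrs: Sequence[AttributeSpec],
    n_sets: int,
    n_blocks: int,
    seed: int,
    *,
    n_restarts: int = 10,
    max_swaps: int = 10_000,
    paired_fractions: bool = False,
) -> Design:
    """Search for an efficient fraction and assemble a blocked choice design.

    By default selects ``2*n_sets`` profiles in one exchange run and randomly
    pairs them into sets; with ``paired_fractions=True`` two fractions of
    ``n_sets`` profiles are selected independently and paired A-against-B.
    Deterministic given ``seed``.
    """
    if n_sets <= 0 or n_blocks <= 0 or n_sets % n_blocks:
        raise ValueError("n_sets must be positive and divisible by n_blocks")
    full = enumerate_full_factorial(attrs)
    if 2 * n_sets > len(full):
        raise ValueError(
            f"cannot draw {2 * n_sets} alternatives from {len(full)} profiles"
        )
    cand = design_code_profiles(full, attrs)
    rng = np.random.default_rng(seed)

    def _search_rows(n_rows: int) -> tuple[list[int], list[float]]:
        best_idx: list[int] | None = None
        best_logdet = -np.inf
        best_log: list[float] = []
        for _ in range(n_restarts):
            idx = list(rng.choice(len(full), size=n_rows, replace=False))
            F, log = _exchange_once(cand[idx], cand, rng, max_swaps)
            if log[-1] > best_logdet:
                # recover profile indices by matching rows back to candidates
                best_idx = [
                    int(np.flatnonzero((cand == row).all(axis=1))[0]) for row in F
                ]
                best_logdet = log[-1]
                best_log = log
        assert best_idx is not None
        return best_idx, best_log

    if paired_fractions:
        idx_a, log_a = _search_rows(n_sets)
        idx_b, log_b = _search_rows(n_sets)
        prof_a = [full[i] for i in idx_a]
        prof_b = [full[i] for i in idx_b]
        # avoid pairing identical profiles by rotating B where needed
        order = list(rng.permutation(n_sets))
        prof_b = [prof_b[i] for i in order]
        for k in range(n_sets):
            if prof_a[k] == prof_b[k]:
                swap = next(
                    (
                        m
                        for m in range(n_sets)
                        if m != k and prof_a[k] != prof_b[m] and prof_a[m] != prof_b[k]
                    ),
                    None,
                )
                if swap is None:
                    raise ValueError("could not avoid identical-profile pairs")
                prof_b[k], prof_b[swap] = prof_b[swap], prof_b[k]
        sets = [
            ChoiceSetDef(id=k + 1, block=0, alternatives=(prof_a[k], prof_b[k]))
            for k in range(n_sets)
        ]
        log = log_a + log_b
    else:
        idx, log = _search_rows(2 * n_sets)
        profiles = [full[i] for i in idx]
        sets = pair_profiles(profiles, seed=int(rng.integers(2**31)))
        sets = [replace(cs, id=k + 1) for k, cs in enumerate(sets)]

    design = block_design(sets, n_blocks, seed=int(rng.integers(2**31)), attrs=attrs)
    return replace(design, seed=seed, search_log=tuple(log))


def pair_profiles(profiles: Sequence[Profile], seed: int) -> list[ChoiceSetDef]:
    """Randomly pair profiles (each used once) into two-alternative sets.

    Identical-profile pairs are rejected by re-shuffling; deterministic
    given ``seed``.
    """
    if len(profiles) % 2:
        raise ValueError("need an even number of profiles to pair")
    rng = np.random.default_rng(seed)
    profiles = list(profiles)
    for _ in range(1000):
        order = rng.permutation(len(profiles))
        pairs = [
            (profiles[order[2 * k]], profiles[order[2 * k + 1]])
            for k in range(len(profiles) // 2)
        ]
        if all(a != b for a, b in pairs):
            return [
                ChoiceSetDef(id=k + 1, block=0, alternatives=pair)
                for k, pair in enumerate(pairs)
            ]
    raise ValueError("could not find a pairing without identical-profile pairs")


def block_design(
    sets: Sequence[ChoiceSetDef],
    n_blocks: int,
    seed: int,
    attrs: Sequence[AttributeSpec] | None = None,
) -> Design:
    """Allocate choice sets into equal-sized blocks (questionnaire versions)."""
    if n_blocks <= 0 or len(sets) % n_blocks:
        raise ValueError(
            f"{len(sets)} choice sets cannot be split into {n_blocks} equal blocks"
        )
    per_block = len(sets) // n_blocks
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sets))
    blocked = [
        replace(sets[order[k]], block=k // per_block + 1) for k in range(len(sets))
    ]
    blocked.sort(key=lambda cs: (cs.block, cs.id))
    if attrs is None:
        raise ValueError("attrs required to score the blocked design")
    eff = d_efficiency([p for cs in blocked for p in cs.alternatives], attrs)
    return Design(
        attributes=tuple(attrs),
        choice_sets=tuple(blocked),
        n_blocks=n_blocks,
        d_efficiency=eff,
        seed=seed,
    )


# --------------------------------------------------------------------------
# Persistence: CSV of alternatives + YAML sidecar with attributes and seed


def save_design(design: Design, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    design.to_frame().to_csv(directory / "design.csv", index=False)
    sidecar = {
        "attributes": [a.to_dict() for a in design.attributes],
        "n_blocks": design.n_blocks,
        "d_efficiency": design.d_efficiency,
        "seed": design.seed,
    }
    (directory / "design.yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))


def load_design(directory: str | Path) -> Design:
    directory = Path(directory)
    sidecar = yaml.safe_load((directory / "design.yaml").read_text())
    attrs = tuple(AttributeSpec.from_dict(d) for d in sidecar["attributes"])
    df = pd.read_csv(directory / "design.csv")
    sets = []
    for set_id, g in df.groupby("set_id", sort=True):
        g = g.sort_values("alternative")
        profs = [
            validate_profile([row[a.name] for a in attrs], attrs)
            for _, row in g.iterrows()
        ]
        sets.append(
            ChoiceSetDef(
                id=int(set_id), block=int(g["block"].iloc[0]), alternatives=(profs[0], profs[1])
            )
        )
    sets.sort(key=lambda cs: (cs.block, cs.id))
    return Design(
        attributes=attrs,
        choice_sets=tuple(sets),
        n_blocks=int(sidecar["n_blocks"]),
        d_efficiency=float(sidecar["d_efficiency"]),
        seed=int(sidecar["seed"]),
    )
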