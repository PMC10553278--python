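"""Post-estimation welfare economics for the fitted choice model.

Willingness-to-accept (WTA) for an attribute level is the marginal rate of
substitution between that level and money: the ratio of the level's utility
coefficient to the cost coefficient.  Because the cost attribute is framed
as annual cost *to the NHS* (compensation the public payer would bear), the
study's convention is the plain ratio ``beta_x / beta_cost``; the textbook
``-beta_x / beta_cost`` is available behind ``negate=True``.

Uncertainty for these nonlinear coefficient ratios uses the Krinsky–Robb
parametric bootstrap: coefficient vectors are drawn from a multivariate
normal with the MLE mean and estimated covariance and the ratio is
recomputed per draw.  Scenario-level welfare uses the log-sum formula for
compensating variation, and the cost-benefit step reports
``net benefit = total WTA - incremental programme cost``.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy import special

from .attributes import AttributeSpec, Profile, coef_names, encode_profile
from .estimation import EstimationResult

__all__ = [
    "CovarianceError",
    "ScenarioValuation",
    "UndefinedImportanceError",
    "UndefinedWTAError",
    "WTAEstimate",
    "compensating_variation",
    "krinsky_robb_ci",
    "marginal_wta",
    "net_benefit",
    "relative_importance",
    "round_euro",
    "scenario_utility",
    "scenario_valuation",
    "total_scenario_wta",
]

COST = "cost"


class UndefinedWTAError(ZeroDivisionError):
    """WTA ratio undefined because the cost coefficient is zero."""


class UndefinedImportanceError(ValueError):
    """Relative importance undefined (no attribute has a nonzero range)."""


class CovarianceError(ValueError):
    """Coefficient covariance is not positive semi-definite."""


def round_euro(x: float) -> float:
    """Round a euro amount to 2 decimals, half-up (presentation only)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class WTAEstimate:
    """Marginal WTA for one attribute level, in euro per year."""

    level: str
    wta: float
    ci: tuple[float, float] | None = None
    reps: int = 0
    seed: int | None = None
    warning: str | None = None


@dataclass(frozen=True)
class ScenarioValuation:
    """Welfare valuation of moving from a worst to a best service scenario."""

    reference_profile: Profile
    target_profile: Profile
    marginal: tuple[WTAEstimate, ...]
    total_wta: float
    compensating_variation: float
    incremental_cost: float
    net_benefit: float

    def to_dict(self) -> dict:
        return {
            "reference_profile": list(self.reference_profile),
            "target_profile": list(self.target_profile),
            "marginal_wta": {
                m.level: {"wta": m.wta, "ci": list(m.ci) if m.ci else None}
                for m in self.marginal
            },
            "total_wta": self.total_wta,
            "compensating_variation": self.compensating_variation,
            "incremental_cost": self.incremental_cost,
            "net_benefit": self.net_benefit,
        }


def _cost_beta(result: EstimationResult, cost_name: str) -> float:
    if cost_name not in result.names:
        raise KeyError(f"no coefficient named {cost_name!r} in the fitted model")
    b = result[cost_name]
    if b == 0.0:
        raise UndefinedWTAError(
            f"cost coefficient {cost_name!r} is exactly zero; WTA is undefined"
        )
    return b


def _wta_warning(result: EstimationResult, cost_name: str, alpha: float = 0.05) -> str | None:
    try:
        p = result.p_value(cost_name)
    except (ValueError, IndexError):
        return None
    if not np.isfinite(p) or p >= alpha:
        return (
            f"cost coefficient {cost_name!r} is not statistically significant "
            f"(p = {p:.3f}); WTA ratios should be interpreted with caution"
        )
    return None


def marginal_wta(
    result: EstimationResult,
    level: str,
    *,
    cost_name: str = COST,
    negate: bool = False,
    reps: int = 0,
    seed: int | None = None,
    alpha: float = 0.05,
) -> WTAEstimate:
    """Marginal WTA for one attribute level: ``beta_level / beta_cost`` (euro/yr).

    With ``reps > 0`` a Krinsky–Robb percentile CI is attached.
    """
    b_cost = _cost_beta(result, cost_name)
    b = result[level]
    sign = -1.0 if negate else 1.0
    ci = None
    if reps:
        ci = krinsky_robb_ci(
            result, level, reps=reps, seed=0 if seed is None else seed,
            alpha=alpha, cost_name=cost_name, negate=negate,
        )
    return WTAEstimate(
        level=level,
        wta=sign * b / b_cost,
        ci=ci,
        reps=reps,
        seed=seed,
        warning=_wta_warning(result, cost_name),
    )


def _psd_factor(cov: np.ndarray, repair: bool) -> np.ndarray:
    vals, vecs = np.linalg.eigh(np.asarray(cov, dtype=float))
    tol = 1e-10 * max(1.0, float(np.abs(vals).max(initial=0.0)))
    if vals.min(initial=0.0) < -tol and not repair:
        raise CovarianceError(
            "covariance matrix is not positive semi-definite "
            f"(min eigenvalue {vals.min():.3g}); pass repair=True to project "
            "onto the nearest PSD matrix"
        )
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def krinsky_robb_ci(
    result: EstimationResult,
    level: str,
    reps: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    *,
    cost_name: str = COST,
    negate: bool = False,
    repair: bool = False,
) -> tuple[float, float]:
    """Krinsky–Robb percentile CI for the WTA ratio of one level.

    Draws ``reps`` coefficient vectors from N(beta_hat, cov), recomputes the
    ratio per draw, and returns the (alpha/2, 1-alpha/2) percentiles.  Draws
    whose cost coefficient is numerically zero are rejected and redrawn.
    """
    _cost_beta(result, cost_name)  # raises if undefined at the point estimate
    i = result.names.index(level)
    j = result.names.index(cost_name)
    A = _psd_factor(result.cov, repair)
    rng = np.random.default_rng(seed)
    sign = -1.0 if negate else 1.0
    ratios = np.empty(0)
    for _ in range(100):  # redraw until enough non-degenerate cost draws
        z = rng.standard_normal((reps - len(ratios), len(result.beta)))
        draws = result.beta + z @ A.T
        keep = np.abs(draws[:, j]) >= 1e-12
        ratios = np.concatenate([ratios, sign * draws[keep, i] / draws[keep, j]])
        if len(ratios) >= reps:
            break
    lo, hi = np.percentile(ratios[:reps], [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def _attribute_utility_range(
    result: EstimationResult, attr: AttributeSpec
) -> tuple[float, float]:
    """(min, max) utility over the attribute's levels, reference level = 0."""
    cols = attr.column_names()
    utilities = []
    for idx in range(attr.n_levels):
        x = attr.encode_level(idx)
        utilities.append(float(sum(result[c] * v for c, v in zip(cols, x))))
    return min(utilities), max(utilities)


def relative_importance(
    result: EstimationResult,
    attrs: Sequence[AttributeSpec],
    p_threshold: float | None = 0.05,
) -> dict[str, float]:
    """Share of each attribute's utility range in the total range.

    An attribute's range is max minus min level utility (reference = 0).
    Attributes with no level coefficient significant at ``p_threshold`` are
    excluded before computing shares (pass ``None`` to keep all).  Shares
    sum to 1.
    """
    kept: dict[str, float] = {}
    for a in attrs:
        if p_threshold is not None:
            p_min = min(result.p_value(c) for c in a.column_names())
            if p_min >= p_threshold:
                continue
        lo, hi = _attribute_utility_range(result, a)
        kept[a.name] = hi - lo
    total = sum(kept.values())
    if total <= 0:
        raise UndefinedImportanceError("all attribute utility ranges are zero")
    return {name: r / total for name, r in kept.items()}


def scenario_utility(
    beta: Sequence[float] | EstimationResult,
    profile: Profile,
    attrs: Sequence[AttributeSpec],
) -> float:
    """Deterministic utility V = beta . x of one profile."""
    b = beta.beta if isinstance(beta, EstimationResult) else np.asarray(beta, dtype=float)
    x = encode_profile(profile, attrs)
    if b.shape != x.shape:
        raise ValueError(
            f"beta has length {len(b)} but the encoding has {len(x)} columns"
        )
    return float(b @ x)


def total_scenario_wta(
    result: EstimationResult,
    best: Profile,
    worst: Profile,
    attrs: Sequence[AttributeSpec],
    *,
    cost_name: str = COST,
    negate: bool = False,
    reps: int = 0,
    seed: int | None = None,
) -> tuple[float, list[WTAEstimate]]:
    """Total WTA for moving worst -> best: sum of per-attribute marginal WTAs.

    The scenarios may differ on any categorical attribute; each differing
    attribute contributes ``WTA(best level) - WTA(worst level)`` (a
    reference level contributes zero).
    """
    b_cost = _cost_beta(result, cost_name)
    sign = -1.0 if negate else 1.0
    parts: list[WTAEstimate] = []
    total = 0.0
    for ai, a in enumerate(attrs):
        if best[ai] == worst[ai]:
            continue
        if a.coding == "continuous":
            raise UndefinedWTAError(
                f"scenarios differ on the monetary attribute {a.name!r}; "
                "marginal WTA is defined for non-cost attributes only"
            )
        cols = a.column_names()
        ub = float(sum(result[c] * v for c, v in zip(cols, a.encode_level(best[ai]))))
        uw = float(sum(result[c] * v for c, v in zip(cols, a.encode_level(worst[ai]))))
        wta = sign * (ub - uw) / b_cost
        level_name = (
            f"{a.name}:{a.levels[best[ai]]}"
            if worst[ai] == a.reference_index
            else f"{a.name}:{a.levels[worst[ai]]}->{a.levels[best[ai]]}"
        )
        ci = None
        if reps:
            # KR on the utility-difference ratio when the move is from the
            # reference level; general moves reuse the same draw machinery
            if worst[ai] == a.reference_index and level_name in result.names:
                ci = krinsky_robb_ci(
                    result, level_name, reps=reps, seed=0 if seed is None else seed,
                    cost_name=cost_name, negate=negate,
                )
        parts.append(
            WTAEstimate(level=level_name, wta=wta, ci=ci, reps=reps, seed=seed,
                        warning=_wta_warning(result, cost_name))
        )
        total += wta
    return total, parts


def compensating_variation(
    beta: Sequence[float] | EstimationResult,
    scenario0: Sequence[Profile],
    scenario1: Sequence[Profile],
    attrs: Sequence[AttributeSpec],
    *,
    cost_name: str = COST,
) -> float:
    """Log-sum compensating variation between two choice environments.

    ``CV = (1/beta_cost) * [logsumexp(V_j in scenario1) - logsumexp(V_j in
    scenario0)]`` in euro per year.  Each scenario is the list of
    alternatives available in that state.
    """
    if isinstance(beta, EstimationResult):
        b_cost = _cost_beta(beta, cost_name)
        b = beta.beta
    else:
        b = np.asarray(beta, dtype=float)
        names = coef_names(attrs)
        if cost_name not in names:
            raise KeyError(f"no column named {cost_name!r} in the encoding")
        b_cost = float(b[names.index(cost_name)])
        if b_cost == 0.0:
            raise UndefinedWTAError("cost coefficient is zero; CV is undefined")
    v0 = [scenario_utility(b, p, attrs) for p in scenario0]
    v1 = [scenario_utility(b, p, attrs) for p in scenario1]
    return float((special.logsumexp(v1) - special.logsumexp(v0)) / b_cost)


def net_benefit(total_wta: float, incremental_cost: float) -> float:
    """Cost-benefit net benefit: total WTA minus incremental cost (euro/yr)."""
    return total_wta - incremental_cost


def scenario_valuation(
    result: EstimationResult,
    attrs: Sequence[AttributeSpec],
    best: Profile,
    worst: Profile,
    incremental_cost: float,
    *,
    reps: int = 0,
    seed: int | None = None,
) -> ScenarioValuation:
    """Full welfare + CBA summary for a worst -> best scenario move."""
    total, parts = total_scenario_wta(
        result, best, worst, attrs, reps=reps, seed=seed
    )
    cv = compensating_variation(result, [worst], [best], attrs)
    return ScenarioValuation(
        reference_profile=tuple(worst),
        target_profile=tuple(best),
        marginal=tuple(parts),
        total_wta=total,
        compensating_variation=cv,
        incremental_cost=incremental_cost,
        net_benefit=net_benefit(total, incremental_cost),
    )
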