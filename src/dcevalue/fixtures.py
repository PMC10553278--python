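"""Reference fixture: the pharmacy–primary-care collaborative trial DCE.

The fixture reproduces the published valuation inputs of a trial exit
discrete choice experiment on collaborative hypertension/hyperlipidemia
management between community pharmacies and primary care: five service
attributes (waiting time for a medical appointment, model of pharmacy
intervention, integration with primary care, 5-year stroke risk, and annual
cost to the NHS in euro), the conditional-logit coefficient columns reported
for the pooled sample and for the intervention and control arms, the
most/least preferred scenario profiles used for scenario valuation, and the
annual incremental programme cost carried in from the companion costing
study.  The raw individual-level choices were never deposited, so these
published summaries — plus the simulator — are what downstream stages are
exercised against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attributes import AttributeSpec, Profile

__all__ = ["CoefficientTable", "StudyFixture", "result_from_table", "study_fixture"]


@dataclass(frozen=True)
class CoefficientTable:
    """One fitted coefficient column: names, point estimates, p-values."""

    names: tuple[str, ...]
    beta: tuple[float, ...]
    p_values: tuple[float, ...]
    n_individuals: int
    n_observations: int

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.beta))

    def beta_array(self) -> np.ndarray:
        return np.asarray(self.beta, dtype=float)


@dataclass(frozen=True)
class StudyFixture:
    attributes: tuple[AttributeSpec, ...]
    coefficients: dict[str, CoefficientTable]  # keys: all / intervention / control
    best_profile: Profile
    worst_profile: Profile
    incremental_cost: float  # euro per patient per year
    n_choice_sets: int
    n_blocks: int
    lr_chi2: dict[str, float] | None = None  # published full-vs-null chi-square


def study_fixture() -> StudyFixture:
    """Attribute space, published coefficients, scenarios and cost constant."""
    attributes = (
        AttributeSpec(
            name="pharmacy_model",
            levels=("counter_5min", "office_15min_q3m", "office_30min_q6m"),
        ),
        AttributeSpec(
            name="integration",
            levels=("weak", "partial", "full"),
        ),
        AttributeSpec(
            name="waiting_time",
            levels=("7d_45d", "48h_30d", "same_day_15d"),
        ),
        AttributeSpec(
            name="stroke_risk",
            levels=("same", "slightly_lower", "much_lower"),
        ),
        AttributeSpec(
            name="cost",
            levels=("eur0", "eur30", "eur51", "eur76"),
            coding="continuous",
            level_values=(0.0, 30.0, 51.0, 76.0),
        ),
    )
    names = (
        "pharmacy_model:office_15min_q3m",
        "pharmacy_model:office_30min_q6m",
        "integration:partial",
        "integration:full",
        "waiting_time:48h_30d",
        "waiting_time:same_day_15d",
        "stroke_risk:slightly_lower",
        "stroke_risk:much_lower",
        "cost",
    )
    coefficients = {
        "all": CoefficientTable(
            names=names,
            beta=(0.551, 0.888, 0.376, 0.622, 0.381, 1.150, 0.121, 0.067, 0.002),
            p_values=(0.003, 0.000, 0.023, 0.001, 0.022, 0.000, 0.589, 0.712, 0.510),
            n_individuals=122,
            n_observations=976,
        ),
        "intervention": CoefficientTable(
            names=names,
            beta=(0.605, 0.948, 0.417, 0.634, 0.267, 1.049, 0.181, 0.232, 0.003),
            p_values=(0.009, 0.000, 0.043, 0.007, 0.199, 0.000, 0.516, 0.309, 0.514),
            n_individuals=78,
            n_observations=624,
        ),
        "control": CoefficientTable(
            names=names,
            beta=(0.481, 0.792, 0.308, 0.617, 0.585, 1.349, 0.022, -0.220, 0.001),
            p_values=(0.119, 0.026, 0.269, 0.055, 0.038, 0.000, 0.954, 0.463, 0.805),
            n_individuals=44,
            n_observations=352,
        ),
    }
    # Chi-square of the full-vs-null likelihood-ratio test per column, at
    # nine degrees of freedom, as published.
    lr_chi2 = {"all": 101.28, "intervention": 63.66, "control": 40.303}
    # Most vs least preferred service bundle: the scenarios differ on the
    # three attributes with significant preference weights; stroke risk and
    # cost are held at their reference/zero levels.
    best = (2, 2, 2, 0, 0)
    worst = (0, 0, 0, 0, 0)
    return StudyFixture(
        attributes=attributes,
        coefficients=coefficients,
        best_profile=best,
        worst_profile=worst,
        incremental_cost=88.80,
        n_choice_sets=36,
        n_blocks=9,
        lr_chi2=lr_chi2,
    )


def result_from_table(
    table: CoefficientTable, lr_chi2: float | None = None
) -> "EstimationResult":
    """Build an :class:`~dcevalue.estimation.EstimationResult` from a
    published coefficient column.

    Only point estimates and p-values are printed, so the covariance is
    reconstructed as diagonal with standard errors back-solved from the
    two-sided Wald p-values (``se = |beta| / z``, where ``z`` is the normal
    quantile for the printed p; p-values printed as 0.000 are floored at
    0.0005).  This synthetic covariance preserves the printed significance
    calls — enough for WTA point ratios, significance screening and
    scenario valuation — but is not the (unpublished) fitted covariance.
    """
    from scipy import stats

    from .estimation import EstimationResult

    beta = table.beta_array()
    se = np.empty_like(beta)
    for k, (b, p) in enumerate(zip(beta, table.p_values)):
        p_eff = min(max(p, 0.0005), 0.9995)
        z = stats.norm.isf(p_eff / 2)
        se[k] = abs(b) / z if b != 0 else 1.0
    n_sets = table.n_observations // 2
    llnull = -n_sets * np.log(2.0)
    llf = llnull + (lr_chi2 or 0.0) / 2.0
    return EstimationResult(
        names=table.names,
        beta=beta,
        cov=np.diag(se**2),
        llf=llf,
        llnull=llnull,
        lr_stat=2 * (llf - llnull),
        df=len(beta),
        n_individuals=table.n_individuals,
        n_observations=table.n_observations,
    )
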