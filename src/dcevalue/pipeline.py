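"""End-to-end orchestration: design -> data -> fit -> welfare -> CBA.

A :class:`PipelineConfig` (YAML or JSON) drives the full valuation run and
every stage logs its seed, so a rerun with the same config produces
byte-identical machine-readable output.  The report bundle contains a
``results.json``, a human-readable ``report.txt`` with coefficient/WTA and
scenario-valuation tables, and CSV copies of both tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from .attributes import AttributeSpec
from .data import (
    detect_dominant_responders,
    read_choices,
    validate_observations,
    write_choices,
)
from .design import Design, load_design, save_design, search_fractional_design
from .estimation import EstimationResult, fit_clogit, lr_test
from .fixtures import study_fixture
from .simulate import SimulationConfig, simulate_choices
from .welfare import (
    UndefinedImportanceError,
    relative_importance,
    round_euro,
    scenario_valuation,
)

__all__ = ["PipelineConfig", "PipelineError", "load_attributes", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_attributes(source: str | Path | None) -> tuple[AttributeSpec, ...]:
    """Load an attribute list from YAML/JSON, or the built-in study fixture."""
    if source is None or source == "fixture":
        return study_fixture().attributes
    doc = yaml.safe_load(Path(source).read_text())
    return tuple(AttributeSpec.from_dict(d) for d in doc["attributes"])


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative settings for a full valuation run."""

    output_dir: str
    attrs: str | None = None  # path or "fixture"
    choices: str | None = None  # path to CSV; None -> simulate
    design_dir: str | None = None  # load a saved design instead of searching
    n_sets: int = 36
    n_blocks: int = 9
    design_seed: int = 1
    design_restarts: int = 10
    sim_beta: str | Mapping[str, Sequence[float]] = "fixture"
    sim_n_respondents: Mapping[str, int] = field(
        default_factory=lambda: {"intervention": 78, "control": 44}
    )
    sim_sets_per_respondent: int = 4
    sim_dominant_fraction: Mapping[str, float] = field(default_factory=dict)
    sim_seed: int = 2
    groups: tuple[str, ...] = ("all", "intervention", "control")
    bootstrap_reps: int = 0
    estimation_seed: int = 3
    welfare_group: str = "intervention"
    best_profile: tuple[int, ...] | None = None
    worst_profile: tuple[int, ...] | None = None
    kr_reps: int = 1000
    welfare_seed: int = 4
    incremental_cost: float = 88.80
    alpha: float = 0.05

    def validate(self) -> None:
        if self.kr_reps < 2 or (self.bootstrap_reps and self.bootstrap_reps < 2):
            raise ValueError("replication counts must be >= 2")
        if self.welfare_group not in self.groups:
            raise ValueError(
                f"welfare_group {self.welfare_group!r} not among fitted groups"
            )

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("groups", "best_profile", "worst_profile"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["groups"] = list(self.groups)
        for key in ("best_profile", "worst_profile"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _fit_table(results: Mapping[str, EstimationResult], attrs) -> pd.DataFrame:
    rows = []
    for group, res in results.items():
        chi2, df, p = lr_test(res)
        for name, b, se, pv in zip(res.names, res.beta, res.se, res.p_values):
            row = {
                "group": group,
                "coefficient": name,
                "beta": b,
                "se": se,
                "p_value": pv,
            }
            if name in res.bootstrap_ci:
                row["ci_low"], row["ci_high"] = res.bootstrap_ci[name]
            if name != "cost" and res["cost"] != 0:
                row["wta"] = round_euro(b / res["cost"])
            rows.append(row)
        rows.append(
            {
                "group": group,
                "coefficient": "(LR chi2, df, p)",
                "beta": chi2,
                "se": float(df),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full valuation pipeline and write the report bundle.

    Returns the results dictionary that is also written to
    ``<output_dir>/results.json``.  Any stage failure removes partially
    written outputs and raises :class:`PipelineError` naming the stage.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    caveats: list[str] = []
    try:
        stage = "attributes"
        attrs = load_attributes(config.attrs)

        stage = "design"
        if config.design_dir:
            design = load_design(config.design_dir)
        else:
            design = search_fractional_design(
                attrs,
                config.n_sets,
                config.n_blocks,
                seed=config.design_seed,
                n_restarts=config.design_restarts,
            )
        save_design(design, out / "design")
        written += [out / "design" / "design.csv", out / "design" / "design.yaml"]

        stage = "choices"
        if config.choices:
            obs = read_choices(config.choices, attrs)
        else:
            fx = study_fixture()
            if config.sim_beta == "fixture":
                beta = {
                    g: fx.coefficients[g].beta_array() for g in ("intervention", "control")
                }
            elif isinstance(config.sim_beta, str) and config.sim_beta.startswith("fixture:"):
                beta = fx.coefficients[config.sim_beta.split(":", 1)[1]].beta_array()
            else:
                beta = config.sim_beta
            obs = simulate_choices(
                SimulationConfig(
                    design=design,
                    true_beta=beta,
                    n_respondents=dict(config.sim_n_respondents),
                    sets_per_respondent=config.sim_sets_per_respondent,
                    dominant_fraction=dict(config.sim_dominant_fraction),
                    seed=config.sim_seed,
                )
            )
            write_choices(obs, attrs, out / "choices.csv")
            written.append(out / "choices.csv")

        stage = "validate"
        validate_observations(obs, attrs)

        stage = "qc-dominance"
        dominance = detect_dominant_responders(obs, attrs)
        n_resp = len({o.respondent_id for o in obs})
        for name, flagged in dominance.items():
            if flagged:
                caveats.append(
                    f"dominance QC: {len(flagged)}/{n_resp} respondents always "
                    f"chose the best level of {name!r}"
                )

        stage = "fit"
        results: dict[str, EstimationResult] = {}
        for group in config.groups:
            results[group] = fit_clogit(
                obs,
                attrs,
                group=None if group == "all" else group,
                bootstrap_reps=config.bootstrap_reps,
                seed=config.estimation_seed,
            )
            if results[group].bootstrap_failed:
                caveats.append(
                    f"{results[group].bootstrap_failed} bootstrap refits failed "
                    f"for group {group!r}"
                )

        stage = "welfare"
        fx = study_fixture()
        best = config.best_profile or fx.best_profile
        worst = config.worst_profile or fx.worst_profile
        res_w = results[config.welfare_group]
        valuation = scenario_valuation(
            res_w,
            attrs,
            best,
            worst,
            config.incremental_cost,
            reps=config.kr_reps,
            seed=config.welfare_seed,
        )
        for m in valuation.marginal:
            if m.warning:
                caveats.append(m.warning)
                break
        try:
            importance = {
                g: relative_importance(r, attrs, p_threshold=config.alpha)
                for g, r in results.items()
            }
        except UndefinedImportanceError:
            importance = {}
            caveats.append("relative importance undefined (no significant attribute)")

        stage = "report"
        payload = {
            "config": config.to_dict(),
            "config_hash": config.digest(),
            "seeds": {
                "design": config.design_seed,
                "simulation": config.sim_seed,
                "estimation": config.estimation_seed,
                "welfare": config.welfare_seed,
            },
            "design": {
                "n_sets": len(design.choice_sets),
                "n_blocks": design.n_blocks,
                "d_efficiency": design.d_efficiency,
            },
            "dominance_qc": {k: v for k, v in dominance.items()},
            "estimation": {g: r.to_dict() for g, r in results.items()},
            "relative_importance": importance,
            "welfare": valuation.to_dict(),
            "net_benefit": round_euro(valuation.net_benefit),
            "caveats": caveats,
        }
        results_path = out / "results.json"
        results_path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        written.append(results_path)

        coef_table = _fit_table(results, attrs)
        coef_table.to_csv(out / "coefficients.csv", index=False)
        written.append(out / "coefficients.csv")
        scen_rows = [
            {"attribute_level": m.level, "marginal_wta": round_euro(m.wta)}
            for m in valuation.marginal
        ]
        scen_rows.append({"attribute_level": "total", "marginal_wta": round_euro(valuation.total_wta)})
        scen = pd.DataFrame(scen_rows)
        scen.to_csv(out / "scenario_wta.csv", index=False)
        written.append(out / "scenario_wta.csv")

        report = _render_report(payload, coef_table, scen)
        (out / "report.txt").write_text(report)
        written.append(out / "report.txt")
        return payload
    except PipelineError:
        raise
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc


def _render_report(payload: dict, coef_table: pd.DataFrame, scen: pd.DataFrame) -> str:
    lines = [
        "DCE valuation report",
        "====================",
        f"config hash: {payload['config_hash']}",
        f"seeds: {payload['seeds']}",
        "",
        f"Design: {payload['design']['n_sets']} choice sets in "
        f"{payload['design']['n_blocks']} blocks, "
        f"relative D-efficiency {payload['design']['d_efficiency']:.3f}",
        "",
        "Coefficients and WTA by group",
        "-----------------------------",
        coef_table.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        "",
        "Scenario valuation (worst -> best)",
        "----------------------------------",
        scen.to_string(index=False),
        "",
        f"Compensating variation: {round_euro(payload['welfare']['compensating_variation'])} EUR/yr",
        f"Incremental cost:       {round_euro(payload['welfare']['incremental_cost'])} EUR/yr",
        f"Net benefit:            {payload['net_benefit']} EUR/yr",
        "",
        "Caveats",
        "-------",
    ]
    lines += [f"- {c}" for c in payload["caveats"]] or ["- none"]
    return "\n".join(lines) + "\n"
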