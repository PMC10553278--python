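"""Conditional (McFadden) logit estimation by explicit maximum likelihood.

The random-utility model: alternative j in choice set s has utility
``U_sj = V_sj + eps_sj`` with ``V_sj = beta . x_sj`` and i.i.d. type-I
extreme-value errors, so the probability of choosing j is
``exp(V_sj) / sum_k exp(V_sk)``.  The log-likelihood is globally concave in
``beta``; we maximize it by Newton–Raphson with analytic gradient and
Hessian (quasi-Newton fallback), and take the coefficient covariance as the
inverse observed information at the optimum.

:class:`ConditionalLogit` follows the scikit-learn estimator protocol
(``fit(X, y, sets=...)`` / ``predict_proba`` / ``get_params``); the
module-level functions (:func:`fit_clogit`, :func:`log_likelihood`,
:func:`lr_test`, :func:`bootstrap_coefficients`) are thin wrappers over it
operating on choice observations.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .attributes import AttributeSpec, coef_names
from .data import ChoiceObservation, encode_design_matrix

__all__ = [
    "BootstrapUnstableError",
    "ConditionalLogit",
    "EstimationResult",
    "SeparationError",
    "bootstrap_coefficients",
    "fit_clogit",
    "log_likelihood",
    "lr_test",
]


class SeparationError(RuntimeError):
    """A covariate perfectly predicts choice; the MLE diverges."""


class BootstrapUnstableError(RuntimeError):
    """Too many bootstrap refits failed for the CIs to be trusted."""


def _prepare(X, y, sets):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(bool)
    sets = np.asarray(sets)
    if X.ndim != 2 or len(X) != len(y) or len(y) != len(sets):
        raise ValueError("X, y and sets must have matching first dimensions")
    _, set_idx = np.unique(sets, return_inverse=True)
    order = np.argsort(set_idx, kind="stable")
    X, y, set_idx = X[order], y[order], set_idx[order]
    n_sets = set_idx.max() + 1
    if (np.bincount(set_idx[y], minlength=n_sets) != 1).any():
        raise ValueError("each choice set needs exactly one chosen alternative")
    return X, y, set_idx, n_sets


def _ll_grad_hess(beta, X, y, set_idx, n_sets, order=2):
    """Log-likelihood and derivatives, stabilized with per-set log-sum-exp."""
    v = X @ beta
    vmax = np.full(n_sets, -np.inf)
    np.maximum.at(vmax, set_idx, v)
    ev = np.exp(v - vmax[set_idx])
    denom = np.bincount(set_idx, weights=ev, minlength=n_sets)
    ll = float(v[y].sum() - (np.log(denom) + vmax).sum())
    if order == 0:
        return ll, None, None
    p = ev / denom[set_idx]
    grad = X[y].sum(axis=0) - (p[:, None] * X).sum(axis=0)
    if order == 1:
        return ll, grad, None
    pX = p[:, None] * X
    xbar = np.zeros((n_sets, X.shape[1]))
    np.add.at(xbar, set_idx, pX)
    hess = -(X.T @ pX) + xbar.T @ xbar
    return ll, grad, hess


def _check_identification(X, y, set_idx, names):
    """Within-set differences must have full column rank and no separation."""
    # two-alternative sets: chosen-minus-other difference per set
    d = X[y] - X[~y]
    zero = np.all(np.abs(d) < 1e-12, axis=0)
    if zero.any():
        bad = [names[j] for j in np.flatnonzero(zero)]
        raise SeparationError(
            f"covariates never differ within choice sets: {bad}; "
            "their coefficients are not identified"
        )
    if np.linalg.matrix_rank(d) < d.shape[1]:
        _, R = np.linalg.qr(d)
        diag = np.abs(np.diag(R))
        bad = [names[j] for j in range(len(names)) if diag[j] <= 1e-10 * diag.max()]
        raise SeparationError(
            f"within-set differenced design matrix is rank deficient; "
            f"collinear columns: {bad}"
        )
    for j in range(X.shape[1]):
        dj = d[:, j]
        if (dj >= -1e-12).all() and (dj > 1e-12).any() or (dj <= 1e-12).all() and (
            dj < -1e-12
        ).any():
            raise SeparationError(
                f"covariate {names[j]!r} perfectly predicts choice (separation); "
                "the MLE does not exist"
            )
    # general (quasi-)separation: a direction w with d_s.w >= 0 for every set
    # and > 0 for some set makes the likelihood increase without bound
    res = optimize.linprog(
        c=-d.sum(axis=0),
        A_ub=-d,
        b_ub=np.zeros(len(d)),
        bounds=[(-1, 1)] * d.shape[1],
        method="highs",
    )
    if res.status == 0 and -res.fun > 1e-8:
        w = res.x / max(np.max(np.abs(res.x)), 1e-12)
        involved = [names[j] for j in np.flatnonzero(np.abs(w) > 1e-6)]
        raise SeparationError(
            "choices are separated along a covariate direction "
            f"(involving {involved}); the MLE does not exist"
        )


class ConditionalLogit(BaseEstimator):
    """Conditional logit choice model (scikit-learn estimator interface).

    Parameters
    ----------
    tol:
        Convergence tolerance on the gradient max-norm.
    max_iter:
        Newton–Raphson iteration cap before falling back to BFGS.
    start:
        Optional starting coefficient vector (default: zeros).

    Attributes (after :meth:`fit`)
    ------------------------------
    coef_ : (p,) MLE coefficients.
    cov_ : (p, p) inverse observed information.
    llf_, llnull_ : log-likelihood at the optimum and at ``beta = 0``.
    lr_stat_, df_ : likelihood-ratio statistic ``2(llf - llnull)`` and its df.
    n_iter_, converged_ : optimizer diagnostics.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 200, start=None):
        self.tol = tol
        self.max_iter = max_iter
        self.start = start

    def fit(self, X, y, sets=None):
        if sets is None:
            raise ValueError("sets (choice-set labels per row) is required")
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        names = list(getattr(self, "feature_names_in_", range(np.shape(X)[1])))
        X, y, set_idx, n_sets = _prepare(X, y, sets)
        self.n_features_in_ = X.shape[1]
        _check_identification(X, y, set_idx, [str(n) for n in names])

        beta = (
            np.zeros(X.shape[1])
            if self.start is None
            else np.asarray(self.start, dtype=float).copy()
        )
        if beta.shape != (X.shape[1],):
            raise ValueError("start vector length does not match covariate count")

        ll, grad, hess = _ll_grad_hess(beta, X, y, set_idx, n_sets)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            if np.max(np.abs(grad)) < self.tol:
                converged = True
                break
            try:
                step = np.linalg.solve(-hess, grad)
            except np.linalg.LinAlgError:
                break
            # damped Newton: halve until the likelihood does not decrease
            lam = 1.0
            for _ in range(40):
                cand = beta + lam * step
                ll_new, g_new, h_new = _ll_grad_hess(cand, X, y, set_idx, n_sets)
                if ll_new >= ll - 1e-12:
                    beta, ll, grad, hess = cand, ll_new, g_new, h_new
                    break
                lam /= 2
            else:
                break
        else:
            it = self.max_iter
        if not converged and np.max(np.abs(grad)) >= self.tol:
            # quasi-Newton fallback on the negated likelihood
            res = optimize.minimize(
                lambda b: -_ll_grad_hess(b, X, y, set_idx, n_sets, order=1)[0],
                beta,
                jac=lambda b: -_ll_grad_hess(b, X, y, set_idx, n_sets, order=1)[1],
                method="BFGS",
                options={"gtol": self.tol, "maxiter": 10 * self.max_iter},
            )
            beta = res.x
            ll, grad, hess = _ll_grad_hess(beta, X, y, set_idx, n_sets)
            converged = np.max(np.abs(grad)) < max(self.tol, 1e-6)
        if not converged:
            raise SeparationError(
                "conditional logit did not converge "
                f"(|grad|_max = {np.max(np.abs(grad)):.3g}); data may be separated"
            )
        self.coef_ = beta
        self.cov_ = np.linalg.inv(-hess)
        self.llf_ = ll
        self.llnull_ = _ll_grad_hess(np.zeros_like(beta), X, y, set_idx, n_sets, order=0)[0]
        self.lr_stat_ = 2.0 * (self.llf_ - self.llnull_)
        self.df_ = X.shape[1]
        self.n_iter_ = it
        self.converged_ = converged
        self.n_sets_ = int(n_sets)
        return self

    def predict_proba(self, X, sets=None):
        """Within-set choice probabilities for each alternative row."""
        if sets is None:
            raise ValueError("sets (choice-set labels per row) is required")
        X = np.asarray(X, dtype=float)
        sets = np.asarray(sets)
        _, set_idx = np.unique(sets, return_inverse=True)
        v = X @ self.coef_
        vmax = np.full(set_idx.max() + 1, -np.inf)
        np.maximum.at(vmax, set_idx, v)
        ev = np.exp(v - vmax[set_idx])
        denom = np.bincount(set_idx, weights=ev)
        return ev / denom[set_idx]


@dataclass(frozen=True)
class EstimationResult:
    """Fitted conditional-logit model with uncertainty and fit statistics."""

    names: tuple[str, ...]
    beta: np.ndarray
    cov: np.ndarray
    llf: float
    llnull: float
    lr_stat: float
    df: int
    n_individuals: int
    n_observations: int  # alternative rows (= 2 x choice sets answered)
    bootstrap_ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    bootstrap_reps: int = 0
    bootstrap_failed: int = 0
    seed: int | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        object.__setattr__(self, "cov", np.asarray(self.cov, dtype=float))
        if self.beta.shape != (len(self.names),):
            raise ValueError("beta length does not match coefficient names")
        if self.cov.shape != (len(self.names),) * 2:
            raise ValueError("covariance shape does not match coefficient names")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")

    def __getitem__(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def p_values(self) -> np.ndarray:
        """Wald p-values from the asymptotic normal distribution."""
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.beta / self.se
        return 2 * stats.norm.sf(np.abs(z))

    def p_value(self, name: str) -> float:
        return float(self.p_values[self.names.index(name)])

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "beta": self.beta.tolist(),
            "cov": self.cov.tolist(),
            "llf": self.llf,
            "llnull": self.llnull,
            "lr_stat": self.lr_stat,
            "df": self.df,
            "n_individuals": self.n_individuals,
            "n_observations": self.n_observations,
            "bootstrap_ci": {k: list(v) for k, v in self.bootstrap_ci.items()},
            "bootstrap_reps": self.bootstrap_reps,
            "bootstrap_failed": self.bootstrap_failed,
            "seed": self.seed,
            "converged": self.converged,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "EstimationResult":
        return cls(
            names=tuple(d["names"]),
            beta=np.asarray(d["beta"]),
            cov=np.asarray(d["cov"]),
            llf=d["llf"],
            llnull=d["llnull"],
            lr_stat=d["lr_stat"],
            df=d["df"],
            n_individuals=d["n_individuals"],
            n_observations=d["n_observations"],
            bootstrap_ci={k: tuple(v) for k, v in d.get("bootstrap_ci", {}).items()},
            bootstrap_reps=d.get("bootstrap_reps", 0),
            bootstrap_failed=d.get("bootstrap_failed", 0),
            seed=d.get("seed"),
            converged=d.get("converged", True),
        )

    @classmethod
    def load(cls, path: str | Path) -> "EstimationResult":
        return cls.from_dict(json.loads(Path(path).read_text()))


def log_likelihood(beta, data: pd.DataFrame) -> float:
    """Conditional-logit log-likelihood of encoded data at ``beta``.

    ``data`` is the frame produced by
    :func:`dcevalue.data.encode_design_matrix` (columns ``respondent_id``,
    ``set_id``, ``chosen`` plus covariates).
    """
    covs = [c for c in data.columns if c not in ("respondent_id", "set_id", "chosen")]
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (len(covs),):
        raise ValueError(f"beta has length {len(beta)}, expected {len(covs)}")
    sets = list(zip(data["respondent_id"], data["set_id"]))
    X, y, set_idx, n_sets = _prepare(data[covs].to_numpy(), data["chosen"], pd.factorize(pd.Series(sets))[0])
    return _ll_grad_hess(beta, X, y, set_idx, n_sets, order=0)[0]


def _encoded_arrays(data: pd.DataFrame):
    covs = [c for c in data.columns if c not in ("respondent_id", "set_id", "chosen")]
    task = pd.factorize(pd.Series(list(zip(data["respondent_id"], data["set_id"]))))[0]
    return data[covs], data["chosen"].to_numpy(bool), task, covs


def fit_clogit(
    obs: Sequence[ChoiceObservation] | pd.DataFrame,
    attrs: Sequence[AttributeSpec] | None = None,
    *,
    group: str | None = None,
    start=None,
    tol: float = 1e-8,
    max_iter: int = 200,
    bootstrap_reps: int = 0,
    seed: int | None = None,
) -> EstimationResult:
    """Fit the conditional logit to choice observations.

    ``obs`` may be raw observations (with ``attrs`` for encoding; ``group``
    optionally restricts to the intervention or control arm) or an
    already-encoded frame from :func:`~dcevalue.data.encode_design_matrix`.
    With ``bootstrap_reps > 0`` percentile CIs from a respondent-level
    cluster bootstrap are attached.
    """
    if isinstance(obs, pd.DataFrame):
        data = obs
        raw: Sequence[ChoiceObservation] | None = None
    else:
        raw = [o for o in obs if group is None or o.group == group]
        if attrs is None:
            raise ValueError("attrs required to encode raw observations")
        data = encode_design_matrix(raw, attrs)
    Xdf, y, task, covs = _encoded_arrays(data)
    model = ConditionalLogit(tol=tol, max_iter=max_iter, start=start).fit(Xdf, y, sets=task)
    result = EstimationResult(
        names=tuple(covs),
        beta=model.coef_,
        cov=model.cov_,
        llf=model.llf_,
        llnull=model.llnull_,
        lr_stat=model.lr_stat_,
        df=model.df_,
        n_individuals=data["respondent_id"].nunique(),
        n_observations=len(data),
        seed=seed,
        converged=model.converged_,
    )
    if bootstrap_reps:
        if raw is None:
            raise ValueError("bootstrap requires raw observations (respondent clusters)")
        ci, failed = bootstrap_coefficients(
            raw, attrs, reps=bootstrap_reps, seed=0 if seed is None else seed
        )
        result = dataclasses.replace(
            result,
            bootstrap_ci=ci,
            bootstrap_reps=bootstrap_reps,
            bootstrap_failed=failed,
        )
    return result


def lr_test(result: EstimationResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of the fitted model against the null (beta = 0)."""
    chi2 = 2.0 * (result.llf - result.llnull)
    p = float(stats.chi2.sf(chi2, result.df)) if chi2 > 0 else 1.0
    return chi2, result.df, p


def bootstrap_coefficients(
    obs: Sequence[ChoiceObservation],
    attrs: Sequence[AttributeSpec],
    reps: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[dict[str, tuple[float, float]], int]:
    """Respondent-level cluster bootstrap percentile CIs for the coefficients.

    Respondents are resampled with replacement at the original cohort size
    and the model refitted per replicate.  Failed refits (separation in a
    resample) are skipped and counted; more than 20% failures raises
    :class:`BootstrapUnstableError`.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    respondents = sorted({o.respondent_id for o in obs})
    if len(respondents) < 2:
        raise BootstrapUnstableError("cluster bootstrap needs at least 2 respondents")
    names = coef_names(attrs)
    # encode once; resample pre-split per-respondent arrays per replicate
    data = encode_design_matrix(list(obs), attrs)
    X_all = data[names].to_numpy()
    y_all = data["chosen"].to_numpy(bool)
    task_all = pd.factorize(
        pd.Series(list(zip(data["respondent_id"], data["set_id"])))
    )[0]
    rid_all = data["respondent_id"].to_numpy()
    blocks = {
        r: (X_all[rid_all == r], y_all[rid_all == r], task_all[rid_all == r])
        for r in respondents
    }
    rng = np.random.default_rng(seed)
    draws = []
    failed = 0
    for _ in range(reps):
        sample = rng.choice(len(respondents), size=len(respondents), replace=True)
        Xs, ys, ts = [], [], []
        offset = 0
        for ri in sample:
            Xb, yb, tb = blocks[respondents[ri]]
            Xs.append(Xb)
            ys.append(yb)
            # re-key cloned respondents' sets so duplicates stay distinct
            ts.append(tb + offset * (task_all.max() + 1))
            offset += 1
        try:
            model = ConditionalLogit().fit(
                np.concatenate(Xs), np.concatenate(ys), sets=np.concatenate(ts)
            )
        except (SeparationError, np.linalg.LinAlgError):
            failed += 1
            continue
        draws.append(model.coef_)
    if failed > 0.2 * reps:
        raise BootstrapUnstableError(
            f"{failed}/{reps} bootstrap refits failed; CIs are unreliable"
        )
    arr = np.asarray(draws)
    lo, hi = np.percentile(arr, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)
    return {n: (float(l), float(h)) for n, l, h in zip(names, lo, hi)}, failed
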