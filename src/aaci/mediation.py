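"""Parallel multiple-mediator decomposition with bootstrap confidence intervals.

Quantifies how much of an exposure–outcome association runs through a set of
mediators (here: how much of the dietary amino-acid composition index's
association with incident type-2 diabetes runs through serum valine, glutamic
acid and histidine).  The model is the classic product-of-coefficients
decomposition with all mediators entering the outcome equation jointly
(no mediator→mediator paths):

    m_i = a_i * x + covariates + e_i            (one linear model per mediator)
    y   = c' * x + sum_i b_i * m_i + covariates (single outcome model)
    y   = c  * x + covariates                   (total-effect model, no mediators)

    indirect_i        = a_i * b_i
    percent mediated  = 100 * a_i * b_i / c
    total % mediated  = signed sum of the components

All coefficients are standardized.  For a binary outcome the default is a
probit (or logit) model with coefficients standardized on the latent-index
scale (y*-standardization: divide by the SD of the fitted linear predictor
plus the link's residual variance, 1 for probit, pi^2/3 for logit), the
convention structural-equation software uses for binary endpoints.  With the
linear link the decomposition is exact: c = c' + sum_i a_i*b_i identically.

Percentages are signed: a mediator working against the total effect
(inconsistent mediation / suppression) contributes a negative percentage,
and a protective mediator depressed by a harmful exposure contributes a
positive one (negative a-path times negative b-path).

Confidence intervals come from a case-resampling percentile bootstrap,
deterministic given the seed.  Model fitting here is self-contained
(ordinary least squares and Newton-scoring IRLS for logit/probit) so a
bootstrap replicate costs a few matrix solves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

LATENT_RESIDUAL_VAR = {"probit": 1.0, "logit": np.pi**2 / 3.0}

#: |total effect| below this is treated as zero for percent-mediated purposes.
BETA_TOT_TOL = 1e-10

DEFAULT_MEDIATORS = ("serum_valine", "serum_glutamic_acid", "serum_histidine")


class MediationError(RuntimeError):
    """Mediation model could not be fitted (non-convergence, bad spec)."""


@dataclass(frozen=True)
class MediationSpec:
    """Configuration of one parallel-mediation analysis."""

    exposure: str = "aaci"
    mediators: tuple[str, ...] = DEFAULT_MEDIATORS
    outcome: str = "t2dm_incident"
    covariates: tuple[str, ...] = ()
    n_bootstrap: int = 1000
    seed: int = 0
    outcome_link: str = "probit"  # probit | logit | linear

    def __post_init__(self) -> None:
        roles = {self.exposure, self.outcome, *self.covariates}
        clash = roles & set(self.mediators)
        if clash:
            raise ValueError(f"mediators overlap exposure/outcome/covariates: {sorted(clash)}")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if self.outcome_link not in ("probit", "logit", "linear"):
            raise ValueError(f"unknown outcome_link {self.outcome_link!r}")


@dataclass
class MediationResult:
    """Point estimates, p-values and (optionally) bootstrap CIs."""

    spec: MediationSpec
    n: int
    beta_tot: float
    direct: float
    a_path: dict[str, float]
    b_path: dict[str, float]
    indirect: dict[str, float]
    percent_mediated: dict[str, float]
    total_percent_mediated: float
    p_values: dict[str, float] = field(default_factory=dict)
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_boot_dropped: int = 0
    inconsistent: bool = False

    def summary(self) -> str:
        """Text path-diagram summary of the decomposition."""
        lines = [
            f"Parallel mediation: {self.spec.exposure} -> {self.spec.outcome} "
            f"({self.spec.outcome_link} outcome link, n={self.n})",
            f"  total effect beta_tot = {self.beta_tot:+.4f}"
            + (
                "  95% CI ({:.4f}, {:.4f})".format(*self.ci["beta_tot"])
                if "beta_tot" in self.ci
                else ""
            ),
            f"  direct  effect        = {self.direct:+.4f}",
        ]
        for m in self.spec.mediators:
            lines.append(
                f"  {self.spec.exposure} --a={self.a_path[m]:+.4f}--> {m} "
                f"--b={self.b_path[m]:+.4f}--> {self.spec.outcome}: "
                f"indirect {self.indirect[m]:+.4f} "
                f"({self.percent_mediated[m]:.1f}% of total)"
            )
        lines.append(f"  total mediated: {self.total_percent_mediated:.1f}%")
        if self.inconsistent:
            lines.append("  note: inconsistent mediation (indirect and total effects of opposite sign)")
        return "\n".join(lines)


# ---------------------------------------------------------------- fitting --


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS coefficients and covariance (for Wald p-values)."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    dof = max(X.shape[0] - X.shape[1], 1)
    cov = np.linalg.inv(XtX) * (resid @ resid / dof)
    return beta, cov


def _irls(X: np.ndarray, y: np.ndarray, link: str, tol: float = 1e-10, maxiter: int = 100):
    """Newton-scoring IRLS for a binary GLM (logit or probit)."""
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        eta = np.clip(X @ beta, -35, 35)
        if link == "logit":
            p = 1.0 / (1.0 + np.exp(-eta))
            w = p * (1.0 - p)
            score = X.T @ (y - p)
        else:  # probit
            p = np.clip(stats.norm.cdf(eta), 1e-12, 1 - 1e-12)
            phi = stats.norm.pdf(eta)
            w = phi**2 / (p * (1.0 - p))
            score = X.T @ (phi * (y - p) / (p * (1.0 - p)))
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise MediationError("singular information matrix in IRLS") from exc
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    else:
        raise MediationError(f"IRLS ({link}) did not converge in {maxiter} iterations")
    eta = np.clip(X @ beta, -35, 35)
    if link == "logit":
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
    else:
        p = np.clip(stats.norm.cdf(eta), 1e-12, 1 - 1e-12)
        w = stats.norm.pdf(eta) ** 2 / (p * (1.0 - p))
    cov = np.linalg.inv((X * w[:, None]).T @ X)
    return beta, cov


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd <= 1e-12 * max(1.0, abs(float(v.mean()))):
        raise MediationError("zero-variance variable in mediation model")
    return (v - v.mean()) / sd


def _design(cov: np.ndarray, *cols: np.ndarray) -> np.ndarray:
    parts = [np.ones((cov.shape[0], 1))] + [c[:, None] for c in cols]
    if cov.shape[1]:
        parts.append(cov)
    return np.hstack(parts)


def _fit_outcome(X: np.ndarray, y: np.ndarray, link: str):
    """Outcome-model coefficients on a standardized scale plus their scaling.

    For the linear link ``y`` is already z-scored and OLS coefficients are
    used as-is.  For probit/logit the raw coefficients are divided by the SD
    of the latent index (fitted linear predictor variance plus the link's
    residual variance), the y*-standardization used for binary endpoints.
    """
    if link == "linear":
        beta, cov = _ols(X, y)
        return beta, cov, 1.0
    beta, cov = _irls(X, y, link)
    latent_sd = float(np.sqrt(np.var(X @ beta) + LATENT_RESIDUAL_VAR[link]))
    return beta / latent_sd, cov / latent_sd**2, latent_sd


def _point_estimates(x, M, y, C, link):
    """One full pass: total effect, a/b paths, direct effect (standardized)."""
    k = M.shape[1]
    # total-effect model (no mediators)
    bt, _, _ = _fit_outcome(_design(C, x), y, link)
    beta_tot = bt[1]
    # a-paths: one z-scored linear model per mediator
    Xa = _design(C, x)
    a = np.empty(k)
    for i in range(k):
        a[i] = _ols(Xa, M[:, i])[0][1]
    # joint outcome model with exposure + all mediators
    bo, _, _ = _fit_outcome(_design(C, x, *(M[:, i] for i in range(k))), y, link)
    direct, b = bo[1], bo[2 : 2 + k]
    return beta_tot, direct, a, b


def _percent(indirect: np.ndarray, beta_tot: float) -> np.ndarray:
    if abs(beta_tot) < BETA_TOT_TOL:
        return np.full(indirect.shape, np.nan)
    return 100.0 * indirect / beta_tot


def aggregate_percent_mediated(components) -> float:
    """Total percent mediated: the signed sum of per-mediator percentages."""
    vals = np.asarray(list(components), dtype=float)
    return float(vals.sum())


def fit_mediation(cohort: pd.DataFrame, spec: MediationSpec) -> MediationResult:
    """Point estimates and Wald p-values for a parallel-mediation model.

    The exposure and mediators are z-scored on the analysis sample (listwise
    deletion over every model variable); the outcome is z-scored for the
    linear link and y*-standardized for probit/logit.
    """
    cols = [spec.exposure, *spec.mediators, spec.outcome, *spec.covariates]
    data = cohort[cols].dropna()
    x = _zscore(data[spec.exposure].to_numpy(float))
    M = np.column_stack([_zscore(data[m].to_numpy(float)) for m in spec.mediators])
    y = data[spec.outcome].to_numpy(float)
    if spec.outcome_link == "linear":
        y = _zscore(y)
    elif not set(np.unique(y)) <= {0.0, 1.0}:
        raise MediationError("binary outcome links require a 0/1 outcome")
    C = data[list(spec.covariates)].to_numpy(float) if spec.covariates else np.empty((len(data), 0))

    cond = np.linalg.cond(np.corrcoef(M, rowvar=False)) if M.shape[1] > 1 else 1.0
    if cond > 1e4:
        warnings.warn(f"mediators nearly collinear (condition number {cond:.1e})")

    beta_tot, direct, a, b = _point_estimates(x, M, y, C, spec.outcome_link)
    indirect = a * b
    pct = _percent(indirect, beta_tot)
    if np.isnan(pct).all() and abs(beta_tot) < BETA_TOT_TOL:
        warnings.warn("total effect is ~0; percent mediated undefined (reported as NA)")

    # Wald p-values per path from the analytic covariances
    p_values: dict[str, float] = {}
    bt_raw, bt_cov, _ = _fit_outcome(_design(C, x), y, spec.outcome_link)
    p_values["beta_tot"] = _wald_p(bt_raw[1], bt_cov[1, 1])
    Xa = _design(C, x)
    for i, m in enumerate(spec.mediators):
        ba, cova = _ols(Xa, M[:, i])
        p_values[f"a_{m}"] = _wald_p(ba[1], cova[1, 1])
    bo, bo_cov, _ = _fit_outcome(
        _design(C, x, *(M[:, i] for i in range(M.shape[1]))), y, spec.outcome_link
    )
    p_values["direct"] = _wald_p(bo[1], bo_cov[1, 1])
    for i, m in enumerate(spec.mediators):
        p_values[f"b_{m}"] = _wald_p(bo[2 + i], bo_cov[2 + i, 2 + i])

    meds = list(spec.mediators)
    return MediationResult(
        spec=spec,
        n=len(data),
        beta_tot=float(beta_tot),
        direct=float(direct),
        a_path=dict(zip(meds, map(float, a))),
        b_path=dict(zip(meds, map(float, b))),
        indirect=dict(zip(meds, map(float, indirect))),
        percent_mediated=dict(zip(meds, map(float, pct))),
        total_percent_mediated=aggregate_percent_mediated(pct),
        p_values=p_values,
        inconsistent=bool(np.sign(indirect.sum()) * np.sign(beta_tot) < 0),
    )


def _wald_p(est: float, var: float) -> float:
    if var <= 0:
        return np.nan
    return float(2 * stats.norm.sf(abs(est) / np.sqrt(var)))


def bootstrap_mediation(cohort: pd.DataFrame, spec: MediationSpec) -> MediationResult:
    """Mediation with percentile (2.5/97.5) bootstrap CIs for every quantity.

    Case-resampling bootstrap, deterministic given ``spec.seed``.  Replicates
    whose resample has no outcome cases (or no non-cases) under a binary link
    are dropped and counted; more than 10% dropped raises a warning.  With
    ``n_bootstrap == 1`` the CI degenerates to the point estimate.
    """
    result = fit_mediation(cohort, spec)
    meds = list(spec.mediators)
    names = (
        ["beta_tot", "direct"]
        + [f"a_{m}" for m in meds]
        + [f"b_{m}" for m in meds]
        + [f"indirect_{m}" for m in meds]
        + [f"percent_{m}" for m in meds]
        + ["total_percent"]
    )
    if spec.n_bootstrap == 1:
        point = _flatten(result, meds)
        result.ci = {nm: (point[nm], point[nm]) for nm in names}
        return result

    cols = [spec.exposure, *meds, spec.outcome, *spec.covariates]
    data = cohort[cols].dropna().reset_index(drop=True)
    n = len(data)
    rng = np.random.default_rng(spec.seed)
    draws: list[dict[str, float]] = []
    dropped = 0
    x_all = data[spec.exposure].to_numpy(float)
    M_all = data[list(meds)].to_numpy(float)
    y_all = data[spec.outcome].to_numpy(float)
    C_all = data[list(spec.covariates)].to_numpy(float) if spec.covariates else np.empty((n, 0))
    binary = spec.outcome_link != "linear"
    for _ in range(spec.n_bootstrap):
        idx = rng.integers(0, n, size=n)
        y = y_all[idx]
        if binary and (y.sum() == 0 or y.sum() == n):
            dropped += 1
            continue
        try:
            x = _zscore(x_all[idx])
            M = np.column_stack([_zscore(M_all[idx, j]) for j in range(M_all.shape[1])])
            C = C_all[idx]
            yz = _zscore(y) if not binary else y
            beta_tot, direct, a, b = _point_estimates(x, M, yz, C, spec.outcome_link)
        except (MediationError, np.linalg.LinAlgError):
            dropped += 1
            continue
        indirect = a * b
        pct = _percent(indirect, beta_tot)
        rec = {"beta_tot": beta_tot, "direct": direct, "total_percent": np.nansum(pct)}
        for j, m in enumerate(meds):
            rec[f"a_{m}"] = a[j]
            rec[f"b_{m}"] = b[j]
            rec[f"indirect_{m}"] = indirect[j]
            rec[f"percent_{m}"] = pct[j]
        draws.append(rec)
    if dropped > 0.10 * spec.n_bootstrap:
        warnings.warn(f"{dropped}/{spec.n_bootstrap} bootstrap replicates dropped")
    if not draws:
        raise MediationError("all bootstrap replicates failed")
    frame = pd.DataFrame(draws)
    result.ci = {
        nm: tuple(np.nanpercentile(frame[nm].to_numpy(), [2.5, 97.5])) for nm in names
    }
    result.n_boot_dropped = dropped
    return result


def _flatten(result: MediationResult, meds: list[str]) -> dict[str, float]:
    out = {
        "beta_tot": result.beta_tot,
        "direct": result.direct,
        "total_percent": result.total_percent_mediated,
    }
    for m in meds:
        out[f"a_{m}"] = result.a_path[m]
        out[f"b_{m}"] = result.b_path[m]
        out[f"indirect_{m}"] = result.indirect[m]
        out[f"percent_{m}"] = result.percent_mediated[m]
    return out
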