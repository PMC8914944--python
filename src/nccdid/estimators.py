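"""Point estimation for the step/slope and year-specific rate-ratio models.

Both models are marginal mean models fitted by estimating equations with an
independence working correlation.  With that working correlation the point
estimates coincide with the stacked-data solutions — ordinary least squares
for the continuous model and the log-link quasi-score (IRLS) solution for
the count model — so those are what these routines solve directly.  Within-
person dependence is handled at the inference stage (cluster bootstrap); a
cluster-robust sandwich variance is attached as a diagnostic only.

Continuous outcome (e.g. ppFEV1), step/slope model::

    E(Y_ij | X_i) = beta_0 + beta_St X_i + beta_Sl X_i j + beta_J j

where ``beta_St`` is the immediate level shift in the (pseudo-)treated group
and ``beta_Sl`` the change in annual slope.  Count outcome (e.g. annual IV
antibiotic days), year-specific log-rate model::

    log E(Y_ij | X_i) = gamma_0 + (visit terms) + sum_k gamma_Xk X_i 1(j = k-1)

so ``exp(gamma_Xk)`` is the rate ratio after k years of treatment.  Visit
terms default to one indicator per visit index (saturated secular trend);
a linear-in-j term is available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .cohort import AnalysisSet, CohortError

logger = logging.getLogger("nccdid")

#: relative singular-value tolerance for rank checks
RANK_TOL = 1e-8
#: IRLS convergence: relative parameter change
IRLS_TOL = 1e-10
IRLS_MAX_ITER = 100


class FitError(ValueError):
    """Model cannot be fitted (rank deficiency, empty cells, no contrast)."""


class ConvergenceError(FitError):
    """The iterative score solver failed to converge."""


# -- covariate encodings -------------------------------------------------

VALID_ENCODINGS = ("continuous", "binary", "count_baseline")


@dataclass(frozen=True)
class CovariateSpec:
    """Ordered baseline covariates with per-covariate encoding rules.

    Encodings: ``continuous`` and ``binary`` enter as a single column;
    ``count_baseline`` expands a baseline count into two columns, an
    indicator of a nonzero count and a linear term for the nonzero counts
    (the linear column equals the raw count, which is 0 exactly when the
    indicator is 0).
    """

    names: tuple[str, ...]
    encodings: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("covariate names must be unique")
        for name in self.names:
            enc = self.encoding(name)
            if enc not in VALID_ENCODINGS:
                raise ValueError(f"unknown encoding {enc!r} for {name!r}")

    @classmethod
    def from_names(
        cls, names: Sequence[str], encodings: Mapping[str, str] | None = None
    ) -> "CovariateSpec":
        return cls(names=tuple(names), encodings=dict(encodings or {}))

    def encoding(self, name: str) -> str:
        return self.encodings.get(name, "continuous")

    def encode(self, df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        """Design columns and their names for the covariates in ``df``."""
        cols: list[np.ndarray] = []
        names: list[str] = []
        for name in self.names:
            v = df[name].to_numpy(dtype=float)
            enc = self.encoding(name)
            if enc == "count_baseline":
                cols.append((v != 0).astype(float))
                cols.append(v)
                names.extend([f"{name}_nonzero", f"{name}_linear"])
            else:
                cols.append(v)
                names.append(name)
        if not cols:
            return np.empty((len(df), 0)), []
        return np.column_stack(cols), names


# -- core solvers (shared with the bootstrap) ----------------------------


def check_rank(design: np.ndarray, names: Sequence[str]) -> None:
    """Raise :class:`FitError` naming dependent columns if rank-deficient."""
    if design.shape[0] < design.shape[1]:
        raise FitError(
            f"fewer rows ({design.shape[0]}) than design columns "
            f"({design.shape[1]})"
        )
    s = scipy.linalg.svdvals(design)
    if s[0] == 0 or s[-1] < RANK_TOL * s[0]:
        # QR with column pivoting localises the dependent columns
        _, _, piv = scipy.linalg.qr(design, mode="economic", pivoting=True)
        rank = int(np.sum(s >= RANK_TOL * s[0]))
        dependent = [names[i] for i in sorted(piv[rank:])]
        raise FitError(f"design matrix is rank deficient; collinear: {dependent}")


def solve_ols(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares coefficients for the stacked person-visit rows."""
    beta, *_ = scipy.linalg.lstsq(design, y, lapack_driver="gelsd")
    return beta


def solve_poisson(
    design: np.ndarray, y: np.ndarray, beta0: np.ndarray | None = None
) -> np.ndarray:
    """Log-link quasi-score (IRLS) solution with variance prop. to mean.

    Overdispersion scales the quasi-score uniformly, so the solution is the
    Poisson maximum-likelihood point estimate; only inference differs.
    """
    n, p = design.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    if beta0 is None:
        beta[0] = np.log(max(y.mean(), 1e-8))  # assumes column 0 is intercept
    for _ in range(IRLS_MAX_ITER):
        eta = np.clip(design @ beta, -30.0, 30.0)
        mu = np.exp(eta)
        w = np.sqrt(mu)
        z = eta + (y - mu) / mu
        beta_new = solve_ols(design * w[:, None], z * w)
        denom = max(np.max(np.abs(beta)), 1.0)
        delta = np.max(np.abs(beta_new - beta)) / denom
        beta = beta_new
        if delta < IRLS_TOL:
            return beta
    raise ConvergenceError(
        f"IRLS did not converge in {IRLS_MAX_ITER} iterations (delta={delta:.2e})"
    )


def cluster_sandwich(
    design: np.ndarray,
    resid: np.ndarray,
    clusters: np.ndarray,
    weight: np.ndarray | None = None,
) -> np.ndarray:
    """Cluster-robust (sandwich) covariance of estimating-equation estimates.

    ``resid`` are raw residuals, ``weight`` the working weights (mu for the
    log-link model, None for identity).  Diagnostic only; reported intervals
    come from the cluster bootstrap.
    """
    w = np.ones(len(resid)) if weight is None else weight
    bread = np.linalg.pinv(design.T @ (design * w[:, None]))
    scores = design * resid[:, None]
    order = np.argsort(clusters, kind="stable")
    sorted_scores = scores[order]
    _, starts = np.unique(clusters[order], return_index=True)
    cluster_sums = np.add.reduceat(sorted_scores, starts, axis=0)
    meat = cluster_sums.T @ cluster_sums
    return bread @ meat @ bread


# -- design construction -------------------------------------------------


def step_slope_design(
    x: np.ndarray, j: np.ndarray, cov: np.ndarray | None = None
) -> np.ndarray:
    cols = [np.ones_like(x, dtype=float), x.astype(float), x * j, j.astype(float)]
    design = np.column_stack(cols)
    if cov is not None and cov.shape[1]:
        design = np.hstack([design, cov])
    return design


STEP_SLOPE_NAMES = ["beta_0", "beta_St", "beta_Sl", "beta_J"]


def count_design(
    x: np.ndarray,
    j: np.ndarray,
    treatment_years: Sequence[int],
    visit_terms: str = "saturated",
    visit_levels: Sequence[int] | None = None,
    cov: np.ndarray | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Design for the year-specific log-rate model.

    ``treatment_years`` lists years k (1-based) with a gamma_Xk column
    X * 1(j = k-1).  ``visit_terms`` is ``"saturated"`` (one indicator per
    visit level above the first) or ``"linear"``.
    """
    cols = [np.ones(len(x))]
    names = ["gamma_0"]
    if visit_terms == "saturated":
        levels = sorted(set(np.unique(j))) if visit_levels is None else list(visit_levels)
        for lev in levels[1:]:
            cols.append((j == lev).astype(float))
            names.append(f"gamma_J{int(lev)}")
    elif visit_terms == "linear":
        cols.append(j.astype(float))
        names.append("gamma_J")
    else:
        raise ValueError(f"unknown visit_terms {visit_terms!r}")
    for k in treatment_years:
        cols.append((x * (j == k - 1)).astype(float))
        names.append(f"gamma_X{k}")
    design = np.column_stack(cols)
    if cov is not None and cov.shape[1]:
        design = np.hstack([design, cov])
    return design, names


# -- fitted-model containers ---------------------------------------------


@dataclass
class StepSlopeEstimate:
    """Fitted step/slope model coefficients (outcome units)."""

    beta_0: float
    beta_St: float
    beta_Sl: float
    beta_J: float
    covariate_coefficients: dict[str, float]
    n_persons: int
    n_records: int
    robust_se: dict[str, float]

    def to_dict(self) -> dict:
        out = {
            "beta_0": self.beta_0,
            "beta_St": self.beta_St,
            "beta_Sl": self.beta_Sl,
            "beta_J": self.beta_J,
        }
        out.update(self.covariate_coefficients)
        return out


@dataclass
class CountEffects:
    """Fitted year-specific log-rate model: gamma_Xk and exp(gamma_Xk)."""

    gamma_0: float
    gamma_J: dict[str, float]
    gamma_X: np.ndarray  # one log-rate-ratio per treatment year
    treatment_years: tuple[int, ...]
    covariate_coefficients: dict[str, float]
    n_persons: int
    n_records: int
    robust_se: dict[str, float]

    @property
    def rate_ratios(self) -> np.ndarray:
        return np.exp(self.gamma_X)

    def to_dict(self) -> dict:
        out = {"gamma_0": self.gamma_0}
        out.update(self.gamma_J)
        for k, g in zip(self.treatment_years, self.gamma_X):
            out[f"gamma_X{k}"] = float(g)
        for k, rr in zip(self.treatment_years, self.rate_ratios):
            out[f"rate_ratio_year{k}"] = float(rr)
        out.update(self.covariate_coefficients)
        return out


# -- fitting entry points ------------------------------------------------


def _prepare(aset: AnalysisSet):
    df = aset.data
    x = df["X"].to_numpy(dtype=float)
    j = df["visit"].to_numpy(dtype=float)
    y = df["outcome"].to_numpy(dtype=float)
    persons = df["person_id"].to_numpy()
    for level in (0, 1):
        if len(np.unique(persons[x == level])) < 2:
            raise FitError(f"need >= 2 persons with X={level}")
    if aset.covariate_spec is not None and aset.covariate_spec.names:
        cov, cov_names = aset.covariate_spec.encode(df)
    else:
        cov, cov_names = np.empty((len(df), 0)), []
    return x, j, y, persons, cov, cov_names


def fit_step_slope(aset: AnalysisSet) -> StepSlopeEstimate:
    """Fit the continuous step/slope model on an analysis set.

    Solves the pooled least-squares estimating equations over all stacked
    person-visit rows; with an independence working correlation these are
    the marginal-model point estimates.
    """
    if aset.outcome_kind != "continuous":
        raise FitError("fit_step_slope requires a continuous outcome")
    x, j, y, persons, cov, cov_names = _prepare(aset)
    design = step_slope_design(x, j, cov)
    names = STEP_SLOPE_NAMES + cov_names
    check_rank(design, names)
    beta = solve_ols(design, y)
    resid = y - design @ beta
    codes = pd.factorize(persons)[0]
    vcov = cluster_sandwich(design, resid, codes)
    se = dict(zip(names, np.sqrt(np.diag(vcov))))
    return StepSlopeEstimate(
        beta_0=float(beta[0]),
        beta_St=float(beta[1]),
        beta_Sl=float(beta[2]),
        beta_J=float(beta[3]),
        covariate_coefficients=dict(zip(cov_names, map(float, beta[4:]))),
        n_persons=len(np.unique(persons)),
        n_records=len(y),
        robust_se=se,
    )


def fit_count_effects(
    aset: AnalysisSet,
    n_treatment_years: int | None = None,
    visit_terms: str = "saturated",
) -> CountEffects:
    """Fit the year-specific log-rate model for a count outcome.

    ``n_treatment_years`` limits the gamma_Xk columns to years 1..K; by
    default one column per visit index observed in the X=1 arm (year k
    corresponds to visit j = k-1).
    """
    if aset.outcome_kind != "count":
        raise FitError("fit_count_effects requires a count outcome")
    x, j, y, persons, cov, cov_names = _prepare(aset)
    if (y < 0).any() or (y != np.round(y)).any():
        raise CohortError("count outcomes must be nonnegative integers")
    treated_visits = sorted(int(v) for v in np.unique(j[x == 1]))
    if n_treatment_years is None:
        years = [v + 1 for v in treated_visits]
    else:
        years = [v + 1 for v in treated_visits if v + 1 <= n_treatment_years]
    for k in years:
        cell = y[(x == 1) & (j == k - 1)]
        if cell.sum() == 0:
            raise FitError(
                f"all outcomes zero in the X=1, year-{k} cell; "
                "log rate ratio is unidentified"
            )
    design, names = count_design(x, j, years, visit_terms=visit_terms, cov=cov)
    names = names + cov_names
    check_rank(design, names)
    beta = solve_poisson(design, y)
    mu = np.exp(np.clip(design @ beta, -30, 30))
    codes = pd.factorize(persons)[0]
    vcov = cluster_sandwich(design, y - mu, codes, weight=mu)
    se = dict(zip(names, np.sqrt(np.diag(vcov))))
    n_visit = len(names) - len(cov_names) - len(years) - 1
    gamma_j = dict(zip(names[1 : 1 + n_visit], map(float, beta[1 : 1 + n_visit])))
    gx = beta[1 + n_visit : 1 + n_visit + len(years)]
    return CountEffects(
        gamma_0=float(beta[0]),
        gamma_J=gamma_j,
        gamma_X=np.asarray(gx, dtype=float),
        treatment_years=tuple(years),
        covariate_coefficients=dict(
            zip(cov_names, map(float, beta[1 + n_visit + len(years) :]))
        ),
        n_persons=len(np.unique(persons)),
        n_records=len(y),
        robust_se=se,
    )


# -- standardization (g-computation) -------------------------------------


def standardize_effect(aset: AnalysisSet, at_visit: int = 0) -> float:
    """Standardized mean difference at one visit via g-computation.

    Fits the outcome model (linear in the encoded covariates) in the X=0
    records at ``at_visit``, averages its predictions over the empirical
    covariate distribution of the X=1 records at that visit, and returns the
    mean observed X=1 outcome minus that standardized mean — the covariate-
    standardized contrast with the X=1 group as the standard population.
    With no covariates the model is intercept-only and the result collapses
    to the unadjusted difference in means at that visit.
    """
    spec = aset.covariate_spec or CovariateSpec(names=())
    df = aset.data
    at = df.loc[df["visit"] == at_visit]
    d0 = at.loc[at["X"] == 0]
    d1 = at.loc[at["X"] == 1]
    if len(d0) == 0 or len(d1) == 0:
        raise FitError(f"no records at visit {at_visit} in one X level")
    _check_overlap(d0, d1, spec)
    cov0, cov_names = spec.encode(d0)
    design0 = np.hstack([np.ones((len(d0), 1)), cov0])
    check_rank(design0, ["intercept"] + cov_names)
    beta = solve_ols(design0, d0["outcome"].to_numpy(dtype=float))
    cov1, _ = spec.encode(d1)
    design1 = np.hstack([np.ones((len(d1), 1)), cov1])
    standardized_mean = float(np.mean(design1 @ beta))
    return float(d1["outcome"].mean()) - standardized_mean


def _check_overlap(d0: pd.DataFrame, d1: pd.DataFrame, spec: CovariateSpec) -> None:
    """Discrete strata in X=1 must occur in X=0; continuous only warns."""
    discrete = [n for n in spec.names if spec.encoding(n) == "binary"]
    continuous = [n for n in spec.names if spec.encoding(n) != "binary"]
    if discrete:
        strata0 = set(map(tuple, d0[discrete].to_numpy().tolist()))
        strata1 = set(map(tuple, d1[discrete].to_numpy().tolist()))
        orphan = strata1 - strata0
        if orphan:
            raise FitError(
                f"covariate strata present in X=1 but absent in X=0 "
                f"(columns {discrete}): {sorted(orphan)}"
            )
    if continuous:
        logger.warning(
            "overlap of continuous covariates %s is not verifiable; "
            "standardization extrapolates the outcome model",
            continuous,
        )
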