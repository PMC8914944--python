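"""Negative-control-corrected effect estimation with cluster-bootstrap CIs.

For a chosen comparison the naive treatment effect (NTE) and its matching
negative control effect (NCE) are estimated by label switching, and the
corrected effect is their combination,

    NCCTE = NTE - NCE            (difference scale, continuous outcomes)
    NCCTE = NTE / NCE            (rate-ratio scale, count outcomes)

which identifies the average treatment effect in the treated when the
untreated-world period x genotype interaction is zero.  Inference is by
nonparametric bootstrap resampling persons (the cluster unit) with
replacement; one person-level resample per iteration feeds the NTE, NCE and
NCCTE together, so a person contributing to both periods is resampled as a
unit and the corrected effect's interval reflects joint resampling of all
groups.  Confidence intervals are 95% percentile intervals; p-values invert
the percentile interval (smallest alpha at which the (1-alpha) interval
excludes the null).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortError, ContrastKind
from .estimators import (
    CovariateSpec,
    FitError,
    count_design,
    solve_ols,
    solve_poisson,
    step_slope_design,
)

logger = logging.getLogger("nccdid")

#: alpha grid for percentile-interval inversion p-values
ALPHA_GRID = np.round(np.arange(0.001, 1.0, 0.001), 3)

#: maximum tolerated fraction of failed bootstrap resamples
MAX_FAILURE_RATE = 0.05

COMPARISONS = {
    "time_period": (ContrastKind.NTE_P, ContrastKind.NCE_P),
    "genotype": (ContrastKind.NTE_G, ContrastKind.NCE_G),
}

# group code = 2 * P + G: C=0, A=1, D=2, B=3
_GROUP_CODE = {"C": 0, "A": 1, "D": 2, "B": 3}


class BootstrapError(RuntimeError):
    """Too many resamples failed for the interval to be trustworthy."""


def ncc_combine(nte_point: float, nce_point: float, scale: str) -> float:
    """Correct a naive effect by its negative control effect.

    On the ``difference`` scale the corrected effect is ``nte - nce``; on
    the ``rate_ratio`` scale it is ``nte / nce`` (subtraction of log rate
    ratios), requiring strictly positive inputs.
    """
    if scale == "difference":
        return nte_point - nce_point
    if scale == "rate_ratio":
        if nte_point <= 0 or nce_point <= 0:
            raise ValueError(
                f"rate ratios must be positive, got NTE={nte_point}, NCE={nce_point}"
            )
        return nte_point / nce_point
    raise ValueError(f"unknown scale {scale!r}")


def percent_reduction(rate_ratio: float) -> float:
    """Rate ratio expressed as a percentage reduction, 100 * (1 - RR)."""
    return 100.0 * (1.0 - rate_ratio)


# -- bootstrap machinery -------------------------------------------------


@dataclass
class BootstrapResult:
    """Point estimate with percentile-bootstrap CI and p-value."""

    point: float
    ci_low: float
    ci_high: float
    p_value: float
    B: int
    seed: int
    n_failed: int = 0

    def to_dict(self) -> dict:
        return {
            "point": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "B": self.B,
            "seed": self.seed,
            "n_failed": self.n_failed,
        }


def percentile_ci(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    lo = (1.0 - level) / 2.0
    return float(np.quantile(draws, lo)), float(np.quantile(draws, 1.0 - lo))


def invert_pvalue(draws: np.ndarray, null: float = 0.0) -> float:
    """Smallest alpha whose (1 - alpha) percentile interval excludes null."""
    lower = np.quantile(draws, ALPHA_GRID / 2.0)
    upper = np.quantile(draws, 1.0 - ALPHA_GRID / 2.0)
    excluded = (null < lower) | (null > upper)
    if not excluded.any():
        return 1.0
    return float(ALPHA_GRID[int(np.argmax(excluded))])


def resample_cohort(cohort: Cohort, rng: np.random.Generator) -> Cohort:
    """Person-level resample with replacement, relabelling duplicates.

    A sampled person carries all their records in both periods; the k-th
    occurrence of a person gets a distinct id so cluster identities stay
    one-to-one with resampled persons.
    """
    df = cohort.data
    persons = df["person_id"].unique()
    sampled = rng.choice(persons, size=len(persons), replace=True)
    groups = {pid: sub for pid, sub in df.groupby("person_id", sort=False)}
    parts = []
    for k, pid in enumerate(sampled):
        part = groups[pid].copy()
        part["person_id"] = f"{pid}#{k}"
        parts.append(part)
    out = pd.concat(parts, ignore_index=True)
    return Cohort(out, outcome_kind=cohort.outcome_kind, max_visits=cohort.max_visits)


def bootstrap_effect(
    cohort: Cohort,
    estimator: Callable[[Cohort], float],
    B: int,
    seed: int,
    null: float = 0.0,
) -> BootstrapResult:
    """Cluster bootstrap of an arbitrary cohort-level scalar estimator.

    Persons are the resampling unit.  Resamples on which the estimator
    raises are dropped and counted; more than 5% failures is an error.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if B < 100:
        logger.warning("B=%d < 100: bootstrap CI will be unstable", B)
    point = float(estimator(cohort))
    rng = np.random.default_rng(seed)
    draws = []
    n_failed = 0
    for _ in range(B):
        boot = resample_cohort(cohort, rng)
        try:
            draws.append(float(estimator(boot)))
        except (FitError, CohortError, np.linalg.LinAlgError):
            n_failed += 1
    if n_failed > MAX_FAILURE_RATE * B:
        raise BootstrapError(f"{n_failed}/{B} bootstrap resamples failed")
    arr = np.asarray(draws)
    lo, hi = percentile_ci(arr)
    return BootstrapResult(
        point=point,
        ci_low=lo,
        ci_high=hi,
        p_value=invert_pvalue(arr, null=null),
        B=B,
        seed=seed,
        n_failed=n_failed,
    )


# -- flat array representation for fast joint refits ---------------------


class _FlatCohort:
    """Cohort rows grouped by person in contiguous numpy blocks."""

    def __init__(
        self,
        cohort: Cohort,
        covariate_spec: CovariateSpec | None,
        adjustment: str,
    ) -> None:
        df = cohort.data
        df = df.loc[df["outcome"].notna()]
        if adjustment != "unadjusted" and covariate_spec and covariate_spec.names:
            missing_cols = [c for c in covariate_spec.names if c not in df.columns]
            if missing_cols:
                raise CohortError(f"covariates not in cohort: {missing_cols}")
            complete = df[list(covariate_spec.names)].notna().all(axis=1)
            n_drop = int((~complete).sum())
            if n_drop:
                logger.info("dropped %d records with missing covariates", n_drop)
            df = df.loc[complete]
        codes, _ = pd.factorize(df["person_id"], sort=False)
        order = np.argsort(codes, kind="stable")
        df = df.iloc[order]
        codes = codes[order]
        self.n_persons = int(codes.max()) + 1 if len(codes) else 0
        boundaries = np.flatnonzero(np.diff(codes)) + 1
        self.starts = np.concatenate([[0], boundaries]).astype(np.int64)
        self.lens = np.diff(np.concatenate([self.starts, [len(codes)]])).astype(
            np.int64
        )
        self.gcode = (
            2 * df["period"].to_numpy(dtype=np.int64)
            + df["genotype"].to_numpy(dtype=np.int64)
        )
        self.j = df["visit"].to_numpy(dtype=float)
        self.y = df["outcome"].to_numpy(dtype=float)
        if adjustment != "unadjusted" and covariate_spec and covariate_spec.names:
            self.cov, _ = covariate_spec.encode(df)
        else:
            self.cov = None
        self.n_records = len(df)
        # person counts per group for precondition checks
        grp_person = {}
        for gname, gc in _GROUP_CODE.items():
            mask = self.gcode == gc
            grp_person[gname] = len(np.unique(self._person_of_rows(mask)))
        self.group_persons = grp_person

    def _person_of_rows(self, mask: np.ndarray) -> np.ndarray:
        person_idx = np.repeat(np.arange(self.n_persons), self.lens)
        return person_idx[mask]

    def all_rows(self) -> np.ndarray:
        return np.arange(self.n_records, dtype=np.int64)

    def gather(self, sampled: np.ndarray) -> np.ndarray:
        """Row indices of the sampled persons, blocks concatenated."""
        starts = self.starts[sampled]
        lens = self.lens[sampled]
        total = int(lens.sum())
        if total == 0:
            return np.empty(0, dtype=np.int64)
        steps = np.ones(total, dtype=np.int64)
        offs = np.cumsum(lens)[:-1]
        steps[0] = starts[0]
        if len(starts) > 1:
            steps[offs] = starts[1:] - (starts[:-1] + lens[:-1] - 1)
        return np.cumsum(steps)


def _contrast_codes(kind: ContrastKind) -> tuple[int, int]:
    return (
        _GROUP_CODE[kind.control_group.value],
        _GROUP_CODE[kind.treated_group.value],
    )


def _fit_contrast(
    flat: _FlatCohort,
    rows: np.ndarray,
    kind: ContrastKind,
    outcome_kind: str,
    adjustment: str,
    years: Sequence[int],
    visit_levels: Sequence[int],
    warm: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Effect components for one contrast on one set of rows.

    Returns ``(components, full_beta)``: step/slope for continuous outcomes
    (or per-visit standardized differences reduced to step/slope when
    ``adjustment == 'standardized'``), per-year log rate ratios for counts.
    """
    ctrl, trt = _contrast_codes(kind)
    sel = rows[(flat.gcode[rows] == ctrl) | (flat.gcode[rows] == trt)]
    if len(sel) == 0:
        raise FitError(f"contrast {kind.value}: no records")
    x = (flat.gcode[sel] == trt).astype(float)
    if x.min() == x.max():
        raise FitError(f"contrast {kind.value}: only one X level present")
    j = flat.j[sel]
    y = flat.y[sel]
    cov = flat.cov[sel] if flat.cov is not None else None

    if outcome_kind == "continuous":
        if adjustment == "standardized":
            comps = _standardized_step_slope(x, j, y, cov)
            return comps, comps
        design = step_slope_design(x, j, cov if adjustment == "conditional" else None)
        beta = solve_ols(design, y)
        return beta[1:3].copy(), beta

    # count outcome: per-year log rate ratios
    for k in years:
        cell = y[(x == 1) & (j == k - 1)]
        if len(cell) == 0 or cell.sum() == 0:
            raise FitError(f"contrast {kind.value}: empty/all-zero X=1 year-{k} cell")
    design, names = count_design(
        x,
        j,
        years,
        visit_levels=visit_levels,
        cov=cov if adjustment == "conditional" else None,
    )
    beta = solve_poisson(design, y, beta0=warm)
    n_visit = len(visit_levels) - 1
    gx = beta[1 + n_visit : 1 + n_visit + len(years)]
    return gx.copy(), beta


def _standardized_step_slope(
    x: np.ndarray, j: np.ndarray, y: np.ndarray, cov: np.ndarray | None
) -> np.ndarray:
    """Per-visit g-computation differences reduced to a step and a slope."""
    if cov is None:
        raise FitError("standardized adjustment requires covariates")
    visits = []
    diffs = []
    for v in np.unique(j):
        at = j == v
        m0 = at & (x == 0)
        m1 = at & (x == 1)
        if m0.sum() < 2 or m1.sum() < 1:
            continue
        d0 = np.hstack([np.ones((int(m0.sum()), 1)), cov[m0]])
        beta = solve_ols(d0, y[m0])
        d1 = np.hstack([np.ones((int(m1.sum()), 1)), cov[m1]])
        diffs.append(float(y[m1].mean() - np.mean(d1 @ beta)))
        visits.append(float(v))
    if len(visits) < 2:
        raise FitError("standardized step/slope needs >= 2 visits with both X levels")
    vd = np.column_stack([np.ones(len(visits)), np.asarray(visits)])
    coef = solve_ols(vd, np.asarray(diffs))
    return coef  # [step at j=0, slope per visit]


# -- effect triples ------------------------------------------------------


@dataclass
class EffectRecord:
    """One effect (NTE, NCE or NCCTE): named components with intervals."""

    name: str
    components: dict[str, BootstrapResult]

    def points(self) -> dict[str, float]:
        return {k: v.point for k, v in self.components.items()}

    def to_dict(self) -> dict:
        return {k: v.to_dict() for k, v in self.components.items()}


@dataclass
class EffectTriple:
    """Matched NTE, NCE and NCCTE on a common scale.

    ``scale`` is ``difference`` (continuous; components ``step`` and
    ``slope``) or ``rate_ratio`` (count; components ``year1``..``yearK``).
    The corrected points satisfy NCCTE = NTE - NCE (difference) or
    log NCCTE = log NTE - log NCE (rate ratio) exactly.
    """

    comparison: str
    scale: str
    nte: EffectRecord
    nce: EffectRecord
    nccte: EffectRecord
    adjustment: str
    B: int
    seed: int
    n_failed: int = 0

    def to_dict(self) -> dict:
        return {
            "comparison": self.comparison,
            "scale": self.scale,
            "adjustment": self.adjustment,
            "B": self.B,
            "seed": self.seed,
            "n_failed": self.n_failed,
            "nte": self.nte.to_dict(),
            "nce": self.nce.to_dict(),
            "nccte": self.nccte.to_dict(),
        }

    def to_rows(self) -> list[dict]:
        rows = []
        for eff in ("nte", "nce", "nccte"):
            rec: EffectRecord = getattr(self, eff)
            for comp, br in rec.components.items():
                rows.append(
                    {
                        "comparison": self.comparison,
                        "scale": self.scale,
                        "adjustment": self.adjustment,
                        "effect": eff.upper(),
                        "component": comp,
                        "point": br.point,
                        "ci_low": br.ci_low,
                        "ci_high": br.ci_high,
                        "p_value": br.p_value,
                    }
                )
        return rows


def _prepare_estimation(
    cohort: Cohort,
    comparison: str,
    outcome_kind: str | None,
    adjustment: str,
    covariate_spec: CovariateSpec | None,
    n_treatment_years: int | None,
):
    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}")
    outcome_kind = outcome_kind or cohort.outcome_kind
    if outcome_kind != cohort.outcome_kind:
        raise CohortError(
            f"outcome_kind {outcome_kind!r} does not match cohort "
            f"({cohort.outcome_kind!r})"
        )
    if adjustment not in ("unadjusted", "conditional", "standardized"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    if adjustment != "unadjusted" and (
        covariate_spec is None or not covariate_spec.names
    ):
        raise ValueError(f"{adjustment} adjustment requires a covariate_spec")
    if outcome_kind == "count" and adjustment == "standardized":
        raise NotImplementedError(
            "standardized adjustment is implemented for continuous outcomes; "
            "use conditional adjustment for count outcomes"
        )
    nte_kind, nce_kind = COMPARISONS[comparison]
    flat = _FlatCohort(cohort, covariate_spec, adjustment)
    for kind in (nte_kind, nce_kind):
        for grp in (kind.control_group, kind.treated_group):
            if flat.group_persons[grp.value] == 0:
                raise CohortError(
                    f"contrast {kind.value} needs group {grp.value}, "
                    "which is empty in this cohort"
                )
    rows = flat.all_rows()
    if outcome_kind == "count":
        ctrl, trt = _contrast_codes(nte_kind)
        treated_j = np.unique(flat.j[flat.gcode == trt]).astype(int)
        years = [int(v) + 1 for v in sorted(treated_j)]
        if n_treatment_years is not None:
            years = [k for k in years if k <= n_treatment_years]
        visit_levels = sorted(int(v) for v in np.unique(flat.j))
        scale = "rate_ratio"
        comp_names = [f"year{k}" for k in years]
    else:
        years, visit_levels = [], []
        scale = "difference"
        comp_names = ["step", "slope"]
    return flat, rows, nte_kind, nce_kind, years, visit_levels, scale, comp_names


def point_effects(
    cohort: Cohort,
    comparison: str,
    outcome_kind: str | None = None,
    adjustment: str = "unadjusted",
    covariate_spec: CovariateSpec | None = None,
    n_treatment_years: int | None = None,
) -> dict[str, dict[str, float]]:
    """NTE, NCE and NCCTE point estimates without interval estimation.

    Returns ``{"nte": {...}, "nce": {...}, "nccte": {...}}`` keyed by
    component (``step``/``slope`` or ``year1``..); count components are rate
    ratios.
    """
    (flat, rows, nte_kind, nce_kind, years, visit_levels, scale, comp_names) = (
        _prepare_estimation(
            cohort, comparison, outcome_kind, adjustment, covariate_spec,
            n_treatment_years,
        )
    )
    ok = outcome_kind or cohort.outcome_kind
    nte, _ = _fit_contrast(flat, rows, nte_kind, ok, adjustment, years, visit_levels)
    nce, _ = _fit_contrast(flat, rows, nce_kind, ok, adjustment, years, visit_levels)
    nccte = nte - nce  # difference scale, or log-rate-ratio scale for counts
    if scale == "rate_ratio":
        nte, nce, nccte = np.exp(nte), np.exp(nce), np.exp(nccte)
    return {
        "nte": dict(zip(comp_names, map(float, nte))),
        "nce": dict(zip(comp_names, map(float, nce))),
        "nccte": dict(zip(comp_names, map(float, nccte))),
    }


def estimate_ncc(
    cohort: Cohort,
    comparison: str,
    outcome_kind: str | None = None,
    adjustment: str = "unadjusted",
    covariate_spec: CovariateSpec | None = None,
    B: int = 1000,
    seed: int = 0,
    n_treatment_years: int | None = None,
) -> EffectTriple:
    """Estimate the NTE, NCE and NCCTE with joint cluster-bootstrap CIs.

    One person-level resample per bootstrap iteration feeds all three
    effects, so the corrected effect's interval reflects joint resampling
    of every group (persons contributing to both periods move as a unit).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if B < 100:
        logger.warning("B=%d < 100: bootstrap CI will be unstable", B)
    (flat, rows, nte_kind, nce_kind, years, visit_levels, scale, comp_names) = (
        _prepare_estimation(
            cohort, comparison, outcome_kind, adjustment, covariate_spec,
            n_treatment_years,
        )
    )
    ok = outcome_kind or cohort.outcome_kind

    nte_pt, warm_nte = _fit_contrast(
        flat, rows, nte_kind, ok, adjustment, years, visit_levels
    )
    nce_pt, warm_nce = _fit_contrast(
        flat, rows, nce_kind, ok, adjustment, years, visit_levels
    )

    rng = np.random.default_rng(seed)
    nte_draws, nce_draws = [], []
    n_failed = 0
    is_count = ok == "count"
    for _ in range(B):
        sampled = rng.integers(0, flat.n_persons, flat.n_persons)
        idx = flat.gather(sampled)
        try:
            d_nte, _ = _fit_contrast(
                flat, idx, nte_kind, ok, adjustment, years, visit_levels,
                warm=warm_nte if is_count else None,
            )
            d_nce, _ = _fit_contrast(
                flat, idx, nce_kind, ok, adjustment, years, visit_levels,
                warm=warm_nce if is_count else None,
            )
        except (FitError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        nte_draws.append(d_nte)
        nce_draws.append(d_nce)
    if n_failed > MAX_FAILURE_RATE * B:
        raise BootstrapError(f"{n_failed}/{B} bootstrap resamples failed")

    nte_arr = np.asarray(nte_draws)
    nce_arr = np.asarray(nce_draws)
    nccte_arr = nte_arr - nce_arr
    nccte_pt = nte_pt - nce_pt

    def record(name: str, pts: np.ndarray, draws: np.ndarray) -> EffectRecord:
        comps = {}
        for i, comp in enumerate(comp_names):
            d = draws[:, i]
            p = invert_pvalue(d, null=0.0)  # log scale for counts: null RR=1
            lo, hi = percentile_ci(d)
            pt = pts[i]
            if scale == "rate_ratio":
                pt, lo, hi = np.exp(pt), np.exp(lo), np.exp(hi)
            comps[comp] = BootstrapResult(
                point=float(pt),
                ci_low=float(lo),
                ci_high=float(hi),
                p_value=p,
                B=B,
                seed=seed,
                n_failed=n_failed,
            )
        return EffectRecord(name=name, components=comps)

    return EffectTriple(
        comparison=comparison,
        scale=scale,
        nte=record("nte", nte_pt, nte_arr),
        nce=record("nce", nce_pt, nce_arr),
        nccte=record("nccte", nccte_pt, nccte_arr),
        adjustment=adjustment,
        B=B,
        seed=seed,
        n_failed=n_failed,
    )
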