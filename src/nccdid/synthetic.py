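"""Synthetic two-genotype x two-period registry cohorts with known truth.

The generator emulates the statistical structure the estimators assume: an
untreated-world mean that is additive in period, genotype and their
interaction,

    E(Y^{X=0} | P=p, G=g) = alpha + beta_P p + beta_G g + gamma_PG p g,

plus a common annual visit slope, a step + slope treatment effect applied
only in the treated cell (G=1, P=1), baseline covariates whose distribution
may depend on G and P, a person-level random intercept shared across both
periods (inducing within-person correlation the independence working model
deliberately ignores), and completely-at-random visit missingness.  Count
outcomes use a log-linear mean with per-year treatment log-rate-ratios and
a person-level gamma frailty for overdispersion.

Because the mean structure is known in closed form, every configuration
carries exact ground-truth naive, negative-control and corrected effects
(:func:`ground_truth`), which recovery and calibration tests compare
against.  Scenario presets mirror the three canonical confounding
structures: ``scenario1`` (outcome independent of G and P given treatment),
``scenario2`` (dependence only through a measured baseline covariate) and
``scenario3`` (direct dependence on G and P).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class CovariateGen:
    """Generative rule for one baseline covariate.

    ``kind`` is ``"binary"`` (Bernoulli with prevalence ``base + g_shift*G +
    p_shift*P``) or ``"normal"`` (mean ``base + g_shift*G + p_shift*P``, SD
    ``sd``).  ``effect`` is the additive effect on the continuous outcome per
    unit of the covariate; ``log_effect`` the effect on the count log rate.
    Drawn once per (person, period), matching baseline measurement in the
    year before visit 0 of each period.
    """

    name: str
    kind: str = "binary"
    base: float = 0.5
    g_shift: float = 0.0
    p_shift: float = 0.0
    sd: float = 1.0
    effect: float = 0.0
    log_effect: float = 0.0

    def mean(self, g: int, p: int) -> float:
        m = self.base + self.g_shift * g + self.p_shift * p
        return float(np.clip(m, 0.0, 1.0)) if self.kind == "binary" else float(m)


@dataclass(frozen=True)
class CountParams:
    """Count-outcome generative parameters (log scale unless noted).

    ``baseline_rate`` is the untreated mean count per year (natural scale);
    ``log_rr_treat`` the per-treatment-year log rate ratios applied in the
    (G=1, P=1) cell at visits j = 0, 1, ...; ``dispersion`` the variance of
    the person-level gamma frailty (0 = Poisson).
    """

    baseline_rate: float = 18.0
    log_rr_treat: tuple[float, ...] = (
        np.log(0.5),
        np.log(0.4),
        np.log(0.4),
        np.log(0.4),
    )
    dispersion: float = 0.5
    beta_P: float = 0.0
    beta_G: float = 0.0
    gamma_PG: float = 0.0
    beta_J: float = 0.0


#: genotype-label frequencies for the G=0 group, loosely mirroring the
#: frequency of F508del homozygotes (~54%) and heterozygotes among
#: nongating genotypes; used only by sensitivity-filter tests.
DEFAULT_G0_LABELS = {"F508del_hom": 0.54, "F508del_het": 0.36, "other": 0.10}


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generative configuration; defaults give a scenario-3 registry.

    Defaults are sized as a scaled-down registry: 450 treatment-eligible and
    2,000 ineligible persons, up to J=4 annual visits per period, 70% of
    persons contributing to both periods.  Outcome scale mimics ppFEV1
    (baseline ~70 points, annual decline 0.5, between-person SD 10, residual
    SD 5) with a 5-point treatment step and 0.5-point/yr slope change.
    """

    n_g1: int = 450
    n_g0: int = 2000
    p_both_periods: float = 0.7
    J: int = 4
    alpha: float = 70.0
    beta_P: float = 1.0
    beta_G: float = 2.0
    gamma_PG: float = 0.0
    beta_J: float = -0.5
    delta_St: float = 5.0
    delta_Sl: float = 0.5
    sd_person: float = 10.0
    sd_noise: float = 5.0
    covariate_specs: tuple[CovariateGen, ...] = ()
    count_params: CountParams = field(default_factory=CountParams)
    p_missing_visit: float = 0.1
    g0_label_probs: dict | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_g1 < 1 or self.n_g0 < 1:
            raise ConfigError("need at least one person per genotype group")
        if not (0.0 <= self.p_both_periods <= 1.0):
            raise ConfigError("p_both_periods must be in [0, 1]")
        if not (0.0 <= self.p_missing_visit <= 1.0):
            raise ConfigError("p_missing_visit must be in [0, 1]")
        if self.J < 1:
            raise ConfigError("J must be >= 1")
        if self.sd_person < 0 or self.sd_noise < 0:
            raise ConfigError("SDs must be nonnegative")
        if self.count_params.baseline_rate <= 0:
            raise ConfigError("baseline_rate must be positive")
        if self.count_params.dispersion < 0:
            raise ConfigError("dispersion must be nonnegative")
        names = [c.name for c in self.covariate_specs]
        if len(set(names)) != len(names):
            raise ConfigError("covariate names must be unique")


def scenario_config(name: str, **overrides) -> SyntheticConfig:
    """Preset configurations for the three confounding scenarios.

    - ``scenario1``: no G or P effect on the untreated outcome.
    - ``scenario2``: G and P act on the outcome only through a measured
      binary baseline covariate ``H`` (prevalence shifted by G and P).
    - ``scenario3``: direct G and P effects (beta_G=2, beta_P=1, gamma_PG=0).
    """
    base = SyntheticConfig()
    if name == "scenario1":
        cfg = replace(base, beta_P=0.0, beta_G=0.0, gamma_PG=0.0)
    elif name == "scenario2":
        cfg = replace(
            base,
            beta_P=0.0,
            beta_G=0.0,
            gamma_PG=0.0,
            covariate_specs=(
                CovariateGen(
                    name="H", kind="binary", base=0.5, g_shift=0.2, p_shift=0.1,
                    effect=5.0, log_effect=0.1,
                ),
            ),
        )
    elif name == "scenario3":
        cfg = base
    else:
        raise ConfigError(f"unknown scenario {name!r}")
    return replace(cfg, **overrides)


# -- panel construction --------------------------------------------------


def _draw_panel(config: SyntheticConfig, rng: np.random.Generator):
    """Person/period/visit skeleton shared by both outcome generators.

    Returns per-record arrays (person index, G, P, j), per-person arrays
    (random-effect draw index), and per-record covariate values.
    """
    n = config.n_g1 + config.n_g0
    genotype = np.concatenate([np.ones(config.n_g1, int), np.zeros(config.n_g0, int)])
    ids = np.array(
        [f"g1-{i:05d}" for i in range(config.n_g1)]
        + [f"g0-{i:05d}" for i in range(config.n_g0)]
    )
    both = rng.random(n) < config.p_both_periods
    solo_period = rng.integers(0, 2, size=n)
    # person-period pairs
    pp_person = np.concatenate([np.arange(n)[both], np.arange(n)[both],
                                np.arange(n)[~both]])
    pp_period = np.concatenate([np.zeros(both.sum(), int), np.ones(both.sum(), int),
                                solo_period[~both]])
    order = np.lexsort((pp_period, pp_person))
    pp_person, pp_period = pp_person[order], pp_period[order]
    m = len(pp_person)
    # covariates per (person, period)
    cov_pp: dict[str, np.ndarray] = {}
    for spec in config.covariate_specs:
        mean = (
            spec.base
            + spec.g_shift * genotype[pp_person]
            + spec.p_shift * pp_period
        )
        if spec.kind == "binary":
            cov_pp[spec.name] = (rng.random(m) < np.clip(mean, 0, 1)).astype(float)
        elif spec.kind == "normal":
            cov_pp[spec.name] = mean + spec.sd * rng.standard_normal(m)
        else:
            raise ConfigError(f"unknown covariate kind {spec.kind!r}")
    # expand to visits, apply missingness
    J = config.J
    rec_pp = np.repeat(np.arange(m), J)
    visit = np.tile(np.arange(J), m)
    keep = rng.random(len(rec_pp)) >= config.p_missing_visit
    # guarantee every person-period keeps >= 1 visit (re-add visit 0)
    kept_pp = np.zeros(m, bool)
    kept_pp[rec_pp[keep]] = True
    keep |= (visit == 0) & ~kept_pp[rec_pp]
    rec_pp, visit = rec_pp[keep], visit[keep]
    person_idx = pp_person[rec_pp]
    period = pp_period[rec_pp]
    g = genotype[person_idx]
    cov = {k: v[rec_pp] for k, v in cov_pp.items()}
    # genotype labels
    probs = config.g0_label_probs or DEFAULT_G0_LABELS
    labels_g0 = rng.choice(list(probs), size=n, p=list(probs.values()))
    labels = np.where(genotype == 1, "gating", labels_g0)
    return ids, genotype, labels, person_idx, g, period, visit, cov


def _to_cohort(
    config, ids, labels, person_idx, g, period, visit, cov, y, outcome_kind
) -> Cohort:
    df = pd.DataFrame(
        {
            "person_id": ids[person_idx],
            "genotype": g,
            "period": period,
            "visit": visit,
            "outcome": y,
        }
    )
    for k, v in cov.items():
        df[k] = v
    df["genotype_label"] = labels[person_idx]
    return Cohort(df, outcome_kind=outcome_kind, max_visits=config.J)


def simulate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate a continuous-outcome cohort under the configured model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    ids, genotype, labels, person_idx, g, period, visit, cov = _draw_panel(config, rng)
    b = config.sd_person * rng.standard_normal(len(ids))
    treated = (g == 1) & (period == 1)
    mean = (
        config.alpha
        + config.beta_P * period
        + config.beta_G * g
        + config.gamma_PG * period * g
        + config.beta_J * visit
        + treated * (config.delta_St + config.delta_Sl * visit)
    )
    for spec in config.covariate_specs:
        mean = mean + spec.effect * cov[spec.name]
    y = mean + b[person_idx] + config.sd_noise * rng.standard_normal(len(mean))
    return _to_cohort(
        config, ids, labels, person_idx, g, period, visit, cov, y, "continuous"
    )


def simulate_count_cohort(config: SyntheticConfig) -> Cohort:
    """Generate a count-outcome cohort (gamma-frailty overdispersed counts)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    ids, genotype, labels, person_idx, g, period, visit, cov = _draw_panel(config, rng)
    cp = config.count_params
    log_rr = np.zeros(config.J)
    upto = min(config.J, len(cp.log_rr_treat))
    log_rr[:upto] = cp.log_rr_treat[:upto]
    treated = (g == 1) & (period == 1)
    eta = (
        np.log(cp.baseline_rate)
        + cp.beta_P * period
        + cp.beta_G * g
        + cp.gamma_PG * period * g
        + cp.beta_J * visit
        + treated * log_rr[visit]
    )
    for spec in config.covariate_specs:
        eta = eta + spec.log_effect * cov[spec.name]
    if cp.dispersion > 0:
        shape = 1.0 / cp.dispersion
        frailty = rng.gamma(shape, cp.dispersion, size=len(ids))
    else:
        frailty = np.ones(len(ids))
    y = rng.poisson(np.exp(eta) * frailty[person_idx]).astype(float)
    return _to_cohort(
        config, ids, labels, person_idx, g, period, visit, cov, y, "count"
    )


# -- closed-form ground truth --------------------------------------------


@dataclass(frozen=True)
class ComparisonTruth:
    """True step/slope effects for one comparison on the difference scale."""

    nte_step: float
    nte_slope: float
    nce_step: float
    nce_slope: float

    @property
    def nccte_step(self) -> float:
        return self.nte_step - self.nce_step

    @property
    def nccte_slope(self) -> float:
        return self.nte_slope - self.nce_slope


@dataclass(frozen=True)
class GroundTruth:
    """Closed-form effects implied by a generator configuration.

    Difference-scale step/slope truths per comparison, count-scale per-year
    log rate ratios, and the causal estimand itself (``cte_step``,
    ``cte_slope``): the treatment step and slope actually applied in the
    treated cell.  When ``gamma_PG = 0`` the corrected effects equal the
    estimand for both comparisons.
    """

    time_period: ComparisonTruth
    genotype: ComparisonTruth
    cte_step: float
    cte_slope: float
    count_nte_log_rr: dict[str, np.ndarray]
    count_nce_log_rr: dict[str, np.ndarray]

    def count_nccte_log_rr(self, comparison: str) -> np.ndarray:
        return self.count_nte_log_rr[comparison] - self.count_nce_log_rr[comparison]

    def as_dict(self) -> dict:
        out = {"cte_step": self.cte_step, "cte_slope": self.cte_slope}
        for comp in ("time_period", "genotype"):
            t: ComparisonTruth = getattr(self, comp)
            out[comp] = {
                "nte_step": t.nte_step,
                "nte_slope": t.nte_slope,
                "nce_step": t.nce_step,
                "nce_slope": t.nce_slope,
                "nccte_step": t.nccte_step,
                "nccte_slope": t.nccte_slope,
                "count_nte_log_rr": list(self.count_nte_log_rr[comp]),
                "count_nce_log_rr": list(self.count_nce_log_rr[comp]),
                "count_nccte_log_rr": list(self.count_nccte_log_rr(comp)),
            }
        return out


def ground_truth(config: SyntheticConfig) -> GroundTruth:
    """Expected (unadjusted) effects implied by the generator's mean model.

    Covariate-mediated shifts contribute ``effect * (prevalence or mean
    shift)`` to the naive and negative-control contrasts and cancel exactly
    in the corrected effects.  Slope truths: only the treated cell's slope
    differs (by ``delta_Sl``), so every NCE slope is 0.
    """
    config.validate()
    cov_p = sum(s.effect * s.p_shift for s in config.covariate_specs)
    cov_g = sum(s.effect * s.g_shift for s in config.covariate_specs)
    tp = ComparisonTruth(
        nte_step=config.delta_St + config.beta_P + config.gamma_PG + cov_p,
        nte_slope=config.delta_Sl,
        nce_step=config.beta_P + cov_p,
        nce_slope=0.0,
    )
    gt = ComparisonTruth(
        nte_step=config.delta_St + config.beta_G + config.gamma_PG + cov_g,
        nte_slope=config.delta_Sl,
        nce_step=config.beta_G + cov_g,
        nce_slope=0.0,
    )
    cp = config.count_params
    lcov_p = sum(s.log_effect * s.p_shift for s in config.covariate_specs)
    lcov_g = sum(s.log_effect * s.g_shift for s in config.covariate_specs)
    log_rr = np.zeros(config.J)
    upto = min(config.J, len(cp.log_rr_treat))
    log_rr[:upto] = cp.log_rr_treat[:upto]
    nte_log = {
        "time_period": log_rr + cp.beta_P + cp.gamma_PG + lcov_p,
        "genotype": log_rr + cp.beta_G + cp.gamma_PG + lcov_g,
    }
    nce_log = {
        "time_period": np.full(config.J, cp.beta_P + lcov_p),
        "genotype": np.full(config.J, cp.beta_G + lcov_g),
    }
    return GroundTruth(
        time_period=tp,
        genotype=gt,
        cte_step=config.delta_St + config.gamma_PG,
        cte_slope=config.delta_Sl,
        count_nte_log_rr=nte_log,
        count_nce_log_rr=nce_log,
    )
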