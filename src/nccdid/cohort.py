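"""Data model for a two-genotype x two-period longitudinal cohort.

A cohort holds one row per person-visit: a person identifier, a binary
genotype indicator ``G`` (1 = treatment-eligible genotype), a binary period
indicator ``P`` (1 = post-introduction period), a 0-based annual visit index
``j``, an outcome value, and optional baseline covariates measured in the
year before visit 0 of each period (so a person observed in both periods may
carry different baseline values in each).

The four genotype-by-period cells are labelled A (P=0, G=1), B (P=1, G=1),
C (P=0, G=0) and D (P=1, G=0).  Only group B is treated.  Analysis sets are
built by pairing two groups and attaching a pseudo-treatment label ``X``;
for negative-control contrasts the treatment label is switched onto an
untreated group.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("nccdid")

#: canonical column names of the long-format table
CORE_COLUMNS = ("person_id", "genotype", "period", "visit", "outcome")

#: optional free-text genotype label used by sensitivity filters
LABEL_COLUMN = "genotype_label"


class CohortError(ValueError):
    """Invalid cohort data (domain violations, duplicates, empty groups)."""


class SchemaError(CohortError):
    """A required column is missing or mis-declared."""


class GroupId(enum.Enum):
    """Genotype-by-period cell: A=(P0,G1), B=(P1,G1), C=(P0,G0), D=(P1,G0)."""

    A = "A"
    B = "B"
    C = "C"
    D = "D"

    @property
    def period(self) -> int:
        return {"A": 0, "B": 1, "C": 0, "D": 1}[self.value]

    @property
    def genotype(self) -> int:
        return {"A": 1, "B": 1, "C": 0, "D": 0}[self.value]


class ContrastKind(enum.Enum):
    """Two-group contrast with a pseudo-treatment label X.

    Naive effects compare the treated group B against a control; negative
    control effects switch the treatment label onto an untreated group:

    - ``NTE_P``: groups A (X=0) vs B (X=1) — time-period comparison.
    - ``NTE_G``: groups D (X=0) vs B (X=1) — genotype comparison.
    - ``NCE_P``: groups C (X=0) vs D (X=1) — label switched onto D.
    - ``NCE_G``: groups C (X=0) vs A (X=1) — label switched onto A.
    """

    NTE_P = "NTE_P"
    NTE_G = "NTE_G"
    NCE_P = "NCE_P"
    NCE_G = "NCE_G"

    @property
    def control_group(self) -> GroupId:
        return {
            ContrastKind.NTE_P: GroupId.A,
            ContrastKind.NTE_G: GroupId.D,
            ContrastKind.NCE_P: GroupId.C,
            ContrastKind.NCE_G: GroupId.C,
        }[self]

    @property
    def treated_group(self) -> GroupId:
        """The group carrying the (possibly switched) label X = 1."""
        return {
            ContrastKind.NTE_P: GroupId.B,
            ContrastKind.NTE_G: GroupId.B,
            ContrastKind.NCE_P: GroupId.D,
            ContrastKind.NCE_G: GroupId.A,
        }[self]


def assign_group(genotype: int, period: int) -> GroupId:
    """Map a (genotype, period) pair to its group label.

    Raises :class:`CohortError` if either argument is not 0 or 1.
    """
    if genotype not in (0, 1) or period not in (0, 1):
        raise CohortError(
            f"genotype and period must be 0 or 1, got G={genotype!r}, P={period!r}"
        )
    return {
        (0, 1): GroupId.A,
        (1, 1): GroupId.B,
        (0, 0): GroupId.C,
        (1, 0): GroupId.D,
    }[(period, genotype)]


@dataclass(frozen=True)
class VisitRecord:
    """One person-visit row: outcome Y at visit j for (person, G, P)."""

    person_id: str
    genotype: int
    period: int
    visit: int
    outcome_value: float
    covariates: Mapping[str, float] = field(default_factory=dict)

    @property
    def group(self) -> GroupId:
        return assign_group(self.genotype, self.period)


@dataclass
class Cohort:
    """Validated long-format cohort.

    Parameters
    ----------
    data
        One row per person-visit with columns ``person_id, genotype, period,
        visit, outcome`` plus any covariate columns and an optional
        ``genotype_label`` column.
    outcome_kind
        ``"continuous"`` or ``"count"``; count outcomes must be nonnegative
        integers.
    max_visits
        Number of annual visits per period, J (visit indices run 0..J-1).
    """

    data: pd.DataFrame
    outcome_kind: str = "continuous"
    max_visits: int = 4

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        df = self.data
        if self.outcome_kind not in ("continuous", "count"):
            raise CohortError(f"unknown outcome_kind {self.outcome_kind!r}")
        for col in CORE_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing required column {col!r}")
        for col in ("genotype", "period"):
            bad = ~df[col].isin([0, 1])
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise CohortError(
                    f"non-binary {col} value {df[col].iloc[row]!r} in row {row}"
                )
        visits = df["visit"].to_numpy()
        if len(df) and (
            (visits < 0).any()
            or (visits >= self.max_visits).any()
            or not np.array_equal(visits, visits.astype(int))
        ):
            raise CohortError(
                f"visit indices must be integers in 0..{self.max_visits - 1}"
            )
        dup = df.duplicated(subset=["person_id", "period", "visit"])
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0])
            raise CohortError(
                f"duplicate (person_id, period, visit) at row {row}: "
                f"{tuple(df.loc[row, ['person_id', 'period', 'visit']])}"
            )
        if self.outcome_kind == "count" and len(df):
            y = df["outcome"].to_numpy(dtype=float)
            if np.isnan(y).any() or (y < 0).any() or (y != np.round(y)).any():
                raise CohortError("count outcomes must be nonnegative integers")
        # covariates constant within (person, period)
        for col in self.covariate_columns:
            nun = df.groupby(["person_id", "period"])[col].nunique(dropna=False)
            if (nun > 1).any():
                key = nun[nun > 1].index[0]
                raise CohortError(
                    f"covariate {col!r} varies within (person, period) {key}"
                )

    # -- derived views ---------------------------------------------------

    @property
    def covariate_columns(self) -> list[str]:
        reserved = set(CORE_COLUMNS) | {LABEL_COLUMN}
        return [c for c in self.data.columns if c not in reserved]

    @property
    def n_persons(self) -> int:
        return self.data["person_id"].nunique()

    def group_labels(self) -> pd.Series:
        """Group label (A/B/C/D) of every record."""
        g = self.data["genotype"].to_numpy()
        p = self.data["period"].to_numpy()
        lab = np.where(g == 1, np.where(p == 1, "B", "A"), np.where(p == 1, "D", "C"))
        return pd.Series(lab, index=self.data.index, name="group")

    def group_sizes(self) -> dict[str, int]:
        """Person counts per group (a person may appear in two groups)."""
        labels = self.group_labels()
        out = {g.value: 0 for g in GroupId}
        sizes = (
            self.data.assign(group=labels)
            .groupby("group", sort=False)["person_id"]
            .nunique()
        )
        out.update(sizes.to_dict())
        return out

    def records(self) -> Iterable[VisitRecord]:
        covs = self.covariate_columns
        for row in self.data.itertuples(index=False):
            d = row._asdict()
            yield VisitRecord(
                person_id=d["person_id"],
                genotype=int(d["genotype"]),
                period=int(d["period"]),
                visit=int(d["visit"]),
                outcome_value=d["outcome"],
                covariates={c: d[c] for c in covs},
            )

    def equals(self, other: "Cohort") -> bool:
        a = canonical_order(self.data)
        b = canonical_order(other.data)
        return (
            self.outcome_kind == other.outcome_kind
            and self.max_visits == other.max_visits
            and list(a.columns) == list(b.columns)
            and a.equals(b)
        )


@dataclass
class AnalysisSet:
    """A two-group contrast: records of the pair tagged with X in {0, 1}.

    ``X = 1`` marks the contrast's (pseudo-)treated group — group B for the
    naive effects, and the label-switched group (D for NCE_P, A for NCE_G)
    for the negative control effects.
    """

    data: pd.DataFrame  # includes an "X" column
    contrast: ContrastKind
    outcome_kind: str
    covariate_spec: "CovariateSpec | None" = None  # noqa: F821 (estimators)
    max_visits: int = 4

    def __post_init__(self) -> None:
        x = self.data["X"]
        if not set(np.unique(x)) <= {0, 1}:
            raise CohortError("X must be binary")
        for level in (0, 1):
            if not (x == level).any():
                raise CohortError(f"contrast {self.contrast.value}: no X={level} records")

    @property
    def n_persons(self) -> int:
        return self.data["person_id"].nunique()


def build_contrast(
    cohort: Cohort,
    kind: ContrastKind,
    covariate_spec: "CovariateSpec | None" = None,  # noqa: F821
) -> AnalysisSet:
    """Select the contrast's two groups and attach the pseudo-treatment X.

    Records outside the pair are excluded.  For adjusted analyses, records
    of persons missing any covariate named in ``covariate_spec`` are dropped
    (complete case) with a logged count.
    """
    labels = cohort.group_labels()
    ctrl, trt = kind.control_group, kind.treated_group
    for grp in (ctrl, trt):
        if not (labels == grp.value).any():
            raise CohortError(
                f"contrast {kind.value} requires group {grp.value}, "
                "which is empty in this cohort"
            )
    mask = labels.isin([ctrl.value, trt.value])
    df = cohort.data.loc[mask].copy()
    df["X"] = (labels.loc[mask] == trt.value).astype(int)
    if covariate_spec is not None and covariate_spec.names:
        missing = [c for c in covariate_spec.names if c not in df.columns]
        if missing:
            raise SchemaError(f"covariates not in cohort: {missing}")
        complete = df[list(covariate_spec.names)].notna().all(axis=1)
        n_drop = int((~complete).sum())
        if n_drop:
            logger.info(
                "contrast %s: dropped %d records with missing covariates",
                kind.value,
                n_drop,
            )
        df = df.loc[complete]
    return AnalysisSet(
        data=df.reset_index(drop=True),
        contrast=kind,
        outcome_kind=cohort.outcome_kind,
        covariate_spec=covariate_spec,
        max_visits=cohort.max_visits,
    )


def restrict_genotype_subset(
    cohort: Cohort, keep: Callable[[str], bool] | Sequence[str]
) -> Cohort:
    """Restrict the G=0 (ineligible-genotype) persons by genotype label.

    ``keep`` is a predicate on the ``genotype_label`` column, or a collection
    of labels to retain.  G=1 persons are always kept; used for sensitivity
    analyses that narrow the comparison genotypes.
    """
    if LABEL_COLUMN not in cohort.data.columns:
        raise SchemaError(f"cohort has no {LABEL_COLUMN!r} column")
    if not callable(keep):
        allowed = set(keep)
        keep = lambda lab: lab in allowed  # noqa: E731
    labels = cohort.data[LABEL_COLUMN]
    g0 = cohort.data["genotype"] == 0
    retained = ~g0 | labels.map(keep).astype(bool)
    if g0.any() and not (retained & g0).any():
        raise CohortError("predicate removes every G=0 person")
    return Cohort(
        data=cohort.data.loc[retained].reset_index(drop=True),
        outcome_kind=cohort.outcome_kind,
        max_visits=cohort.max_visits,
    )


# -- baseline summaries --------------------------------------------------


def summarize_baseline(
    cohort: Cohort, covariates: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-group baseline table: n, mean (SD) / count (%) per covariate.

    Each person contributes one baseline row per period (their covariates are
    constant within a period), so a person present in both periods appears in
    both of their groups with the period-specific baseline values.  Binary
    covariates (values within {0, 1}) are summarised as count (%), others as
    mean (SD); a single observation reports SD 0.0.
    """
    if covariates is None:
        covariates = cohort.covariate_columns
    for c in covariates:
        if c not in cohort.data.columns:
            raise SchemaError(f"covariate {c!r} not in cohort")
    df = cohort.data.assign(group=cohort.group_labels())
    base = df.drop_duplicates(subset=["person_id", "period"])
    rows = []
    for grp in GroupId:
        sub = base.loc[base["group"] == grp.value]
        row: dict[str, object] = {"group": grp.value, "n_persons": len(sub)}
        for c in covariates:
            vals = sub[c].dropna().to_numpy(dtype=float)
            binary = len(vals) == 0 or np.isin(vals, [0.0, 1.0]).all()
            if binary:
                row[f"{c}_count"] = int(vals.sum())
                row[f"{c}_pct"] = (
                    100.0 * vals.mean() if len(vals) else 0.0
                )
            else:
                row[f"{c}_mean"] = float(vals.mean()) if len(vals) else np.nan
                row[f"{c}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def write_summary(table: pd.DataFrame, path: str | Path, fmt: str = "csv") -> None:
    path = Path(path)
    if fmt == "csv":
        table.to_csv(path)
    elif fmt == "json":
        path.write_text(json.dumps(table.reset_index().to_dict("records"), indent=2))
    else:
        raise ValueError(f"unknown format {fmt!r}")


# -- long-format I/O -----------------------------------------------------


def canonical_order(df: pd.DataFrame) -> pd.DataFrame:
    """Rows sorted by (person_id, period, visit); core columns first."""
    reserved = [c for c in CORE_COLUMNS if c in df.columns]
    rest = [c for c in df.columns if c not in reserved]
    out = df[reserved + rest].sort_values(
        ["person_id", "period", "visit"], kind="mergesort"
    )
    return out.reset_index(drop=True)


def read_long_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    outcome_kind: str = "continuous",
    max_visits: int = 4,
    sep: str = ",",
) -> Cohort:
    """Read a delimited long-format table into a validated :class:`Cohort`.

    ``schema`` maps canonical names (``person_id``, ``genotype``, ``period``,
    ``visit``, ``outcome``) to the file's column names; unmapped extra columns
    are carried as covariates (plus ``genotype_label`` if present).  Rows with
    a missing outcome are dropped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, dtype={"person_id": str})
    schema = dict(schema or {})
    rename = {v: k for k, v in schema.items() if v in df.columns}
    missing = [k for k, v in schema.items() if v not in df.columns]
    if missing:
        raise SchemaError(f"schema names absent from file: {missing}")
    df = df.rename(columns=rename)
    for col in CORE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path.name}")
    df["person_id"] = df["person_id"].astype(str)
    n_missing = int(df["outcome"].isna().sum())
    if n_missing:
        logger.info("%s: dropped %d rows with missing outcome", path.name, n_missing)
        df = df.loc[df["outcome"].notna()]
    for col in ("genotype", "period", "visit"):
        df[col] = pd.to_numeric(df[col]).astype(int)
    return Cohort(canonical_order(df), outcome_kind=outcome_kind, max_visits=max_visits)


def write_long_table(cohort: Cohort, path: str | Path, sep: str = ",") -> None:
    """Write a cohort losslessly with deterministic row and column order."""
    canonical_order(cohort.data).to_csv(path, sep=sep, index=False)
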