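import numpy as np
import pandas as pd
import pytest

import nccdid as nd


def make_analysis_set(
    x, j, y, persons=None, outcome_kind="continuous", cov=None, spec=None,
    contrast=nd.ContrastKind.NTE_P, max_visits=4,
):
    """Assemble an AnalysisSet directly from arrays (estimator tests)."""
    x = np.asarray(x)
    if persons is None:
        persons = [f"p{i}" for i in range(len(x))]
    df = pd.DataFrame(
        {
            "person_id": persons,
            "X": x.astype(int),
            "visit": np.asarray(j).astype(int),
            "outcome": np.asarray(y, dtype=float),
        }
    )
    if cov is not None:
        for name, vals in cov.items():
            df[name] = vals
    return nd.AnalysisSet(
        data=df,
        contrast=contrast,
        outcome_kind=outcome_kind,
        covariate_spec=spec,
        max_visits=max_visits,
    )


@pytest.fixture
def four_group_cohort():
    """One person per group, two visits each, a baseline covariate."""
    rows = []
    for pid, g, p in [("a1", 1, 0), ("b1", 1, 1), ("c1", 0, 0), ("d1", 0, 1)]:
        for j in (0, 1):
            rows.append(
                {
                    "person_id": pid,
                    "genotype": g,
                    "period": p,
                    "visit": j,
                    "outcome": 50.0 + 10 * g + 5 * p + j,
                    "age": {"a1": 10.0, "b1": 20.0, "c1": 30.0, "d1": 40.0}[pid],
                }
            )
    return nd.Cohort(pd.DataFrame(rows))


@pytest.fixture
def scenario3_cohort():
    cfg = nd.scenario_config("scenario3", n_g1=80, n_g0=120, seed=42)
    return nd.simulate_cohort(cfg)
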