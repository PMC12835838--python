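import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import maihda as m

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def codebook():
    return m.default_codebook()


@pytest.fixture(scope="session")
def schema(codebook):
    return m.build_schema(codebook)


@pytest.fixture(scope="session")
def analytic_cohort(codebook, schema):
    """Filtered, stratified synthetic cohort under the default study conditions
    (moderate interaction variance, no item non-response)."""
    cfg = m.SyntheticConfig(n=2500, seed=11, sigma_int2=0.3, missingness={})
    cohort = m.generate_population(cfg, codebook)
    filtered, _ = m.apply_complete_case_filter(cohort, codebook)
    stratified, strata = m.assign_strata(filtered, schema)
    return cfg, stratified, strata


@pytest.fixture(scope="session")
def maihda_result(analytic_cohort, schema, codebook):
    _, cohort, _ = analytic_cohort
    return m.run_maihda(
        cohort, schema, codebook, m.MaihdaOptions(ci_reps=500, seed=7)
    )


def toy_grouped_cohort():
    """2 strata x 3 observations; used by the integration oracles."""
    df = pd.DataFrame(
        {
            "stratum_id": ["a"] * 3 + ["b"] * 3,
            "online_info_seeking": ["Yes", "No", "Yes", "No", "No", "Yes"],
        }
    )
    return m.CohortTable(df, provenance="filtered")


def write_cohort_csv(path, rows, codebook):
    """Write a minimal cohort CSV with the codebook's column order."""
    cols = list(codebook.variable_names) + [codebook.outcome.name]
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, index=False)
    return path
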