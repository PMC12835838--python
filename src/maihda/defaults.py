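"""Default study configuration: the Brazilian digital-exclusion survey.

The package ships, as its default analysis configuration, the structure of a
2021–2023 cross-sectional survey of people experiencing homelessness and urban
community residents in Brazil: five categorical social dimensions (gender,
race/ethnicity, schooling, family income, public-health-system use), a binary
outcome (sought COVID-19 information online), the published marginal category
frequencies, and the published additive odds ratios. These defaults drive the
synthetic-data generator and the out-of-the-box pipeline; users with their own
survey supply their own codebook.
"""

from __future__ import annotations

import math

from .cohort import Codebook, Variable

__all__ = [
    "DEFAULT_BETA0",
    "DEFAULT_BETAS",
    "DEFAULT_MARGINALS",
    "DEFAULT_MISSINGNESS",
    "DEFAULT_REFERENCES",
    "DEFAULT_SIGMA_INT2",
    "default_codebook",
]

# Analytic category order doubles as the digit-code order for stratum IDs.
_GENDER = Variable(
    "gender", ("Man", "Woman", "No answer"), (True, True, False), missing_label="No answer"
)
_RACE = Variable("race_ethnicity", ("White", "Black or Brown", "Other"), (True, True, True))
_SCHOOLING = Variable(
    "schooling",
    ("No schooling", "Basic education", "Secondary education", "Higher education"),
    (True, True, True, True),
)
_INCOME = Variable(
    "income",
    (
        "Low income",
        "1-2 minimum wages",
        "2-3 minimum wages",
        "More than 3 minimum wages",
        "Did not know",
    ),
    (True, True, True, True, False),
    missing_label="Did not know",
)
_SUS = Variable("sus_use", ("Yes", "No"), (True, True))
_OUTCOME = Variable("online_info_seeking", ("Yes", "No"), (True, True))


def default_codebook() -> Codebook:
    """Codebook of the default survey: 5 dimensions, 2x3x4x4x2 = 192 strata."""
    return Codebook(
        variables=(_GENDER, _RACE, _SCHOOLING, _INCOME, _SUS),
        outcome=_OUTCOME,
        key_variables=("gender", "race_ethnicity", "schooling", "income", "sus_use"),
        outcome_positive="Yes",
    )


# Published marginal counts, renormalized over analytic categories only.
DEFAULT_MARGINALS: dict[str, dict[str, float]] = {
    "gender": {"Man": 1600 / 2601, "Woman": 1001 / 2601},
    "race_ethnicity": {
        "White": 601 / 2652,
        "Black or Brown": 1942 / 2652,
        "Other": 109 / 2652,
    },
    "schooling": {
        "No schooling": 905 / 2650,
        "Basic education": 726 / 2650,
        "Secondary education": 871 / 2650,
        "Higher education": 148 / 2650,
    },
    "income": {
        "Low income": 1655 / 2476,
        "1-2 minimum wages": 570 / 2476,
        "2-3 minimum wages": 157 / 2476,
        "More than 3 minimum wages": 94 / 2476,
    },
    "sus_use": {"Yes": 2433 / 2652, "No": 219 / 2652},
}

# Reference (omitted) category per dimension in the additive model.
DEFAULT_REFERENCES: dict[str, str] = {
    "gender": "Man",
    "race_ethnicity": "Black or Brown",
    "schooling": "No schooling",
    "income": "Low income",
    "sus_use": "Yes",
}

# Additive log-odds effects: natural logs of the published odds ratios.
DEFAULT_BETA0: float = math.log(0.19)
DEFAULT_BETAS: dict[tuple[str, str], float] = {
    ("gender", "Woman"): math.log(1.49),
    ("race_ethnicity", "White"): math.log(1.05),
    ("race_ethnicity", "Other"): math.log(1.35),
    ("schooling", "Basic education"): math.log(1.78),
    ("schooling", "Secondary education"): math.log(3.37),
    ("schooling", "Higher education"): math.log(5.59),
    ("income", "1-2 minimum wages"): math.log(2.37),
    ("income", "2-3 minimum wages"): math.log(2.85),
    ("income", "More than 3 minimum wages"): math.log(4.54),
    ("sus_use", "No"): math.log(0.92),
}

# Between-stratum interaction variance on the latent scale: sized so the
# full-model variance partition coefficient sits near 1% (0.0332/(0.0332+3.29)).
DEFAULT_SIGMA_INT2: float = 0.033

# Item non-response rates matching the published non-analytic response shares
# (gender "No answer" 51/2652, income "Did not know" 176/2652) plus a small
# outcome non-response; jointly they yield ~9% incomplete records.
DEFAULT_MISSINGNESS: dict[str, float] = {
    "gender": 51 / 2652,
    "income": 176 / 2652,
    "online_info_seeking": 0.009,
}
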