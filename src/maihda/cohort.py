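"""Cohort ingestion, validation, complete-case filtering and design-stage sizes.

Individual survey records are held as a :class:`CohortTable` — a thin wrapper
around a :class:`pandas.DataFrame` of category labels — validated against a
:class:`Codebook` that declares, per variable, the ordered category labels and
which of them are *analytic* (usable in the intersectional cross-classification)
versus response codes such as "No answer" that are treated as missing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from ._util import ceil_tol, round_half_up

MISSING = ""  # internal sentinel for a missing cell

__all__ = [
    "Codebook",
    "CohortTable",
    "ExclusionReport",
    "SampleSizeSpec",
    "SchemaError",
    "ValidationError",
    "Variable",
    "apply_complete_case_filter",
    "cochran_sample_size",
    "descriptive_table",
    "read_cohort",
]


class SchemaError(ValueError):
    """The file or codebook structure does not match expectations."""


class ValidationError(ValueError):
    """Cell values violate the codebook."""


@dataclass(frozen=True)
class Variable:
    """One survey variable: ordered labels plus per-label analytic flags."""

    name: str
    categories: tuple[str, ...]
    analytic: tuple[bool, ...]
    #: label written when the value is masked (e.g. "No answer"); empty-string
    #: missing is used when None.
    missing_label: str | None = None

    def __post_init__(self) -> None:
        if len(self.categories) < 2:
            raise SchemaError(f"variable {self.name!r} needs >=2 categories")
        if len(self.analytic) != len(self.categories):
            raise SchemaError(f"variable {self.name!r}: analytic flags mismatch")
        if self.missing_label is not None and self.missing_label not in self.categories:
            raise SchemaError(
                f"variable {self.name!r}: missing_label {self.missing_label!r} not a category"
            )

    @property
    def analytic_categories(self) -> tuple[str, ...]:
        return tuple(c for c, a in zip(self.categories, self.analytic) if a)

    def is_analytic(self, label: str) -> bool:
        try:
            return self.analytic[self.categories.index(label)]
        except ValueError:
            return False


@dataclass(frozen=True)
class Codebook:
    """Ordered variable definitions, the outcome, and the complete-case keys."""

    variables: tuple[Variable, ...]
    outcome: Variable
    key_variables: tuple[str, ...]
    outcome_positive: str

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate variable names in codebook")
        if len(self.outcome.analytic_categories) != 2:
            raise SchemaError("outcome must have exactly 2 analytic categories")
        if self.outcome_positive not in self.outcome.analytic_categories:
            raise SchemaError("outcome_positive must be an analytic outcome category")
        unknown = set(self.key_variables) - set(names)
        if unknown:
            raise SchemaError(f"key variables not in codebook: {sorted(unknown)}")

    @property
    def variable_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def variable(self, name: str) -> Variable:
        if name == self.outcome.name:
            return self.outcome
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    # -- YAML round-trip -----------------------------------------------------

    def to_dict(self) -> dict:
        def var(v: Variable) -> dict:
            return {
                "name": v.name,
                "categories": [
                    {"label": c, "analytic": bool(a)}
                    for c, a in zip(v.categories, v.analytic)
                ],
                "missing_label": v.missing_label,
            }

        return {
            "variables": [var(v) for v in self.variables],
            "outcome": var(self.outcome),
            "key_variables": list(self.key_variables),
            "outcome_positive": self.outcome_positive,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Codebook":
        def var(vd: Mapping) -> Variable:
            cats = tuple(c["label"] for c in vd["categories"])
            flags = tuple(bool(c.get("analytic", True)) for c in vd["categories"])
            return Variable(vd["name"], cats, flags, vd.get("missing_label"))

        return cls(
            variables=tuple(var(v) for v in d["variables"]),
            outcome=var(d["outcome"]),
            key_variables=tuple(d["key_variables"]),
            outcome_positive=d["outcome_positive"],
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Codebook":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class CohortTable:
    """Individual records; ``provenance`` is ``"raw"`` or ``"filtered"``."""

    df: pd.DataFrame
    provenance: str = "raw"

    @property
    def n(self) -> int:
        return len(self.df)

    def copy(self) -> "CohortTable":
        return CohortTable(self.df.copy(), self.provenance)


@dataclass
class ExclusionReport:
    """Complete-case accounting; counts always reconcile."""

    n_raw: int
    n_excluded: int
    n_retained: int
    pct_excluded: float
    per_variable: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "n_raw": self.n_raw,
                "n_excluded": self.n_excluded,
                "n_retained": self.n_retained,
                "pct_excluded": self.pct_excluded,
                "per_variable": self.per_variable,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs to the Cochran simple-random-sampling size formula."""

    z: float = 1.96
    epsilon: float = 0.05
    p_hat: float = 0.5
    population: int | None = None  # None = unbounded (infinite population)

    def __post_init__(self) -> None:
        if not (0 < self.epsilon < 1):
            raise ValueError("epsilon must be in (0, 1)")
        if not (0 <= self.p_hat <= 1):
            raise ValueError("p_hat must be in [0, 1]")
        if self.z <= 0:
            raise ValueError("z must be positive")
        if self.population is not None and self.population < 1:
            raise ValueError("population must be >= 1 when bounded")


def read_cohort(path: str | Path, codebook: Codebook) -> CohortTable:
    """Read a delimited cohort file and validate every cell against the codebook.

    Missing values may be encoded as empty strings or the literal ``NA``; a
    variable's designated missing label (e.g. "No answer") is kept verbatim —
    it is a real category, just a non-analytic one.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.apply(lambda s: s.str.strip())
    df = df.replace("NA", MISSING)

    required = set(codebook.variable_names) | {codebook.outcome.name}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise SchemaError(f"missing required columns: {sorted(missing_cols)}")
    unknown_cols = set(df.columns) - required - {"participant_id"}
    if unknown_cols:
        raise SchemaError(f"unknown columns not in codebook: {sorted(unknown_cols)}")

    problems: list[str] = []
    for name in sorted(required):
        var = codebook.variable(name)
        col = df[name]
        bad = ~(col.isin(var.categories) | (col == MISSING))
        if bad.any():
            for idx, val in col[bad].head(20).items():
                problems.append(f"row {idx}: {name}={val!r}")
    if problems:
        raise ValidationError(
            "unknown category labels:\n  " + "\n  ".join(problems)
        )
    return CohortTable(df.reset_index(drop=True), provenance="raw")


def _complete_mask(df: pd.DataFrame, codebook: Codebook) -> tuple[pd.Series, dict[str, int]]:
    checked = list(codebook.key_variables) + [codebook.outcome.name]
    ok = pd.Series(True, index=df.index)
    per_variable: dict[str, int] = {}
    for name in checked:
        var = codebook.variable(name)
        analytic = set(var.analytic_categories)
        good = df[name].isin(analytic)
        per_variable[name] = int((~good).sum())
        ok &= good
    return ok, per_variable


def apply_complete_case_filter(
    cohort: CohortTable, codebook: Codebook
) -> tuple[CohortTable, ExclusionReport]:
    """Drop records missing or non-analytic on any key variable or the outcome.

    Non-analytic responses ("No answer", "Did not know") count as missing for
    inclusion purposes, mirroring how analytic category sets are defined.
    """
    ok, per_variable = _complete_mask(cohort.df, codebook)
    retained = cohort.df[ok].reset_index(drop=True)
    n_raw, n_ret = len(cohort.df), len(retained)
    if n_ret == 0:
        raise ValidationError("complete-case filter left no analytic rows")
    report = ExclusionReport(
        n_raw=n_raw,
        n_excluded=n_raw - n_ret,
        n_retained=n_ret,
        pct_excluded=round_half_up(100.0 * (n_raw - n_ret) / n_raw, 1) if n_raw else 0.0,
        per_variable=per_variable,
    )
    return CohortTable(retained, provenance="filtered"), report


def descriptive_table(cohort: CohortTable, codebook: Codebook) -> pd.DataFrame:
    """Frequency table (variable, category, n, percent) over the whole cohort.

    Percentages use the cohort size as denominator and are rounded half-up to
    one decimal, the presentation convention of descriptive survey tables.
    A "(missing)" row appears for variables with blank cells.
    """
    total = cohort.n
    rows: list[dict] = []
    for name in list(codebook.variable_names) + [codebook.outcome.name]:
        var = codebook.variable(name)
        counts = cohort.df[name].value_counts()
        for label in var.categories:
            n = int(counts.get(label, 0))
            if n == 0 and not var.is_analytic(label):
                continue
            rows.append(
                {
                    "variable": name,
                    "category": label,
                    "n": n,
                    "percent": round_half_up(100.0 * n / total, 1) if total else 0.0,
                }
            )
        n_missing = int(counts.get(MISSING, 0))
        if n_missing:
            rows.append(
                {
                    "variable": name,
                    "category": "(missing)",
                    "n": n_missing,
                    "percent": round_half_up(100.0 * n_missing / total, 1),
                }
            )
    return pd.DataFrame(rows, columns=["variable", "category", "n", "percent"])


def cochran_sample_size(spec: SampleSizeSpec) -> int:
    """Minimum sample size under simple random sampling.

    ``n0 = z^2 p(1-p) / eps^2`` for an unbounded population; with a finite
    population ``N`` the correction ``n = n0 / (1 + (n0 - 1)/N)`` is applied
    to the *unrounded* ``n0``. The result is rounded up to the next integer.
    """
    n0 = spec.z**2 * spec.p_hat * (1.0 - spec.p_hat) / spec.epsilon**2
    if spec.population is None:
        return ceil_tol(n0)
    n = n0 / (1.0 + (n0 - 1.0) / spec.population)
    return ceil_tol(n)
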