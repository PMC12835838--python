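"""Intersectional strata: the full cross-classification and digit-coded IDs.

A stratum is one cell of the cross-classification of the analytic social
dimensions (e.g. gender x race/ethnicity x schooling x income x public-system
use -> 2*3*4*4*2 = 192 cells). Each cell gets a compact digit-string ID, one
digit per dimension, where digit ``d`` is the 1-based position of the category
in the schema's ordered list — e.g. ``"21321"`` = (Woman, White, Secondary
education, 1-2 minimum wages, SUS yes).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .cohort import Codebook, CohortTable, SchemaError

__all__ = [
    "StrataSchema",
    "Stratum",
    "assign_strata",
    "build_schema",
    "observed_strata",
    "strata_frame",
]


@dataclass(frozen=True)
class StrataSchema:
    """Ordered dimensions, each with its ordered analytic categories."""

    dimensions: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        for name, cats in self.dimensions:
            if len(cats) < 2:
                raise SchemaError(f"dimension {name!r} has <2 analytic categories")
            if len(cats) > 9:
                raise SchemaError(f"dimension {name!r} exceeds single-digit encoding")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.dimensions)

    @property
    def n_possible(self) -> int:
        n = 1
        for _, cats in self.dimensions:
            n *= len(cats)
        return n

    def encode(self, categories: Sequence[str]) -> str:
        if len(categories) != len(self.dimensions):
            raise ValueError("category tuple length does not match schema")
        digits = []
        for (name, cats), label in zip(self.dimensions, categories):
            try:
                digits.append(str(cats.index(label) + 1))
            except ValueError:
                raise ValueError(f"unknown category {label!r} for dimension {name!r}")
        return "".join(digits)

    def decode(self, stratum_id: str) -> tuple[str, ...]:
        if len(stratum_id) != len(self.dimensions):
            raise ValueError(f"stratum id {stratum_id!r} has wrong length")
        labels = []
        for (name, cats), ch in zip(self.dimensions, stratum_id):
            idx = int(ch) - 1
            if not (0 <= idx < len(cats)):
                raise ValueError(f"digit {ch!r} out of range for dimension {name!r}")
            labels.append(cats[idx])
        return tuple(labels)

    def all_cells(self):
        """Yield ``(id, categories)`` for every possible cell, in ID order."""
        for combo in itertools.product(*(cats for _, cats in self.dimensions)):
            yield self.encode(combo), combo


@dataclass
class Stratum:
    id: str
    categories: tuple[str, ...]
    n_obs: int

    @property
    def observed(self) -> bool:
        return self.n_obs > 0


def build_schema(codebook: Codebook) -> StrataSchema:
    """Schema over the codebook's analytic categories, in codebook order."""
    return StrataSchema(
        tuple((v.name, v.analytic_categories) for v in codebook.variables)
    )


def assign_strata(
    cohort: CohortTable, schema: StrataSchema
) -> tuple[CohortTable, list[Stratum]]:
    """Attach a ``stratum_id`` column and tabulate all possible cells.

    Requires a filtered cohort (every cell analytic). The returned stratum
    list covers every possible cell, including unobserved ones (``n_obs=0``),
    in ID order.
    """
    if cohort.provenance != "filtered":
        raise ValueError("assign_strata requires a filtered cohort")
    df = cohort.df.copy()
    ids = [
        schema.encode(tuple(row))
        for row in df[list(schema.names)].itertuples(index=False, name=None)
    ]
    df["stratum_id"] = ids
    counts = df["stratum_id"].value_counts()
    strata = [
        Stratum(sid, cats, int(counts.get(sid, 0))) for sid, cats in schema.all_cells()
    ]
    return CohortTable(df, provenance="filtered"), strata


def observed_strata(strata: Sequence[Stratum]) -> int:
    """Number of cells with at least one record."""
    return sum(1 for s in strata if s.observed)


def strata_frame(strata: Sequence[Stratum], schema: StrataSchema) -> pd.DataFrame:
    """CSV-ready table: id, one column per dimension, n_obs, observed."""
    rows = []
    for s in strata:
        row = {"stratum_id": s.id}
        row.update(dict(zip(schema.names, s.categories)))
        row["n_obs"] = s.n_obs
        row["observed"] = s.observed
        rows.append(row)
    return pd.DataFrame(rows)
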