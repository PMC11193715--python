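"""Longitudinal heterogeneous cohort tables.

A cohort is a set of N participants observed over V annual visits on D
longitudinal variables plus a handful of static (per-participant) variables.
The long form has one CSV row per attended visit; the wide form has one row
per participant with `<var>_VIS<vv>` columns.  Visits are indexed by age:
visit 0 corresponds to `base_age`, so a study covering ages 3-18 has 16
visits.  Missingness appears at two levels: a whole visit can be skipped
(attendance), and a single cell can be missing within an attended visit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VariableSpec",
    "VisitMap",
    "CohortTable",
    "infer_visit",
    "long_to_wide",
    "wide_to_long",
    "build_missingness_indicators",
    "median_impute",
    "read_variable_specs",
    "write_variable_specs",
]

DTYPES = {"real", "positive_real", "count", "categorical", "ordinal", "boolean"}


class VisitRangeError(ValueError):
    """Age maps outside the study's visit grid."""


class VisitCollisionError(ValueError):
    """Two long rows map to the same (participant, visit)."""


@dataclass(frozen=True)
class VariableSpec:
    """Statistical type, role and module assignment of one column."""

    name: str
    dtype: str
    role: str = "longitudinal"  # "static" | "longitudinal"
    module: str | None = None
    n_categories: int | None = None

    def __post_init__(self):
        if self.dtype not in DTYPES:
            raise ValueError(f"unknown dtype {self.dtype!r} for {self.name}")
        if self.role not in ("static", "longitudinal"):
            raise ValueError(f"unknown role {self.role!r} for {self.name}")
        if self.dtype in ("categorical", "ordinal"):
            if self.n_categories is None or self.n_categories < 2:
                raise ValueError(f"{self.name}: categorical/ordinal needs n_categories >= 2")
        if self.dtype == "boolean" and self.n_categories is None:
            object.__setattr__(self, "n_categories", 2)

    @property
    def is_discrete(self) -> bool:
        return self.dtype in ("categorical", "ordinal", "boolean")


@dataclass(frozen=True)
class VisitMap:
    """Age-to-visit translation: visit v covers age `base_age + v`."""

    base_age: int = 3
    n_visits: int = 16

    def infer_visit(self, age: float) -> int:
        return infer_visit(age, self)

    def age_of(self, visit: int) -> float:
        return float(self.base_age + visit)


def infer_visit(age: float, visit_map: VisitMap) -> int:
    """Map an age in years to its visit index by round-half-up."""
    if age <= 0:
        raise VisitRangeError(f"age must be positive, got {age}")
    visit = int(np.floor(age + 0.5)) - visit_map.base_age
    if not 0 <= visit < visit_map.n_visits:
        raise VisitRangeError(
            f"age {age} maps to visit {visit}, outside [0, {visit_map.n_visits - 1}]"
        )
    return visit


def _wide_col(var: str, visit: int) -> str:
    return f"{var}_VIS{visit:02d}"


@dataclass
class CohortTable:
    """Wide-form container: values[n, v, d] with observedness masks.

    `static` holds per-participant covariates indexed by participant id; the
    participant id itself counts as the first static column, so the wide view
    has `n_static + V * D` columns.
    """

    specs: Sequence[VariableSpec]
    static: pd.DataFrame  # index: participant id; columns: static vars (minus the id)
    values: np.ndarray  # (N, V, D) float64; NaN where missing
    mask: np.ndarray  # (N, V, D) bool, True = observed
    attendance: np.ndarray  # (N, V) bool, True = visit attended
    visit_map: VisitMap = field(default_factory=VisitMap)
    id_name: str = "pers_id"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.attendance = np.asarray(self.attendance, dtype=bool)
        # a missed visit blanks every cell of that visit
        self.mask = self.mask & self.attendance[:, :, None]
        self.values = np.where(self.mask, self.values, np.nan)
        if self.values.shape != self.mask.shape:
            raise ValueError("values/mask shape mismatch")
        if self.values.shape[:2] != self.attendance.shape:
            raise ValueError("attendance shape mismatch")

    # -- basic views ------------------------------------------------------
    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_visits(self) -> int:
        return self.values.shape[1]

    @property
    def ids(self) -> pd.Index:
        return self.static.index

    @property
    def longitudinal_specs(self) -> list[VariableSpec]:
        return [s for s in self.specs if s.role == "longitudinal"]

    @property
    def static_specs(self) -> list[VariableSpec]:
        return [s for s in self.specs if s.role == "static"]

    @property
    def long_var_names(self) -> list[str]:
        return [s.name for s in self.longitudinal_specs]

    def var_index(self, name: str) -> int:
        return self.long_var_names.index(name)

    def variable(self, name: str) -> np.ndarray:
        """(N, V) track of one longitudinal variable, NaN where missing."""
        return self.values[:, :, self.var_index(name)]

    @property
    def n_wide_columns(self) -> int:
        # participant id is the wide index; static covariates count as columns
        return len(self.static.columns) + self.n_visits * len(self.long_var_names)

    def copy(self) -> "CohortTable":
        return CohortTable(
            specs=list(self.specs),
            static=self.static.copy(),
            values=self.values.copy(),
            mask=self.mask.copy(),
            attendance=self.attendance.copy(),
            visit_map=self.visit_map,
            id_name=self.id_name,
        )

    # -- wide DataFrame ----------------------------------------------------
    def to_wide(self) -> pd.DataFrame:
        """Static columns first, then variable-major / visit-ascending."""
        blocks = [self.static]
        for d, name in enumerate(self.long_var_names):
            block = pd.DataFrame(
                self.values[:, :, d],
                index=self.static.index,
                columns=[_wide_col(name, v) for v in range(self.n_visits)],
            )
            blocks.append(block)
        out = pd.concat(blocks, axis=1)
        out.index.name = self.id_name
        return out

    def module_slice(self, module: str) -> tuple[np.ndarray, np.ndarray, list[VariableSpec]]:
        """(values, mask, specs) restricted to one module's variables."""
        idx = [d for d, s in enumerate(self.longitudinal_specs) if s.module == module]
        if not idx:
            raise KeyError(f"no longitudinal variables in module {module!r}")
        specs = [self.longitudinal_specs[d] for d in idx]
        return self.values[:, :, idx], self.mask[:, :, idx], specs


def long_to_wide(
    long_table: pd.DataFrame,
    specs: Sequence[VariableSpec],
    visit_map: VisitMap,
    id_col: str = "pers_id",
    age_col: str = "age",
) -> CohortTable:
    """Pivot per-visit rows into one wide row per participant.

    Rows are assigned to visits by rounding the age column; a visit with no
    row becomes a missing block.  Raises on (participant, visit) collisions
    and on out-of-range ages.
    """
    long_specs = [s for s in specs if s.role == "longitudinal"]
    static_specs = [s for s in specs if s.role == "static"]
    var_names = [s.name for s in long_specs]
    V, D = visit_map.n_visits, len(var_names)

    ids = pd.Index(pd.unique(long_table[id_col]), name=id_col)
    n = len(ids)
    pos = {pid: i for i, pid in enumerate(ids)}

    values = np.full((n, V, D), np.nan)
    attendance = np.zeros((n, V), dtype=bool)

    visits = np.array([infer_visit(a, visit_map) for a in long_table[age_col]])
    rows_i = long_table[id_col].map(pos).to_numpy()
    flat = rows_i * V + visits
    uniq, counts = np.unique(flat, return_counts=True)
    if (counts > 1).any():
        i, v = divmod(int(uniq[counts > 1][0]), V)
        raise VisitCollisionError(f"participant {ids[i]!r}: two rows map to visit {v}")
    attendance[rows_i, visits] = True
    for d, name in enumerate(var_names):
        values[rows_i, visits, d] = long_table[name].to_numpy(dtype=float)

    mask = attendance[:, :, None] & ~np.isnan(values)

    static = (
        long_table.groupby(id_col, sort=False)[[s.name for s in static_specs]].first()
        if static_specs
        else pd.DataFrame(index=ids)
    )
    static = static.reindex(ids)

    return CohortTable(
        specs=list(specs),
        static=static,
        values=values,
        mask=mask,
        attendance=attendance,
        visit_map=visit_map,
        id_name=id_col,
    )


def wide_to_long(cohort: CohortTable, visit_map: VisitMap | None = None) -> pd.DataFrame:
    """Emit one row per attended (participant, visit), restoring the age column."""
    vm = visit_map or cohort.visit_map
    var_names = cohort.long_var_names
    records = []
    for i, pid in enumerate(cohort.ids):
        stat = cohort.static.loc[pid].to_dict() if len(cohort.static.columns) else {}
        for v in range(cohort.n_visits):
            if not cohort.attendance[i, v]:
                continue
            rec = {cohort.id_name: pid, **stat, "age": vm.age_of(v)}
            for d, name in enumerate(var_names):
                rec[name] = cohort.values[i, v, d]
            records.append(rec)
    cols = [cohort.id_name, *cohort.static.columns, "age", *var_names]
    return pd.DataFrame.from_records(records, columns=cols)


def build_missingness_indicators(cohort: CohortTable) -> pd.DataFrame:
    """Per-participant boolean visit-attendance indicators (True = attended)."""
    cols = [f"visit{v:02d}" for v in range(cohort.n_visits)]
    return pd.DataFrame(cohort.attendance.copy(), index=cohort.ids, columns=cols)


def median_impute(cohort: CohortTable, variables: Iterable[str]) -> CohortTable:
    """Fill cell-level missingness of the named variables with their medians.

    Only cells inside attended visits are imputed; visit-level missingness is
    information (it feeds the attendance indicators) and is never filled.
    """
    out = cohort.copy()
    for name in variables:
        d = out.var_index(name)
        track = out.values[:, :, d]
        holes = out.attendance & ~out.mask[:, :, d]
        if not holes.any():
            continue
        med = np.nanmedian(track)
        track[holes] = med
        out.mask[:, :, d] |= holes
    return out


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def read_variable_specs(path) -> list[VariableSpec]:
    """Read a JSON or YAML list of variable declarations."""
    text = open(path).read()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return [VariableSpec(**entry) for entry in raw]


def write_variable_specs(specs: Sequence[VariableSpec], path) -> None:
    entries = []
    for s in specs:
        e = {"name": s.name, "dtype": s.dtype, "role": s.role}
        if s.module is not None:
            e["module"] = s.module
        if s.n_categories is not None:
            e["n_categories"] = s.n_categories
        entries.append(e)
    with open(path, "w") as fh:
        if str(path).endswith(".json"):
            json.dump(entries, fh, indent=2)
        else:
            yaml.safe_dump(entries, fh, sort_keys=False)
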