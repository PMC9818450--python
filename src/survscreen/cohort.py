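"""Cohort data model: expression matrices, clinical survival tables, and
the alignment / dichotomization primitives every downstream stage consumes.

An analysis cohort pairs a normalized (log-scale) gene-expression matrix
(genes x samples) with a clinical table carrying right-censored survival
endpoints and the standard AML confounders (age, sex, WBC, transplant type,
ELN risk category, treatment arm).  All times are in months internally;
loaders convert from a declared unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("survscreen")

# ---------------------------------------------------------------------------
# controlled vocabularies

SEX_LEVELS = ("male", "female")
TRANSPLANT_LEVELS = ("allo", "auto", "none")
ELN_LEVELS = ("favorable", "intermediate", "adverse")  # ordered, favorable first
TREATMENT_LEVELS = ("HSCT", "chemo_only")
CR_LEVELS = ("CR/CRi", "refractory")
ELN_DIALECTS = ("ELN2010", "ELN2017")
ENDPOINTS = ("OS", "DFS", "EFS")

_CATEGORY_LEVELS = {
    "sex": SEX_LEVELS,
    "transplant": TRANSPLANT_LEVELS,
    "eln": ELN_LEVELS,
    "treatment": TREATMENT_LEVELS,
    "cr_status": CR_LEVELS,
}

#: months per declared input time unit
_TIME_FACTORS = {"months": 1.0, "days": 12.0 / 365.25, "years": 12.0}

REQUIRED_CLINICAL = ("sample_id", "os_time", "os_event")
OPTIONAL_CLINICAL = (
    "dfs_time",
    "dfs_event",
    "efs_time",
    "efs_event",
    "age",
    "sex",
    "wbc",
    "transplant",
    "eln",
    "treatment",
    "cr_status",
)


class CohortError(ValueError):
    """Raised on any cohort-level validation failure."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ExpressionMatrix:
    """Normalized log-scale expression, genes x samples.

    ``values[i, j]`` is the expression of ``gene_ids[i]`` in
    ``sample_ids[j]``.  Identifiers are unique; the matrix is finite.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise CohortError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for kind, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise CohortError(f"duplicated {kind} id: {dup!r}")
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise CohortError(
                f"non-finite expression value for gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene(self, gene_id: str) -> np.ndarray:
        """Expression vector of one gene across samples."""
        try:
            idx = self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None
        return self.values[idx]

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [pos[s] for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids), self.values[:, cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class ClinicalTable:
    """Typed per-sample clinical table, one row per sample.

    ``data`` is indexed by sample id; times are months and strictly
    positive, event flags are 0/1 integers, categoricals use the module's
    controlled vocabularies.
    """

    data: pd.DataFrame
    eln_dialect: str | None = None

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise CohortError(f"duplicated sample id in clinical table: {dup!r}")
        for col in ("os_time", "dfs_time", "efs_time"):
            if col in df.columns:
                t = df[col].dropna()
                if (t <= 0).any():
                    bad = t[t <= 0].index[0]
                    raise CohortError(f"{col} must be > 0; sample {bad!r} violates")
        for col in ("os_event", "dfs_event", "efs_event"):
            if col in df.columns:
                e = df[col].dropna()
                if not e.isin([0, 1]).all():
                    bad = e[~e.isin([0, 1])].index[0]
                    raise CohortError(f"{col} must be 0/1; sample {bad!r} violates")
        for col, levels in _CATEGORY_LEVELS.items():
            if col in df.columns:
                vals = df[col].dropna()
                bad = vals[~vals.isin(levels)]
                if len(bad):
                    raise CohortError(
                        f"unknown {col} value {bad.iloc[0]!r} (sample {bad.index[0]!r}); "
                        f"allowed: {levels}"
                    )
        if self.eln_dialect is not None and self.eln_dialect not in ELN_DIALECTS:
            raise CohortError(f"unknown ELN dialect {self.eln_dialect!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def endpoints(self) -> list[str]:
        """Endpoints with both a time and an event column present."""
        out = []
        for ep in ENDPOINTS:
            lo = ep.lower()
            if f"{lo}_time" in self.data.columns and f"{lo}_event" in self.data.columns:
                out.append(ep)
        return out

    def survival(self, endpoint: str = "OS") -> tuple[np.ndarray, np.ndarray]:
        """(times, events) arrays for an endpoint, complete cases only."""
        lo = endpoint.lower()
        if endpoint not in self.endpoints():
            raise CohortError(f"endpoint {endpoint} not available in this table")
        sub = self.data[[f"{lo}_time", f"{lo}_event"]].dropna()
        return sub[f"{lo}_time"].to_numpy(float), sub[f"{lo}_event"].to_numpy(int)

    def subset(self, sample_ids: list[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(sample_ids)].copy(), self.eln_dialect)


@dataclass
class Cohort:
    """Aligned expression + clinical data; the unit every stage consumes."""

    name: str
    expression: ExpressionMatrix
    clinical: ClinicalTable

    def __post_init__(self) -> None:
        if self.expression.n_samples == 0:
            raise CohortError(f"cohort {self.name!r} is empty")
        if self.expression.sample_ids != self.clinical.sample_ids:
            raise CohortError(
                f"cohort {self.name!r}: expression and clinical sample ids differ "
                "(run harmonize first)"
            )

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids

    @property
    def n_samples(self) -> int:
        return self.expression.n_samples

    def endpoints(self) -> list[str]:
        return self.clinical.endpoints()


@dataclass
class GroupLabels:
    """High/low dichotomization of one gene at a cutpoint.

    ``high`` means expression strictly greater than the cutpoint; ties at
    the cutpoint go to the low group.
    """

    labels: pd.Series  # sample_id -> "high" | "low"
    cutpoint: float
    gene_id: str | None = None

    def __post_init__(self) -> None:
        counts = self.labels.value_counts()
        if counts.get("high", 0) == 0 or counts.get("low", 0) == 0:
            raise CohortError(
                f"degenerate dichotomization at cutpoint {self.cutpoint}: "
                "one group is empty"
            )

    @property
    def indicator(self) -> np.ndarray:
        """1 for high, 0 for low, aligned with ``labels`` order."""
        return (self.labels == "high").to_numpy(int)

    @property
    def n_high(self) -> int:
        return int((self.labels == "high").sum())

    @property
    def n_low(self) -> int:
        return int((self.labels == "low").sum())


# ---------------------------------------------------------------------------
# loaders / writers


def _first_duplicate(ids) -> str | None:
    seen = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def _sniff_sep(path) -> str:
    with open(path) as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def load_expression(path, sep: str | None = None) -> ExpressionMatrix:
    """Load a genes-x-samples delimited text matrix.

    First column holds gene identifiers, the header row sample identifiers;
    tab- or comma-delimited (sniffed when ``sep`` is None).  Duplicate ids
    and non-numeric cells are hard errors naming the offender.
    """
    sep = sep or _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    gene_ids = [str(g) for g in raw.index]
    sample_ids = [str(s) for s in raw.columns]
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        try:
            # correctly-rounded float() parse: load/write round trips exactly
            values[:, j] = raw[col].to_numpy(dtype="U").astype(float)
        except ValueError:
            for i, cell in enumerate(raw[col]):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise CohortError(
                        f"non-numeric expression cell at gene {gene_ids[i]!r}, "
                        f"sample {col!r} (value {cell!r}) in {path}"
                    ) from None
    return ExpressionMatrix(gene_ids, sample_ids, values)


def _shortest_repr(v) -> str:
    return repr(float(v))


def write_expression(matrix: ExpressionMatrix, path, sep: str = "\t") -> None:
    # shortest-repr floats: load -> write -> load is value-exact
    matrix.to_frame().to_csv(path, sep=sep, index_label="gene_id", float_format=_shortest_repr)


def load_clinical(
    path,
    column_map: dict,
    sep: str | None = None,
) -> ClinicalTable:
    """Load a clinical table using a declared column mapping.

    ``column_map`` binds canonical field names to file columns and declares
    encodings, e.g.::

        {
          "sample_id": "patient", "os_time": "OS_days", "os_event": "status",
          "age": "age", "sex": "gender",
          "encodings": {"sex": {"M": "male", "F": "female"}},
          "time_unit": "days",
          "eln_dialect": "ELN2017",
        }

    Times are converted to months from the declared unit (days / 365.25 x 12,
    years x 12).  Unknown category values after encoding are rejected.
    """
    sep = sep or _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype={column_map.get("sample_id", "sample_id"): str})
    encodings = column_map.get("encodings", {})
    unit = column_map.get("time_unit", "months")
    if unit not in _TIME_FACTORS:
        raise CohortError(f"unknown time unit {unit!r}; expected one of {sorted(_TIME_FACTORS)}")
    factor = _TIME_FACTORS[unit]

    for field_name in REQUIRED_CLINICAL:
        col = column_map.get(field_name)
        if col is None:
            raise CohortError(f"column map missing mandatory field {field_name!r}")
        if col not in raw.columns:
            raise CohortError(f"mandatory column {col!r} (field {field_name!r}) absent from {path}")

    out = {}
    for field_name in REQUIRED_CLINICAL + OPTIONAL_CLINICAL:
        col = column_map.get(field_name)
        if col is None:
            continue
        if col not in raw.columns:
            raise CohortError(f"declared column {col!r} (field {field_name!r}) absent from {path}")
        series = raw[col]
        if field_name in encodings:
            mapping = {str(k): v for k, v in encodings[field_name].items()}
            series = series.astype(str).where(series.notna()).map(mapping)
            unmapped = raw[col].notna() & series.isna()
            if unmapped.any():
                raise CohortError(
                    f"value {raw[col][unmapped].iloc[0]!r} in column {col!r} not covered "
                    f"by the declared encoding for {field_name!r}"
                )
        if field_name.endswith("_time"):
            series = pd.to_numeric(series) * factor
        elif field_name.endswith("_event"):
            series = pd.to_numeric(series)
        elif field_name in ("age", "wbc"):
            series = pd.to_numeric(series)
        out[field_name] = series

    df = pd.DataFrame(out)
    df = df.set_index(pd.Index(raw[column_map["sample_id"]].astype(str), name="sample_id"))
    df = df.drop(columns=["sample_id"])
    return ClinicalTable(df, eln_dialect=column_map.get("eln_dialect"))


def write_clinical(table: ClinicalTable, path, sep: str = "\t") -> None:
    table.data.to_csv(path, sep=sep, index_label="sample_id", float_format=_shortest_repr)


# ---------------------------------------------------------------------------
# alignment & dichotomization


def harmonize(expression: ExpressionMatrix, clinical: ClinicalTable, name: str) -> Cohort:
    """Restrict both components to the shared samples, identically ordered.

    Sample order follows the expression matrix.  Dropped-sample counts are
    logged; an empty intersection is a hard error.
    """
    clin_ids = set(clinical.sample_ids)
    shared = [s for s in expression.sample_ids if s in clin_ids]
    if not shared:
        raise CohortError(f"cohort {name!r}: expression and clinical tables share no sample ids")
    dropped_expr = expression.n_samples - len(shared)
    dropped_clin = len(clin_ids) - len(shared)
    if dropped_expr or dropped_clin:
        logger.info(
            "cohort %s: dropped %d expression-only and %d clinical-only samples "
            "during harmonization (%d retained)",
            name, dropped_expr, dropped_clin, len(shared),
        )
    return Cohort(name, expression.subset_samples(shared), clinical.subset(shared))


def dichotomize(values: pd.Series, cutpoint: float, gene_id: str | None = None) -> GroupLabels:
    """Split samples into high (value > cutpoint) and low (value <= cutpoint).

    The cutpoint must fall strictly inside the observed range so both
    groups are non-empty; ties at the cutpoint go to the low group.
    """
    values = pd.Series(values, dtype=float)
    vmin, vmax = values.min(), values.max()
    if not (vmin <= cutpoint < vmax):
        raise CohortError(
            f"cutpoint {cutpoint} outside the open interior of the observed "
            f"range [{vmin}, {vmax}]"
        )
    labels = pd.Series(np.where(values > cutpoint, "high", "low"), index=values.index)
    return GroupLabels(labels, float(cutpoint), gene_id)
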