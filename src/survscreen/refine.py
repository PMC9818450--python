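"""Risk-group refinement by a binary expression marker.

Takes a base categorical risk system (e.g. ELN favorable / intermediate /
adverse), shifts marker-high patients one level toward adverse (default
mapping, fully overridable), and compares the stratification power of the
base and refined groupings by Kaplan-Meier + log-rank on the identical
sample set.  Also contrasts the marker's hazard across treatment
subgroups (HSCT vs chemotherapy-only) with an explicit interaction model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortError, ELN_LEVELS, GroupLabels
from .survival import (
    CoxFit,
    KMCurve,
    LogRankResult,
    SurvivalError,
    cox_fit,
    km_estimate,
    logrank_test,
)

logger = logging.getLogger("survscreen")

#: default refinement: marker-high shifts one level toward adverse
DEFAULT_MAPPING = {
    ("favorable", "low"): "favorable",
    ("favorable", "high"): "intermediate",
    ("intermediate", "low"): "intermediate",
    ("intermediate", "high"): "adverse",
    ("adverse", "low"): "adverse",
    ("adverse", "high"): "adverse",
}


@dataclass
class RefinedGroups:
    """Refined risk assignment and the (base, marker) -> refined mapping used."""

    assignments: pd.Series  # sample_id -> refined category
    mapping: dict[tuple[str, str], str]
    base_system: str

    @property
    def categories(self) -> list[str]:
        return sorted(self.assignments.unique())


@dataclass
class GroupingEvaluation:
    """KM curves per category plus the across-category log-rank test."""

    name: str
    km: dict[str, KMCurve]
    logrank: LogRankResult
    sizes: dict[str, int]


@dataclass
class StratificationComparison:
    """Base vs refined grouping evaluated on the identical sample set."""

    base: GroupingEvaluation
    refined: GroupingEvaluation
    n: int


@dataclass
class SubgroupHazard:
    """Marker hazard per treatment arm plus the pooled interaction model."""

    subgroup_fits: dict[str, CoxFit]  # treatment level -> univariate marker fit
    interaction_fit: CoxFit           # marker + treatment + marker x treatment


def refine_risk(
    base_groups: pd.Series,
    marker_labels: GroupLabels,
    mapping: dict[tuple[str, str], str] | None = None,
    base_system: str = "ELN",
    base_levels=ELN_LEVELS,
) -> RefinedGroups:
    """Refine a base risk category with a binary marker.

    Default mapping shifts marker-high patients one level toward adverse
    (favorable -> intermediate, intermediate -> adverse, adverse stays);
    marker-low patients keep their base category.  A custom total mapping
    over (base category, marker level) pairs may be supplied.
    """
    mapping = dict(DEFAULT_MAPPING if mapping is None else mapping)
    shared = base_groups.index.intersection(marker_labels.labels.index)
    if shared.empty:
        raise CohortError("base groups and marker labels share no samples")
    base = base_groups.loc[shared].dropna()
    marker = marker_labels.labels.loc[base.index]
    unknown = base[~base.isin(base_levels)]
    if len(unknown):
        raise CohortError(
            f"unknown base category {unknown.iloc[0]!r} (sample {unknown.index[0]!r})"
        )
    refined = {}
    for sid in base.index:
        key = (base.loc[sid], marker.loc[sid])
        if key not in mapping:
            raise CohortError(f"refinement mapping does not cover combination {key}")
        refined[sid] = mapping[key]
    return RefinedGroups(pd.Series(refined, name="refined"), mapping, base_system)


def _evaluate_grouping(name: str, times, events, groups: pd.Series) -> GroupingEvaluation:
    levels = groups.unique()
    if len(levels) < 2:
        raise SurvivalError(
            f"grouping {name!r} has a single category; log-rank is undefined (dof = 0)"
        )
    sizes = groups.value_counts().to_dict()
    for lvl, n in sizes.items():
        if n < 2:
            warnings.warn(
                f"grouping {name!r}: category {lvl!r} has fewer than 2 samples; retained",
                stacklevel=3,
            )
    km = {}
    for lvl in levels:
        m = (groups == lvl).to_numpy()
        km[str(lvl)] = km_estimate(times[m], events[m])
    lr = logrank_test(times, events, groups.to_numpy())
    return GroupingEvaluation(name, km, lr, {str(k): int(v) for k, v in sizes.items()})


def evaluate_stratification(
    cohort: Cohort,
    grouping_a: pd.Series,
    grouping_b: pd.Series,
    endpoint: str = "OS",
    names: tuple[str, str] = ("base", "refined"),
) -> StratificationComparison:
    """Compare two categorical groupings of the same samples.

    Both groupings are restricted to their common samples with the
    endpoint observed, then each gets per-category KM curves and an
    across-category log-rank test.
    """
    lo = endpoint.lower()
    clin = cohort.clinical.data
    surv = clin[[f"{lo}_time", f"{lo}_event"]].dropna()
    shared = surv.index.intersection(grouping_a.dropna().index).intersection(
        grouping_b.dropna().index
    )
    if shared.empty:
        raise CohortError("groupings share no samples with the endpoint observed")
    times = surv.loc[shared, f"{lo}_time"].to_numpy(float)
    events = surv.loc[shared, f"{lo}_event"].to_numpy(int)
    base = _evaluate_grouping(names[0], times, events, grouping_a.loc[shared])
    refined = _evaluate_grouping(names[1], times, events, grouping_b.loc[shared])
    return StratificationComparison(base, refined, len(shared))


def subgroup_hazard(
    cohort: Cohort,
    marker_labels: GroupLabels,
    treatment_column: str = "treatment",
    endpoint: str = "OS",
) -> SubgroupHazard:
    """Marker hazard within each treatment arm plus a pooled interaction fit.

    Fits a univariate Cox model on the marker indicator separately in each
    treatment subgroup, and a pooled model with marker, treatment, and
    marker x treatment terms; under proportional hazards the interaction
    coefficient equals the difference of the subgroup log-HRs.
    """
    lo = endpoint.lower()
    clin = cohort.clinical.data
    cols = clin[[f"{lo}_time", f"{lo}_event", treatment_column]].dropna()
    shared = cols.index.intersection(marker_labels.labels.index)
    cols = cols.loc[shared]
    levels = cols[treatment_column].unique()
    if len(levels) < 2:
        raise CohortError(
            f"treatment column {treatment_column!r} is constant; subgroup contrast undefined"
        )
    times = cols[f"{lo}_time"].to_numpy(float)
    events = cols[f"{lo}_event"].to_numpy(int)
    marker = (marker_labels.labels.loc[cols.index] == "high").to_numpy(float)

    fits = {}
    for lvl in sorted(map(str, levels)):
        m = (cols[treatment_column] == lvl).to_numpy()
        if events[m].sum() == 0:
            raise CohortError(f"treatment subgroup {lvl!r} has zero events")
        fits[lvl] = cox_fit(
            marker[m][:, None], times[m], events[m], covariates=["marker_high"]
        )

    # pooled interaction model; chemotherapy-only is the natural control arm
    level_names = sorted(map(str, levels))
    ref = "chemo_only" if "chemo_only" in level_names else level_names[0]
    treat = (cols[treatment_column].astype(str) != ref).to_numpy(float)
    X = np.column_stack([marker, treat, marker * treat])
    inter = cox_fit(
        X, times, events, covariates=["marker_high", "treatment", "marker_x_treatment"]
    )
    return SubgroupHazard(subgroup_fits=fits, interaction_fit=inter)
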