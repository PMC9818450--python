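"""Transcriptome-wide prognostic screen.

For each gene in each cohort: find the ROC-optimal cutpoint for censored
overall survival, dichotomize the cohort into high/low expression groups,
fit univariate and confounder-adjusted Cox models on the group indicator,
and apply the filter gates (AUC > 0.5, sensitivity > 0.5, specificity >
0.5, univariate p < 0.05, multivariate p < 0.05).  Genes passing every
gate in every cohort with a consistent effect direction form the
cross-cohort intersection — the de facto false-discovery control of the
design.  Also provides the two-group clinical comparison tests
(Mann-Whitney / Fisher) and the drug-response correlation rule
(|Spearman rho| > 0.3 with p < 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, CohortError, GroupLabels, dichotomize
from .survival import CoxFit, SurvivalError, cox_fit, td_roc

logger = logging.getLogger("survscreen")

DEFAULT_HORIZON = 36.0  # months; the screen evaluates ROC at 3 years
DEFAULT_CONFOUNDERS = ("age", "sex", "wbc", "transplant", "eln")

#: candidate cutpoints restricted to this central quantile band to keep
#: both groups large enough for a stable Cox fit
CUTPOINT_BAND = (0.10, 0.90)


@dataclass
class GateThresholds:
    """Filter-gate configuration: strict inequalities throughout."""

    auc: float = 0.5
    sensitivity: float = 0.5
    specificity: float = 0.5
    alpha: float = 0.05
    #: "strict" requires multivariate p < alpha as a gate; "uni_only"
    #: gates on the univariate p only (multivariate fit still reported)
    gate_mode: str = "strict"

    def __post_init__(self):
        for name in ("auc", "sensitivity", "specificity", "alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"gate threshold {name}={v} outside (0, 1)")
        if self.gate_mode not in ("strict", "uni_only"):
            raise ValueError(f"unknown gate_mode {self.gate_mode!r}")


@dataclass
class CutpointResult:
    """ROC-optimal threshold for one gene at the evaluation horizon."""

    gene_id: str
    cutpoint: float
    auc: float
    sensitivity: float
    specificity: float
    horizon: float
    n_high: int
    n_low: int


@dataclass
class GeneScreenResult:
    """Per-gene, per-cohort screen outcome with the per-gate ledger."""

    cohort: str
    gene_id: str
    cutpoint: CutpointResult | None
    univariate: CoxFit | None
    multivariate: CoxFit | None
    gates: dict[str, bool]
    direction: str | None  # high_is_worse | low_is_worse
    failure_reason: str | None = None

    @property
    def passed(self) -> bool:
        return bool(self.gates) and all(self.gates.values())


@dataclass
class ScreenSummary:
    """Merged multi-cohort screen: per-cohort results and the intersection."""

    results: dict[str, dict[str, GeneScreenResult]]  # cohort -> gene -> result
    intersection: list[str]
    directions: dict[str, str]  # intersection gene -> shared direction

    def per_cohort_pass(self) -> dict[str, list[str]]:
        return {
            c: sorted(g for g, r in genes.items() if r.passed)
            for c, genes in self.results.items()
        }


@dataclass
class DrugCorrelationResult:
    """Spearman association of one gene with one drug-response readout."""

    gene_id: str
    drug_id: str
    rho: float
    p_value: float
    flagged: bool
    n: int


# ---------------------------------------------------------------------------
# optimal cutpoint


def optimal_cutpoint(
    marker,
    times,
    events,
    horizon: float = DEFAULT_HORIZON,
    gene_id: str = "marker",
    band: tuple[float, float] = CUTPOINT_BAND,
) -> CutpointResult:
    """Youden-optimal dichotomization threshold from the time-dependent ROC.

    Candidate thresholds are the observed marker values inside the central
    quantile ``band`` (default 10th-90th percentile).  The cutpoint
    maximizes J = sensitivity + specificity - 1; ties in J are broken
    toward the more balanced high/low split, then toward the smaller
    cutpoint.  Because only marker ranks matter, the chosen partition is
    invariant under strictly increasing marker transforms.
    """
    marker = np.asarray(marker, dtype=float)
    roc = td_roc(marker, times, events, horizon)
    lo, hi = np.quantile(marker, band)
    admissible = (roc.thresholds >= lo) & (roc.thresholds <= hi) & (roc.thresholds < marker.max())
    if not admissible.any():
        raise SurvivalError(
            f"no admissible candidate threshold in the {band} quantile band "
            f"(marker nearly constant?)"
        )
    cand = roc.thresholds[admissible]
    sens = roc.sensitivity[admissible]
    spec = roc.specificity[admissible]
    j = sens + spec - 1.0
    n = marker.size
    n_high = np.array([(marker > c).sum() for c in cand])
    balance = np.abs(2 * n_high - n)  # smaller = more balanced split
    # lexicographic argmin over (-J, imbalance, cutpoint)
    order = np.lexsort((cand, balance, -j))
    best = order[0]
    return CutpointResult(
        gene_id=gene_id,
        cutpoint=float(cand[best]),
        auc=roc.auc,
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        horizon=float(horizon),
        n_high=int(n_high[best]),
        n_low=int(n - n_high[best]),
    )


# ---------------------------------------------------------------------------
# confounder design matrix


def confounder_design(
    clinical: pd.DataFrame, confounders=DEFAULT_CONFOUNDERS
) -> tuple[np.ndarray, list[str], pd.Index]:
    """Numeric design matrix for the requested confounders.

    Encoding: age and WBC continuous; sex male=1 (female reference);
    transplant allo=1 (auto reference); ELN as two indicators with
    favorable as reference.  Confounder columns absent from the table are
    skipped (logged once by the caller); rows with a missing value in any
    used column are dropped (complete-case per model).
    """
    cols: dict[str, pd.Series] = {}
    for conf in confounders:
        if conf not in clinical.columns:
            continue
        col = clinical[conf]
        if conf in ("age", "wbc"):
            cols[conf] = pd.to_numeric(col)
        elif conf == "sex":
            cols["sex_male"] = col.map({"male": 1.0, "female": 0.0})
        elif conf == "transplant":
            cols["transplant_allo"] = col.map({"allo": 1.0, "auto": 0.0, "none": 0.0})
        elif conf == "eln":
            cols["eln_intermediate"] = col.map(
                {"favorable": 0.0, "intermediate": 1.0, "adverse": 0.0}
            )
            cols["eln_adverse"] = col.map(
                {"favorable": 0.0, "intermediate": 0.0, "adverse": 1.0}
            )
        elif conf == "treatment":
            cols["treatment_hsct"] = col.map({"HSCT": 1.0, "chemo_only": 0.0})
        else:
            cols[conf] = pd.to_numeric(col)
    if not cols:
        return np.empty((len(clinical), 0)), [], clinical.index
    design = pd.DataFrame(cols, index=clinical.index)
    complete = design.dropna()
    return complete.to_numpy(float), list(complete.columns), complete.index


# ---------------------------------------------------------------------------
# per-gene screen


def screen_gene(
    cohort: Cohort,
    gene_id: str,
    confounders=DEFAULT_CONFOUNDERS,
    thresholds: GateThresholds | None = None,
    horizon: float = DEFAULT_HORIZON,
    endpoint: str = "OS",
    cutpoint: float | None = None,
    band: tuple[float, float] = CUTPOINT_BAND,
) -> GeneScreenResult:
    """Screen one gene in one cohort through the full gate cascade.

    Cutpoint (optimal unless supplied), dichotomization, univariate Cox on
    the high/low indicator, confounder-adjusted Cox, then the five gates.
    Degenerate genes (constant expression, unconverged fits, no admissible
    cutpoint) fail with a recorded reason instead of raising.
    """
    thresholds = thresholds or GateThresholds()
    marker = pd.Series(cohort.expression.gene(gene_id), index=cohort.sample_ids)

    lo = endpoint.lower()
    clin = cohort.clinical.data
    surv_cols = clin[[f"{lo}_time", f"{lo}_event"]].dropna()
    times = surv_cols[f"{lo}_time"].to_numpy(float)
    events = surv_cols[f"{lo}_event"].to_numpy(int)
    marker_ep = marker.loc[surv_cols.index].to_numpy()

    def fail(reason: str) -> GeneScreenResult:
        return GeneScreenResult(
            cohort=cohort.name, gene_id=gene_id, cutpoint=None, univariate=None,
            multivariate=None, gates={}, direction=None, failure_reason=reason,
        )

    # 1. cutpoint: either reuse the supplied (OS-derived) one or optimize here
    try:
        if cutpoint is None:
            cut = optimal_cutpoint(
                marker_ep, times, events, horizon=horizon, gene_id=gene_id, band=band
            )
        else:
            roc = td_roc(marker_ep, times, events, horizon)
            idx = int(np.argmin(np.abs(roc.thresholds - cutpoint)))
            n_high = int((marker_ep > cutpoint).sum())
            cut = CutpointResult(
                gene_id, float(cutpoint), roc.auc,
                float(roc.sensitivity[idx]), float(roc.specificity[idx]),
                float(horizon), n_high, int(marker_ep.size - n_high),
            )
    except (SurvivalError, CohortError) as exc:
        return fail(f"cutpoint: {exc}")

    # 2. dichotomize on the full cohort at the chosen cutpoint
    try:
        labels = dichotomize(marker.loc[surv_cols.index], cut.cutpoint, gene_id)
    except CohortError as exc:
        return fail(f"dichotomization: {exc}")
    group = labels.indicator.astype(float)

    # 3. univariate Cox on the group indicator
    try:
        uni = cox_fit(group[:, None], times, events, covariates=["group_high"])
    except SurvivalError as exc:
        return fail(f"univariate Cox: {exc}")
    if not uni.converged:
        return fail("univariate Cox did not converge (possible separation)")

    # 4. multivariate Cox: group + available confounders, complete cases
    conf_X, conf_names, conf_idx = confounder_design(clin.loc[surv_cols.index], confounders)
    try:
        keep = surv_cols.index.get_indexer(conf_idx)
        Xm = np.column_stack([group[keep], conf_X])
        multi = cox_fit(
            Xm, times[keep], events[keep], covariates=["group_high"] + conf_names
        )
    except SurvivalError as exc:
        return fail(f"multivariate Cox: {exc}")
    if not multi.converged:
        return fail("multivariate Cox did not converge (possible separation)")

    # 5. gates (strict inequalities, matching the published filter)
    uni_p = float(uni.p_values[0])
    multi_p = float(multi.p_values[0])
    gates = {
        "auc_gate": cut.auc > thresholds.auc,
        "sens_gate": cut.sensitivity > thresholds.sensitivity,
        "spec_gate": cut.specificity > thresholds.specificity,
        "uni_p_gate": uni_p < thresholds.alpha,
        "multi_p_gate": (
            multi_p < thresholds.alpha if thresholds.gate_mode == "strict" else True
        ),
    }
    direction = "high_is_worse" if multi.coef[0] > 0 else "low_is_worse"
    return GeneScreenResult(
        cohort=cohort.name, gene_id=gene_id, cutpoint=cut, univariate=uni,
        multivariate=multi, gates=gates, direction=direction,
    )


def screen_cohort(
    cohort: Cohort,
    confounders=DEFAULT_CONFOUNDERS,
    genes: list[str] | None = None,
    thresholds: GateThresholds | None = None,
    horizon: float = DEFAULT_HORIZON,
    endpoint: str = "OS",
    band: tuple[float, float] = CUTPOINT_BAND,
) -> list[GeneScreenResult]:
    """Screen every requested gene in a cohort; failures never abort the run."""
    genes = list(genes) if genes is not None else list(cohort.expression.gene_ids)
    if not genes:
        raise CohortError("empty gene list")
    missing_conf = [c for c in confounders if c not in cohort.clinical.data.columns]
    if missing_conf:
        logger.info(
            "cohort %s: confounders %s absent; multivariate fits exclude them",
            cohort.name, missing_conf,
        )
    out = []
    for gene_id in genes:
        try:
            res = screen_gene(
                cohort, gene_id, confounders=confounders, thresholds=thresholds,
                horizon=horizon, endpoint=endpoint, band=band,
            )
        except Exception as exc:  # isolation: one bad gene never kills the run
            logger.warning("cohort %s gene %s: unexpected failure: %s", cohort.name, gene_id, exc)
            res = GeneScreenResult(
                cohort=cohort.name, gene_id=gene_id, cutpoint=None, univariate=None,
                multivariate=None, gates={}, direction=None,
                failure_reason=f"unexpected: {exc}",
            )
        out.append(res)
    n_pass = sum(r.passed for r in out)
    logger.info("cohort %s: %d/%d genes pass all gates", cohort.name, n_pass, len(out))
    return out


def intersect_cohorts(per_cohort: dict[str, list[GeneScreenResult]]) -> ScreenSummary:
    """Merge per-cohort screens: genes passing everywhere with one direction.

    A gene enters the intersection only if it passes all gates in every
    cohort AND its effect direction (from the sign of the adjusted group
    coefficient) is identical across cohorts.
    """
    if len(per_cohort) < 2:
        raise CohortError("cross-cohort intersection needs at least two cohorts")
    results = {c: {r.gene_id: r for r in rs} for c, rs in per_cohort.items()}
    shared = set.intersection(*(set(m) for m in results.values()))
    if not shared:
        raise CohortError("cohorts share no gene ids")
    intersection, directions = [], {}
    for gene in sorted(shared):
        rs = [results[c][gene] for c in results]
        if all(r.passed for r in rs) and len({r.direction for r in rs}) == 1:
            intersection.append(gene)
            directions[gene] = rs[0].direction
    return ScreenSummary(results=results, intersection=intersection, directions=directions)


# ---------------------------------------------------------------------------
# group comparison & multiple-testing report


def compare_groups(
    clinical: pd.DataFrame,
    labels: GroupLabels,
    variables: list[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare clinical variables between the high and low groups.

    Continuous variables get a two-sided Mann-Whitney test (exact for
    small samples without ties, normal approximation otherwise);
    categorical variables get Fisher's exact test on the contingency table
    (a seeded permutation version for tables larger than 2x2).
    """
    idx = labels.labels.index
    clin = clinical.loc[idx]
    high = labels.labels == "high"
    if variables is None:
        variables = [c for c in clin.columns if not c.endswith(("_time", "_event"))]
    rows = []
    for var in variables:
        col = clin[var].dropna()
        if col.nunique() < 2:
            raise CohortError(f"variable {var!r} has a single observed value")
        hi_mask = high.loc[col.index]
        if pd.api.types.is_numeric_dtype(col):
            u, p = stats.mannwhitneyu(
                col[hi_mask], col[~hi_mask], alternative="two-sided", method="auto"
            )
            rows.append({"variable": var, "test": "mann-whitney", "statistic": float(u),
                         "p_value": float(p)})
        else:
            table = pd.crosstab(hi_mask, col).to_numpy()
            if table.shape == (2, 2):
                odds, p = stats.fisher_exact(table, alternative="two-sided")
                stat = float(odds)
            else:
                res = stats.fisher_exact(
                    table, method=stats.PermutationMethod(rng=np.random.default_rng(seed))
                )
                stat, p = float(res.statistic), float(res.pvalue)
            rows.append({"variable": var, "test": "fisher-exact", "statistic": stat,
                         "p_value": float(p)})
    return pd.DataFrame(rows)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (auxiliary report only; the
    screen itself applies no multiplicity correction — the cross-cohort
    intersection is the error control)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adj, 0, 1)
    return out


# ---------------------------------------------------------------------------
# drug-response correlation


def correlate_drug_response(
    expression: pd.Series,
    drug_auc: pd.DataFrame,
    gene_id: str = "marker",
    rho_threshold: float = 0.3,
    alpha: float = 0.05,
) -> list[DrugCorrelationResult]:
    """Spearman correlation of a gene with per-sample drug-response AUCs.

    A drug is flagged as strongly correlated when |rho| > ``rho_threshold``
    and p < ``alpha`` (both strict).  Missing pairs are dropped per drug;
    fewer than 3 complete pairs is an error for that drug.
    """
    out = []
    for drug in drug_auc.columns:
        paired = pd.concat([expression, drug_auc[drug]], axis=1, join="inner").dropna()
        if len(paired) < 3:
            raise CohortError(f"drug {drug!r}: fewer than 3 paired observations")
        rho, p = stats.spearmanr(paired.iloc[:, 0], paired.iloc[:, 1])
        flagged = bool(abs(rho) > rho_threshold and p < alpha)
        out.append(
            DrugCorrelationResult(gene_id, str(drug), float(rho), float(p), flagged, len(paired))
        )
    return out
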