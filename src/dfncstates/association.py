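"""Covariate-adjusted association of occupancy rates with symptom scores.

One ordinary-least-squares model per (state OCR, timepoint) pair — with K = 3
states and five follow-ups that is 15 models per stratum — adjusting for age,
sex, education, income, marital status, employment, scanning site and
neighbourhood deprivation (ADI percentile).  The OCR t-statistic is converted
to a partial correlation r = t / sqrt(t**2 + df); Benjamini-Hochberg FDR is
applied within each stratum's family of tests.  Sex-stratified reruns drop sex
as a covariate, and two independent correlations can be compared through
Fisher's r-to-z transform.  A PCL-5 cutoff of 31 at the first follow-up splits
the cohort into posttraumatic-stress (PTS) and non-PTS groups, whose
separately clustered states can be compared centroid-by-centroid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .states import StateModel, cluster_states, match_states, ocr_table
from .windows import DfncWindows
from .synthetic import TIMEPOINTS, PCL5_COLUMNS

logger = logging.getLogger(__name__)

#: Covariates used in the full-cohort models; sex is dropped in stratified runs.
DEFAULT_COVARIATES: tuple[str, ...] = (
    "age", "sex", "education", "income_level", "employment", "marital",
    "site", "adi_percentile",
)
_CATEGORICAL = ("sex", "employment", "marital", "site")


@dataclass(frozen=True)
class AssociationResult:
    """One GLM's report for the OCR term."""

    predictor: str
    timepoint: str
    stratum: str
    beta: float
    se: float
    t: float
    df: int
    r: float
    ci_low: float
    ci_high: float
    p: float
    p_fdr: float | None
    n_used: int


@dataclass(frozen=True)
class FisherComparison:
    """Fisher r-to-z comparison of two independent correlations."""

    r1: float
    n1: int
    r2: float
    n2: int
    z_stat: float
    p_value: float
    tails: str


def t_to_r(t: float, df: float) -> float:
    """Partial correlation from a t-statistic: r = sign(t) * sqrt(t^2/(t^2+df))."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(np.sign(t) * np.sqrt(t**2 / (t**2 + df)))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving,
    capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_z_compare(
    r1: float, n1: int, r2: float, n2: int, tails: str = "one"
) -> FisherComparison:
    """Compare two independent correlations via Fisher's z-transform.

    Z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); the p-value is
    the upper-tail standard-normal probability of |Z| (one-tailed) or twice
    that (two-tailed).
    """
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("both sample sizes must exceed 3")
    if not (abs(r1) < 1 and abs(r2) < 1):
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (np.arctanh(r1) - np.arctanh(r2)) / se
    p = stats.norm.sf(abs(z))
    if tails == "two":
        p *= 2.0
    return FisherComparison(r1=r1, n1=n1, r2=r2, n2=n2, z_stat=float(z),
                            p_value=float(p), tails=tails)


def classify_pts(phenotypes: pd.DataFrame, cutoff: float = 31.0) -> pd.DataFrame:
    """Label subjects PTS / non-PTS from their first-follow-up PCL-5 score.

    Scores strictly above the cutoff are PTS; scores at or below it are
    non-PTS.  Subjects missing the score are excluded with a warning.
    """
    col = PCL5_COLUMNS["WK2"]
    df = phenotypes[["subject_id", col]].copy()
    missing = df[col].isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} subjects missing the WK2 score; excluded",
                      stacklevel=2)
        df = df[~missing]
    out = pd.DataFrame({
        "subject_id": df["subject_id"].to_numpy(),
        "label": np.where(df[col] > cutoff, "PTS", "non-PTS"),
    })
    out.attrs["cutoff"] = cutoff
    return out


def _design_matrix(df: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Dummy-code categorical covariates (first level dropped) and keep
    numeric ones as-is; income is an ordered category coded by level index."""
    parts = []
    for cov in covariates:
        if cov in _CATEGORICAL:
            dummies = pd.get_dummies(df[cov].astype("category"), prefix=cov,
                                     drop_first=True, dtype=float)
            parts.append(dummies)
        else:
            parts.append(df[[cov]].astype(float))
    return pd.concat(parts, axis=1) if parts else pd.DataFrame(index=df.index)


def fit_glm_association(
    ocr: pd.Series | np.ndarray,
    outcome: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
    predictor: str = "ocr",
    timepoint: str = "",
    stratum: str = "all",
    min_n: int = 10,
) -> AssociationResult:
    """OLS of outcome on [intercept, OCR, dummy-coded covariates].

    Listwise deletion over all columns.  Collinear design columns are dropped
    with a warning.  Returns beta/SE/t for the OCR term, its partial
    correlation, and a t-quantile 95% confidence interval.
    """
    x = pd.Series(np.asarray(ocr, dtype=float), name="ocr")
    y = pd.Series(np.asarray(outcome, dtype=float), name="y")
    frames = [x, y]
    if covariates is not None:
        Z = _design_matrix(covariates.reset_index(drop=True), covariates.columns)
        frames.append(Z.reset_index(drop=True))
    data = pd.concat([f.reset_index(drop=True) for f in frames], axis=1).dropna()
    n = len(data)
    if n < min_n:
        raise ValueError(f"only {n} complete cases (need >= {min_n})")
    if data["ocr"].std() == 0:
        raise ValueError("OCR predictor is constant")

    X = data.drop(columns="y")
    X = sm.add_constant(X, has_constant="add")
    # drop collinear columns (never the intercept or the predictor)
    keep = ["const", "ocr"]
    for col in [c for c in X.columns if c not in keep]:
        trial = X[keep + [col]]
        if np.linalg.matrix_rank(trial.to_numpy()) == trial.shape[1]:
            keep.append(col)
        else:
            warnings.warn(f"dropping collinear design column {col!r}", stacklevel=2)
    X = X[keep]
    if n - X.shape[1] < 3:
        raise ValueError(
            f"only {n} complete cases for {X.shape[1]} design columns")

    fit = sm.OLS(data["y"].to_numpy(), X.to_numpy()).fit()
    i = keep.index("ocr")
    beta, se, t = fit.params[i], fit.bse[i], fit.tvalues[i]
    df = int(fit.df_resid)
    tcrit = stats.t.ppf(0.975, df)
    return AssociationResult(
        predictor=predictor, timepoint=timepoint, stratum=stratum,
        beta=float(beta), se=float(se), t=float(t), df=df,
        r=t_to_r(t, df), ci_low=float(beta - tcrit * se),
        ci_high=float(beta + tcrit * se), p=float(fit.pvalues[i]),
        p_fdr=None, n_used=n,
    )


def run_association_suite(
    ocr: pd.DataFrame,
    phenotypes: pd.DataFrame,
    strata: Sequence[str] = ("all", "female", "male"),
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    timepoints: Sequence[str] = TIMEPOINTS,
    min_n: int = 10,
) -> pd.DataFrame:
    """All (state x timepoint) models per stratum, FDR-corrected per stratum.

    ``ocr`` is indexed by subject_id with one column per state.  Sex is
    removed from the covariate list in sex-stratified runs.  Models with
    fewer than ``min_n`` complete cases are skipped and logged.
    """
    merged = ocr.reset_index().merge(phenotypes, on="subject_id", how="inner")
    state_cols = list(ocr.columns)
    results: list[AssociationResult] = []
    for stratum in strata:
        if stratum == "all":
            sub = merged
            covs = list(covariates)
        else:
            sub = merged[merged["sex"] == stratum]
            covs = [c for c in covariates if c != "sex"]
        stratum_results = []
        for state_col in state_cols:
            for tp in timepoints:
                ycol = PCL5_COLUMNS[tp]
                try:
                    res = fit_glm_association(
                        sub[state_col], sub[ycol], sub[covs],
                        predictor=state_col, timepoint=tp, stratum=stratum,
                        min_n=min_n,
                    )
                except ValueError as exc:
                    logger.warning("skipping %s/%s/%s: %s", stratum, state_col, tp, exc)
                    continue
                stratum_results.append(res)
        if stratum_results:
            adj = bh_fdr([r.p for r in stratum_results])
            stratum_results = [
                AssociationResult(**{**r.__dict__, "p_fdr": float(q)})
                for r, q in zip(stratum_results, adj)
            ]
        results.extend(stratum_results)
    columns = [f.name for f in AssociationResult.__dataclass_fields__.values()]
    return pd.DataFrame([r.__dict__ for r in results], columns=columns)


@dataclass
class GroupStateComparison:
    """Separately clustered states of two groups, matched centroid-by-centroid."""

    model_a: StateModel
    model_b: StateModel
    group_a: str
    group_b: str
    permutation: np.ndarray
    matched_correlations: np.ndarray
    ocr_means: pd.DataFrame  # rows: group, columns: state of group A's labeling


def compare_group_states(
    windows: Sequence[DfncWindows],
    pts_labels: pd.DataFrame,
    K: int = 3,
    n_init: int = 10,
    max_iter: int = 1000,
    seed: int | None = None,
) -> GroupStateComparison:
    """Cluster two groups' windows separately and compare the resulting states.

    Returns the Hungarian matching between the two centroid sets, the matched
    Pearson correlations, and per-group mean OCR (group B's states reordered
    to group A's matching).
    """
    lab = dict(zip(pts_labels["subject_id"], pts_labels["label"]))
    grp_a = [w for w in windows if lab.get(w.subject_id) == "non-PTS"]
    grp_b = [w for w in windows if lab.get(w.subject_id) == "PTS"]
    if not grp_a or not grp_b:
        raise ValueError("both groups must be nonempty")
    model_a, vec_a = cluster_states(grp_a, K, max_iter=max_iter, n_init=n_init, seed=seed)
    model_b, vec_b = cluster_states(grp_b, K, max_iter=max_iter, n_init=n_init, seed=seed)
    perm, corrs = match_states(model_a, model_b)

    ocr_a = ocr_table(vec_a, K).mean(axis=0)
    ocr_b_raw = ocr_table(vec_b, K).mean(axis=0)
    ocr_b = pd.Series({f"state_{k + 1}": ocr_b_raw.iloc[perm[k]] for k in range(K)})
    means = pd.DataFrame([ocr_a, ocr_b], index=["non-PTS", "PTS"])
    return GroupStateComparison(
        model_a=model_a, model_b=model_b, group_a="non-PTS", group_b="PTS",
        permutation=perm, matched_correlations=corrs, ocr_means=means,
    )


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------


class OcrAssociationModel:
    """Association of occupancy rates with longitudinal symptom scores.

    Parameters
    ----------
    ocr : DataFrame indexed by subject_id, one column per state.
    phenotypes : DataFrame with subject_id, covariates and per-timepoint
        symptom-score columns.
    """

    def __init__(self, ocr: pd.DataFrame, phenotypes: pd.DataFrame,
                 covariates: Sequence[str] = DEFAULT_COVARIATES):
        self.ocr = ocr
        self.phenotypes = phenotypes
        self.covariates = tuple(covariates)

    @classmethod
    def from_results(cls, state_results, phenotypes: pd.DataFrame,
                     **kwargs) -> "OcrAssociationModel":
        """Build directly from fitted :class:`~dfncstates.states.DfncStateResults`."""
        return cls(state_results.ocr(), phenotypes, **kwargs)

    def fit(self, strata: Sequence[str] = ("all", "female", "male"),
            timepoints: Sequence[str] = TIMEPOINTS,
            min_n: int = 10) -> "OcrAssociationResults":
        table = run_association_suite(
            self.ocr, self.phenotypes, strata=strata,
            covariates=self.covariates, timepoints=timepoints, min_n=min_n,
        )
        return OcrAssociationResults(self, table)


@dataclass
class OcrAssociationResults:
    """The full grid of fitted OCR-symptom models."""

    model: OcrAssociationModel
    table: pd.DataFrame

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        """Rows surviving FDR at the given level."""
        return self.table[self.table["p_fdr"] < alpha]

    def summary(self, alpha: float = 0.05) -> str:
        lines = ["OCR-symptom association suite"]
        for stratum, grp in self.table.groupby("stratum", sort=False):
            lines.append(f"  stratum {stratum!r}: {len(grp)} models")
            hits = grp[grp["p_fdr"] < alpha]
            for _, row in hits.iterrows():
                lines.append(
                    f"    {row.predictor} x {row.timepoint}: "
                    f"r={row.r:+.3f}, beta={row.beta:+.4g}, SE={row.se:.4g}, "
                    f"95% CI [{row.ci_low:+.4g}, {row.ci_high:+.4g}], "
                    f"p_fdr={row.p_fdr:.3g}, N={int(row.n_used)}"
                )
            if hits.empty:
                lines.append(f"    no FDR-significant associations at {alpha}")
        return "\n".join(lines)
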