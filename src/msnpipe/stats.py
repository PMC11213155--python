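"""Association screens: OLS linear models of cognition, MSN features and
mean thickness on ADI group with demographic covariates.

Three model families are screened, mirroring the study design:

(i)   cognitive score ~ ADI + age + sex + education + practice
(iia) global MSN feature (4) ~ ADI + age + sex + education
(iib) local MSN feature (4 x 68) ~ ADI + age + sex + education

plus the per-region mean-thickness check with the (iia/iib) covariates.
Inference is classical OLS (two-sided t tests); the local screen reports
p-values at the 0.01 tier and flags mediator candidates at the stricter
0.005 tier (both strict inequalities).  Benjamini-Hochberg q-values are
reported alongside for transparency, but selection is on raw p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .graph import GLOBAL_MEASURES, NODAL_MEASURES

__all__ = [
    "RegressionResult",
    "fit_linear_model",
    "cognitive_associations",
    "msn_associations",
    "thickness_associations",
    "select_mediator_candidates",
    "AssociationScreen",
]

COGNITIVE_COVARIATES = ("age", "sex", "education_years", "practice")
MSN_COVARIATES = ("age", "sex", "education_years")


@dataclass
class RegressionResult:
    """Tidy single-model OLS summary (one row per design term)."""

    outcome: str
    terms: pd.DataFrame  # columns: term, beta, se, t, p
    n: int
    df_resid: int

    def coef(self, term: str) -> pd.Series:
        row = self.terms.loc[self.terms["term"] == term]
        if row.empty:
            raise KeyError(f"no term {term!r} in model for {self.outcome!r}")
        return row.iloc[0]


def _check_full_rank(design: pd.DataFrame) -> None:
    x = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify the dependent columns via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(x, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(x.shape) * np.finfo(float).eps
        bad = [design.columns[piv[i]] for i in range(x.shape[1]) if diag[i] <= tol]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_linear_model(y, design: pd.DataFrame, outcome: str = "y") -> RegressionResult:
    """Ordinary least squares with classical standard errors.

    *design* must already contain the intercept column (use
    ``statsmodels.api.add_constant`` or the helpers in this module).
    """
    y = np.asarray(y, dtype=float)
    if len(y) <= design.shape[1]:
        raise ValueError(
            f"need more observations ({len(y)}) than design terms ({design.shape[1]})"
        )
    _check_full_rank(design)
    fit = sm.OLS(y, design).fit()
    terms = pd.DataFrame({
        "term": design.columns,
        "beta": fit.params.to_numpy(),
        "se": fit.bse.to_numpy(),
        "t": fit.tvalues.to_numpy(),
        "p": fit.pvalues.to_numpy(),
    })
    return RegressionResult(outcome, terms, int(fit.nobs), int(fit.df_resid))


def _design(cohort: pd.DataFrame, covariates) -> pd.DataFrame:
    cols = ["adi", *covariates]
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort table is missing columns: {missing}")
    design = cohort[cols].astype(float)
    return sm.add_constant(design, prepend=True)


def _complete_cases(cohort: pd.DataFrame, cols) -> pd.DataFrame:
    sub = cohort[list(cols)]
    kept = sub.dropna()
    dropped = len(sub) - len(kept)
    if dropped:
        import warnings

        warnings.warn(f"dropping {dropped} rows with missing values", stacklevel=3)
    return kept


def cognitive_associations(
    cohort: pd.DataFrame,
    outcomes=("mPACC", "CF", "WAIS_DS", "TMTt", "SMD", "RAVLT_L"),
    alpha: float = 0.05,
) -> tuple[list[RegressionResult], pd.DataFrame]:
    """Model family (i): one OLS per cognitive outcome.

    Returns the full per-model results and a tidy summary of the ADI term
    with a significance flag at ``p < alpha`` (strict).
    """
    results = []
    rows = []
    for outcome in outcomes:
        data = _complete_cases(cohort, [outcome, "adi", *COGNITIVE_COVARIATES])
        res = fit_linear_model(
            data[outcome], _design(data, COGNITIVE_COVARIATES), outcome
        )
        results.append(res)
        coef = res.coef("adi")
        rows.append({
            "outcome": outcome, "beta_adi": coef.beta, "se": coef.se,
            "t": coef.t, "p": coef.p, "n": res.n,
            "significant": bool(coef.p < alpha),
        })
    return results, pd.DataFrame(rows)


def _feature_screen(features: pd.DataFrame, cohort: pd.DataFrame,
                    covariates) -> pd.DataFrame:
    merged = features.join(cohort.set_index("subject_id"), how="inner")
    rows = []
    for col in features.columns:
        data = merged[[col, "adi", *covariates]].dropna()
        res = fit_linear_model(data[col], _design(data, covariates), col)
        coef = res.coef("adi")
        rows.append({
            "feature": col, "beta_adi": coef.beta, "se": coef.se,
            "t": coef.t, "p": coef.p, "n": res.n,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["q_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def msn_associations(
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    alpha_report: float = 0.01,
    alpha_candidate: float = 0.005,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Model families (iia) and (iib): ADI screens of the network features.

    *features* is the GraphFeatureExtractor output indexed by subject_id
    (4 global columns plus 4x68 ``<measure>__<roi>`` nodal columns).
    Returns ``(global_results, local_results)``; the local table carries
    ``measure``/``roi`` columns and significance flags at the reporting
    (p < 0.01) and mediator-candidate (p < 0.005) tiers.
    """
    global_cols = [c for c in features.columns if c in GLOBAL_MEASURES]
    local_cols = [c for c in features.columns if "__" in c]
    glob = _feature_screen(features[global_cols], cohort, MSN_COVARIATES)
    loc = _feature_screen(features[local_cols], cohort, MSN_COVARIATES)
    if len(glob):
        glob["significant"] = glob["p"] < alpha_report
    if len(loc):
        parts = loc["feature"].str.split("__", n=1, expand=True)
        loc.insert(1, "measure", parts[0])
        loc.insert(2, "roi", parts[1])
        loc["significant"] = loc["p"] < alpha_report
        loc["mediator_candidate"] = loc["p"] < alpha_candidate
    return glob, loc


def thickness_associations(
    mean_thickness: pd.DataFrame, cohort: pd.DataFrame
) -> pd.DataFrame:
    """Per-region mean cortical thickness ~ ADI + age + sex + education.

    *mean_thickness* has one column per region (68), indexed by
    subject_id.
    """
    return _feature_screen(mean_thickness, cohort, MSN_COVARIATES)


def select_mediator_candidates(
    local_results: pd.DataFrame, alpha: float = 0.005
) -> list[tuple[str, str]]:
    """Local features whose ADI term satisfies ``p < alpha`` (strict),
    returned as ``(measure, roi)`` pairs in table order."""
    hits = local_results.loc[local_results["p"] < alpha]
    return list(zip(hits["measure"], hits["roi"]))


class AssociationScreen(BaseEstimator):
    """Estimator wrapper running all three association screens at once.

    ``fit(features, cohort)`` populates ``cognitive_``, ``global_``,
    ``local_`` result tables and the ``candidates_`` list; *features* may
    be None to run the cognitive screen alone.
    """

    def __init__(self, alpha_cognitive: float = 0.05, alpha_report: float = 0.01,
                 alpha_candidate: float = 0.005):
        self.alpha_cognitive = alpha_cognitive
        self.alpha_report = alpha_report
        self.alpha_candidate = alpha_candidate

    def fit(self, features: pd.DataFrame | None, cohort: pd.DataFrame):
        _, self.cognitive_ = cognitive_associations(cohort, alpha=self.alpha_cognitive)
        if features is not None:
            self.global_, self.local_ = msn_associations(
                features, cohort, self.alpha_report, self.alpha_candidate
            )
            self.candidates_ = select_mediator_candidates(
                self.local_, self.alpha_candidate
            )
        else:
            self.global_ = self.local_ = None
            self.candidates_ = []
        return self
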