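"""Product-of-coefficients mediation with nonparametric bootstrap CIs.

The hypothesised pathway is exposure (ADI group) -> mediator (a network
feature) -> outcome (a cognitive score).  Four OLS fits give the paths:

    a       from  M ~ X + covariates
    b, c'   from  Y ~ X + M + covariates
    c       from  Y ~ X + covariates

The indirect (mediated) effect is a*b; when all three models share the
same covariate set the decomposition c = c' + a*b holds exactly.
Uncertainty in a*b is assessed by case resampling: whole rows are drawn
with replacement, the paths are refit per replicate, and a percentile
(optionally bias-corrected) confidence interval is formed from the
replicate a*b values.  Significance means the CI excludes zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator

__all__ = [
    "MediationPaths",
    "MediationResult",
    "mediation_paths",
    "bootstrap_indirect",
    "run_mediation",
    "ProductOfCoefficientsMediation",
]


@dataclass(frozen=True)
class MediationPaths:
    a: float
    b: float
    c: float
    c_prime: float

    @property
    def indirect(self) -> float:
        return self.a * self.b


@dataclass
class MediationResult:
    """Path estimates plus a bootstrap CI for the indirect effect a*b."""

    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    ci_low: float
    ci_high: float
    n_boot: int
    ci_level: float
    significant: bool
    seed: int | None
    n: int
    mediator: str = "M"
    outcome: str = "Y"
    n_redrawn: int = 0

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "mediator", "outcome", "a", "b", "c", "c_prime", "indirect",
                "ci_low", "ci_high", "n_boot", "ci_level", "significant",
                "seed", "n",
            )
        }

    def path_diagram(self) -> str:
        """Plain-text path diagram of the fitted mediation model."""
        return (
            f"            {self.mediator}\n"
            f"       a={self.a:+.3f}   b={self.b:+.3f}\n"
            f"      /                 \\\n"
            f"  ADI ------ c'={self.c_prime:+.3f} ----> {self.outcome}\n"
            f"  total c={self.c:+.3f}; "
            f"indirect a*b={self.indirect:+.3f} "
            f"[{self.ci_low:+.3f}, {self.ci_high:+.3f}]"
            f" ({'significant' if self.significant else 'not significant'})"
        )


def _as_design(x, cols) -> np.ndarray:
    mats = [np.ones((len(x), 1)), np.asarray(x, float).reshape(len(x), -1)]
    for c in cols:
        mats.append(np.asarray(c, float).reshape(len(x), -1))
    return np.hstack(mats)


def _solve(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise ValueError("rank-deficient design in mediation regression")
    return coef


def mediation_paths(x, m, y, covariates=None,
                    outcome_covariates=None) -> MediationPaths:
    """OLS path estimates for a single-mediator model.

    *covariates* enter every model; *outcome_covariates* (if given) enter
    only the two outcome-side models (Y ~ ...).  With no extra
    outcome-side covariates the identity ``c = c' + a*b`` is exact.
    """
    x = np.asarray(x, float)
    m = np.asarray(m, float)
    y = np.asarray(y, float)
    if not (len(x) == len(m) == len(y)):
        raise ValueError("x, m, y must have equal length")
    covs = [np.asarray(c, float) for c in (covariates or [])]
    ocovs = covs + [np.asarray(c, float) for c in (outcome_covariates or [])]
    dm = _as_design(x, covs)                      # M ~ X + C
    dy_full = np.hstack([_as_design(x, []), m[:, None],
                         *[c.reshape(len(x), -1) for c in ocovs]])  # Y ~ X + M + C
    dy_tot = _as_design(x, ocovs)                 # Y ~ X + C
    a = _solve(dm, m)[1]
    coef_full = _solve(dy_full, y)
    c_prime, b = coef_full[1], coef_full[2]
    c = _solve(dy_tot, y)[1]
    return MediationPaths(float(a), float(b), float(c), float(c_prime))


def _batched_paths(xm: np.ndarray, dy: np.ndarray, m: np.ndarray,
                   y: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Indirect effects a*b for a batch of bootstrap index vectors.

    ``xm``: mediator-model design (n, p); ``dy``: outcome-model design
    including the mediator column at position 2 (n, q).  Returns an array
    of a*b per replicate; non-finite where a replicate design is singular.
    """
    xb = xm[idx]                      # (B, n, p)
    db = dy[idx]                      # (B, n, q)
    mb = m[idx]
    yb = y[idx]
    xtx = np.einsum("bnp,bnq->bpq", xb, xb)
    xtm = np.einsum("bnp,bn->bp", xb, mb)
    dtd = np.einsum("bnp,bnq->bpq", db, db)
    dty = np.einsum("bnp,bn->bp", db, yb)
    B = idx.shape[0]
    ab = np.full(B, np.nan)
    for k in range(B):  # small solves; loop cost negligible vs einsum
        try:
            a = np.linalg.solve(xtx[k], xtm[k])[1]
            coef = np.linalg.solve(dtd[k], dty[k])
            ab[k] = a * coef[2]
        except np.linalg.LinAlgError:
            pass
    return ab


def bootstrap_indirect(
    x, m, y,
    covariates=None,
    outcome_covariates=None,
    n_boot: int = 10_000,
    seed: int | None = None,
    ci_level: float = 0.95,
    method: str = "percentile",
    max_redraws: int = 100,
    _chunk: int = 512,
) -> MediationResult:
    """Case-resampling bootstrap CI for the indirect effect a*b.

    Whole rows (x, m, y, covariates) are resampled with replacement
    ``n_boot`` times; each replicate's paths are refit by OLS.  Replicates
    with a singular design are redrawn (up to *max_redraws*, tallied in
    ``n_redrawn``).  ``method`` selects a ``"percentile"`` or
    ``"bias-corrected"`` interval.  Deterministic under *seed*.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    if method not in ("percentile", "bias-corrected"):
        raise ValueError(f"unknown CI method {method!r}")
    point = mediation_paths(x, m, y, covariates, outcome_covariates)
    x = np.asarray(x, float)
    m = np.asarray(m, float)
    y = np.asarray(y, float)
    n = len(x)
    covs = [np.asarray(c, float) for c in (covariates or [])]
    ocovs = covs + [np.asarray(c, float) for c in (outcome_covariates or [])]
    xm = _as_design(x, covs)
    dy = np.hstack([_as_design(x, []), m[:, None],
                    *[c.reshape(n, -1) for c in ocovs]])
    rng = np.random.default_rng(seed)
    draws = np.empty(n_boot)
    pos = 0
    redrawn = 0
    while pos < n_boot:
        size = min(_chunk, n_boot - pos)
        idx = rng.integers(0, n, size=(size, n))
        ab = _batched_paths(xm, dy, m, y, idx)
        bad = ~np.isfinite(ab)
        tries = 0
        while bad.any() and tries < max_redraws:
            redo = rng.integers(0, n, size=(int(bad.sum()), n))
            ab[bad] = _batched_paths(xm, dy, m, y, redo)
            redrawn += int(bad.sum())
            bad = ~np.isfinite(ab)
            tries += 1
        if bad.any():
            raise RuntimeError(
                "bootstrap replicates remained rank-deficient after "
                f"{max_redraws} redraw rounds"
            )
        draws[pos:pos + size] = ab
        pos += size
    alpha = 1.0 - ci_level
    if method == "percentile":
        lo, hi = np.quantile(draws, [alpha / 2, 1 - alpha / 2])
    else:  # bias-corrected
        prop = np.mean(draws < point.indirect)
        prop = min(max(prop, 1.0 / (n_boot + 1)), n_boot / (n_boot + 1.0))
        z0 = norm.ppf(prop)
        z = norm.ppf(1 - alpha / 2)
        lo, hi = np.quantile(draws, norm.cdf([2 * z0 - z, 2 * z0 + z]))
    significant = bool(lo > 0 or hi < 0)
    return MediationResult(
        a=point.a, b=point.b, c=point.c, c_prime=point.c_prime,
        indirect=point.indirect, ci_low=float(lo), ci_high=float(hi),
        n_boot=n_boot, ci_level=ci_level, significant=significant,
        seed=seed, n=n, n_redrawn=redrawn,
    )


def run_mediation(
    cohort: pd.DataFrame,
    features: pd.DataFrame,
    candidate: tuple[str, str] | str,
    outcome: str,
    covariates=("age", "sex", "education_years"),
    practice_in_outcome: bool = True,
    n_boot: int = 10_000,
    seed: int | None = None,
    ci_level: float = 0.95,
    method: str = "percentile",
) -> MediationResult:
    """Wire a selected network feature as mediator of the ADI->score path.

    *candidate* is a ``(measure, roi)`` pair (naming a ``measure__roi``
    feature column) or a bare feature column name.  Covariates age, sex
    and education enter every model; the practice count additionally
    enters the outcome-side models when ``practice_in_outcome`` (echoing
    its role in the cognitive association models).
    """
    col = candidate if isinstance(candidate, str) else "__".join(candidate)
    if col not in features.columns:
        raise KeyError(f"feature column {col!r} not found")
    merged = features[[col]].join(cohort.set_index("subject_id"), how="inner")
    need = [col, outcome, "adi", *covariates] + (
        ["practice"] if practice_in_outcome else []
    )
    merged = merged[need].dropna()
    res = bootstrap_indirect(
        merged["adi"], merged[col], merged[outcome],
        covariates=[merged[c] for c in covariates],
        outcome_covariates=(
            [merged["practice"]] if practice_in_outcome else None
        ),
        n_boot=n_boot, seed=seed, ci_level=ci_level, method=method,
    )
    res.mediator = col
    res.outcome = outcome
    return res


class ProductOfCoefficientsMediation(BaseEstimator):
    """Scikit-learn style estimator for single-mediator analysis.

    ``fit(df)`` expects a DataFrame holding the exposure, mediator,
    outcome and covariate columns; fitted attributes expose the paths
    (``a_``, ``b_``, ``c_``, ``c_prime_``, ``indirect_``), the bootstrap
    CI (``ci_``) and the significance flag (``significant_``).
    """

    def __init__(self, exposure: str = "adi", mediator: str = "mediator",
                 outcome: str = "outcome", covariates: tuple[str, ...] = (),
                 outcome_covariates: tuple[str, ...] = (),
                 n_boot: int = 10_000, ci_level: float = 0.95,
                 method: str = "percentile", random_state: int | None = None):
        self.exposure = exposure
        self.mediator = mediator
        self.outcome = outcome
        self.covariates = covariates
        self.outcome_covariates = outcome_covariates
        self.n_boot = n_boot
        self.ci_level = ci_level
        self.method = method
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "ProductOfCoefficientsMediation":
        res = bootstrap_indirect(
            X[self.exposure], X[self.mediator], X[self.outcome],
            covariates=[X[c] for c in self.covariates],
            outcome_covariates=[X[c] for c in self.outcome_covariates] or None,
            n_boot=self.n_boot, seed=self.random_state,
            ci_level=self.ci_level, method=self.method,
        )
        res.mediator = self.mediator
        res.outcome = self.outcome
        self.result_ = res
        self.a_, self.b_ = res.a, res.b
        self.c_, self.c_prime_ = res.c, res.c_prime
        self.indirect_ = res.indirect
        self.ci_ = (res.ci_low, res.ci_high)
        self.significant_ = res.significant
        return self
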