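"""Variant-trait association: normalization, regression models, screening.

Quantitative traits are residualized on age and age^2 within each sex
stratum and then rank-inverse-normal transformed with the Blom offset
(rank - 3/8)/(n + 1/4), so every trait enters regression as a standard
normal z-score and per-allele effects are in SD units. Per variant the
stage offers ordinary least squares (quantitative traits), logistic
regression (prevalent disease) and Cox proportional hazards (incident
disease from register follow-up, Breslow ties by default). The screen
collects every variant x trait result below a reporting threshold and
states how many such hits chance alone would produce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AssocResult",
    "int_transform",
    "linear_assoc",
    "logistic_assoc",
    "cox_assoc",
    "screen_all",
    "biomarker_disease_test",
    "homozygote_fisher_test",
]

MISSING = -1


class AssociationError(RuntimeError):
    """Raised when a model cannot produce a valid estimate."""


@dataclass
class AssocResult:
    """One variant x trait test result; effect is per alternate allele."""

    variant_id: str
    trait: str
    n: int
    effect: float
    se: float
    p: float
    model: str

    def __post_init__(self):
        if self.se <= 0 or not np.isfinite(self.se):
            raise AssociationError(f"invalid standard error {self.se}")


def _residualize(y: np.ndarray, age: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(age), age, age * age])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def int_transform(values, sex, age, min_stratum: int = 10) -> np.ndarray:
    """Sex-stratified residualization + rank inverse-normal transform.

    Within each sex stratum the trait is residualized on age + age^2 and
    the residual ranks (ties averaged) are mapped to normal quantiles with
    the Blom offset (r - 3/8)/(n + 1/4). Strata are then recombined in the
    original order. Missing values propagate as NaN.
    """
    y = np.asarray(values, dtype=float)
    sex = np.asarray(sex)
    age = np.asarray(age, dtype=float)
    z = np.full_like(y, np.nan)
    for s in pd.unique(sex):
        idx = np.flatnonzero((sex == s) & np.isfinite(y) & np.isfinite(age))
        if idx.size == 0:
            continue
        if idx.size < min_stratum:
            raise AssociationError(
                f"stratum {s!r} has {idx.size} non-missing values; need >= {min_stratum}"
            )
        resid = _residualize(y[idx], age[idx])
        if np.ptp(resid) == 0:
            raise AssociationError(f"trait constant within stratum {s!r}")
        ranks = stats.rankdata(resid, method="average")
        z[idx] = stats.norm.ppf((ranks - 0.375) / (idx.size + 0.25))
    return z


def _design(dosage, covariates):
    d = np.asarray(dosage, dtype=float)
    cols = [np.ones_like(d), d]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        cols.extend(C.T)
    return np.column_stack(cols)


def _valid_mask(dosage, y, covariates):
    d = np.asarray(dosage, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = (d != MISSING) & np.isfinite(d) & np.isfinite(y)
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        mask &= np.all(np.isfinite(C), axis=1)
    return mask


def linear_assoc(dosage, trait, covariates=None, variant_id="variant", trait_id="trait") -> AssocResult:
    """Per-allele OLS effect of dosage on a (typically INT-transformed) trait.

    Closed-form least squares with the usual t-based two-sided p.
    Missing dosages (coded -1) and non-finite trait values are dropped.
    """
    mask = _valid_mask(dosage, trait, covariates)
    d = np.asarray(dosage, dtype=float)[mask]
    y = np.asarray(trait, dtype=float)[mask]
    if d.size < 3 or np.ptp(d) == 0:
        raise AssociationError("zero genotype variance among analysed samples")
    C = None
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        C = C[mask] if C.ndim > 1 else C[mask, None] if C.ndim == 1 else C
    X = _design(d, C)
    XtX_inv = np.linalg.pinv(X.T @ X)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    if dof <= 0:
        raise AssociationError("not enough samples for the design")
    sigma2 = float(resid @ resid) / dof
    se = float(np.sqrt(sigma2 * XtX_inv[1, 1]))
    t = beta[1] / se
    p = float(2 * stats.t.sf(abs(t), dof))
    return AssocResult(variant_id, trait_id, int(d.size), float(beta[1]), se, max(p, 5e-324), "linear")


def logistic_assoc(dosage, case_status, covariates=None, variant_id="variant", trait_id="disease") -> AssocResult:
    """Per-allele log-odds from maximum-likelihood logistic regression."""
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    mask = _valid_mask(dosage, case_status, covariates)
    d = np.asarray(dosage, dtype=float)[mask]
    y = np.asarray(case_status, dtype=float)[mask]
    if len(np.unique(y)) < 2:
        raise AssociationError("both outcome classes must be present")
    if np.ptp(d) == 0:
        raise AssociationError("zero genotype variance among analysed samples")
    C = None
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        C = C[mask] if C.ndim > 1 else C[mask, None]
    X = _design(d, C)
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise AssociationError(f"logistic fit failed: {exc}") from exc
    if not np.all(np.isfinite(fit.bse)):
        raise AssociationError("separable data: non-finite standard errors")
    return AssocResult(
        variant_id, trait_id, int(len(y)), float(fit.params[1]), float(fit.bse[1]),
        float(max(fit.pvalues[1], 5e-324)), "logistic",
    )


def cox_assoc(
    dosage, event, time, covariates=None, ties: str = "breslow",
    variant_id="variant", trait_id="disease",
) -> AssocResult:
    """Per-allele log-hazard from a Cox proportional-hazards model.

    Partial-likelihood fit with Breslow tie handling by default (Efron via
    ``ties='efron'``); Wald two-sided p.
    """
    import statsmodels.api as sm

    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown tie method {ties!r}")
    mask = _valid_mask(dosage, event, covariates)
    t = np.asarray(time, dtype=float)
    mask &= np.isfinite(t) & (t > 0)
    d = np.asarray(dosage, dtype=float)[mask]
    ev = np.asarray(event, dtype=float)[mask]
    if ev.sum() < 1:
        raise AssociationError("no events observed")
    if np.ptp(d) == 0:
        raise AssociationError("zero genotype variance among analysed samples")
    X = d[:, None]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        C = C[mask] if C.ndim > 1 else C[mask, None]
        X = np.column_stack([X, C])
    fit = sm.PHReg(t[mask], X, status=ev, ties=ties).fit()
    eff = float(fit.params[0])
    se = float(fit.bse[0])
    p = float(2 * stats.norm.sf(abs(eff / se)))
    return AssocResult(variant_id, trait_id, int(len(d)), eff, se, max(p, 5e-324), f"cox_{ties}")


def screen_all(
    results: list[AssocResult],
    n_variants: int,
    n_traits: int,
    screen_p: float = 2e-4,
    alpha: float = 0.05,
) -> dict:
    """Collect screen hits and the chance/Bonferroni arithmetic.

    Returns the hits (p < ``screen_p``), the expected count of chance hits
    ``n_variants * n_traits * screen_p``, and the study-wide Bonferroni
    threshold ``alpha / (n_variants * n_traits)`` with per-hit flags.
    """
    n_tests = n_variants * n_traits
    bonferroni = alpha / n_tests
    hits = sorted((r for r in results if r.p < screen_p), key=lambda r: r.p)
    return {
        "n_variants": n_variants,
        "n_traits": n_traits,
        "n_tests": n_tests,
        "screen_p": screen_p,
        "expected_chance_hits": n_tests * screen_p,
        "bonferroni_threshold": bonferroni,
        "n_hits": len(hits),
        "hits": [
            {
                "variant_id": r.variant_id,
                "trait": r.trait,
                "n": r.n,
                "effect": r.effect,
                "se": r.se,
                "p": r.p,
                "model": r.model,
                "study_wide_significant": r.p < bonferroni,
            }
            for r in hits
        ],
    }


def biomarker_disease_test(trait_values, case_status) -> tuple[float, float]:
    """Welch one-sided t-tests of a biomarker against disease status.

    Returns (p_higher_in_cases, p_lower_in_cases): the two one-tailed
    tests of whether cases have higher, respectively lower, biomarker
    levels than controls.
    """
    y = np.asarray(trait_values, dtype=float)
    case = np.asarray(case_status, dtype=bool)
    ok = np.isfinite(y)
    a, b = y[ok & case], y[ok & ~case]
    if a.size < 2 or b.size < 2:
        raise AssociationError("both groups need at least 2 observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise AssociationError("degenerate variance in both groups")
    hi = stats.ttest_ind(a, b, equal_var=False, alternative="greater").pvalue
    lo = stats.ttest_ind(a, b, equal_var=False, alternative="less").pvalue
    return float(hi), float(lo)


def homozygote_fisher_test(knockout: np.ndarray, case_status) -> float:
    """Fisher exact p on the 2x2 knockout x case table (secondary test)."""
    ko = np.asarray(knockout, dtype=float)
    case = np.asarray(case_status, dtype=bool)
    ok = ko != MISSING
    ko2 = ko[ok] == 2
    case = case[ok]
    table = [
        [int((ko2 & case).sum()), int((ko2 & ~case).sum())],
        [int((~ko2 & case).sum()), int((~ko2 & ~case).sum())],
    ]
    _, p = stats.fisher_exact(table)
    return float(p)
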