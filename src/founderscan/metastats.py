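"""Fixed-effects meta-analysis and combined-probability methods.

Discovery and replication results are combined by inverse-variance
weighting: beta_c = sum(beta_i / SE_i^2) / sum(1 / SE_i^2) with
SE_c = (sum 1/SE_i^2)^(-1/2) and a two-sided normal p. Fisher's combined
probability refers -2 * sum(ln p_i) to a chi-square with 2k degrees of
freedom; because the individual p-values may be one- or two-sided the
module takes them as given and offers a ``one_sided`` switch that halves
two-sided inputs before combining. Cochran's Q is reported as a
heterogeneity diagnostic, never as a gate.

The package ships a published summary-statistics table
(``data/lof_screen_summary.tsv``) from a screen of Finnish-enriched
loss-of-function variants across quantitative traits, with discovery,
replication and combined columns; :func:`verify_combined_columns` checks
which printed combined rows the IVW estimator reproduces.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "MetaResult",
    "ivw_meta",
    "fisher_combined",
    "forest_summary",
    "load_screen_summary",
    "verify_combined_columns",
]


@dataclass
class MetaResult:
    """Fixed-effects combination of per-study (effect, SE) pairs."""

    effect: float
    se: float
    p: float
    study_effects: list = field(default_factory=list)
    study_ses: list = field(default_factory=list)
    study_ns: list = field(default_factory=list)
    cochran_q: float | None = None
    q_p: float | None = None

    @property
    def n_studies(self) -> int:
        return len(self.study_effects)

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        return self.effect - z * self.se, self.effect + z * self.se


def ivw_meta(studies: list[tuple[float, float]], ns: list[int] | None = None) -> MetaResult:
    """Inverse-variance-weighted fixed-effects meta-analysis.

    ``studies`` is a list of (effect, SE) pairs on a common scale (SD
    units, log-OR or log-HR). Associative: combining a combined result
    with a further study equals combining all studies at once.
    """
    if not studies:
        raise ValueError("need at least one study")
    betas = np.array([b for b, _ in studies], dtype=float)
    ses = np.array([s for _, s in studies], dtype=float)
    if np.any(ses <= 0) or not np.all(np.isfinite(ses)) or not np.all(np.isfinite(betas)):
        raise ValueError("all standard errors must be positive and finite")
    w = 1.0 / ses**2
    effect = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    p = float(2 * stats.norm.sf(abs(effect / se)))
    if len(studies) > 1:
        q = float(np.sum(w * (betas - effect) ** 2))
        q_p = float(stats.chi2.sf(q, len(studies) - 1))
    else:
        q = q_p = None
    return MetaResult(
        effect=effect,
        se=se,
        p=max(p, 5e-324),
        study_effects=list(betas),
        study_ses=list(ses),
        study_ns=list(ns) if ns is not None else [],
        cochran_q=q,
        q_p=q_p,
    )


def fisher_combined(p_values, one_sided: bool = False) -> float:
    """Fisher's combined probability over k studies (chi-square, 2k df).

    With ``one_sided=True`` the inputs are taken to be two-sided p-values
    of effects already aligned in direction, and are halved before
    combining. Works in log space; p = 0 inputs are rejected.
    """
    ps = np.asarray(list(p_values), dtype=float)
    if ps.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(ps <= 0) or np.any(ps > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if one_sided:
        ps = ps / 2.0
    chi2 = -2.0 * np.sum(np.log(ps))
    return float(stats.chi2.sf(chi2, 2 * ps.size))


def forest_summary(
    cohort_results: dict[str, tuple[float, float]],
    log_scale: bool = True,
    order: list[str] | None = None,
) -> pd.DataFrame:
    """Forest-plot table: per-cohort effect with 95% CI plus a combined row.

    ``cohort_results`` maps cohort name -> (effect, SE) on the log scale
    when ``log_scale`` (CI half-width 1.96*SE on that scale; ratios are
    exponentiated into ``ratio``/``ratio_lo``/``ratio_hi`` columns).
    The combined row is the IVW meta-analysis of the listed cohorts.
    """
    if not cohort_results:
        raise ValueError("need at least one cohort result")
    names = order or list(cohort_results)
    rows = []
    for name in names:
        b, se = cohort_results[name]
        rows.append({"cohort": name, "effect": b, "se": se, "lo": b - 1.96 * se, "hi": b + 1.96 * se})
    meta = ivw_meta([cohort_results[n] for n in names])
    rows.append(
        {"cohort": "combined", "effect": meta.effect, "se": meta.se,
         "lo": meta.effect - 1.96 * meta.se, "hi": meta.effect + 1.96 * meta.se}
    )
    df = pd.DataFrame(rows)
    if log_scale:
        for c_out, c_in in (("ratio", "effect"), ("ratio_lo", "lo"), ("ratio_hi", "hi")):
            df[c_out] = np.exp(df[c_in])
    return df


def load_screen_summary() -> pd.DataFrame:
    """Published discovery/replication/combined summary statistics table."""
    ref = importlib.resources.files("founderscan.data") / "lof_screen_summary.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def verify_combined_columns(df: pd.DataFrame | None = None, tol: float = 0.002) -> pd.DataFrame:
    """Recompute every dual-entry row's combined (beta, SE) by IVW.

    Returns one row per summary-table row that has both discovery and
    replication entries, with the recomputed values and whether they match
    the printed combined columns within ``tol``.
    """
    if df is None:
        df = load_screen_summary()
    both = df.dropna(subset=["beta_rep", "beta_comb"])
    rows = []
    for r in both.itertuples(index=False):
        meta = ivw_meta([(r.beta_disc, r.se_disc), (r.beta_rep, r.se_rep)])
        rows.append(
            {
                "trait": r.trait,
                "gene": r.gene,
                "ivw_beta": meta.effect,
                "ivw_se": meta.se,
                "printed_beta": r.beta_comb,
                "printed_se": r.se_comb,
                "beta_match": math.isclose(meta.effect, r.beta_comb, abs_tol=tol),
                "se_match": math.isclose(meta.se, r.se_comb, abs_tol=tol),
            }
        )
    out = pd.DataFrame(rows)
    out["match"] = out["beta_match"] & out["se_match"]
    return out
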