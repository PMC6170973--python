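"""Cluster-sensitization profiles and their association with allergic
outcomes.

A subject is *sensitized to a cluster* if positive to at least one of its
member components; subjects positive to no active component form the
nonsensitized group (all cluster indicators zero).  Current asthma is the
2-of-3 rule over current wheeze, asthma medication and physician-diagnosed
asthma ever; current rhinitis is a single questionnaire item.

Associations are logistic regressions — univariable (one cluster indicator
at a time) and multiple (all cluster indicators in one joint model) — with
Wald 95% confidence intervals (z = 1.96).  Complete separation is flagged,
never silently penalized; an optional L2-penalized fit exists for degenerate
designs but is off by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .panel_io import BinaryPanel

__all__ = [
    "AssociationResult",
    "derive_asthma",
    "derive_outcomes",
    "build_profiles",
    "univariable_or",
    "multiple_or",
    "cross_age_confusion",
    "results_table",
]

logger = logging.getLogger(__name__)

_Z95 = 1.959963984540054  # normal quantile for a 95% Wald interval
_SE_SEPARATION_GUARD = 50.0  # a Wald SE this large signals a diverging coefficient


@dataclass
class AssociationResult:
    """One odds ratio: exposure vs outcome, with Wald 95% CI and p-value."""

    outcome: str
    exposure: str
    model: str  # "univariable" | "multiple"
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if np.isfinite(self.odds_ratio) and np.isfinite(self.ci_low) and np.isfinite(self.ci_high):
            if not (self.ci_low <= self.odds_ratio <= self.ci_high):
                raise ValueError("CI must bracket the odds ratio")


def derive_asthma(
    current_wheeze: pd.Series | np.ndarray,
    asthma_medication: pd.Series | np.ndarray,
    physician_asthma_ever: pd.Series | np.ndarray,
) -> pd.Series:
    """Current asthma: any 2 of {current wheeze, asthma medication,
    physician-diagnosed asthma ever}.  Missing any feature -> missing outcome."""
    frame = pd.DataFrame(
        {
            "wheeze": pd.Series(current_wheeze),
            "meds": pd.Series(asthma_medication),
            "dx": pd.Series(physician_asthma_ever),
        }
    ).astype(float)
    total = frame.sum(axis=1, skipna=False)
    return (total >= 2).where(total.notna())


def derive_outcomes(records: pd.DataFrame) -> pd.DataFrame:
    """Add the derived ``current_asthma`` column to a per-subject outcome
    table with columns current_wheeze / asthma_medication /
    physician_asthma_ever / current_rhinitis."""
    out = records.copy()
    out["current_asthma"] = derive_asthma(
        records["current_wheeze"],
        records["asthma_medication"],
        records["physician_asthma_ever"],
    )
    return out


def build_profiles(
    panel: BinaryPanel,
    clustering: Mapping[str, object],
    active: Sequence[str],
) -> pd.DataFrame:
    """Per-subject cluster-sensitization indicators.

    ``clustering`` maps each active component to its cluster label.  Output:
    one boolean column per cluster plus ``nonsensitized`` (all-negative
    subjects).  Subjects absent from the panel at this age are excluded
    (logged)."""
    active = [c for c in active if c in panel.component_ids]
    missing_cluster = [c for c in active if c not in clustering]
    if missing_cluster:
        raise ValueError(f"clustering does not cover active components: {missing_cluster}")
    clusters = sorted({clustering[c] for c in active}, key=str)
    present = panel.present_subjects()
    dropped = len(panel.subject_ids) - len(present)
    if dropped:
        logger.info(
            "build_profiles: %d subject(s) absent at age %s excluded", dropped, panel.age_label
        )
    sub = panel.data.loc[present, active]
    out = pd.DataFrame(index=pd.Index(present, name="subject_id"))
    for k in clusters:
        members = [c for c in active if clustering[c] == k]
        out[str(k)] = (sub[members] == 1).any(axis=1)
    out["nonsensitized"] = ~out[[str(k) for k in clusters]].any(axis=1)
    return out


def _wald_result(
    outcome_name: str,
    exposure_name: str,
    model: str,
    coef: float,
    se: float,
    n_used: int,
    flags: tuple[str, ...] = (),
) -> AssociationResult:
    from scipy.stats import norm

    if not np.isfinite(coef) or not np.isfinite(se) or se > _SE_SEPARATION_GUARD:
        return AssociationResult(
            outcome_name, exposure_name, model,
            odds_ratio=float(np.exp(coef)) if np.isfinite(coef) else np.nan,
            ci_low=np.nan, ci_high=np.nan, p_value=np.nan, n_used=n_used,
            flags=flags + ("separation",),
        )
    zval = coef / se if se > 0 else np.inf
    return AssociationResult(
        outcome_name, exposure_name, model,
        odds_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(coef - _Z95 * se)),
        ci_high=float(np.exp(coef + _Z95 * se)),
        p_value=float(2 * norm.sf(abs(zval))),
        n_used=n_used,
        flags=flags,
    )


def _complete_cases(outcome: pd.Series, design: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    joined = pd.concat([outcome.rename("__y"), design], axis=1, join="inner").dropna()
    return joined["__y"].to_numpy(dtype=float), joined.drop(columns="__y").to_numpy(dtype=float)


def univariable_or(
    outcome: pd.Series,
    exposure: pd.Series,
    outcome_name: str = "outcome",
    exposure_name: str = "exposure",
) -> AssociationResult:
    """Logistic MLE with intercept + one binary indicator.

    For a binary exposure this equals the 2x2 cross-product (ad/bc) odds
    ratio with the standard large-sample Wald interval.  Any empty 2x2 cell
    is complete separation: flagged, no crash.
    """
    y, x = _complete_cases(pd.Series(outcome), pd.Series(exposure).to_frame("x"))
    x = x[:, 0]
    n_used = y.shape[0]
    if np.unique(x).size < 2:
        return AssociationResult(
            outcome_name, exposure_name, "univariable",
            np.nan, np.nan, np.nan, np.nan, n_used, flags=("degenerate-exposure",),
        )
    if set(np.unique(x)) <= {0.0, 1.0} and set(np.unique(y)) <= {0.0, 1.0}:
        a = float(((x == 1) & (y == 1)).sum())
        b = float(((x == 1) & (y == 0)).sum())
        c = float(((x == 0) & (y == 1)).sum())
        d = float(((x == 0) & (y == 0)).sum())
        if min(a, b, c, d) == 0:
            unbounded = np.inf if (b == 0 or c == 0) and a * d > 0 else 0.0
            return AssociationResult(
                outcome_name, exposure_name, "univariable",
                odds_ratio=unbounded, ci_low=np.nan, ci_high=np.nan,
                p_value=np.nan, n_used=n_used, flags=("separation",),
            )
        coef = np.log(a * d / (b * c))
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        return _wald_result(outcome_name, exposure_name, "univariable", coef, se, n_used)
    design = sm.add_constant(x)
    fit = sm.GLM(y, design, family=sm.families.Binomial()).fit()
    return _wald_result(
        outcome_name, exposure_name, "univariable", float(fit.params[1]), float(fit.bse[1]), n_used
    )


def multiple_or(
    outcome: pd.Series,
    profile: pd.DataFrame,
    outcome_name: str = "outcome",
    penalized: bool = False,
) -> list[AssociationResult]:
    """Adjusted odds ratios: one joint logistic model containing every
    cluster indicator simultaneously.

    Degenerate (constant) columns are flagged and excluded from the fit;
    the remaining estimates are unaffected.  Non-convergence or a diverging
    Wald SE flags the affected estimates.  ``penalized=True`` switches to an
    L2-regularized fit (no standard errors; CIs unavailable)."""
    cols = list(profile.columns)
    y, X = _complete_cases(pd.Series(outcome), profile.astype(float))
    n_used = y.shape[0]
    degenerate = [c for j, c in enumerate(cols) if np.unique(X[:, j]).size < 2]
    keep = [c for c in cols if c not in degenerate]
    keep_idx = [cols.index(c) for c in keep]
    results: list[AssociationResult] = []
    for c in degenerate:
        results.append(
            AssociationResult(
                outcome_name, str(c), "multiple",
                np.nan, np.nan, np.nan, np.nan, n_used, flags=("degenerate-exposure",),
            )
        )
    if not keep:
        return results
    design = sm.add_constant(X[:, keep_idx])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        flags = ("collinear",)
    else:
        flags = ()
    model = sm.GLM(y, design, family=sm.families.Binomial())
    if penalized:
        fit = model.fit_regularized(alpha=1.0 / max(n_used, 1), L1_wt=0.0)
        for j, c in enumerate(keep, start=1):
            results.append(
                AssociationResult(
                    outcome_name, str(c), "multiple",
                    odds_ratio=float(np.exp(fit.params[j])),
                    ci_low=np.nan, ci_high=np.nan, p_value=np.nan,
                    n_used=n_used, flags=flags + ("penalized",),
                )
            )
        return _in_input_order(results, cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(maxiter=100)
    if not fit.converged:
        flags = flags + ("non-convergence",)
    for j, c in enumerate(keep, start=1):
        results.append(
            _wald_result(
                outcome_name, str(c), "multiple",
                float(fit.params[j]), float(fit.bse[j]), n_used, flags=flags,
            )
        )
    return _in_input_order(results, cols)


def _in_input_order(results: list[AssociationResult], cols: list) -> list[AssociationResult]:
    order = {str(c): i for i, c in enumerate(cols)}
    return sorted(results, key=lambda r: order[r.exposure])


def cross_age_confusion(
    profiles_t1: pd.DataFrame, profiles_t2: pd.DataFrame
) -> pd.DataFrame:
    """Cluster x cluster counts of subjects sensitized to cluster A at the
    first age and cluster B at the second (subjects can hit several cells).
    Only subjects with data at both ages contribute."""
    c1 = [c for c in profiles_t1.columns if c != "nonsensitized"]
    c2 = [c for c in profiles_t2.columns if c != "nonsensitized"]
    shared = profiles_t1.index.intersection(profiles_t2.index)
    if shared.empty:
        warnings.warn("no subjects shared between the two ages", stacklevel=2)
        return pd.DataFrame(0, index=c1, columns=c2, dtype=int)
    a = profiles_t1.loc[shared, c1].to_numpy(dtype=bool)
    b = profiles_t2.loc[shared, c2].to_numpy(dtype=bool)
    counts = a.T.astype(int) @ b.astype(int)
    return pd.DataFrame(counts, index=c1, columns=c2, dtype=int)


def results_table(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Flatten association results for delimited-text export."""
    return pd.DataFrame(
        [
            {
                "outcome": r.outcome,
                "exposure": r.exposure,
                "model": r.model,
                "OR": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p_value,
                "n": r.n_used,
                "flags": ";".join(r.flags),
            }
            for r in results
        ]
    )
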