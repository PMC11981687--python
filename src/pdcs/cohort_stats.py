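"""Trial normalization, per-condition summaries and the mixed-model contrast.

Each trial consists of three BFI segments (control before, test, control
after).  All samples of a trial are normalized to 100% of the median of the
first control segment; per-segment medians of this relative BFI (rBFI) feed
the group analysis: per-condition medians and quartiles, pairwise mean
differences, Cohen's d effect sizes, and a linear mixed-effects contrast

    rBFI ~ Trial + Condition + (Condition | Subject)

with Trial as a categorical fixed effect and a random intercept and condition
slope per subject.  The mixed-model engine is statsmodels' MixedLM; this
module owns the data marshaling, the formula and the fallback to a
random-intercept-only model when the full random structure is singular.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .traces import BfiTrace

__all__ = [
    "CONDITIONS",
    "TrialRecord",
    "LmeResult",
    "GroupResult",
    "normalize_trial",
    "trial_table",
    "cohens_d",
    "lme_contrast",
    "condition_summary",
    "significance_stars",
]

logger = logging.getLogger(__name__)

CONDITIONS = ("control_before", "test", "control_after")

#: Star thresholds used in figure annotations.
STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class TrialRecord:
    """One trial-and-condition row of the group table."""

    subject_id: str
    trial_id: str
    condition: str
    rbfi_median: float
    pi: float = float("nan")
    pulse_rate_hz: float = float("nan")
    n_bar_sp: float = float("nan")
    n_bar_de: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "trial_id": self.trial_id,
            "condition": self.condition,
            "rbfi_median": self.rbfi_median,
            "pi": self.pi,
            "pulse_rate_hz": self.pulse_rate_hz,
            "n_bar_sp": self.n_bar_sp,
            "n_bar_de": self.n_bar_de,
        }


@dataclass(frozen=True)
class LmeResult:
    """Condition-effect statistics from the mixed model."""

    coef: float
    tvalue: float
    pvalue: float
    conditions: tuple[str, str]
    converged: bool
    fallback_random_intercept: bool


@dataclass
class GroupResult:
    """Per-condition summaries and pairwise contrasts of a trial table."""

    per_condition: pd.DataFrame  # median, q25, q75, n per condition
    contrasts: pd.DataFrame  # cond_a, cond_b, mean_diff, cohens_d
    lme: dict[tuple[str, str], LmeResult] = field(default_factory=dict)


def normalize_trial(
    traces: Mapping[str, BfiTrace],
) -> tuple[dict[str, BfiTrace], dict[str, float]]:
    """Normalize a trial's segments to 100% of the first control median.

    ``traces`` maps condition labels (at minimum 'control_before') to fitted
    BfiTraces.  Every sample of every segment is multiplied by
    100 / median(valid control_before BFI); the function returns the
    normalized traces and the per-segment medians of the normalized valid
    samples (the control_before median is 100 by construction).  A trial
    whose first control has no valid samples is unusable.
    """
    if "control_before" not in traces:
        raise ValueError("trial must include a 'control_before' segment")
    ref = traces["control_before"].valid_bfi()
    if ref.size == 0:
        raise ValueError("control_before has no valid samples; trial unusable")
    scale = 100.0 / float(np.median(ref))
    normalized = {label: t.scaled(scale) for label, t in traces.items()}
    medians = {
        label: float(np.median(t.valid_bfi())) if t.valid_bfi().size else float("nan")
        for label, t in normalized.items()
    }
    return normalized, medians


def trial_table(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Assemble TrialRecords into the long-format group table."""
    if len(records) == 0:
        raise ValueError("no trial records")
    return pd.DataFrame([r.as_dict() for r in records])


def cohens_d(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Cohen's d = (mean_a - mean_b) / pooled SD (n-1 weighted pooling).

    Returns NaN when the pooled standard deviation is zero (undefined
    effect size).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def lme_contrast(
    table: pd.DataFrame,
    conditions: tuple[str, str] = ("control_before", "test"),
    metric: str = "rbfi_median",
) -> LmeResult:
    """Mixed-model contrast of one condition pair.

    Fits metric ~ Trial + Condition with a random intercept and condition
    slope per subject (REML).  On non-convergence or a singular
    random-effects covariance the model falls back to a random intercept
    only, with a logged warning.  Returns the Wald t and p of the condition
    effect (second condition minus first).
    """
    present = set(table["condition"].unique())
    missing = [c for c in conditions if c not in present]
    if missing:
        raise ValueError(f"conditions not present in table: {missing}")
    if table["subject_id"].nunique() < 2:
        raise ValueError("need at least 2 subjects for a mixed model")
    sub = table[table["condition"].isin(conditions)].copy()
    sub["cond"] = (sub["condition"] == conditions[1]).astype(float)
    if sub["trial_id"].nunique() > 1:
        formula = f"{metric} ~ C(trial_id) + cond"
    else:
        formula = f"{metric} ~ cond"

    def _fit(re_formula: str):
        model = smf.mixedlm(
            formula, sub, groups=sub["subject_id"], re_formula=re_formula
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(reml=True)

    fallback = False
    try:
        fit = _fit("~cond")
        cov = np.asarray(fit.cov_re)
        singular = (not fit.converged) or np.any(np.diag(cov) <= 1e-10) or (
            np.linalg.cond(cov) > 1e8
        )
    except (np.linalg.LinAlgError, ValueError):
        singular = True
        fit = None
    if singular:
        logger.warning(
            "random-slope fit singular or non-convergent for %s; falling back "
            "to random intercept only", conditions,
        )
        fallback = True
        fit = _fit("1")
    if fit is None or "cond" not in fit.params.index:
        raise RuntimeError("mixed model is rank deficient: no condition effect estimable")
    return LmeResult(
        coef=float(fit.params["cond"]),
        tvalue=float(fit.tvalues["cond"]),
        pvalue=float(fit.pvalues["cond"]),
        conditions=conditions,
        converged=bool(fit.converged),
        fallback_random_intercept=fallback,
    )


def condition_summary(
    table: pd.DataFrame,
    metric: str = "rbfi_median",
    contrasts: Sequence[tuple[str, str]] | None = None,
    with_lme: bool = False,
) -> GroupResult:
    """Medians, quartiles and pairwise contrasts of a trial table.

    Medians use the midpoint convention for even counts.  p-values, when
    requested via ``with_lme``, are reported raw (no multiple-testing
    correction), one mixed-model fit per contrast pair.
    """
    conditions = [c for c in CONDITIONS if c in set(table["condition"])]
    if not conditions:
        raise ValueError("table contains no recognized conditions")
    rows = []
    for cond in conditions:
        vals = table.loc[table["condition"] == cond, metric].dropna()
        if vals.empty:
            raise ValueError(f"condition {cond!r} has no observations")
        rows.append({
            "condition": cond,
            "median": float(vals.median()),
            "q25": float(vals.quantile(0.25)),
            "q75": float(vals.quantile(0.75)),
            "n": int(vals.size),
        })
    per_condition = pd.DataFrame(rows).set_index("condition")

    if contrasts is None:
        contrasts = [
            (a, b)
            for i, a in enumerate(conditions)
            for b in conditions[i + 1 :]
        ]
    crows = []
    lme: dict[tuple[str, str], LmeResult] = {}
    for a, b in contrasts:
        va = table.loc[table["condition"] == a, metric].dropna().to_numpy()
        vb = table.loc[table["condition"] == b, metric].dropna().to_numpy()
        crows.append({
            "cond_a": a,
            "cond_b": b,
            "mean_diff": float(vb.mean() - va.mean()),
            "cohens_d": cohens_d(vb, va),
        })
        if with_lme:
            lme[(a, b)] = lme_contrast(table, conditions=(a, b), metric=metric)
    return GroupResult(
        per_condition=per_condition,
        contrasts=pd.DataFrame(crows),
        lme=lme,
    )


def significance_stars(p: float) -> str:
    """Figure-legend star annotation: *p<0.05, **p<0.01, ***p<0.001."""
    for threshold, stars in STAR_LEVELS:
        if p < threshold:
            return stars
    return "ns"
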