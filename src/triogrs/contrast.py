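"""Mothers-as-cases / fathers-as-controls GRS contrasts.

Under the null of no maternal genetic effect, mothers and fathers of
affected children are exchangeable draws from the same population, so their
genetic risk score distributions coincide.  A maternal excess — in the mean,
or in the tail above a paternal percentile cut-point — signals a maternal
genetic effect.  Two contrasts are provided:

* **mean contrast** — two-sample equal-variance Student's t on the scores,
  with a Shapiro-Wilk normality check that triggers a log transform of both
  groups when either rejects (and all values are positive);
* **threshold contrast** — scores are dichotomized at a nearest-rank
  empirical percentile of the *fathers'* distribution (top 5th, 10th, 25th
  by default); the resulting 2x2 table (mothers as cases) is tested with a
  two-sided Fisher's exact test, and the odds ratio gets a Woolf logit 95%
  CI with Haldane-Anscombe correction when a cell is zero.

:func:`run_contrast_suite` applies both contrasts per condition over a
subgroup of trios (cohort, overt-phenotype exclusion, CTD-subtype filters).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: contrasted score columns, in reporting order
SCORE_COLUMNS = {
    "combined": "score_combined",
    "OBESITY": "score_obesity",
    "HTN": "score_htn",
    "T2D": "score_t2d",
}

DEFAULT_LEVELS = (0.95, 0.90, 0.75)


@dataclass
class MeanContrastResult:
    condition: str
    mean_mothers: float
    mean_fathers: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    transform_applied: str  # "none" or "log"


@dataclass
class ThresholdContrastResult:
    condition: str
    quantile_level: float
    cutoff: float
    a: int  # mothers high
    b: int  # mothers low
    c: int  # fathers high
    d: int  # fathers low
    odds_ratio: float
    ci_low: float
    ci_high: float
    fisher_p: float
    corrected: bool = False  # Haldane-Anscombe +0.5 applied


@dataclass
class SubgroupSpec:
    """Conjunctive trio filters for subgroup and sensitivity re-analyses."""

    cohort: str = "all"  # all | CHOP | PCGC
    exclude_overt_phenotype: bool = False
    ctd_subtype: str | None = None


@dataclass
class ContrastSuiteResult:
    means: pd.DataFrame
    thresholds: pd.DataFrame
    subgroup: SubgroupSpec = field(default_factory=SubgroupSpec)
    n_trios: int = 0


# ---------------------------------------------------------------------------
# mean contrast
# ---------------------------------------------------------------------------

def _shapiro_p(x: np.ndarray) -> float:
    if np.ptp(x) == 0:  # degenerate: Shapiro undefined, treat as no evidence
        return 1.0
    return float(stats.shapiro(x).pvalue)


def mean_contrast(mother_scores, father_scores, normality_alpha: float = 0.05,
                  condition: str = "combined") -> MeanContrastResult:
    """Equal-variance Student's t comparison of parental mean scores.

    Each group is Shapiro-Wilk tested; if either rejects at
    ``normality_alpha`` and every value in both groups is positive, both
    groups are log-transformed before the t-test.
    """
    m = np.asarray(mother_scores, dtype=float)
    f = np.asarray(father_scores, dtype=float)
    for name, v in (("mothers", m), ("fathers", f)):
        if v.size < 3:
            raise ValidationError(f"{name}: need at least 3 values for the mean contrast")
        if not np.all(np.isfinite(v)):
            raise ValidationError(f"{name}: non-finite score")

    transform = "none"
    tm, tf = m, f
    if min(_shapiro_p(m), _shapiro_p(f)) < normality_alpha:
        if np.all(m > 0) and np.all(f > 0):
            tm, tf = np.log(m), np.log(f)
            transform = "log"
        else:
            logger.warning("normality rejected but values are not all positive; log transform skipped")

    dof = tm.size + tf.size - 2
    if np.ptp(tm) == 0 and np.ptp(tf) == 0:
        # zero pooled variance: identical constants -> no evidence; else infinite separation
        t_stat, p = (0.0, 1.0) if tm[0] == tf[0] else (math.inf, 0.0)
    else:
        res = stats.ttest_ind(tm, tf, equal_var=True)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return MeanContrastResult(
        condition=condition,
        mean_mothers=float(m.mean()),
        mean_fathers=float(f.mean()),
        t_statistic=t_stat,
        degrees_of_freedom=float(dof),
        p_value=p,
        transform_applied=transform,
    )


# ---------------------------------------------------------------------------
# threshold contrast
# ---------------------------------------------------------------------------

def percentile_threshold(father_scores, quantile_level: float) -> float:
    """Nearest-rank empirical quantile of the fathers' scores.

    The cut-point is the ``ceil(n * q)``-th order statistic, so it is always
    an observed score and is deterministic under ties.
    """
    f = np.asarray(father_scores, dtype=float)
    if f.size == 0:
        raise ValidationError("cannot take a percentile of an empty score vector")
    if not 0 < quantile_level < 1:
        raise ValueError("quantile_level must be in (0, 1)")
    if quantile_level >= 0.95 and f.size < 20:
        warnings.warn(
            f"only {f.size} fathers for the {quantile_level:.0%} cut-point; tail is unstable",
            stacklevel=2,
        )
    rank = math.ceil(f.size * quantile_level)
    return float(np.sort(f)[rank - 1])


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p (sum of table probabilities <= observed)."""
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def odds_ratio_woolf(a: int, b: int, c: int, d: int):
    """Odds ratio with Woolf logit 95% CI.

    When any cell is zero, the Haldane-Anscombe +0.5 correction is applied
    to all cells for both the point estimate and the interval.  Returns
    ``(or, ci_low, ci_high, corrected)``.
    """
    if a == b == c == d == 0:
        raise ValidationError("all four cells of the 2x2 table are zero")
    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = ((x + 0.5) for x in (a, b, c, d)) if corrected else (a, b, c, d)
    or_ = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    z = stats.norm.ppf(0.975)
    return or_, math.exp(math.log(or_) - z * se), math.exp(math.log(or_) + z * se), corrected


def dichotomize_and_test(mother_scores, father_scores, cutoff: float,
                         condition: str = "combined",
                         quantile_level: float = float("nan")) -> ThresholdContrastResult:
    """Dichotomize both groups at ``cutoff`` and test the 2x2 table.

    "High" means strictly greater than the cut-point; mothers are the cases
    and fathers the controls, so an odds ratio above 1 means mothers are
    over-represented in the high-score tail.
    """
    m = np.asarray(mother_scores, dtype=float)
    f = np.asarray(father_scores, dtype=float)
    if m.size == 0 or f.size == 0:
        raise ValidationError("both parental groups must be non-empty")
    if not math.isfinite(cutoff):
        raise ValidationError("cutoff must be finite")
    a = int((m > cutoff).sum())
    b = m.size - a
    c = int((f > cutoff).sum())
    d = f.size - c
    or_, lo, hi, corrected = odds_ratio_woolf(a, b, c, d)
    p = fisher_exact_2x2(a, b, c, d)
    return ThresholdContrastResult(
        condition=condition, quantile_level=quantile_level, cutoff=float(cutoff),
        a=a, b=b, c=c, d=d,
        odds_ratio=or_, ci_low=lo, ci_high=hi, fisher_p=p, corrected=corrected,
    )


# ---------------------------------------------------------------------------
# suite
# ---------------------------------------------------------------------------

def filter_trios(trios: pd.DataFrame, subgroup: SubgroupSpec) -> pd.DataFrame:
    """Apply a :class:`SubgroupSpec` to a trio table (filters conjunctive)."""
    out = trios
    if subgroup.cohort != "all":
        out = out[out["cohort"] == subgroup.cohort.upper()]
    if subgroup.exclude_overt_phenotype:
        overt = (
            (out["maternal_preeclampsia"] == "yes")
            | (out["maternal_htn_medication"] == "yes")
            | (out["maternal_pregestational_diabetes"] == "yes")
        )
        out = out[~overt]
    if subgroup.ctd_subtype is not None:
        out = out[out["ctd_subtype"] == subgroup.ctd_subtype]
    return out


def run_contrast_suite(grs: pd.DataFrame, trios: pd.DataFrame,
                       subgroup: SubgroupSpec | None = None,
                       quantile_levels=DEFAULT_LEVELS,
                       normality_alpha: float = 0.05,
                       panel_sizes: dict | None = None) -> ContrastSuiteResult:
    """Run mean and threshold contrasts for every condition over a subgroup.

    Percentile cut-points are always recomputed from the *filtered*
    fathers, so each subgroup is judged against its own paternal
    distribution.

    Returns a :class:`ContrastSuiteResult` whose ``means`` frame has one row
    per condition and whose ``thresholds`` frame has one row per
    (condition, quantile level).
    """
    subgroup = subgroup or SubgroupSpec()
    sel = filter_trios(trios, subgroup)
    if len(sel) < 10:
        raise ValidationError(
            f"subgroup filter leaves {len(sel)} trios (<10); refusing unstable estimates"
        )
    scores = grs.set_index("sample_id")
    missing = [s for s in pd.concat([sel["mother_id"], sel["father_id"]]) if s not in scores.index]
    if missing:
        raise ValidationError(f"GRS table does not cover all parents: missing {missing[:5]}")

    mean_rows, thr_rows = [], []
    for cond, col in SCORE_COLUMNS.items():
        m = scores.loc[sel["mother_id"], col].to_numpy(dtype=float)
        f = scores.loc[sel["father_id"], col].to_numpy(dtype=float)
        mc = mean_contrast(m, f, normality_alpha=normality_alpha, condition=cond)
        row = vars(mc).copy()
        if panel_sizes:
            row["n_snps"] = panel_sizes.get(cond)
        mean_rows.append(row)
        for q in sorted(quantile_levels, reverse=True):
            cutoff = percentile_threshold(f, q)
            thr_rows.append(vars(dichotomize_and_test(m, f, cutoff, condition=cond, quantile_level=q)))
    return ContrastSuiteResult(
        means=pd.DataFrame(mean_rows),
        thresholds=pd.DataFrame(thr_rows),
        subgroup=subgroup,
        n_trios=len(sel),
    )
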