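"""Cohort characteristic summaries with between-cohort tests.

Builds "Table 1"-style summaries: per-cohort counts and percentages for
categorical trio fields with a Fisher's exact test of the levels x cohorts
table, and normality-aware t-tests for continuous measures.

Percentages use the variable's non-``unknown`` total within each cohort as
the denominator, uniformly across variables.  ``unknown`` rows are reported
with counts but excluded from both percentages and the exact test.

For contingency tables beyond 2x2, scipy offers no exact test, so the
r-by-c Fisher p is computed here: exact enumeration of all tables with the
observed margins when their number is small, otherwise a seeded Monte Carlo
estimate using Patefield sampling (``scipy.stats.random_table``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from . import contrast
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: give up exact enumeration after this many tables and fall back to Monte Carlo
ENUM_TABLE_CAP = 200_000
MC_DRAWS = 100_000
_REL_TOL = 1e-7  # float slack when comparing table probabilities


@dataclass
class CategoricalSummary:
    variable: str
    table: pd.DataFrame  # level, count/pct per cohort
    fisher_p: float
    method: str  # enumeration | monte-carlo


@dataclass
class ContinuousSummary:
    shapiro_p_a: float
    shapiro_p_b: float
    transform_applied: str
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    mean_a: float
    mean_b: float


def format_percentage(count: int, denominator: int) -> float:
    """Percentage to one decimal, half away from zero (190/466 -> 40.8)."""
    if denominator <= 0:
        raise ValidationError("percentage denominator must be positive")
    x = 100.0 * count / denominator
    return math.floor(x * 10 + 0.5) / 10


# ---------------------------------------------------------------------------
# r x c Fisher's exact test
# ---------------------------------------------------------------------------

def _log_table_prob(table: np.ndarray, lg_margins: float) -> float:
    return lg_margins - float(gammaln(table + 1).sum())


def fisher_exact_rxc(table, seed: int = 0, enum_table_cap: int = ENUM_TABLE_CAP,
                     n_mc: int = MC_DRAWS) -> tuple[float, str]:
    """Two-sided Fisher's exact p for an r x c contingency table.

    The p-value is the total conditional probability (given margins) of
    tables no more probable than the observed one.  Exact enumeration is
    used while the number of candidate tables stays below
    ``enum_table_cap``; beyond that a Monte Carlo estimate with ``n_mc``
    Patefield draws (seeded) is returned.  Returns ``(p, method)``.
    """
    obs = np.asarray(table, dtype=np.int64)
    if obs.ndim != 2 or obs.size == 0:
        raise ValidationError("contingency table must be 2-dimensional")
    if (obs < 0).any():
        raise ValidationError("contingency table cells must be nonnegative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    obs = obs[rows > 0][:, cols > 0]
    rows, cols = obs.sum(axis=1), obs.sum(axis=0)
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        return 1.0, "degenerate"
    n = int(obs.sum())
    lg_margins = float(gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(n + 1))
    lp_obs = _log_table_prob(obs, lg_margins)
    cut = lp_obs + abs(lp_obs) * _REL_TOL + 1e-12

    total = 0.0
    count = 0
    r, c = obs.shape
    cells = np.zeros((r, c), dtype=np.int64)

    def fill(i: int, j: int, row_left: np.ndarray, col_left: np.ndarray):
        nonlocal total, count
        if count > enum_table_cap:
            raise _EnumOverflow
        if i == r - 1:
            # last row is forced by the remaining column margins
            cells[i, :] = col_left
            count += 1
            lp = _log_table_prob(cells, lg_margins)
            if lp <= cut:
                total += math.exp(lp)
            return
        if j == c - 1:
            if col_left[j] < row_left[i]:
                return
            cells[i, j] = row_left[i]
            cl = col_left.copy()
            cl[j] -= row_left[i]
            rl = row_left.copy()
            rl[i] = 0
            fill(i + 1, 0, rl, cl)
            return
        hi = min(row_left[i], col_left[j])
        for v in range(hi + 1):
            cells[i, j] = v
            rl = row_left.copy()
            rl[i] -= v
            cl = col_left.copy()
            cl[j] -= v
            fill(i, j + 1, rl, cl)

    try:
        fill(0, 0, rows.copy(), cols.copy())
        return min(1.0, total), "enumeration"
    except _EnumOverflow:
        pass
    except RecursionError:
        pass

    rng = np.random.default_rng(seed)
    draws = stats.random_table(rows, cols).rvs(n_mc, random_state=rng)
    lps = lg_margins - gammaln(np.asarray(draws) + 1).sum(axis=(1, 2))
    p = float(np.mean(lps <= cut))
    return p, "monte-carlo"


class _EnumOverflow(Exception):
    pass


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_categorical(trios: pd.DataFrame, variable: str, seed: int = 0) -> CategoricalSummary:
    """Per-cohort counts/percentages for one categorical trio field.

    Percentages are over each cohort's non-``unknown`` total for the
    variable; the Fisher p is computed on the levels x cohorts table with
    ``unknown`` excluded.
    """
    if variable not in trios.columns:
        raise ValidationError(f"variable {variable!r} not in trio table")
    cohorts = ("PCGC", "CHOP")
    values = trios[[variable, "cohort"]].astype(str)
    known = values[values[variable] != "unknown"]
    for cohort in cohorts:
        if (known["cohort"] == cohort).sum() == 0:
            raise ValidationError(f"cohort {cohort} has no non-missing observations for {variable!r}")

    levels = list(pd.unique(values[variable]))
    rows = []
    denom = {c: int((known["cohort"] == c).sum()) for c in cohorts}
    for level in levels:
        row: dict = {"level": level}
        for cohort in cohorts:
            cnt = int(((values[variable] == level) & (values["cohort"] == cohort)).sum())
            row[f"count_{cohort.lower()}"] = cnt
            row[f"pct_{cohort.lower()}"] = (
                format_percentage(cnt, denom[cohort]) if level != "unknown" else float("nan")
            )
        rows.append(row)
    table_df = pd.DataFrame(rows)

    ct = table_df[table_df["level"] != "unknown"][["count_pcgc", "count_chop"]].to_numpy()
    if ct.shape[0] < 2:
        p, method = 1.0, "degenerate"  # a single level cannot differ between cohorts
    else:
        p, method = fisher_exact_rxc(ct, seed=seed)
    return CategoricalSummary(variable=variable, table=table_df, fisher_p=p, method=method)


def summarize_continuous(values_a, values_b, normality_alpha: float = 0.05) -> ContinuousSummary:
    """Two-cohort comparison of a continuous measure.

    Same normality / log-transform / equal-variance Student's t rule as the
    parental mean contrast.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    sw_a = contrast._shapiro_p(a)
    sw_b = contrast._shapiro_p(b)
    mc = contrast.mean_contrast(a, b, normality_alpha=normality_alpha)
    return ContinuousSummary(
        shapiro_p_a=sw_a, shapiro_p_b=sw_b,
        transform_applied=mc.transform_applied,
        t_statistic=mc.t_statistic,
        degrees_of_freedom=mc.degrees_of_freedom,
        p_value=mc.p_value,
        mean_a=mc.mean_mothers, mean_b=mc.mean_fathers,
    )


DEFAULT_TABLE1_FIELDS = (
    "ctd_subtype", "child_sex", "extracardiac",
    "maternal_age_band", "paternal_age_band", "maternal_bmi_band",
    "maternal_pregestational_diabetes", "maternal_gestational_diabetes",
    "maternal_preeclampsia", "maternal_htn_medication",
)


def cohort_table(trios: pd.DataFrame, fields=DEFAULT_TABLE1_FIELDS, seed: int = 0) -> pd.DataFrame:
    """Stacked Table-1-style summary for several categorical fields."""
    frames = []
    for i, var in enumerate(fields):
        if var not in trios.columns:
            continue
        try:
            summary = summarize_categorical(trios, var, seed=seed + i)
        except ValidationError as exc:
            logger.warning("skipping %s: %s", var, exc)
            continue
        t = summary.table.copy()
        t.insert(0, "variable", var)
        t["fisher_p"] = [summary.fisher_p] + [np.nan] * (len(t) - 1)
        frames.append(t)
    if not frames:
        raise ValidationError("no summarizable fields in trio table")
    return pd.concat(frames, ignore_index=True)
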