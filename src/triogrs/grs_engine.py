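"""Weighted genetic risk scores for parents of case trios.

A per-condition score for a sample is the weighted sum of its risk-allele
dosages over that condition's SNP panel,

    S = sum_i w_i * g_i,      g_i in [0, 2],

with weights and risk-allele definitions taken from the weight table; the
combined score is the exact sum of the three per-condition scores.  Scores
are raw weighted sums — no rescaling by SNP count or weight total — so they
are comparable to published per-condition means.

Only parents are scored: the design contrasts mothers against fathers, and
offspring genotypes play no role in the scores.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .errors import AlignmentError, ValidationError
from .io_formats import CONDITIONS, DosageMatrix

logger = logging.getLogger(__name__)

MISSING_POLICIES = ("impute_role_mean", "drop_sample", "score_available")


def orient_dosage(dosage: float, counted_allele: str, other_allele: str,
                  effect_allele: str, weight_other: str, snp_id: str = "?"):
    """Orient a single dosage onto the weight table's effect allele.

    Returns ``(oriented_dosage, flipped)``.  Flipping maps ``d -> 2 - d``
    (NaN stays NaN).  Allele pairs that do not match the weight entry in
    either order raise :class:`AlignmentError`; no strand complementing is
    attempted.
    """
    if counted_allele == effect_allele and other_allele == weight_other:
        return dosage, False
    if counted_allele == weight_other and other_allele == effect_allele:
        return 2.0 - dosage, True
    raise AlignmentError(
        f"{snp_id}: genotype alleles {counted_allele}/{other_allele} do not match "
        f"weight-table alleles {effect_allele}/{weight_other} in either order"
    )


def align_alleles(dosages: DosageMatrix, weights: pd.DataFrame) -> DosageMatrix:
    """Orient every SNP column of ``dosages`` onto its effect allele.

    Columns already counted on the effect allele pass through unchanged;
    columns counted on the other allele are flipped (``2 - d``).  The
    returned matrix has every ``oriented`` flag set.
    """
    wt = weights.set_index("snp_id")
    matrix = dosages.dosage.copy()
    counted = list(dosages.counted_allele)
    other = list(dosages.other_allele)
    for j, snp in enumerate(dosages.snp_ids):
        if snp not in wt.index:
            raise AlignmentError(f"{snp}: not present in weight table")
        entry = wt.loc[snp]
        _, flipped = orient_dosage(
            0.0, counted[j], other[j], entry["effect_allele"], entry["other_allele"], snp
        )
        if flipped:
            matrix[:, j] = 2.0 - matrix[:, j]
            counted[j], other[j] = other[j], counted[j]
    return replace(
        dosages,
        dosage=matrix,
        counted_allele=counted,
        other_allele=other,
        oriented=np.ones(len(dosages.snp_ids), dtype=bool),
    )


def compute_grs(dosages: DosageMatrix, weights: pd.DataFrame, roles: pd.DataFrame,
                missing_policy: str = "impute_role_mean") -> pd.DataFrame:
    """Compute per-condition and combined GRS for every parent.

    Parameters
    ----------
    dosages
        Allele-aligned dosage matrix (see :func:`align_alleles`); samples
        not listed in ``roles`` (e.g. children) are ignored.
    weights
        Validated weight table; every scored SNP must be a column of
        ``dosages``.
    roles
        Frame with ``sample_id``, ``role`` (mother/father) and optionally
        ``cohort`` — typically :func:`triogrs.io_formats.parent_roles`.
    missing_policy
        ``impute_role_mean`` (default) replaces a missing dosage with the
        mean oriented dosage of that SNP among samples of the same parental
        role; ``drop_sample`` removes samples with any missing genotype;
        ``score_available`` sums over the non-missing SNPs only.

    Returns
    -------
    pandas.DataFrame
        One row per scored sample: ``sample_id``, ``role``, ``cohort``,
        ``score_htn``, ``score_obesity``, ``score_t2d``, ``score_combined``
        and per-condition ``n_missing_*`` counts (pre-imputation).
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"missing_policy must be one of {MISSING_POLICIES}")
    if not np.all(dosages.oriented):
        dosages = align_alleles(dosages, weights)

    roles = roles.drop_duplicates(subset="sample_id")
    role_set = set(roles["sample_id"])
    keep = [s for s in dosages.sample_ids if s in role_set]
    if not keep:
        raise ValidationError("no scored sample appears in the roles table")
    dm = dosages.subset_samples(keep)
    meta = roles.set_index("sample_id").loc[keep]
    role_arr = meta["role"].to_numpy()
    cohort_arr = meta["cohort"].to_numpy() if "cohort" in meta.columns else np.array(["?"] * len(keep))

    col_of = {s: j for j, s in enumerate(dm.snp_ids)}
    cond_cols: dict[str, np.ndarray] = {}
    cond_w: dict[str, np.ndarray] = {}
    for cond in CONDITIONS:
        sub = weights[weights["condition"] == cond]
        if sub.empty:
            raise ValidationError(f"condition {cond} has zero scored SNPs")
        absent = [s for s in sub["snp_id"] if s not in col_of]
        if absent:
            raise ValidationError(f"scored SNPs absent from dosage matrix: {absent[:5]}")
        cond_cols[cond] = np.array([col_of[s] for s in sub["snp_id"]])
        cond_w[cond] = sub["weight"].to_numpy(dtype=float)

    X = dm.dosage
    missing = np.isnan(X)
    all_missing = missing.all(axis=1)
    if missing_policy in ("impute_role_mean",) and all_missing.any():
        bad = np.asarray(dm.sample_ids)[all_missing][0]
        raise ValidationError(f"sample {bad} has all SNPs missing; cannot impute")

    if missing_policy == "drop_sample":
        ok = ~missing.any(axis=1)
        if not ok.any():
            raise ValidationError("drop_sample policy removed every sample")
        dropped = int((~ok).sum())
        if dropped:
            logger.info("drop_sample: removed %d sample(s) with missing genotypes", dropped)
        X, missing = X[ok], missing[ok]
        keep = list(np.asarray(dm.sample_ids)[ok])
        role_arr, cohort_arr = role_arr[ok], cohort_arr[ok]
    elif missing_policy == "impute_role_mean":
        X = X.copy()
        with np.errstate(invalid="ignore"):
            overall = np.nanmean(X, axis=0)  # fallback for a SNP fully missing within one role
        for role in np.unique(role_arr):
            rows = role_arr == role
            block = X[rows]
            with np.errstate(invalid="ignore"):
                col_mean = np.nanmean(block, axis=0)
            col_mean = np.where(np.isnan(col_mean), overall, col_mean)
            if np.isnan(col_mean).any():
                j = int(np.argwhere(np.isnan(col_mean))[0])
                raise ValidationError(f"SNP {dm.snp_ids[j]} is missing in every sample")
            idx = np.where(np.isnan(block))
            block[idx] = col_mean[idx[1]]
            X[rows] = block

    out = pd.DataFrame({"sample_id": keep, "role": role_arr, "cohort": cohort_arr})
    score_cols = {"HTN": "score_htn", "OBESITY": "score_obesity", "T2D": "score_t2d"}
    for cond in CONDITIONS:
        cols, w = cond_cols[cond], cond_w[cond]
        sub = X[:, cols]
        n_miss = missing[:, cols].sum(axis=1).astype(int)
        if missing_policy == "score_available":
            sub = np.where(np.isnan(sub), 0.0, sub)
        out[score_cols[cond]] = sub @ w
        out[f"n_missing_{score_cols[cond][6:]}"] = n_miss
    return combine_scores(out)


def combine_scores(grs: pd.DataFrame) -> pd.DataFrame:
    """(Re)compute ``score_combined`` as the exact sum of the three scores."""
    for col in ("score_htn", "score_obesity", "score_t2d"):
        if col not in grs.columns:
            raise ValidationError(f"cannot combine scores: {col} absent")
    grs = grs.copy()
    grs["score_combined"] = grs["score_htn"] + grs["score_obesity"] + grs["score_t2d"]
    ordered = [c for c in (
        "sample_id", "role", "cohort",
        "score_htn", "score_obesity", "score_t2d", "score_combined",
        "n_missing_htn", "n_missing_obesity", "n_missing_t2d",
    ) if c in grs.columns]
    return grs[ordered + [c for c in grs.columns if c not in ordered]]


def write_grs(grs: pd.DataFrame, path) -> None:
    grs.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_grs(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
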