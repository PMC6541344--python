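"""Per-SNP p-value screening against per-condition Bonferroni thresholds.

The screen consumes maternal-effect association p-values produced upstream
(a trio-based GWAS meta-analysis); it does not compute them.  Each SNP is
classified against the Bonferroni-adjusted threshold for its condition's
panel size:

* ``significant`` — p <= 0.05 / n_snps (exact quotient; ties significant);
* ``suggestive``  — above the threshold but below 0.05 (open band);
* ``null``        — p >= 0.05.

A display threshold rounded to one significant digit accompanies the exact
quotient (0.05/31 -> 0.002, 0.05/46 -> 0.001).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError
from .io_formats import CONDITIONS

ALPHA = 0.05


@dataclass
class ScreenResult:
    snp_id: str
    condition: str
    p_value: float
    threshold: float
    classification: str


def bonferroni_threshold(condition: str, n_snps: int) -> float:
    """Exact Bonferroni threshold ``0.05 / n_snps`` for a condition's panel."""
    if condition.upper() not in CONDITIONS:
        raise ValidationError(f"unknown condition {condition!r}")
    if n_snps < 1:
        raise ValidationError("panel must contain at least one SNP")
    return ALPHA / n_snps


def display_threshold(threshold: float) -> float:
    """Round a threshold to one significant digit for display."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    exponent = math.floor(math.log10(threshold))
    mantissa = round(threshold / 10 ** exponent)
    if mantissa == 10:
        mantissa, exponent = 1, exponent + 1
    return float(f"{mantissa}e{exponent}")


def classify_one(p_value: float, threshold: float) -> str:
    if not 0 < p_value <= 1:
        raise ValidationError(f"p-value {p_value} outside (0, 1]")
    if p_value <= threshold:
        return "significant"
    if p_value < ALPHA:
        return "suggestive"
    return "null"


def classify(associations: pd.DataFrame, panel_sizes: dict[str, int]) -> pd.DataFrame:
    """Classify every association row; sorted by condition then p-value.

    ``associations`` needs ``snp_id``, ``condition``, ``p_value`` (see
    :func:`triogrs.io_formats.read_associations`); ``panel_sizes`` maps each
    condition to the number of SNPs evaluated for it.
    """
    sizes = {k.upper(): v for k, v in panel_sizes.items()}
    out = associations.copy()
    out["condition"] = out["condition"].str.upper()
    unknown = set(out["condition"]) - set(sizes)
    if unknown:
        raise ValidationError(f"no panel size for condition(s) {sorted(unknown)}")
    out["threshold"] = [bonferroni_threshold(c, sizes[c]) for c in out["condition"]]
    out["threshold_display"] = out["threshold"].map(display_threshold)
    out["classification"] = [classify_one(p, t) for p, t in zip(out["p_value"], out["threshold"])]
    return out.sort_values(["condition", "p_value"], kind="stable").reset_index(drop=True)


def write_screen(screen: pd.DataFrame, path) -> None:
    screen.to_csv(path, sep="\t", index=False, float_format="%.6g")
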