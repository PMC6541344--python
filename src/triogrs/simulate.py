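"""Synthetic case-parent trios with a known maternal GRS effect.

The generative model makes the whole mothers-vs-fathers design measurable
at desk scale:

1. A SNP panel mirrors the published score composition: 31 hypertension,
   30 obesity and 46 type-2-diabetes SNPs, each with an effect-allele
   frequency drawn from a band inside (0.05, 0.95) and a positive weight.
2. Parents are drawn independently under Hardy-Weinberg equilibrium
   (random mating); the child receives one allele from each parent by
   Mendelian transmission.
3. The child is affected with probability

       expit(alpha + beta_m * z_m)                      (linear mode)
       expit(alpha + beta_m * 1[z_m > z_q])             (threshold mode)

   where ``z_m`` is the mother's combined GRS standardized against the
   population mean and SD, and ``z_q`` is the *population*
   ``threshold_quantile`` of ``z``.  The intercept ``alpha`` is solved by
   bisection (to 1e-10) so the marginal, unascertained prevalence equals
   ``baseline_prevalence`` (default 1%, the live-birth rate of congenital
   heart defects).
4. Only trios with an affected child are retained (ascertainment), until
   the target cohort size is reached.

Because the effect acts through the mother only, fathers remain draws from
the population distribution under any ``beta_m``; with ``beta_m = 0`` the
parents are exchangeable and the contrast's type-I error can be measured,
with ``beta_m > 0`` its power.
"""

from __future__ import annotations

import logging
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.special import expit, logit

from . import grs_engine, io_formats
from .contrast import dichotomize_and_test, mean_contrast, percentile_threshold
from .errors import ValidationError
from .io_formats import DosageMatrix

logger = logging.getLogger(__name__)

#: CTD subtype mix used for simulated phenotype fields (pooled cohort rates)
DEFAULT_SUBTYPE_PROBS = {
    "ToF": 0.38, "D-TGA": 0.20, "VSD": 0.18, "DORV": 0.11,
    "aortic_arch_anomaly": 0.04, "truncus": 0.03, "IAA": 0.02,
    "L-TGA": 0.016, "complex": 0.019, "other": 0.005,
}

_ALLELE_PAIRS = (("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"))


class SimConfig(BaseModel):
    """Configuration of the trio simulator; ``seed`` is mandatory."""

    seed: int
    n_trios: int = Field(default=721, gt=0)
    n_htn: int = Field(default=31, ge=1)
    n_obesity: int = Field(default=30, ge=1)
    n_t2d: int = Field(default=46, ge=1)
    freq_band: tuple[float, float] = (0.1, 0.9)
    weight_band: tuple[float, float] = (0.05, 0.6)
    beta_m: float = 0.0
    beta_child: float = 0.0  # optional direct child-genotype effect (off by default)
    baseline_prevalence: float = Field(default=0.01, gt=0.0, lt=0.5)
    effect_mode: Literal["linear", "threshold"] = "linear"
    threshold_quantile: float = Field(default=0.95, gt=0.0, lt=1.0)
    missing_rate: float = Field(default=0.0, ge=0.0, lt=1.0)
    chop_fraction: float = Field(default=466 / 721, ge=0.0, le=1.0)
    preeclampsia_rate: float = 0.02
    htn_medication_rate: float = 0.01
    pregestational_diabetes_rate: float = 0.01
    gestational_diabetes_rate: float = 0.05
    unknown_rate: float = 0.02
    male_fraction: float = 0.61

    @model_validator(mode="after")
    def _check_bands(self):
        lo, hi = self.freq_band
        if not (0.05 < lo < hi < 0.95):
            raise ValueError("freq_band must satisfy 0.05 < lo < hi < 0.95 (common variants)")
        wlo, whi = self.weight_band
        if not (0 < wlo < whi):
            raise ValueError("weight_band must be positive and increasing")
        if not np.isfinite(self.beta_m):
            raise ValueError("beta_m must be finite")
        return self


def generate_panel(config: SimConfig) -> pd.DataFrame:
    """Draw the simulated SNP panel (weight-table schema plus ``freq``).

    Deterministic under the config seed.  Frequencies are uniform on
    ``freq_band``, weights uniform on ``weight_band``; alleles use
    non-strand-ambiguous pairs.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    sizes = {"HTN": config.n_htn, "OBESITY": config.n_obesity, "T2D": config.n_t2d}
    rows = []
    k = 0
    for cond, n in sizes.items():
        for _ in range(n):
            eff, oth = _ALLELE_PAIRS[rng.integers(len(_ALLELE_PAIRS))]
            rows.append({
                "snp_id": f"rs{9000001 + k}",
                "chrom": str(1 + k % 22),
                "pos": 10_000 + 1_000 * k,
                "effect_allele": eff,
                "other_allele": oth,
                "weight": float(rng.uniform(*config.weight_band)),
                "condition": cond,
                "freq": float(rng.uniform(*config.freq_band)),
            })
            k += 1
    return pd.DataFrame(rows)


def panel_to_weight_table(panel: pd.DataFrame) -> pd.DataFrame:
    return panel.drop(columns=["freq"])


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def population_moments(panel: pd.DataFrame) -> tuple[float, float]:
    """Exact population mean and SD of the combined GRS under HWE."""
    w = panel["weight"].to_numpy()
    f = panel["freq"].to_numpy()
    mu = float((2 * w * f).sum())
    sd = float(np.sqrt((w ** 2 * 2 * f * (1 - f)).sum()))
    return mu, sd


def _draw_genotypes(rng: np.random.Generator, freqs: np.ndarray, n: int) -> np.ndarray:
    """n x S genotypes under HWE from a single uniform per cell."""
    u = rng.random((n, freqs.size))
    c0 = (1 - freqs) ** 2
    c1 = 1 - freqs ** 2
    return ((u >= c0).astype(np.uint8) + (u >= c1)).astype(np.uint8)


def calibrate_intercept(panel: pd.DataFrame, config: SimConfig,
                        n_mc: int = 400_000) -> dict:
    """Solve the liability intercept for the target marginal prevalence.

    With ``beta_m = 0`` the closed form ``alpha = logit(prevalence)`` is
    exact.  Otherwise the marginal prevalence is estimated over ``n_mc``
    maternal draws from the exact genotype distribution (seeded from the
    config) and ``alpha`` is found by bisection to an interval of 1e-10.
    """
    mu, sd = population_moments(panel)
    out = {"pop_mean": mu, "pop_sd": sd, "z_threshold": None}
    prev = config.baseline_prevalence
    if config.beta_m == 0:
        out["alpha"] = float(logit(prev))
        if config.effect_mode == "threshold":
            out["z_threshold"] = float("inf")  # unused when beta_m = 0
        return out

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    freqs = panel["freq"].to_numpy()
    w = panel["weight"].to_numpy()
    z = np.empty(n_mc)
    chunk = 50_000
    for start in range(0, n_mc, chunk):
        stop = min(start + chunk, n_mc)
        g = _draw_genotypes(rng, freqs, stop - start)
        z[start:stop] = (g @ w - mu) / sd
    if config.effect_mode == "threshold":
        zq = float(np.quantile(z, config.threshold_quantile))
        out["z_threshold"] = zq
        x = (z > zq).astype(float)
    else:
        x = z

    def realized(alpha: float) -> float:
        return float(expit(alpha + config.beta_m * x).mean())

    lo, hi = -40.0, 10.0
    if not (realized(lo) <= prev <= realized(hi)):
        raise ValidationError("prevalence solver failed to bracket the intercept")
    while hi - lo > 1e-10:
        mid = 0.5 * (lo + hi)
        if realized(mid) < prev:
            lo = mid
        else:
            hi = mid
    out["alpha"] = 0.5 * (lo + hi)
    return out


# ---------------------------------------------------------------------------
# trio generation
# ---------------------------------------------------------------------------

def simulate_trios(config: SimConfig, panel: pd.DataFrame | None = None,
                   calibration: dict | None = None):
    """Simulate an ascertained cohort of case-parent trios.

    Returns ``(trios, dosages, truth)``: a pedigree table, a
    :class:`DosageMatrix` over mothers, fathers and children (oriented on
    the effect alleles), and a truth record with the generative parameters
    actually used.
    """
    if panel is None:
        panel = generate_panel(config)
    if calibration is None:
        calibration = calibrate_intercept(panel, config)
    ss = np.random.SeedSequence([config.seed, 2])
    rng = np.random.default_rng(ss)
    return _simulate_core(config, panel, calibration, rng)


def _simulate_core(config: SimConfig, panel: pd.DataFrame, calibration: dict,
                   rng: np.random.Generator):
    freqs = panel["freq"].to_numpy()
    w = panel["weight"].to_numpy()
    mu, sd = calibration["pop_mean"], calibration["pop_sd"]
    alpha, beta = calibration["alpha"], config.beta_m
    n = config.n_trios

    def affection_prob(z_m: np.ndarray, child_z: np.ndarray | None = None) -> np.ndarray:
        if config.effect_mode == "threshold" and beta != 0:
            x = (z_m > calibration["z_threshold"]).astype(float)
        else:
            x = z_m
        eta = alpha + beta * x
        if config.beta_child and child_z is not None:
            eta = eta + config.beta_child * child_z
        return expit(eta)

    mothers_list, fathers_list, children_list = [], [], []
    collected = 0
    attempts = 0
    batch = int(1.3 * n / config.baseline_prevalence) + 100
    while collected < n:
        attempts += 1
        if attempts > 60:
            raise ValidationError("ascertainment failed to reach the target trio count")
        gm = _draw_genotypes(rng, freqs, batch)
        z_m = (gm.astype(float) @ w - mu) / sd
        if config.beta_child:
            gf = _draw_genotypes(rng, freqs, batch)
            gc = _transmit(rng, gm) + _transmit(rng, gf)
            z_c = (gc.astype(float) @ w - mu) / sd
            p = affection_prob(z_m, z_c)
        else:
            gf = gc = None
            p = affection_prob(z_m)
        keep = rng.random(batch) < p
        idx = np.flatnonzero(keep)[: n - collected]
        mothers_list.append(gm[idx])
        if config.beta_child:
            fathers_list.append(gf[idx])
            children_list.append(gc[idx])
        collected += idx.size
        if collected < n:
            batch = int(1.3 * (n - collected) / config.baseline_prevalence) + 1000

    gm = np.vstack(mothers_list)
    if config.beta_child:
        gf = np.vstack(fathers_list)
        gc = np.vstack(children_list)
    else:
        # fathers and children are independent of affection status: draw post hoc
        gf = _draw_genotypes(rng, freqs, n)
        gc = _transmit(rng, gm) + _transmit(rng, gf)

    fam = [f"fam{i:05d}" for i in range(n)]
    m_ids = [f + "_mo" for f in fam]
    f_ids = [f + "_fa" for f in fam]
    c_ids = [f + "_ch" for f in fam]

    dosage = np.vstack([gm, gf, gc]).astype(float)
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan
    dm = DosageMatrix(
        sample_ids=m_ids + f_ids + c_ids,
        snp_ids=panel["snp_id"].tolist(),
        dosage=dosage,
        counted_allele=panel["effect_allele"].tolist(),
        other_allele=panel["other_allele"].tolist(),
        oriented=np.ones(len(panel), dtype=bool),
    )

    trios = _phenotype_table(config, rng, fam, m_ids, f_ids, c_ids)
    truth = {
        "beta_m": beta,
        "beta_child": config.beta_child,
        "effect_mode": config.effect_mode,
        "alpha": calibration["alpha"],
        "pop_mean": mu,
        "pop_sd": sd,
        "z_threshold": calibration.get("z_threshold"),
        "baseline_prevalence": config.baseline_prevalence,
        "seed": config.seed,
    }
    return trios, dm, truth


def _transmit(rng: np.random.Generator, parent: np.ndarray) -> np.ndarray:
    """One transmitted allele per SNP: Bernoulli(parent dosage / 2)."""
    return (rng.random(parent.shape) < parent / 2.0).astype(np.uint8)


def _yes_no(rng, n, p_yes, p_unknown):
    out = np.where(rng.random(n) < p_yes, "yes", "no")
    out[rng.random(n) < p_unknown] = "unknown"
    return out


def _phenotype_table(config, rng, fam, m_ids, f_ids, c_ids) -> pd.DataFrame:
    n = len(fam)
    n_chop = int(round(config.chop_fraction * n))
    cohort = np.array(["CHOP"] * n_chop + ["PCGC"] * (n - n_chop))
    subtypes = list(DEFAULT_SUBTYPE_PROBS)
    probs = np.array([DEFAULT_SUBTYPE_PROBS[s] for s in subtypes])
    probs = probs / probs.sum()
    return pd.DataFrame({
        "family_id": fam,
        "mother_id": m_ids,
        "father_id": f_ids,
        "child_id": c_ids,
        "cohort": cohort,
        "ctd_subtype": rng.choice(subtypes, size=n, p=probs),
        "child_sex": np.where(rng.random(n) < config.male_fraction, "male", "female"),
        "extracardiac": _yes_no(rng, n, 0.43, config.unknown_rate),
        "maternal_preeclampsia": _yes_no(rng, n, config.preeclampsia_rate, config.unknown_rate),
        "maternal_htn_medication": _yes_no(rng, n, config.htn_medication_rate, config.unknown_rate),
        "maternal_pregestational_diabetes": _yes_no(
            rng, n, config.pregestational_diabetes_rate, config.unknown_rate),
        "maternal_gestational_diabetes": _yes_no(
            rng, n, config.gestational_diabetes_rate, config.unknown_rate),
        "maternal_age_band": rng.choice(
            ["<20", "20-<25", "25-<30", "30-<35", "35-<40", ">40"], size=n,
            p=[0.02, 0.10, 0.25, 0.39, 0.20, 0.04]),
        "paternal_age_band": rng.choice(
            ["<20", "20-<25", "25-<30", "30-<35", "35-<40", ">40"], size=n,
            p=[0.01, 0.06, 0.23, 0.37, 0.25, 0.08]),
        "maternal_bmi_band": rng.choice(
            ["<18.5", "18.5-<25", "25-<30", ">30"], size=n, p=[0.05, 0.64, 0.19, 0.12]),
    })


# ---------------------------------------------------------------------------
# operating characteristics
# ---------------------------------------------------------------------------

def operating_characteristics(config: SimConfig, betas, modes=("linear",),
                              levels=(0.95,), n_replicates: int = 200,
                              alpha: float = 0.05,
                              score: str = "score_combined") -> pd.DataFrame:
    """Empirical size/power of the contrast over a (beta_m, mode) grid.

    For every grid cell, ``n_replicates`` cohorts are simulated, scored
    with the real GRS engine, and tested with the threshold (Fisher) and
    mean (t) contrasts at each quantile level.  Returns one row per
    (beta_m, mode, level) with rejection rates, the mean odds ratio, and
    the fraction of replicates where the mothers' mean exceeded the
    fathers'.  Fully deterministic under ``config.seed``.
    """
    betas = list(betas)
    modes = list(modes)
    levels = sorted(levels, reverse=True)
    if not betas or not modes or not levels:
        raise ValidationError("operating-characteristics grid is empty")
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")

    panel = generate_panel(config)
    weights = panel_to_weight_table(panel)
    rows = []
    for mode in modes:
        for bi, beta in enumerate(betas):
            cfg = config.model_copy(update={"beta_m": float(beta), "effect_mode": mode})
            calib = calibrate_intercept(panel, cfg)
            cell_ss = np.random.SeedSequence([config.seed, 3, modes.index(mode), bi])
            rep_rngs = [np.random.default_rng(s) for s in cell_ss.spawn(n_replicates)]
            stats_acc = {lv: {"rej_or": 0, "or_sum": 0.0} for lv in levels}
            rej_mean = 0
            mom_higher = 0
            for rng in rep_rngs:
                trios, dm, _ = _simulate_core(cfg, panel, calib, rng)
                grs = grs_engine.compute_grs(dm, weights, io_formats.parent_roles(trios))
                s = grs.set_index("sample_id")[score]
                m = s.loc[trios["mother_id"]].to_numpy()
                f = s.loc[trios["father_id"]].to_numpy()
                mc = mean_contrast(m, f)
                rej_mean += mc.p_value <= alpha
                mom_higher += mc.mean_mothers > mc.mean_fathers
                for lv in levels:
                    res = dichotomize_and_test(m, f, percentile_threshold(f, lv),
                                               quantile_level=lv)
                    stats_acc[lv]["rej_or"] += res.fisher_p <= alpha
                    stats_acc[lv]["or_sum"] += res.odds_ratio
            for lv in levels:
                rows.append({
                    "beta_m": beta,
                    "mode": mode,
                    "level": lv,
                    "n_replicates": n_replicates,
                    "reject_rate_or": stats_acc[lv]["rej_or"] / n_replicates,
                    "reject_rate_mean": rej_mean / n_replicates,
                    "mean_or": stats_acc[lv]["or_sum"] / n_replicates,
                    "prop_mother_mean_higher": mom_higher / n_replicates,
                })
    return pd.DataFrame(rows)
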