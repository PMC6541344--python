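import numpy as np
import pandas as pd
import pytest

import triogrs as tg


def make_weight_df(n_htn=2, n_obesity=2, n_t2d=2, weights=None, seed=0):
    """Small valid weight table spanning all three conditions."""
    rng = np.random.default_rng(seed)
    rows = []
    k = 0
    for cond, n in (("HTN", n_htn), ("OBESITY", n_obesity), ("T2D", n_t2d)):
        for _ in range(n):
            w = weights[k] if weights is not None else float(rng.uniform(0.1, 0.6))
            rows.append({
                "snp_id": f"rs{100 + k}", "chrom": "1", "pos": 1000 + k,
                "effect_allele": "A", "other_allele": "G",
                "weight": w, "condition": cond,
            })
            k += 1
    return pd.DataFrame(rows)


def naive_grs(dosage, weights_df, snp_ids):
    """Independent per-sample loop oracle for the weighted score sum."""
    col = {s: j for j, s in enumerate(snp_ids)}
    out = {}
    for cond in ("HTN", "OBESITY", "T2D"):
        sub = weights_df[weights_df["condition"] == cond]
        scores = []
        for i in range(dosage.shape[0]):
            s = 0.0
            for snp, w in zip(sub["snp_id"], sub["weight"]):
                s += w * dosage[i, col[snp]]
            scores.append(s)
        out[cond] = np.array(scores)
    return out


@pytest.fixture(scope="session")
def small_cohort():
    """A seeded 150-trio null cohort shared across tests."""
    cfg = tg.SimConfig(seed=11, n_trios=150)
    trios, dm, truth = tg.simulate_trios(cfg)
    weights = tg.panel_to_weight_table(tg.generate_panel(cfg))
    return cfg, trios, dm, weights, truth


@pytest.fixture()
def toy_dosage_matrix():
    weights = make_weight_df()
    dm = tg.DosageMatrix(
        sample_ids=["s1", "s2", "s3", "s4"],
        snp_ids=list(weights["snp_id"]),
        dosage=np.array([
            [2, 1, 0, 2, 1, 0],
            [0, 0, 0, 0, 0, 0],
            [1, 2, 1, 1, 2, 1],
            [2, 2, 2, 2, 2, 2],
        ], dtype=float),
        counted_allele=list(weights["effect_allele"]),
        other_allele=list(weights["other_allele"]),
        oriented=np.ones(6, dtype=bool),
    )
    roles = pd.DataFrame({
        "sample_id": ["s1", "s2", "s3", "s4"],
        "role": ["mother", "father", "mother", "father"],
        "cohort": ["CHOP", "CHOP", "PCGC", "PCGC"],
    })
    return dm, weights, roles
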