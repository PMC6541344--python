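"""Screen per-SNP maternal-effect p-values against Bonferroni thresholds.

The input is a table of association p-values from an upstream trio GWAS
meta-analysis (here: the published suggestive set).  Each condition uses
its own Bonferroni denominator — the number of SNPs in its score panel —
so hypertension (31 SNPs) and obesity (30) screen at ~0.002 and type 2
diabetes (46) at ~0.001.
"""

import pandas as pd

import triogrs as tg

assoc = pd.DataFrame(
    [
        ("rs13139571", "HTN", 0.01), ("rs11191548", "HTN", 0.01),
        ("rs633185", "HTN", 0.03), ("rs1801253", "HTN", 0.01),
        ("rs2815752", "OBESITY", 0.004), ("rs29941", "OBESITY", 0.04),
        ("rs4812829", "T2D", 0.03), ("rs6819243", "T2D", 0.03),
    ],
    columns=["snp_id", "condition", "p_value"],
)

for cond, n in (("HTN", 31), ("OBESITY", 30), ("T2D", 46)):
    thr = tg.bonferroni_threshold(cond, n)
    print(f"{cond}: 0.05/{n} = {thr:.6f}  (display {tg.display_threshold(thr)})")

out = tg.classify(assoc, {"HTN": 31, "OBESITY": 30, "T2D": 46})
print()
print(out[["condition", "snp_id", "p_value", "threshold_display", "classification"]]
      .to_string(index=False))
print("\nEvery SNP lands in the 'suggestive' band: below 0.05 but above its "
      "panel's Bonferroni threshold, i.e. no single SNP survives correction.")
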