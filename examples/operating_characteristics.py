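"""Measure the design's type-I error and power by simulation.

Runs the whole pipeline (simulate -> score -> contrast) over replicate
cohorts at several maternal effect sizes.  At beta_m = 0 the rejection
rate of the 95th-percentile odds-ratio test estimates the type-I error;
at beta_m > 0 it estimates power.  Small replicate counts here keep the
example quick — the test suite runs the full-size study.
"""

import triogrs as tg

cfg = tg.SimConfig(seed=2, n_trios=400)
oc = tg.operating_characteristics(cfg, betas=[0.0, 0.4, 0.8], levels=(0.95,),
                                  n_replicates=40, alpha=0.05)
print(oc.round(3).to_string(index=False))
print("\nreject_rate_or: fraction of replicates where the Fisher test on the "
      "95th-percentile dichotomization rejected at alpha = 0.05; it should "
      "sit near 0.05 at beta_m = 0 and rise with the maternal effect.")
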