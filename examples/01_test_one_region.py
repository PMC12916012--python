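"""Test one region for colocalization from simulated summary statistics.

Builds a synthetic cis-region LD block, draws GWAS Z-scores for a protein
(N = 30,000) and a disease (N = 300,000) with a true local genetic
correlation of 0.8, and runs the colocalization test at thresholds
r0 = 0 (any shared signal) and r0 = 0.5 (strong sharing).
"""

import numpy as np

from hdlc import hdlc_test, simulate_ld_ar1, simulate_sumstats_direct

rng = np.random.default_rng(42)
block = simulate_ld_ar1(M=300, rho=0.9)

h1_sq, h2_sq, true_rg = 0.05, 0.01, 0.8
N1, N2 = 30_000, 300_000
z1, z2 = simulate_sumstats_direct(
    block, h1_sq, h2_sq, true_rg * np.sqrt(h1_sq * h2_sq), N1, N2, rng
)

for r0 in (0.0, 0.5):
    res = hdlc_test(block, z1, z2, N1, N2, r0=r0)
    print(
        f"r0={r0:.1f}: rG_hat={res.rg_hat:+.3f} "
        f"[95% CI {res.rg_ci_low:+.3f}, {res.rg_ci_high:+.3f}]  "
        f"Lambda={res.lam:8.3f}  p={res.pvalue:.3g}"
    )

# rG_hat estimates the local genetic correlation (truth here: +0.80).
# A small p at r0=0.5 means |rG| credibly EXCEEDS 0.5, i.e. the region
# shows strong colocalization, not merely a nonzero genetic correlation.
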