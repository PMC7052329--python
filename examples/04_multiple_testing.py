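"""Compare multiple-testing corrections on one association scan.

Bonferroni controls the family-wise error, Benjamini-Hochberg the false
discovery rate, Storey q-values the positive FDR (scaled by an estimate of
the null proportion pi0).  The fixed -log10(p) > 3.5 rule applies to raw
p-values.
"""

import numpy as np

from gwasbench import (
    adjust_bonferroni, adjust_fdr_bh, adjust_pfdr_storey, compute_pcs,
    fixed_threshold_select, run_glm, simulate_genotypes, simulate_trait,
)

geno = simulate_genotypes(300, 3000, seed=5)
phen, arch = simulate_trait(geno, 20, 0.6, seed=6)
res = run_glm(geno, phen, compute_pcs(geno, 3))
p = res.p[np.isfinite(res.p)]

fixed = fixed_threshold_select(p, 3.5)
bon = adjust_bonferroni(p, alpha=0.05)
bh = adjust_fdr_bh(p, alpha=0.05)
stq = adjust_pfdr_storey(p, alpha=0.05)

print(f"markers tested: {p.size}; simulated QTLs: {arch.n_qtl}")
print(f"fixed -log10(p) > 3.5 : {fixed.size} significant")
print(f"Bonferroni  (FWER)    : {bon.n_significant} significant")
print(f"BH FDR                : {bh.n_significant} significant")
print(f"Storey PFDR (pi0={stq.pi0:.2f}): {stq.n_significant} significant")
# The counts are nested by construction: every Bonferroni hit is a BH hit,
# and every BH hit is a Storey hit at the same cutoff.
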