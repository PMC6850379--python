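"""Classify genes as female-/male-biased/unbiased from RPKM ratios.

Simulates a negative-binomial abdomen expression matrix (5 + 5 samples)
with a 4-fold expression shift on truly biased genes, classifies every
gene by the RPKM_f/RPKM_m > 1.5 / < 0.66 rule, and reports the confusion
against the simulated truth.
"""

import pandas as pd

from fastz import SimTruth, simulate_counts, simulate_expression
from fastz.expression import classify_sex_bias, mean_rpkm_by_sex

truth = SimTruth(n_genes=1000, seed=19)
genes = simulate_counts(truth)
counts, samples = simulate_expression(genes, truth, bias_fold=4.0)

lengths = pd.Series({g.gene_id: g.L_s + g.L_n for g in genes})
levels = mean_rpkm_by_sex(counts, lengths, samples)

confusion = pd.crosstab(
    pd.Series({g.gene_id: g.true_bias for g in genes}, name="truth"),
    pd.Series(
        {
            gid: classify_sex_bias(row.rpkm_f, row.rpkm_m)[0]
            for gid, row in levels.iterrows()
        },
        name="called",
    ),
)
print(confusion)
accuracy = sum(confusion.loc[k, k] for k in confusion.index) / len(genes)
print(f"\nlabel recovery: {accuracy:.1%}")
# at a 4-fold true shift the 1.5-fold rule recovers >90% of labels;
# misses are low-expression genes where sampling noise dominates.
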