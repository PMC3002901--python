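"""Comparison selectors: greedy Wilks-Lambda LOOCV and random forest.

The greedy selector runs stepwise forward discriminant analysis inside a
leave-one-out wrapper (niveau 0.001) and reports how often each gene was
picked across the 30 training sets plus the LOOCV error; the random forest
(500 trees, mtry = all genes, node size 1) ranks genes by mean decrease in
Gini impurity and reports the out-of-bag error.
"""

from crhnet import baselines
from crhnet.synthetic import SyntheticConfig, generate_ratio_matrix

cfg = SyntheticConfig(n_spots=400, n_de_genes=10, seed=7)
pool, truth = generate_ratio_matrix(cfg)
planted = set(truth.de_genes)

greedy = baselines.greedy_loocv(pool, alpha=0.001)
print(f"greedy Wilks-Lambda LOOCV error: {100 * greedy.error:.1f}%")
print(f"per-fold selection sizes: min "
      f"{min(greedy.extras['fold_sizes'])}, max "
      f"{max(greedy.extras['fold_sizes'])}")
print("genes picked in every training set:")
print(greedy.ranking[greedy.ranking["frequency"] == 30].to_string())

rf = baselines.rf_rank(pool, baselines.RfParams(n_trees=500, seed=8))
print(f"\nrandom forest OOB error: {100 * rf.error:.1f}%")
print(f"planted genes in Gini top-50: "
      f"{len(set(rf.top(50)) & planted)}/10")
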