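"""Cross-validated benchmark: supervised scoring vs unsupervised baselines.

Five independent 20-80 train/target splits; per receptor and method the
Spearman concordance with held-out CLR-normalized ADT counts; the summary is
each method's share of receptors won (highest average correlation).
"""

import pandas as pd

from streak import (RunConfig, SyntheticSpec, best_method_proportions, concordance,
                    generate_joint, make_splits, rna_baseline, streak_estimate,
                    streak_train)

spec = SyntheticSpec(n_cells=2000, n_genes=600, n_receptors=5,
                     rna_dropout=0.6, seed=17)
rna, adt, truth = generate_joint(spec)

rows = []
for plan in make_splits(rna.cell_ids, n_repeats=3, train_frac=0.5, seed=17):
    cfg = RunConfig(seed=17)
    sets = streak_train(rna.subset_cells(plan.train_ids),
                        adt.subset_cells(plan.train_ids), cfg)
    target = rna.subset_cells(plan.target_ids)
    adt_target = adt.subset_cells(plan.target_ids)
    est = streak_estimate(target, sets, cfg)
    base = rna_baseline(target, truth.receptor_to_gene)
    table = pd.concat([concordance(est, adt_target, "streak"),
                       concordance(base, adt_target, "rna")], axis=1)
    table["repeat"] = plan.repeat
    rows.append(table)

long = pd.concat(rows).set_index("repeat", append=True)
long.index.names = ["receptor", "repeat"]
print("mean Spearman concordance with held-out ADT, per receptor:")
print(long.groupby(level="receptor").mean().round(3))
shares = best_method_proportions(long)
print("\nshare of receptors won (highest average correlation):")
print(shares.round(1).to_string())
print("\nA win share above 50% for 'streak' mirrors the benchmark finding that")
print("trained weighted gene set scoring beats the normalized-transcript proxy.")
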