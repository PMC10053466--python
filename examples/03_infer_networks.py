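"""Infer the three network types: mm, TT and Tm.

Each network is a GENIE3-style random-forest ranking: per target gene, TF
profiles predict the target profile and every TF's share of the forest's
variance reduction becomes the edge weight. The pairing of omics layers
decides the type: mm (mRNA TF -> mRNA target), TT (translatome ->
translatome), Tm (TF translatome -> target mRNA).
"""

import mogrn

truth = mogrn.generate_truth_network(n_tf=10, n_target=60, mean_out_degree=4.0, seed=3)
atlas = mogrn.simulate_atlas(truth, n_tissues=12, te_sigma=1.0, seed=3)
rna, ribo = atlas.matrices["rna_mean"], atlas.matrices["ribo_mean"]

regulators = mogrn.select_regulators(list(truth.regulators), rna, ribo)
targets = [g for g in mogrn.filter_grn_genes(rna) if g not in set(regulators)]

pairings = {"mm": (rna, rna), "TT": (ribo, ribo), "Tm": (ribo, rna)}
for name, (reg_matrix, tgt_matrix) in pairings.items():
    grn = mogrn.infer_grn(reg_matrix, tgt_matrix, regulators, targets,
                          n_trees=100, seed=11)
    top = grn.edges.head(3)
    hits = len(grn.pairs & truth.pairs & set(zip(top["regulator"], top["target"])))
    print(f"{name}: {len(grn)} ranked edges; top 3:")
    for _, row in top.iterrows():
        true_edge = (row["regulator"], row["target"]) in truth.pairs
        print(f"   {row['regulator']} -> {row['target']} "
              f"weight={row['weight']:.3f} {'(true edge)' if true_edge else ''}")

# Weights are per-target normalized importances (each target's incoming
# weights sum to 1), so a weight of e.g. 0.3 means that TF claims 30% of
# the forest's explanatory power for that target.
top1000 = mogrn.truncate_edges(grn, "top_k", 50)
print(f"after truncation to top 50: {len(top1000)} edges, "
      f"min kept weight {top1000.edges['weight'].min():.4f}")
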