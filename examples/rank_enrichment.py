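"""Mann-Whitney delta-rank enrichment and a cross-taxon comparison.

Simulates signed gene scores (-log p times the direction of regulation)
with one functional class shifted upward (enriched among genes higher in
symbiotic samples), tests every class with the rank-based Mann-Whitney
procedure, and then compares delta ranks between two simulated "taxa"
sharing the planted signal.
"""

from holosym import enrichment, simulate

planted = (("GO:0000003", 1.5),)
ann, scores, truth = simulate.gen_class_annotations(
    n_genes=5_000, n_classes=40, planted=planted, seed=1)
class_map = {c: frozenset(m) for c, m in truth.planted["class_members"].items()}

table = enrichment.mwu_enrichment(scores, class_map, min_size=5, max_frac=0.1)
print("top classes by MWU p:")
print(table.sort_values("p_mwu").head(3).round(4))
print(f"planted class delta rank: {table.loc['GO:0000003', 'delta_rank']:.0f} "
      f"(positive = enriched among up-regulated genes), "
      f"FDR = {table.loc['GO:0000003', 'fdr']:.2e}")

# a second dataset with the same planted class plays the role of another taxon
ann2, scores2, truth2 = simulate.gen_class_annotations(
    n_genes=5_000, n_classes=40, planted=planted, seed=2)
cm2 = {c: frozenset(m) for c, m in truth2.planted["class_members"].items()}
table2 = enrichment.mwu_enrichment(scores2, cm2, min_size=5, max_frac=0.1)

joined, corr = enrichment.cross_taxa_compare(
    {"taxon_a": table, "taxon_b": table2}, alpha=0.05)
shared_sig = joined.index[joined["significant_in_all"]].tolist()
print(f"classes significant (p < 0.05) in both datasets: {shared_sig}")
print(corr.round(3).to_string(index=False))
# The planted class is recovered in both datasets with a positive delta rank.
# It also dominates the Pearson delta-rank correlation (the backgrounds are
# independent), which is why the rank-based Spearman value stays near zero.
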