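"""Competitive gene-set testing with the restandardized maxmean statistic.

Generates a three-group expression matrix with gene sets planted on specific
group patterns, preprocesses it (log2, quantile normalization, total-reads
correction), and runs the rotation test for the old-vs-young contrast.
"""

import rejuvenomics as rj

cfg = rj.SynthExprConfig(n_genes=1500, n_sets=20, set_size=15, effect_log2=1.0, seed=7)
raw, gene_sets, sheet, truth = rj.generate_expression(cfg)
expr = rj.preprocess_expression(raw, sheet["total_reads"], sheet["group"])

res = rj.rotation_test(
    expr, gene_sets, groups=sheet["group"], contrast=("old", "young"),
    B=1999, seed=1, n_random=1000,
)
merged = res.join(truth[["pattern_id"]])
print(merged[["n_genes_used", "S_star", "direction", "p_two_sided", "pattern_id"]]
      .sort_values("p_two_sided").round(3).head(12).to_string())
print("\nSets whose planted pattern separates old from young get small p;")
print("all-equal (null) sets do not - the restandardization keeps the test")
print("competitive, so only sets outrunning the catalogue are called.")

# GSEA-style running-score representation for the top set
scores = rj.moderated_gene_stats(expr, sheet["group"], ("old", "young")).scores
top = res["p_two_sided"].idxmin()
curve, extremum = rj.ks_running_score(scores, gene_sets[top])
print(f"\nrunning-score extremum for {top}: {extremum:+.3f}")
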