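"""Screen methylation- and miRNA-correlated genes on a synthetic cohort.

Generates a 200-sample cohort with 300 planted CpG-gene and 300 planted
miRNA-gene pairs at r = -0.5, then screens all candidate pairs with the
Fisher-Z criterion (z*sqrt(n-3) < -1.96).
"""

from epireg import ScreenConfig, collect_regulated_genes, overlap_genes, \
    pair_cpg_genes, pair_mirna_genes, region_frequency, score_pairs
from epireg.simulate import SimConfig, simulate_cohort

mrna, mirna, meth, annot, lists, survival, truth = simulate_cohort(
    SimConfig(seed=1))

cfg = ScreenConfig()
scored_cpg = score_pairs(pair_cpg_genes(meth, mrna, annot, cfg),
                         meth, mrna, cfg)
scored_mir = score_pairs(pair_mirna_genes(lists, mirna, mrna),
                         mirna, mrna, cfg)
met_genes, met_best = collect_regulated_genes(scored_cpg)
mir_genes, _ = collect_regulated_genes(scored_mir)
both, counts = overlap_genes(met_genes, mir_genes)

print(f"candidate CpG-gene pairs:   {len(scored_cpg)}")
print(f"significant CpG pairs:      {scored_cpg['significant'].sum()}")
print(f"METcor genes:               {len(met_genes)}")
print(f"MIRcor genes:               {len(mir_genes)}")
print(f"overlap (both mechanisms):  {counts['both']}")

true_met = {g for _p, g in truth.true_met_pairs}
sens = len(met_genes & true_met) / len(true_met)
print(f"sensitivity vs planted METcor genes: {sens:.3f}")

freq = region_frequency(scored_cpg, annot)
island = freq.query("dimension=='island_relation' and level=='Island'")
print(f"Island enrichment (significant vs all probes): "
      f"{island['enrichment'].iloc[0]:.2f}")
# A sensitivity near 1 means nearly every planted negative coupling is
# recovered; Island enrichment > 1 mirrors the promoter-island preference
# planted in the annotation.
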