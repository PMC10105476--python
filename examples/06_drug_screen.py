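"""Subtype-specific drug screening from an AUC dose-response panel.

The panel plants 3 drugs per subtype with AUC lower by 0.2 (log2) in the
sensitive subtype, plus 10% missingness.  Drugs above 20% missingness
are dropped, the rest k-NN imputed, and the log2 mean-ratio rule
(every other subtype's mean AUC at least 2^0.05 times higher) calls the
subtype-specific drugs.
"""

from epireg import compare_named_drugs, filter_and_impute, \
    subtype_specific_drugs
from epireg.simulate import SimConfig, simulate_cohort, simulate_drug_panel

cfg = SimConfig(seed=1)
*_omics, truth = simulate_cohort(cfg)
auc, cellline_expr, true_drugs = simulate_drug_panel(cfg, truth.labels)

complete = filter_and_impute(auc)
print(f"drugs retained after missingness filter: {complete.shape[1]} "
      f"of {auc.shape[1]}")

res = subtype_specific_drugs(complete, truth.labels)
for s, drugs in sorted(res.assignments.items()):
    planted = sorted(true_drugs[s])
    print(f"subtype {s}: called {sorted(drugs)} (planted {planted})")

named = sorted(true_drugs[1])[:1] + sorted(true_drugs[3])[:1]
print(compare_named_drugs(complete, truth.labels, named)
      .round(4).to_string(index=False))
# Called = planted for every subtype (lower AUC = more sensitive); the
# named-drug table shows the sensitive subtype has the lowest mean AUC
# with a near-zero Kruskal-Wallis p.
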