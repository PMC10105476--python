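"""Per-sample aberrance frequencies of the two regulated gene sets and
their co-regulation.

A gene is aberrantly high (low) in a sample when its expression exceeds
(falls below) the gene's upper (lower) quartile across samples; the
correlation of the per-sample total frequencies between the METcor and
MIRcor sets quantifies epigenetic co-regulation.
"""

from epireg import aberrance_profile, coregulation_correlation
from epireg.simulate import SimConfig, simulate_cohort

mrna, *_rest, truth = simulate_cohort(SimConfig(seed=1))
met = {g for _p, g in truth.true_met_pairs}
mir = {g for _m, g in truth.true_mir_pairs}

p_met = aberrance_profile(mrna, met, "METcor")
p_mir = aberrance_profile(mrna, mir, "MIRcor")
r, p, corr_matrix, _pm = coregulation_correlation(p_met, p_mir)

print(f"mean METcor aberrance per sample: "
      f"{p_met['freq_total'].mean():.3f}")
print(f"co-regulation: r = {r:.3f}, p = {p:.2e}")
print("pairwise frequency correlations:")
print(corr_matrix.round(3).to_string())
# A clearly positive r says samples with many aberrant methylation-
# regulated genes also have many aberrant miRNA-regulated genes - the
# premise for clustering the two blocks jointly.
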