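"""Joint latent-factor clustering of the METcor and MIRcor expression
blocks with BIC model selection.

Four subtypes are planted (mean shift 1.5 SD on 150 genes each); the EM
factor model with k-1 latent factors is fitted for k = 2..6 and the BIC
minimum picks k.
"""

from sklearn.metrics import adjusted_rand_score

from epireg import ClusterConfig, select_k
from epireg.simulate import SimConfig, simulate_cohort

mrna, *_rest, truth = simulate_cohort(SimConfig(seed=1))
met = sorted({g for _p, g in truth.true_met_pairs})
mir = sorted({g for _m, g in truth.true_mir_pairs})

model = select_k([("METcor", mrna.loc[met]), ("MIRcor", mrna.loc[mir])],
                 ClusterConfig(seed=1))

print("BIC by candidate k:")
for k in sorted(model.bic):
    marker = "  <- chosen" if k == model.k else ""
    print(f"  k={k}: BIC={model.bic[k]:.0f} "
          f"deviance_ratio={model.deviance_ratio[k]:.3f}{marker}")
print(f"cluster sizes: {model.labels.value_counts().sort_index().to_dict()}")
ari = adjusted_rand_score(truth.labels, model.labels)
print(f"adjusted Rand index vs planted subtypes: {ari:.3f}")
# BIC should bottom out at k=4 and ARI ~ 1: the latent space separates
# the planted subtypes essentially perfectly at this effect size.
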