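"""Configurational entropy of coupled torsions by k-NN estimation and MIST.

Generates a 6-angle ensemble with tree-structured von Mises couplings
(exact joint entropy known in closed form), then compares three routes:
the sum of per-angle marginals (ignores all correlations), the maximum-
information-spanning-tree combination, and the declared truth.
"""

import endstate as es

spec = es.EnsembleSpec(
    n_frames=5000, seed=0,
    torsion_spec=[{"kappa": 2.0, "mean_deg": -60.0}]
    + [{"kappa": 0.0, "mean_deg": 0.0}] * 5,
    dependency_tree=[(i, i + 1, 1.0) for i in range(5)],
)
ts, manifest = es.gen_torsion_ensemble(spec)

marginal_sum = es.residue_entropy(ts, k=10)
result = es.mist(ts, k=10)
truth = manifest["true_joint_entropy_nats"]

print(f"marginal sum : {marginal_sum.value:7.4f} nats ({marginal_sum.eu:6.3f} e.u.)")
print(f"MIST combined: {result.combined:7.4f} nats")
print(f"declared truth: {truth:6.4f} nats")
print(f"MIST error   : {result.combined - truth:+7.4f} nats")
print()
print("The marginal sum overestimates the joint entropy because it ignores")
print("the inter-angle mutual information; MIST subtracts the largest")
print("spanning tree of pairwise MIs and recovers the tree-structured truth.")
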