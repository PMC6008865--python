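"""Rotational-translational entropy of a bound subunit's pose ensemble.

Generates a rigid two-body complex whose mobile body wobbles with a 5
degree rotational and 0.5 A translational spread (closed-form 6-D
Gaussian entropy), extracts per-frame poses, and estimates the pose
entropy relative to the 1 M standard state with free rotation.
"""

import endstate as es
from endstate.entropy_rt import balanced_ell

spec = es.EnsembleSpec(
    n_frames=5000, seed=11,
    pose_spec={"rotation": 5.0, "translation": {"sd": 0.5}},
)
ens, manifest = es.gen_pose_ensemble(spec)

pe = es.relative_pose(ens, es.ChainSelection(["A"]), es.ChainSelection(["B"]))
pe.ell = balanced_ell(pe)
res = es.rt_entropy(pe, k=10)

print(f"S_bound  = {res['S_bound_nats']:8.4f} nats "
      f"(closed form {manifest['true_pose_entropy_nats']:8.4f})")
print(f"S_ref    = {res['S_ref_nats']:8.4f} nats  (ln V0 + ln 8 pi^2, 1 M standard state)")
print(f"dS_rt    = {res['dS_rt_eu']:8.2f} e.u.")
print(f"-T dS_rt = {res['minus_TdS_rt_kcal']:8.2f} kcal/mol at 300 K")
print()
print("The bound pose is far more ordered than a freely rotating partner at")
print("1 M, so association pays a large positive -T*dS_rt penalty.")
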