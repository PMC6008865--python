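"""GB/SA enthalpy of a toy dimer-of-dimers association.

Checks the Born-ion oracle, then evaluates the association enthalpy of a
jittered synthetic tetramer by detaching the two dimers from the very
same frames, with the per-term decomposition (covalent terms cancel
exactly in detaching mode).
"""

import math

import endstate as es
from endstate.constants import COULOMB_KCAL
from endstate.model_io import StructureModel

# --- Born ion: polar solvation of a single +1e charge of radius 2 A
ion = StructureModel(["X"], ["X"], ["ION"], [1], ["A"], [[0, 0, 0]])
topo_ion = es.ToyTopology([1.0], [0.0], [0.0], [2.0])
surface = es.sample_surface(ion, topo_ion, 960, probe_radius=0.0)
born = es.gb_radii(ion, surface, topo=topo_ion)
gb = es.gb_polar(ion, topo_ion, born)
analytic = -(COULOMB_KCAL / 2) * (1 - 1 / 78.5) / 2.0
print(f"Born ion: computed {gb:8.3f} vs analytic {analytic:8.3f} kcal/mol")

# --- association enthalpy of the toy tetramer (chains A-D = monomers I-IV)
ens, topo, _ = es.gen_multimer_ensemble(es.EnsembleSpec(n_frames=10, seed=2))
dimers = [es.ChainSelection(["A", "B"]), es.ChainSelection(["C", "D"])]
res = es.association_enthalpy(ens, topo, dimers, n_surface_points=240)
print(f"dH(2D->T) = {res['dH']:+.3f} +/- {res['sem']:.3f} kcal/mol")
for term, val in res["decomposition"].items():
    print(f"   {term:10s} {val:+8.4f}")
print()
print("The decomposition shows which physics drives association; the")
print("covalent term is exactly zero because both dimers keep their")
print("internal geometry when detached from the same frames.")
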