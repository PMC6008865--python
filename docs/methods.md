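# Methods

This note records the models implemented in `endstate`, the parameter
choices that matter, what the synthetic generators do and do not emulate,
and the numerical decisions a maintainer would want to know.

## Free-energy decomposition

The standard free energy of a solvated species is treated in the end-point
picture: ΔG° = ⟨U + ΔW⟩ − TΔS^conf − TΔS^rt, evaluated independently for
each species (tetramer, dimers, monomers) from an ensemble of solute
conformations. The "enthalpy" ⟨U + ΔW⟩ deliberately absorbs solvent
entropy through the implicit-solvation term ΔW; the explicitly counted
entropies are the solute's internal (torsional) entropy and, for
association steps, the rigid-body pose entropy one partner loses. Frames
are treated as independent draws; the standard error of the mean is
sd/√n with no autocorrelation correction (the synthetic ensembles are
i.i.d. by construction, and MD users should subsample to the correlation
time first).

Association differences support two modes. In *detaching* mode the parts
are chain selections cut from the very same complex frames, so intra-part
geometry is identical on both sides and the covalent term cancels exactly
— the decomposition identity ΔH = ΔLJ + ΔCoulomb + Δpolar + Δapolar holds
to machine precision. In *single-species* mode each part brings its own
independently generated ensemble.

## GB/SA solvation

* Surfaces are point-sampled Shrake–Rupley style on a Fibonacci sphere
  lattice (240 points/atom default; 960 in oracle tests). SASA uses the
  1.4 Å probe; the Born-radius integral uses the probe-0 (van der Waals)
  surface so that an isolated ion's Born radius equals its physical
  radius. Boundary ties between coincident spheres are broken in favour
  of the earlier atom so duplicated atoms never double-count area.
* The sphere lattice is oriented in a rotation-equivariant molecular frame
  (covariance principal axes, signs fixed by third moments), which makes
  every surface-derived energy term invariant under rigid motion to
  machine precision for generic molecules. Highly symmetric degenerate
  arrangements fall back to discretization-level invariance.
* Born radii use the Coulomb-field approximation
  1/Rᵢ = (1/4π)∮ (r·n)/|r|⁴ dA, clamped from below at the intrinsic
  radius; polar energies use the Still pairwise expression with
  f_ij = √(r² + RᵢRⱼ·exp(−r²/4RᵢRⱼ)) and f_ii = Rᵢ.
* Constants: ε_in = 1, ε_out = 78.5, probe 1.4 Å, Coulomb constant
  332.0636 kcal·Å·mol⁻¹·e⁻², γ = 5 cal·Å⁻²·mol⁻¹, T = 300 K,
  R = 1.987 cal·mol⁻¹·K⁻¹. All live in a single `Constants` object;
  ε, probe and Coulomb-constant values are the field's de facto standards
  and are flagged as assumptions where the underlying GB programs leave
  them unpublished.
* The pairwise GB energy of two distant ions approaches the sum of their
  isolated Born energies only as 1/r (the screened Coulomb cross term
  −k(1/ε_in − 1/ε_out)q₁q₂/r); the additivity test therefore checks the
  analytic cross term at 50 Å and near-additivity at 10⁴ Å.

## Configurational entropy

The Kozachenko–Leonenko estimator on angular data:
S = ψ(n) − ψ(k) + ln V_d + (d/n)Σ ln r_{i,k}, with r the wrap-around
distance (per-angle minimum image, Euclidean norm across angles; periodic
KD-tree). Defaults k = 10 and n = 5000 frames follow the analysis
settings of the study reproduced here. Duplicate samples either raise or
receive a deterministic 10⁻⁸ rad jitter under an explicit flag. Standard
errors, when requested, come from a 10-block bootstrap over frames — the
error bars on published −TΔS values state no method, so the bootstrap is
this package's own choice.

Residue-level combination keeps full correlation within a residue and none
between residues (a strict overestimate of the joint entropy); MIST
subtracts the maximum spanning tree of pairwise mutual informations,
I = S(x) + S(y) − S(x, y), clipping negative MIs to zero only in the edge
weights (raw values stay in the report). On tree-structured truth MIST is
exact up to estimator error.

Estimator characterization (measured by this package's own tests): the
1-D/2-D estimates are unbiased within ±0.01 nats on torus-supported
fixtures at n = 5000; correlated ("ridge"-like) 2-D joints carry a
−0.01 … −0.02 nat anisotropy bias each, so a 6-angle chain combined
through MIST is accurate to ≈ 0.05 nats at n = 5000. The validation
chain uses couplings with per-edge MI ≈ 0.2 nats, representative of
adjacent-torsion correlations in folded proteins; much stronger couplings
mainly measure the k-NN ridge bias rather than the MIST property.

## Rotational-translational entropy

Poses are (unit quaternion on the w ≥ 0 hemisphere, translation). The
per-frame pose is extracted by superposing each frame on frame 0 through
the reference selection (CA atoms by default; the superposition-atom
choice is open in the source study and CA is this package's default),
then rigid-fitting the mobile selection against its frame-0 coordinates.
The transform is decomposed about the mobile selection's frame-0 centroid
by default; passing a shared `origin` makes reference/mobile swaps exact
transform inverses.

Entropy uses the 6-D mixed metric d² = |Δt|² + ℓ²θ² with θ the quaternion
geodesic angle. The rotational measure is Haar normalized to 8π²; to
leading order a geodesic ball's Haar volume equals the Euclidean 3-ball
volume, so the Kozachenko–Leonenko formula applies with a −3 ln ℓ term
removing the mixing-length scale. The unbound reference is
ln V° + ln 8π² with V° = 1660.6 Å³ (1 M standard state, free rotation).

ℓ defaults to 1 Å/rad and is reported in output; for narrow pose
distributions the helper `balanced_ell` equalizes the translational and
rotational spreads, the standard remedy for the anisotropy bias of k-NN
estimators in mixed metrics. Characterization: on an isotropic 6-D
Gaussian at n = 5000, k = 10 the estimator carries a −0.08 ± 0.03 nat
intrinsic bias (nearly n-independent over reachable n); differences
between nested spreads (e.g. the 6·ln 2 drop when all σ halve) cancel
this bias and are accurate to ≈ 0.01 nats. Sharp-edged uniform supports
(the standard-state box) add a positive boundary bias of ≈ 0.2–0.3 nats
at n ≈ 10⁴, which is why the reference-state cancellation check carries a
wider band than the Gaussian check.

## Structural analytics

* Hydrogen bonds: donor–acceptor ≤ 3.5 Å and H–donor–acceptor angle
  ≤ 30°, both inclusive; hydrogens are assigned to the nearest N/O within
  1.25 Å; structures without hydrogens degrade to a distance-only
  criterion with a logged warning. Occupancies are exact rationals
  (frames satisfying / total), reported strictly above 10 % and flagged
  "major" at ≥ 80 %.
* Ramachandran regions use open intervals, wrap-aware:
  α (−89 < φ < −39, −66 < ψ < −16), β (−180 < φ < −45, 45 < ψ < 225,
  i.e. ψ wraps past +180), left-handed (−40 < φ < 70, 30 < ψ < 140),
  checked in that order so every point maps to exactly one region.
  Residue series report circular means and circular standard deviations.
* Interface contacts: heavy-atom pairs strictly closer than 4.5 Å; native
  contacts are the residue pairs in contact at frame 0; salt bridges are
  basic-N to acidic-O pairs within 4.0 Å inclusive (Arg NH1/NH2/NE,
  Lys NZ vs Asp OD1/OD2, Glu OE1/OE2). These cutoffs are standard values;
  the source study names none.
* Dissociation is operationalized as the first frame where the native
  fraction stays below 0.1 for 10 consecutive frames; a trajectory that
  *ends* below threshold with fewer than 10 frames remaining still
  reports the event (a trajectory that ends dissociated is dissociated).
  If frame 0 has no contacts the native fraction is 0 throughout and
  frame 0 is reported — a stated policy case, not an error.

## Synthetic data: what it does and does not show

The generators emulate the *statistical* structure end-point estimators
consume — marginal shapes, tree correlations, pose spreads, planted
occupancies, scripted contact loss — with analytically known truth, and
they are pure functions of (spec, seed). They do not emulate physics: no
forces, no integrator, no autocorrelation, no solvent, and i.i.d. frames.
Passing tests therefore demonstrate estimator and bookkeeping correctness
under the stated sampling conditions, not force-field accuracy on real
trajectories. Wrapped von Mises noise was chosen over wrapped Gaussians
because its entropy is closed-form; the dissociated-state separation
(8 Å) exceeds both the contact (4.5 Å) and H-bond (3.5 Å) cutoffs with
margin; toy multimer chains A–D stand for monomers I–IV (single-character
ids so ensembles survive the PDB chain column).

## Problem sizes

The default analysis conditions are 5000 frames and k = 10. Test-suite
and acceptance-script runs use: n = 50000 for 1-D entropy recovery,
n = 5000 for the MIST chain and the Gaussian pose fixtures, n = 6000 for
the uniform standard-state check, 10-frame ensembles of the ≤ 200-atom toy
tetramer for GB/SA averages, and 100-frame trajectories for occupancy and
dissociation fixtures.

## Known limitations

No mmCIF or binary trajectory formats; no force-field typing, PME or
cutoffs; no kernel/histogram/quasi-harmonic entropy estimators and no
third-order MIE; no 9-D external-entropy variants; no DSSP 8-class
assignment (Ramachandran classes serve as the secondary-structure
summary); FoldX/BMF-style statistical potentials enter only as ΔΔG ledger
*inputs*. The e.u.-per-event versus per-step kcal/mol conventions of
published association tables are kept as two separate representations and
never silently reconciled.
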