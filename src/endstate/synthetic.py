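"""Synthetic ensembles with known statistical structure.

These generators stand in for molecular-dynamics trajectories: every
output comes with a manifest declaring its ground truth (closed-form
entropies, planted hydrogen-bond occupancies, the scripted dissociation
frame, hand-computed reference energies), so estimator tests never have to
re-derive truth.

Statistical choices are made so truth stays analytic:

* torsion ensembles use von Mises marginals with tree-structured couplings
  (child = parent + von Mises noise, wrapped); the joint entropy is the sum
  of the root marginal entropy and the coupling-noise entropies;
* rigid-body pose ensembles draw rotations either uniformly from SO(3)
  (Haar entropy ln 8π²) or as small-angle isotropic Gaussians in
  rotation-vector space (Gaussian differential entropy), and translations
  as isotropic Gaussians or uniform in a box;
* frames are i.i.d. draws — exactly what end-point estimators assume.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.special import i0e, i1e

from .energy import ToyTopology
from .model_io import Ensemble, StructureModel, TorsionSet
from .constants import SO3_VOLUME, V_STANDARD_A3

__all__ = [
    "EnsembleSpec",
    "DegenerateSpecError",
    "von_mises_entropy",
    "gaussian_entropy",
    "gen_torsion_ensemble",
    "gen_pose_ensemble",
    "gen_hbond_trajectory",
    "gen_dissociation_trajectory",
    "gen_toy_multimer",
    "gen_multimer_ensemble",
    "save_manifest",
]

TWO_PI = 2.0 * math.pi


class DegenerateSpecError(ValueError):
    """A spec with a delta-like (zero-spread) distribution."""


def von_mises_entropy(kappa: float) -> float:
    """Differential entropy (nats) of the von Mises distribution.

    H = ln(2π·I0(κ)) − κ·I1(κ)/I0(κ); κ = 0 gives the uniform circle,
    ln 2π.  Evaluated with exponentially scaled Bessel functions for
    numerical stability at large κ.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if kappa == 0:
        return math.log(TWO_PI)
    return (math.log(TWO_PI) + math.log(i0e(kappa)) + kappa
            - kappa * i1e(kappa) / i0e(kappa))


def gaussian_entropy(sigmas) -> float:
    """Differential entropy (nats) of an axis-aligned Gaussian, Π N(0, σ_i²)."""
    sigmas = np.atleast_1d(np.asarray(sigmas, float))
    if np.any(sigmas <= 0):
        raise DegenerateSpecError("zero-width Gaussian has entropy -inf")
    return float(0.5 * len(sigmas) * math.log(2.0 * math.pi * math.e)
                 + np.sum(np.log(sigmas)))


@dataclass
class EnsembleSpec:
    """Parameters of the synthetic generators.

    Only the sections a given generator needs have to be present.
    ``dependency_tree`` entries are (parent index, child index, coupling κ);
    ``pose_spec`` keys: ``rotation`` ("uniform" or an sd in degrees),
    ``translation`` ({"sd": Å} | {"uniform_box": side Å} | None for fixed);
    ``hbond_spec`` entries: {"target_occupancy": fraction}.
    """

    n_frames: int = 5000
    seed: int = 0
    torsion_spec: list = field(default_factory=list)     # [{"kappa": κ, "mean_deg": μ}]
    dependency_tree: list = field(default_factory=list)  # [(parent, child, κ_coupling)]
    torsion_residues: list | None = None                 # residue id per torsion
    pose_spec: dict | None = None
    hbond_spec: list = field(default_factory=list)
    dissociation_frame: int | None = None
    hinge_retain: bool = False

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for t in self.torsion_spec:
            if t["kappa"] < 0:
                raise ValueError("kappa must be >= 0")
        for _, _, kc in self.dependency_tree:
            if kc < 0:
                raise ValueError("coupling kappa must be >= 0")
        for hb in self.hbond_spec:
            if not 0.0 <= hb["target_occupancy"] <= 1.0:
                raise ValueError("target_occupancy must be in [0, 1]")
        if self.dissociation_frame is not None and self.dissociation_frame >= self.n_frames:
            raise ValueError("dissociation_frame must be < n_frames")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def save_manifest(manifest: dict, path) -> None:
    """Write a generator manifest as a JSON side-car."""
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)


# ---------------------------------------------------------------------------
# Torsion ensembles with tree-structured couplings

def _wrap_rad(x: np.ndarray) -> np.ndarray:
    """Wrap radians into (-π, π]."""
    y = np.mod(-x + math.pi, TWO_PI)
    return -(y - math.pi)


def gen_torsion_ensemble(spec: EnsembleSpec) -> tuple[TorsionSet, dict]:
    """Sample a torsion-angle ensemble with tree-structured correlations.

    Root angles (not a child in ``dependency_tree``) are drawn from
    von Mises(mean, κ); each child equals its parent plus wrapped
    von Mises(0, κ_coupling) noise.  The manifest declares the exact joint
    entropy (sum of root marginal and coupling-noise entropies, all
    closed-form) and the root marginal entropies.
    """
    if not spec.torsion_spec:
        raise ValueError("torsion_spec must be non-empty")
    m = len(spec.torsion_spec)
    children = {c for _, c, _ in spec.dependency_tree}
    if len(children) != len(spec.dependency_tree):
        raise ValueError("each angle may have at most one parent")
    rng = spec.rng()
    ang = np.empty((spec.n_frames, m))

    roots = [i for i in range(m) if i not in children]
    for i in roots:
        mu = math.radians(spec.torsion_spec[i]["mean_deg"])
        ang[:, i] = rng.vonmises(mu, spec.torsion_spec[i]["kappa"], size=spec.n_frames)

    # topological sweep over the forest
    remaining = list(spec.dependency_tree)
    done = set(roots)
    while remaining:
        progressed = False
        for edge in list(remaining):
            p, c, kc = edge
            if p in done:
                noise = rng.vonmises(0.0, kc, size=spec.n_frames)
                ang[:, c] = _wrap_rad(ang[:, p] + noise)
                done.add(c)
                remaining.remove(edge)
                progressed = True
        if not progressed:
            raise ValueError("dependency_tree contains a cycle or orphan child")

    truth = (sum(von_mises_entropy(spec.torsion_spec[i]["kappa"]) for i in roots)
             + sum(von_mises_entropy(kc) for _, _, kc in spec.dependency_tree))

    deg = np.rad2deg(_wrap_rad(ang))
    deg[deg <= -180.0] = 180.0
    residues = spec.torsion_residues or list(range(1, m + 1))
    labels = [("A", int(residues[j]), "phi") for j in range(m)]
    # torsions of the same residue share a group but need distinct names
    name_count: dict = {}
    for j, (ch, rid, _) in enumerate(labels):
        k = name_count.get((ch, rid), 0)
        labels[j] = (ch, rid, ["phi", "psi", "chi1", "chi2", "chi3"][k] if k < 5 else f"t{k}")
        name_count[(ch, rid)] = k + 1
    grouping: dict = {}
    for j, (ch, rid, _) in enumerate(labels):
        grouping.setdefault((ch, rid), []).append(j)

    ts = TorsionSet(angles=deg, torsion_labels=labels, residue_grouping=grouping)
    manifest = {
        "generator": "gen_torsion_ensemble",
        "seed": spec.seed,
        "n_frames": spec.n_frames,
        "true_joint_entropy_nats": truth,
        "root_marginal_entropies_nats": {
            int(i): von_mises_entropy(spec.torsion_spec[i]["kappa"]) for i in roots},
        "edges": [list(e) for e in spec.dependency_tree],
    }
    return ts, manifest


# ---------------------------------------------------------------------------
# Rigid-body pose ensembles

_BODY_TEMPLATE = np.array([
    [0.0, 0.0, 0.0],
    [1.5, 0.0, 0.0],
    [0.0, 1.5, 0.0],
    [0.0, 0.0, 1.5],
])


def _body(chain: str, offset, resid_start: int = 1) -> StructureModel:
    coords = _BODY_TEMPLATE + np.asarray(offset, float)
    n = len(coords)
    return StructureModel(
        atom_names=["CA"] * n, elements=["C"] * n, residue_names=["GLY"] * n,
        residue_ids=list(range(resid_start, resid_start + n)),
        chain_ids=[chain] * n, coords=coords,
    )


def _merge(models: list[StructureModel], model_id: int = 1) -> StructureModel:
    return StructureModel(
        atom_names=np.concatenate([m.atom_names for m in models]),
        elements=np.concatenate([m.elements for m in models]),
        residue_names=np.concatenate([m.residue_names for m in models]),
        residue_ids=np.concatenate([m.residue_ids for m in models]),
        chain_ids=np.concatenate([m.chain_ids for m in models]),
        coords=np.vstack([m.coords for m in models]),
        model_id=model_id,
    )


def gen_pose_ensemble(spec: EnsembleSpec) -> tuple[Ensemble, dict]:
    """Rigid two-body ensemble: body A fixed, body B's pose drawn per frame.

    Rotations are applied about body B's centroid; translations displace its
    centroid, so pose extraction with the default origin recovers exactly the
    drawn (quaternion, translation) sequence (stored in the manifest).  The
    manifest declares the closed-form rotational / translational / total pose
    entropies in nats (rotation w.r.t. Haar measure normalized to 8π²).
    """
    if spec.pose_spec is None:
        raise ValueError("pose_spec must be present")
    ps = spec.pose_spec
    rng = spec.rng()
    n = spec.n_frames

    rot = ps.get("rotation", None)
    if rot == "uniform":
        rots = Rotation.random(n, random_state=np.random.RandomState(spec.seed + 1))
        s_rot = math.log(SO3_VOLUME)
    elif rot is None:
        rots = Rotation.identity(n)
        s_rot = None
    else:
        sd_rad = math.radians(float(rot))
        if sd_rad <= 0:
            raise DegenerateSpecError("rotation sd -> 0: pose entropy diverges to -inf")
        rots = Rotation.from_rotvec(rng.normal(0.0, sd_rad, size=(n, 3)))
        s_rot = gaussian_entropy([sd_rad] * 3)

    tr = ps.get("translation", None)
    if tr is None:
        trans = np.zeros((n, 3))
        s_trans = None
    elif "sd" in tr:
        sd = float(tr["sd"])
        if sd <= 0:
            raise DegenerateSpecError("translation sd -> 0: pose entropy diverges to -inf")
        trans = rng.normal(0.0, sd, size=(n, 3))
        s_trans = gaussian_entropy([sd] * 3)
    elif "uniform_box" in tr:
        side = float(tr["uniform_box"])
        trans = rng.uniform(-side / 2.0, side / 2.0, size=(n, 3))
        s_trans = 3.0 * math.log(side)
    else:
        raise ValueError("translation spec needs 'sd' or 'uniform_box'")

    body_a = _body("A", (0.0, 0.0, 0.0))
    body_b = _body("B", (8.0, 0.0, 0.0))
    cB = body_b.centroid()
    quats = np.empty((n, 4))
    frames = []
    for f in range(n):
        Rm = rots[f].as_matrix()
        q = rots[f].as_quat()  # x, y, z, w
        q = np.array([q[3], q[0], q[1], q[2]])
        quats[f] = -q if q[0] < 0 else q
        moved = (body_b.coords - cB) @ Rm.T + cB + trans[f]
        frames.append(_merge([body_a, body_b.with_coords(moved)], model_id=f + 1))
    ens = Ensemble(frames=frames)

    s_total = None
    if s_rot is not None and s_trans is not None:
        s_total = s_rot + s_trans
    manifest = {
        "generator": "gen_pose_ensemble",
        "seed": spec.seed, "n_frames": n,
        "true_rotational_entropy_nats": s_rot,
        "true_translational_entropy_nats": s_trans,
        "true_pose_entropy_nats": s_total,
        "reference_entropy_nats": math.log(V_STANDARD_A3) + math.log(SO3_VOLUME),
        "true_quaternions": quats,
        "true_translations": trans,
    }
    return ens, manifest


# ---------------------------------------------------------------------------
# Planted hydrogen bonds

def gen_hbond_trajectory(spec: EnsembleSpec) -> tuple[Ensemble, dict]:
    """Trajectory with hydrogen bonds planted at exact target occupancies.

    Each planted bond is an isolated N–H donor / carbonyl-O acceptor pair
    20 Å from its neighbours.  The bond geometry satisfies the 3.5 Å / 30°
    criterion in exactly ``round(target_occupancy × n_frames)`` frames
    (the first ones); in "broken" frames the acceptor is displaced to 6 Å.
    """
    if not spec.hbond_spec:
        raise ValueError("hbond_spec must be non-empty")
    n = spec.n_frames
    planted = []
    for b, hb in enumerate(spec.hbond_spec):
        n_on = int(round(hb["target_occupancy"] * n))
        planted.append({"index": b, "n_on": n_on, "occupancy_exact": n_on / n})

    frames = []
    for f in range(n):
        names, elements, resnames, resids, chains, coords = [], [], [], [], [], []
        for b, hb in enumerate(spec.hbond_spec):
            base = np.array([20.0 * b, 0.0, 0.0])
            on = f < planted[b]["n_on"]
            acc_x = 2.9 if on else 6.0
            # donor residue: N + H; acceptor residue: O
            names += ["N", "H", "O"]
            elements += ["N", "H", "O"]
            resnames += ["GLY", "GLY", "GLY"]
            resids += [2 * b + 1, 2 * b + 1, 2 * b + 2]
            chains += ["A", "A", "B"]
            coords += [base, base + [1.0, 0.0, 0.0], base + [acc_x, 0.0, 0.0]]
        frames.append(StructureModel(names, elements, resnames, resids, chains,
                                     np.array(coords), model_id=f + 1))
    manifest = {
        "generator": "gen_hbond_trajectory",
        "seed": spec.seed, "n_frames": n,
        "planted_bonds": [
            {"donor": ["A", 2 * b + 1, "N"], "acceptor": ["B", 2 * b + 2, "O"],
             "target_occupancy": hb["target_occupancy"],
             "exact_occupancy": planted[b]["occupancy_exact"]}
            for b, hb in enumerate(spec.hbond_spec)
        ],
    }
    return Ensemble(frames=frames), manifest


# ---------------------------------------------------------------------------
# Scripted dissociation

def gen_dissociation_trajectory(spec: EnsembleSpec, n_residues: int = 10) -> tuple[Ensemble, dict]:
    """Two rigid chain groups with a scripted dissociation event.

    Chains A and B are parallel rows of ``n_residues`` CA atoms 3.5 Å
    apart (each residue pair a native contact).  Before
    ``dissociation_frame`` the groups are in contact; from it on, chain B
    either translates 20 Å away, or — with ``hinge_retain`` — rotates
    rigidly about the first residue pair so exactly that one native
    contact survives.  Intra-group geometry is rigid throughout.
    """
    n = spec.n_frames
    event = spec.dissociation_frame
    spacing = 10.0
    a_coords = np.array([[spacing * i, 0.0, 0.0] for i in range(n_residues)])
    b_coords = np.array([[spacing * i, 3.5, 0.0] for i in range(n_residues)])

    if spec.hinge_retain:
        pivot = b_coords[0]
        theta = math.radians(60.0)
        Rz = np.array([[math.cos(theta), -math.sin(theta), 0.0],
                       [math.sin(theta), math.cos(theta), 0.0],
                       [0.0, 0.0, 1.0]])
        b_after = (b_coords - pivot) @ Rz.T + pivot
    else:
        b_after = b_coords + np.array([0.0, 20.0, 0.0])

    def make(chain, coords, mid):
        m = len(coords)
        return StructureModel(["CA"] * m, ["C"] * m, ["GLY"] * m,
                              list(range(1, m + 1)), [chain] * m, coords, model_id=mid)

    frames = []
    for f in range(n):
        dissociated = event is not None and f >= event
        bc = b_after if dissociated else b_coords
        frames.append(_merge([make("A", a_coords, f + 1), make("B", bc, f + 1)], model_id=f + 1))
    manifest = {
        "generator": "gen_dissociation_trajectory",
        "seed": spec.seed, "n_frames": n,
        "dissociation_frame": event,
        "n_native_contacts": n_residues,
        "retained_after_event": (1 if spec.hinge_retain else 0) if event is not None else n_residues,
    }
    return Ensemble(frames=frames), manifest


# ---------------------------------------------------------------------------
# Ideal backbone built from internal coordinates (for torsion oracles)

_BB_GEOM = {  # bond lengths Å and angles degrees of the peptide backbone
    "n_ca": 1.458, "ca_c": 1.525, "c_n": 1.329,
    "n_ca_c": 111.2, "ca_c_n": 116.2, "c_n_ca": 121.7,
}


def _nerf(a, b, c, length, theta_deg, tau_deg) -> np.ndarray:
    """Place atom D given three predecessors, bond length, angle, torsion."""
    th, ta = math.radians(theta_deg), math.radians(tau_deg)
    d2 = np.array([-length * math.cos(th),
                   length * math.sin(th) * math.cos(ta),
                   -length * math.sin(th) * math.sin(ta)])
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def gen_ideal_backbone(n_residues: int, phi_deg: float, psi_deg: float,
                       omega_deg: float = 180.0, chain: str = "A") -> StructureModel:
    """Poly-glycine N–CA–C backbone with every residue at (φ, ψ).

    Built by sequential internal-coordinate placement with standard bond
    lengths and angles, so re-extracting torsions is an exact round trip
    up to floating-point error.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues for any torsion")
    g = _BB_GEOM
    coords = [np.array([0.0, 0.0, 0.0]), np.array([g["n_ca"], 0.0, 0.0])]
    th = math.radians(g["n_ca_c"])
    coords.append(coords[1] + np.array([g["ca_c"] * -math.cos(th),
                                        g["ca_c"] * math.sin(th), 0.0]))
    torsion_cycle = [psi_deg, omega_deg, phi_deg]   # psi(i), omega, phi(i+1)
    lengths = [g["c_n"], g["n_ca"], g["ca_c"]]
    angles = [g["ca_c_n"], g["c_n_ca"], g["n_ca_c"]]
    while len(coords) < 3 * n_residues:
        j = (len(coords) - 3) % 3
        coords.append(_nerf(coords[-3], coords[-2], coords[-1],
                            lengths[j], angles[j], torsion_cycle[j]))
    names = ["N", "CA", "C"] * n_residues
    elements = ["N", "C", "C"] * n_residues
    resids = [1 + i // 3 for i in range(3 * n_residues)]
    return StructureModel(names, elements, ["GLY"] * 3 * n_residues,
                          resids, [chain] * 3 * n_residues, np.array(coords))


# ---------------------------------------------------------------------------
# Toy multimer with hand-computable energies

def _reference_energies(coords: np.ndarray, topo: ToyTopology) -> dict:
    """Direct double-loop reference Coulomb/LJ energies (generator bookkeeping)."""
    from .constants import COULOMB_KCAL
    n = len(coords)
    u_c = u_lj = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if frozenset((i, j)) in topo.exclusions:
                continue
            r = float(np.linalg.norm(coords[i] - coords[j]))
            u_c += COULOMB_KCAL * topo.charges[i] * topo.charges[j] / r
            eps = math.sqrt(topo.lj_epsilon[i] * topo.lj_epsilon[j])
            if eps > 0:
                sig = 0.5 * (topo.lj_sigma[i] + topo.lj_sigma[j])
                sr6 = (sig / r) ** 6
                u_lj += 4.0 * eps * (sr6 * sr6 - sr6)
    return {"U_coulomb": u_c, "U_lj": u_lj}


# chains A-D stand for the tetramer's monomers I-IV (single-character ids
# so ensembles survive the PDB chain column)
_CHAIN_LABELS = ("A", "B", "C", "D")


def gen_toy_multimer(spec: EnsembleSpec, n_chains: int = 4,
                     atoms_per_chain: int = 5) -> tuple[StructureModel, ToyTopology, dict]:
    """Small multi-chain assembly with per-atom charges/LJ/radii/exclusions.

    Chains A–D (standing for monomers I–IV) sit on a 2×2 grid, a
    dimer-of-dimers footprint: A/B and C/D side by side.  Each atom is its
    residue with ids starting at 108, so author-numbering range selections
    are exercised.  The manifest carries direct-summation reference
    Coulomb and LJ energies and per-chain atom bookkeeping.
    """
    if not 1 <= n_chains <= 4:
        raise ValueError("n_chains must be in 1..4")
    rng = spec.rng()
    grid = [(0.0, 0.0), (9.0, 0.0), (0.0, 9.0), (9.0, 9.0)]
    names, elements, resnames, resids, chains, coords = [], [], [], [], [], []
    charges, sig, eps, radii = [], [], [], []
    exclusions = []
    atom_counter = 0
    for ci in range(n_chains):
        ox, oy = grid[ci]
        # compact non-collinear cluster
        local = np.array([[0, 0, 0], [2.8, 0, 0], [0, 2.8, 0],
                          [0, 0, 2.8], [2.0, 2.0, 2.0]])[:atoms_per_chain]
        local = local + rng.normal(0.0, 0.05, size=local.shape)
        for ai in range(atoms_per_chain):
            names.append("CA")
            elements.append("C")
            resnames.append("GLY")
            resids.append(108 + ai)
            chains.append(_CHAIN_LABELS[ci])
            coords.append(local[ai] + [ox, oy, 0.0])
            charges.append([0.3, -0.3, 0.2, -0.2, 0.0][ai % 5])
            sig.append(3.2)
            eps.append(0.12)
            radii.append(1.7)
            if ai > 0:  # chain path: consecutive atoms bonded (1-2 exclusions)
                exclusions.append((atom_counter - 1, atom_counter))
            atom_counter += 1
    model = StructureModel(names, elements, resnames, resids, chains,
                           np.array(coords), model_id=1)
    topo = ToyTopology(charges, sig, eps, radii,
                       exclusions=frozenset(frozenset(p) for p in exclusions))
    ref = _reference_energies(model.coords, topo)
    manifest = {
        "generator": "gen_toy_multimer",
        "seed": spec.seed,
        "n_chains": n_chains, "atoms_per_chain": atoms_per_chain,
        "residue_ids": sorted(set(resids)),
        "atoms_per_residue_per_chain": 1,
        "reference_energies": ref,
    }
    return model, topo, manifest


def gen_multimer_ensemble(spec: EnsembleSpec, n_chains: int = 4,
                          atoms_per_chain: int = 5,
                          rot_sd_deg: float = 2.0,
                          trans_sd: float = 0.2) -> tuple[Ensemble, ToyTopology, dict]:
    """Ensemble of the toy multimer under small per-chain rigid jitter.

    Each frame applies an independent small rotation (about the chain
    centroid) and translation to every chain; intra-chain geometry is
    rigid, so detaching-mode covalent terms cancel exactly.
    """
    model, topo, manifest = gen_toy_multimer(spec, n_chains, atoms_per_chain)
    rng = np.random.default_rng(spec.seed + 17)
    frames = []
    for f in range(spec.n_frames):
        coords = model.coords.copy()
        for ci in range(n_chains):
            mask = model.chain_ids == _CHAIN_LABELS[ci]
            c = coords[mask].mean(axis=0)
            Rm = Rotation.from_rotvec(
                rng.normal(0.0, math.radians(rot_sd_deg), size=3)).as_matrix()
            coords[mask] = (coords[mask] - c) @ Rm.T + c + rng.normal(0.0, trans_sd, size=3)
        frames.append(model.with_coords(coords, model_id=f + 1))
    manifest = dict(manifest, generator="gen_multimer_ensemble",
                    n_frames=spec.n_frames, rot_sd_deg=rot_sd_deg, trans_sd=trans_sd)
    return Ensemble(frames=frames), topo, manifest
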