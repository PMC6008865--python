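"""Enthalpic term of the end-point free energy: ⟨U + ΔW⟩ over an ensemble.

``U`` is the solute potential (Coulomb + Lennard-Jones + optional harmonic
covalent terms), ``ΔW`` the implicit solvation energy: a Generalized Born
polar part (Still pairwise formula with Born radii from a Coulomb-field
surface integral) plus an apolar part proportional to the solvent-accessible
surface area (Shrake–Rupley style point sampling).

Systems are desk-scale toy assemblies described by a :class:`ToyTopology`
(per-atom charge, LJ σ/ε, radius, bonded exclusions); no cutoff is applied.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import Constants, DEFAULT_CONSTANTS
from .model_io import ChainSelection, Ensemble, StructureModel, select

__all__ = [
    "ToyTopology",
    "EnergyRecord",
    "SurfacePointSet",
    "SingularityError",
    "BornRadiusError",
    "PartitionError",
    "solute_potential",
    "sample_surface",
    "gb_radii",
    "gb_polar",
    "apolar",
    "frame_energy",
    "ensemble_enthalpy",
    "association_enthalpy",
]


class SingularityError(ValueError):
    """Two non-excluded atoms closer than 0.01 Å."""


class BornRadiusError(ValueError):
    """Degenerate surface produced a non-positive Born integral."""


class PartitionError(ValueError):
    """Detaching-mode parts do not partition the complex's chains."""


@dataclass
class ToyTopology:
    """Per-atom parameters and bonded exclusions for a toy assembly.

    charges in e, lj_sigma in Å, lj_epsilon in kcal/mol, radii in Å.
    ``exclusions`` holds unordered 1-2/1-3 neighbour pairs excluded from the
    nonbonded sums.  ``bonds`` are optional harmonic terms
    ``(i, j, k [kcal/mol/Å²], r0 [Å])`` feeding ``U_covalent``.
    """

    charges: np.ndarray
    lj_sigma: np.ndarray
    lj_epsilon: np.ndarray
    radii: np.ndarray
    exclusions: frozenset = frozenset()
    bonds: tuple = ()

    def __post_init__(self) -> None:
        self.charges = np.asarray(self.charges, float)
        self.lj_sigma = np.asarray(self.lj_sigma, float)
        self.lj_epsilon = np.asarray(self.lj_epsilon, float)
        self.radii = np.asarray(self.radii, float)
        n = len(self.charges)
        for name in ("lj_sigma", "lj_epsilon", "radii"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != atom count")
        if np.any(self.radii <= 0):
            raise ValueError("radii must be positive")
        self.exclusions = frozenset(frozenset(p) for p in self.exclusions)

    @property
    def n_atoms(self) -> int:
        return len(self.charges)

    def subset(self, indices: np.ndarray) -> "ToyTopology":
        """Topology restricted to ``indices``; cross-boundary bonds dropped."""
        indices = np.asarray(indices, int)
        remap = {int(old): new for new, old in enumerate(indices)}
        keep = set(remap)
        excl = frozenset(
            frozenset((remap[a], remap[b]))
            for a, b in (tuple(p) for p in self.exclusions)
            if a in keep and b in keep
        )
        bonds = tuple(
            (remap[i], remap[j], k, r0)
            for i, j, k, r0 in self.bonds
            if i in keep and j in keep
        )
        return ToyTopology(
            self.charges[indices], self.lj_sigma[indices],
            self.lj_epsilon[indices], self.radii[indices],
            exclusions=excl, bonds=bonds,
        )

    def to_json(self, path) -> None:
        payload = {
            "charges": self.charges.tolist(),
            "lj_sigma": self.lj_sigma.tolist(),
            "lj_epsilon": self.lj_epsilon.tolist(),
            "radii": self.radii.tolist(),
            "exclusions": sorted(sorted(p) for p in self.exclusions),
            "bonds": [list(b) for b in self.bonds],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ToyTopology":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            d["charges"], d["lj_sigma"], d["lj_epsilon"], d["radii"],
            exclusions=frozenset(frozenset(p) for p in d.get("exclusions", [])),
            bonds=tuple(tuple(b) for b in d.get("bonds", [])),
        )


@dataclass(frozen=True)
class EnergyRecord:
    """Per-frame energy terms, kcal/mol."""

    U_covalent: float
    U_lj: float
    U_coulomb: float
    dW_polar: float
    dW_apolar: float

    @property
    def total(self) -> float:
        return self.U_covalent + self.U_lj + self.U_coulomb + self.dW_polar + self.dW_apolar

    def as_dict(self) -> dict:
        return {
            "U_covalent": self.U_covalent, "U_lj": self.U_lj,
            "U_coulomb": self.U_coulomb, "dW_polar": self.dW_polar,
            "dW_apolar": self.dW_apolar, "total": self.total,
        }


@dataclass
class SurfacePointSet:
    """Point-sampled accessible surface: positions, outward normals, weights."""

    points: np.ndarray          # (P, 3) Å
    normals: np.ndarray         # (P, 3) unit outward
    weights: np.ndarray         # (P,) Å² per point
    atom_index: np.ndarray      # (P,) owning atom
    n_atoms: int
    probe_radius: float

    @property
    def total_area(self) -> float:
        return float(self.weights.sum())

    def per_atom_area(self) -> np.ndarray:
        return np.bincount(self.atom_index, weights=self.weights, minlength=self.n_atoms)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (1.0 + math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Rotation-equivariant molecular frame (columns = axes, det +1).

    Principal axes of the coordinate covariance, ordered by decreasing
    eigenvalue, signs fixed by the third moment along each axis (falling
    back to the largest component when the distribution is symmetric), and
    the third axis taken as the cross product.  Sampling the sphere lattice
    in this frame makes surface areas exactly invariant under rigid motion
    of generic molecules.
    """
    if len(coords) < 2:
        return np.eye(3)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    axes = evecs[:, order]
    for j in range(2):
        proj = centered @ axes[:, j]
        skew = float(np.sum(proj ** 3))
        if abs(skew) > 1e-9:
            if skew < 0:
                axes[:, j] = -axes[:, j]
        elif axes[np.argmax(np.abs(axes[:, j])), j] < 0:
            axes[:, j] = -axes[:, j]
    axes[:, 2] = np.cross(axes[:, 0], axes[:, 1])
    return axes


# ---------------------------------------------------------------------------
# Solute potential

def solute_potential(model: StructureModel, topo: ToyTopology) -> EnergyRecord:
    """Nonbonded solute energy (no cutoff) plus optional harmonic covalent terms.

    Coulomb uses k·q_i·q_j/r; Lennard-Jones uses Lorentz–Berthelot combining
    (σ_ij arithmetic mean, ε_ij geometric mean).  Excluded pairs are skipped.
    """
    if model.n_atoms != topo.n_atoms:
        raise ValueError("atom counts of model and topology differ")
    xyz = model.coords
    n = len(xyz)
    iu, ju = np.triu_indices(n, k=1)
    if len(iu):
        rij = np.linalg.norm(xyz[iu] - xyz[ju], axis=1)
        excl = np.array([frozenset((int(a), int(b))) in topo.exclusions
                         for a, b in zip(iu, ju)])
        close = (rij < 0.01) & ~excl
        if close.any():
            a, b = int(iu[close][0]), int(ju[close][0])
            raise SingularityError(f"atoms {a} and {b} overlap (r < 0.01 Å)")
        keep = ~excl
        r = rij[keep]
        qi = topo.charges[iu[keep]] * topo.charges[ju[keep]]
        u_coul = float(np.sum(DEFAULT_CONSTANTS.coulomb * qi / r))
        sig = 0.5 * (topo.lj_sigma[iu[keep]] + topo.lj_sigma[ju[keep]])
        eps = np.sqrt(topo.lj_epsilon[iu[keep]] * topo.lj_epsilon[ju[keep]])
        active = eps > 0
        sr6 = (sig[active] / r[active]) ** 6
        u_lj = float(np.sum(4.0 * eps[active] * (sr6 * sr6 - sr6)))
    else:
        u_coul = u_lj = 0.0
    u_cov = 0.0
    for i, j, k, r0 in topo.bonds:
        d = float(np.linalg.norm(xyz[i] - xyz[j]))
        u_cov += k * (d - r0) ** 2
    return EnergyRecord(U_covalent=u_cov, U_lj=u_lj, U_coulomb=u_coul,
                        dW_polar=0.0, dW_apolar=0.0)


# ---------------------------------------------------------------------------
# Surface sampling, Born radii, GB/SA solvation

def sample_surface(
    model: StructureModel,
    topo: ToyTopology,
    n_points_per_atom: int = 240,
    probe_radius: float | None = None,
    consts: Constants = DEFAULT_CONSTANTS,
) -> SurfacePointSet:
    """Shrake–Rupley style sampling of the probe-expanded surface.

    Each atom gets quasi-uniform points at radius ``r_atom + probe``; points
    inside any other atom's expanded sphere are removed.  Per-point weight is
    ``4π(r+probe)²/n_points``, so surviving weights sum to the SASA.  With
    ``probe_radius=0`` the van der Waals surface is sampled (used as the
    molecular-surface approximation for Born radii).
    """
    probe = consts.probe_radius if probe_radius is None else probe_radius
    xyz = model.coords
    unit = _fibonacci_sphere(n_points_per_atom) @ _canonical_frame(xyz).T
    expanded = topo.radii + probe
    pts, nrm, wts, owner = [], [], [], []
    for i in range(model.n_atoms):
        p = xyz[i] + expanded[i] * unit
        keep = np.ones(len(p), bool)
        for j in range(model.n_atoms):
            if j == i:
                continue
            d = np.linalg.norm(p - xyz[j], axis=1)
            inside = d < expanded[j] - 1e-9
            # boundary tie (coincident spheres): earlier atom keeps the point
            if j < i:
                inside |= d < expanded[j] + 1e-9
            keep &= ~inside
        if keep.any():
            pts.append(p[keep])
            nrm.append(unit[keep])
            w = 4.0 * math.pi * expanded[i] ** 2 / n_points_per_atom
            wts.append(np.full(keep.sum(), w))
            owner.append(np.full(keep.sum(), i, dtype=int))
    if pts:
        points = np.vstack(pts); normals = np.vstack(nrm)
        weights = np.concatenate(wts); atom_index = np.concatenate(owner)
    else:
        points = np.empty((0, 3)); normals = np.empty((0, 3))
        weights = np.empty(0); atom_index = np.empty(0, int)
    return SurfacePointSet(points, normals, weights, atom_index,
                           n_atoms=model.n_atoms, probe_radius=probe)


def gb_radii(model: StructureModel, surface: SurfacePointSet,
             topo: ToyTopology | None = None) -> np.ndarray:
    """Born radii via the Coulomb-field surface-integral approximation.

    1/R_i = (1/4π) Σ_p w_p (r_ip·n_p)/|r_ip|⁴ over the molecular-surface
    sample.  Radii are clamped from below at the intrinsic atomic radius
    (burial can only increase the Born radius).
    """
    if surface.points.size == 0:
        raise BornRadiusError("empty surface sample")
    radii = np.empty(model.n_atoms)
    for i in range(model.n_atoms):
        rip = surface.points - model.coords[i]
        dist = np.linalg.norm(rip, axis=1)
        integrand = np.einsum("pj,pj->p", rip, surface.normals) / dist ** 4
        inv_r = float(np.sum(surface.weights * integrand)) / (4.0 * math.pi)
        if inv_r <= 0:
            raise BornRadiusError(f"non-positive Born integral for atom {i}")
        radii[i] = 1.0 / inv_r
    if topo is not None:
        radii = np.maximum(radii, topo.radii)
    return radii


def gb_polar(model: StructureModel, topo: ToyTopology, born_radii: np.ndarray,
             consts: Constants = DEFAULT_CONSTANTS) -> float:
    """Polar solvation energy, Still's pairwise GB expression (kcal/mol).

    ΔG_pol = −(k/2)(1/ε_in − 1/ε_out) Σ_ij q_i q_j / f_ij with
    f_ij = sqrt(r_ij² + R_i R_j exp(−r_ij²/(4 R_i R_j))) and f_ii = R_i.
    The i = j terms are the Born self-energies.
    """
    R = np.asarray(born_radii, float)
    if np.any(R <= 0):
        raise BornRadiusError("non-positive Born radius")
    xyz = model.coords
    d2 = np.sum((xyz[:, None, :] - xyz[None, :, :]) ** 2, axis=-1)
    RiRj = R[:, None] * R[None, :]
    f = np.sqrt(d2 + RiRj * np.exp(-d2 / (4.0 * RiRj)))
    qq = topo.charges[:, None] * topo.charges[None, :]
    pref = -(consts.coulomb / 2.0) * (1.0 / consts.eps_in - 1.0 / consts.eps_out)
    return float(pref * np.sum(qq / f))


def apolar(surface: SurfacePointSet, consts: Constants = DEFAULT_CONSTANTS) -> float:
    """Apolar solvation: γ × total SASA, in kcal/mol (γ given in cal/Å²/mol)."""
    return consts.gamma * surface.total_area / 1000.0


# ---------------------------------------------------------------------------
# Ensemble averages and association differences

def frame_energy(model: StructureModel, topo: ToyTopology,
                 consts: Constants = DEFAULT_CONSTANTS,
                 n_surface_points: int = 240) -> EnergyRecord:
    """Full U + ΔW energy record for one frame."""
    rec = solute_potential(model, topo)
    sas = sample_surface(model, topo, n_surface_points, consts=consts)
    mol = sample_surface(model, topo, n_surface_points, probe_radius=0.0, consts=consts)
    born = gb_radii(model, mol, topo=topo)
    return EnergyRecord(
        U_covalent=rec.U_covalent, U_lj=rec.U_lj, U_coulomb=rec.U_coulomb,
        dW_polar=gb_polar(model, topo, born, consts),
        dW_apolar=apolar(sas, consts),
    )


def ensemble_enthalpy(ens: Ensemble, topo: ToyTopology,
                      consts: Constants = DEFAULT_CONSTANTS,
                      n_surface_points: int = 240) -> dict:
    """Ensemble average of U + ΔW over frames.

    Returns mean, sem (sd/√n, frames treated as independent) and the
    per-frame :class:`EnergyRecord` list.  A frame failing energy
    evaluation aborts with its index.
    """
    records: list[EnergyRecord] = []
    for idx, frame in enumerate(ens.frames):
        try:
            records.append(frame_energy(frame, topo, consts, n_surface_points))
        except Exception as exc:
            raise RuntimeError(f"energy evaluation failed at frame {idx}: {exc}") from exc
    totals = np.array([r.total for r in records])
    sem = float(totals.std(ddof=1) / math.sqrt(len(totals))) if len(totals) > 1 else 0.0
    term_means = {
        key: float(np.mean([r.as_dict()[key] for r in records]))
        for key in ("U_covalent", "U_lj", "U_coulomb", "dW_polar", "dW_apolar")
    }
    return {"mean": float(totals.mean()), "sem": sem,
            "records": records, "term_means": term_means}


def energies_to_frame(records: list[EnergyRecord]) -> pd.DataFrame:
    """Per-frame energy terms as a tidy DataFrame (TSV-ready, kcal/mol)."""
    return pd.DataFrame([r.as_dict() for r in records]).rename_axis("frame")


_TERMS = ("U_covalent", "U_lj", "U_coulomb", "dW_polar", "dW_apolar")


def association_enthalpy(
    complex_ens: Ensemble,
    topo: ToyTopology,
    parts,
    consts: Constants = DEFAULT_CONSTANTS,
    mode: str = "detach",
    n_surface_points: int = 240,
) -> dict:
    """ΔH of association: ⟨H_complex⟩ − Σ ⟨H_part⟩, with term decomposition.

    In ``detach`` mode ``parts`` is a list of :class:`ChainSelection` that
    must partition the complex's chains; part energies are evaluated on the
    sub-assemblies extracted from the very same frames, so intra-part
    covalent terms cancel exactly.  In ``single`` mode ``parts`` is a list
    of ``(Ensemble, ToyTopology)`` pairs simulated independently.
    """
    comp = ensemble_enthalpy(complex_ens, topo, consts, n_surface_points)
    part_results = []
    if mode == "detach":
        all_chains = set(map(str, complex_ens.frames[0].chain_ids))
        claimed: list[str] = []
        for sel in parts:
            claimed.extend(str(c) for c in sel.chain_ids)
        if sorted(claimed) != sorted(all_chains):
            raise PartitionError(
                f"selections {sorted(claimed)} do not partition chains {sorted(all_chains)}")
        for sel in parts:
            mask = sel.mask(complex_ens.frames[0])
            sub_topo = topo.subset(np.nonzero(mask)[0])
            sub_frames = [select(f, sel) for f in complex_ens.frames]
            part_results.append(ensemble_enthalpy(Ensemble(frames=sub_frames),
                                                  sub_topo, consts, n_surface_points))
    elif mode == "single":
        for ens_p, topo_p in parts:
            part_results.append(ensemble_enthalpy(ens_p, topo_p, consts, n_surface_points))
    else:
        raise ValueError("mode must be 'detach' or 'single'")

    dH = comp["mean"] - sum(p["mean"] for p in part_results)
    sem = math.sqrt(comp["sem"] ** 2 + sum(p["sem"] ** 2 for p in part_results))
    decomposition = {
        t: comp["term_means"][t] - sum(p["term_means"][t] for p in part_results)
        for t in _TERMS
    }
    return {"dH": float(dH), "sem": sem, "decomposition": decomposition,
            "complex": comp, "parts": part_results}
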