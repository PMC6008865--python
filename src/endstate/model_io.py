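"""Structure and ensemble I/O, sub-assembly selection, superposition, torsions.

The ensemble interchange format is the multi-model PDB (``MODEL``/``ENDMDL``
blocks), one :class:`StructureModel` per model.  Residue numbering is PDB
author numbering (1-based, ranges inclusive).  Torsion angles are stored in
degrees on ``(-180, 180]`` and converted to radians only inside entropy
estimators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "StructureModel",
    "Ensemble",
    "ChainSelection",
    "TorsionSet",
    "SuperpositionResult",
    "PDBParseError",
    "RosterError",
    "EmptySelectionError",
    "DegenerateFitError",
    "read_structure",
    "write_structure",
    "select",
    "superpose",
    "dihedral",
    "extract_torsions",
]


class PDBParseError(ValueError):
    """Malformed PDB record (message names the offending line)."""


class RosterError(ValueError):
    """Atom roster differs between models of a multi-model file."""


class EmptySelectionError(ValueError):
    """A chain/residue selection matched no atoms."""


class DegenerateFitError(ValueError):
    """Superposition subset has fewer than 3 non-collinear atoms."""


@dataclass
class StructureModel:
    """One conformation: parallel per-atom arrays plus coordinates in Å."""

    atom_names: np.ndarray
    elements: np.ndarray
    residue_names: np.ndarray
    residue_ids: np.ndarray
    chain_ids: np.ndarray
    coords: np.ndarray
    model_id: int = 1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        for name in ("atom_names", "elements", "residue_names", "chain_ids"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=object))
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        n = len(self.coords)
        for name in ("atom_names", "elements", "residue_names", "residue_ids", "chain_ids"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != atom count")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def roster(self) -> tuple:
        """Hashable (chain, residue_id, atom_name) sequence identifying atoms."""
        return tuple(zip(self.chain_ids, self.residue_ids, self.atom_names))

    def with_coords(self, coords: np.ndarray, model_id: int | None = None) -> "StructureModel":
        return StructureModel(
            self.atom_names, self.elements, self.residue_names,
            self.residue_ids, self.chain_ids, np.asarray(coords, dtype=float),
            model_id=self.model_id if model_id is None else model_id,
        )

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)


@dataclass
class Ensemble:
    """Ordered sequence of frames sharing one atom roster."""

    frames: list[StructureModel]
    frame_times: np.ndarray | None = None  # ps, optional

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("ensemble needs at least one frame")
        ref = self.frames[0].roster()
        for i, f in enumerate(self.frames[1:], start=2):
            if f.roster() != ref:
                raise RosterError(f"model {f.model_id} (frame {i}) atom roster differs from frame 1")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    @property
    def coords(self) -> np.ndarray:
        """Stacked coordinates, shape (n_frames, n_atoms, 3)."""
        return np.stack([f.coords for f in self.frames])

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


@dataclass(frozen=True)
class ChainSelection:
    """Chains and optional inclusive residue ranges (author numbering)."""

    chain_ids: frozenset
    residue_ranges: tuple | None = None

    def __init__(self, chain_ids: Iterable[str], residue_ranges: Sequence[Sequence[int]] | None = None):
        object.__setattr__(self, "chain_ids", frozenset(chain_ids))
        if residue_ranges is not None:
            rr = tuple((int(a), int(b)) for a, b in residue_ranges)
            for a, b in rr:
                if a > b:
                    raise ValueError(f"residue range start {a} > end {b}")
            object.__setattr__(self, "residue_ranges", rr)
        else:
            object.__setattr__(self, "residue_ranges", None)

    def mask(self, model: StructureModel) -> np.ndarray:
        m = np.isin(model.chain_ids.astype(str), sorted(str(c) for c in self.chain_ids))
        if self.residue_ranges is not None:
            rmask = np.zeros(model.n_atoms, dtype=bool)
            for a, b in self.residue_ranges:
                rmask |= (model.residue_ids >= a) & (model.residue_ids <= b)
            m &= rmask
        return m


@dataclass
class TorsionSet:
    """Torsion-angle matrix (frames × torsions, degrees) with labels.

    ``torsion_labels[j]`` is ``(chain_id, residue_id, name)`` with name in
    ``{"phi", "psi", "chi1", ...}``; ``residue_grouping`` maps
    ``(chain_id, residue_id)`` to the torsion column indices of that
    residue and partitions the column index set.
    """

    angles: np.ndarray
    torsion_labels: list[tuple]
    residue_grouping: dict

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2:
            raise ValueError("angles must be frames × torsions")
        if self.angles.shape[1] != len(self.torsion_labels):
            raise ValueError("label count != torsion count")
        if self.angles.size and (self.angles.min() <= -180.0 or self.angles.max() > 180.0):
            raise ValueError("angles must lie in (-180, 180]")
        cols = sorted(i for idx in self.residue_grouping.values() for i in idx)
        if cols != list(range(self.angles.shape[1])):
            raise ValueError("residue_grouping must partition torsion indices")

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    @property
    def n_torsions(self) -> int:
        return self.angles.shape[1]

    def radians(self) -> np.ndarray:
        return np.deg2rad(self.angles)

    def column(self, chain_id, residue_id: int, name: str) -> np.ndarray:
        j = self.torsion_labels.index((chain_id, residue_id, name))
        return self.angles[:, j]


# ---------------------------------------------------------------------------
# PDB reading / writing

def _parse_atom_line(line: str, lineno: int) -> dict:
    if len(line.rstrip("\n")) < 54:
        raise PDBParseError(f"line {lineno}: ATOM record shorter than coordinate fields")
    try:
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or " "
        resid = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38]); y = float(line[38:46]); z = float(line[46:54])
        occ = float(line[54:60]) if line[54:60].strip() else 1.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed ATOM record ({exc})") from exc
    if icode:
        raise PDBParseError(f"line {lineno}: insertion codes are not supported")
    if not element:
        element = "".join(c for c in name if c.isalpha())[:1]
    return dict(name=name, altloc=altloc, resname=resname, chain=chain,
                resid=resid, x=x, y=y, z=z, occ=occ, element=element)


def _build_model(records: list[dict], model_id: int) -> StructureModel:
    # alternate locations: keep the highest-occupancy conformer per atom
    best: dict[tuple, dict] = {}
    order: list[tuple] = []
    for rec in records:
        key = (rec["chain"], rec["resid"], rec["name"])
        if key not in best:
            best[key] = rec
            order.append(key)
        elif rec["occ"] > best[key]["occ"]:
            best[key] = rec
    chosen = [best[k] for k in order]
    return StructureModel(
        atom_names=[r["name"] for r in chosen],
        elements=[r["element"] for r in chosen],
        residue_names=[r["resname"] for r in chosen],
        residue_ids=[r["resid"] for r in chosen],
        chain_ids=[r["chain"] for r in chosen],
        coords=[(r["x"], r["y"], r["z"]) for r in chosen],
        model_id=model_id,
    )


def read_structure(path, accept_multi_model: bool = True) -> Ensemble:
    """Read a (possibly multi-model) PDB file into an :class:`Ensemble`.

    One frame per ``MODEL`` record; a file without ``MODEL`` records yields
    a single frame.  Author residue numbering is preserved.  Raises
    :class:`PDBParseError` on malformed records (naming the line) and
    :class:`RosterError` when models disagree on the atom roster.
    """
    frames: list[StructureModel] = []
    records: list[dict] = []
    model_id = 1
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tag = line[:6].strip()
            if tag == "MODEL":
                if records and not in_model:
                    raise PDBParseError(f"line {lineno}: MODEL record after untagged atoms")
                in_model = True
                try:
                    model_id = int(line.split()[1])
                except (IndexError, ValueError):
                    model_id = len(frames) + 1
            elif tag == "ENDMDL":
                frames.append(_build_model(records, model_id))
                records = []
                in_model = False
            elif tag in ("ATOM", "HETATM"):
                records.append(_parse_atom_line(line, lineno))
    if records:
        frames.append(_build_model(records, model_id if in_model else 1))
    if not frames:
        raise PDBParseError(f"{path}: no ATOM records found")
    if len(frames) > 1 and not accept_multi_model:
        raise ValueError(f"{path}: multi-model file but accept_multi_model=False")
    return Ensemble(frames=frames)


def _format_atom_name(name: str) -> str:
    # short names start in column 14 per PDB convention
    return f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"


def write_structure(obj: Ensemble | StructureModel, path) -> None:
    """Write a model or ensemble as a (multi-model) PDB file."""
    ens = obj if isinstance(obj, Ensemble) else Ensemble(frames=[obj])
    multi = ens.n_frames > 1
    with open(path, "w") as fh:
        for idx, frame in enumerate(ens.frames, start=1):
            if multi:
                fh.write(f"MODEL     {idx:4d}\n")
            serial = 0
            for i in range(frame.n_atoms):
                serial += 1
                if len(str(frame.chain_ids[i])) > 1:
                    raise ValueError(
                        f"chain id {frame.chain_ids[i]!r} does not fit the single-character PDB chain column")
                x, y, z = frame.coords[i]
                fh.write(
                    "ATOM  {serial:5d} {name} {res:<3s} {chain}{resid:4d}    "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}\n".format(
                        serial=serial % 100000,
                        name=_format_atom_name(str(frame.atom_names[i])),
                        res=str(frame.residue_names[i])[:3],
                        chain=str(frame.chain_ids[i])[:1],
                        resid=int(frame.residue_ids[i]),
                        x=x, y=y, z=z, occ=1.00, b=0.00,
                        el=str(frame.elements[i])[:2],
                    )
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Selection and superposition

def select(model: StructureModel, sel: ChainSelection) -> StructureModel:
    """Extract the sub-assembly matching ``sel``; atom order preserved."""
    mask = sel.mask(model)
    if not mask.any():
        raise EmptySelectionError(f"selection {sorted(sel.chain_ids)} matched no atoms")
    return StructureModel(
        model.atom_names[mask], model.elements[mask], model.residue_names[mask],
        model.residue_ids[mask], model.chain_ids[mask], model.coords[mask],
        model_id=model.model_id,
    )


def select_ensemble(ens: Ensemble, sel: ChainSelection) -> Ensemble:
    return Ensemble(frames=[select(f, sel) for f in ens.frames], frame_times=ens.frame_times)


@dataclass(frozen=True)
class SuperpositionResult:
    """Least-squares rigid-body fit: ``x' = rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch(mobile_xyz: np.ndarray, reference_xyz: np.ndarray) -> SuperpositionResult:
    """Kabsch fit of paired coordinate sets; always a proper rotation."""
    P = np.asarray(mobile_xyz, float)
    Q = np.asarray(reference_xyz, float)
    if P.shape != Q.shape or P.shape[0] < 3:
        raise DegenerateFitError("need >= 3 paired atoms for a rigid fit")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2:
        raise DegenerateFitError("superposition atoms are collinear")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    Rmat = Vt.T @ D @ U.T
    t = qc - Rmat @ pc
    rmsd = float(np.sqrt(np.mean(np.sum((P0 @ Rmat.T - Q0) ** 2, axis=1))))
    return SuperpositionResult(rotation=Rmat, translation=t, rmsd=rmsd)


def superpose(
    mobile: StructureModel,
    reference: StructureModel,
    subset: ChainSelection | None = None,
    atom_names: tuple[str, ...] = ("CA",),
) -> SuperpositionResult:
    """Rigid-body least-squares fit of ``mobile`` onto ``reference``.

    The fit uses the atoms of ``subset`` (default: all chains) restricted to
    ``atom_names`` (default CA); atoms are paired by (chain, residue, name).
    """
    def pick(m: StructureModel) -> dict:
        mask = subset.mask(m) if subset is not None else np.ones(m.n_atoms, bool)
        if atom_names:
            mask &= np.isin(m.atom_names.astype(str), atom_names)
        if not mask.any():  # fall back to all subset atoms (e.g. toy models without CA)
            mask = subset.mask(m) if subset is not None else np.ones(m.n_atoms, bool)
        keys = {}
        for i in np.nonzero(mask)[0]:
            keys[(m.chain_ids[i], int(m.residue_ids[i]), m.atom_names[i])] = i
        return keys

    km, kr = pick(mobile), pick(reference)
    shared = [k for k in km if k in kr]
    if len(shared) < 3:
        raise DegenerateFitError(f"only {len(shared)} shared atoms for superposition")
    P = mobile.coords[[km[k] for k in shared]]
    Q = reference.coords[[kr[k] for k in shared]]
    return kabsch(P, Q)


# ---------------------------------------------------------------------------
# Torsion extraction

def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle in degrees on (-180, 180] (IUPAC convention).

    0 for cis (atoms 1 and 4 eclipsed), 180 for trans.
    """
    b1 = np.asarray(p2, float) - p1
    b2 = np.asarray(p3, float) - p2
    b3 = np.asarray(p4, float) - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = math.degrees(math.atan2(np.dot(m1, n2), np.dot(n1, n2)))
    return 180.0 if ang <= -180.0 else ang


_CHI1_GAMMA = ("CG", "CG1", "OG", "OG1", "SG")


def extract_torsions(ens: Ensemble, which: Iterable[str] = ("phi", "psi")) -> TorsionSet:
    """Extract backbone (and chi1) torsions from every frame of an ensemble.

    phi(i) = C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-N(i+1);
    chain termini are omitted.  A residue missing a defining atom is
    skipped (not fatal).
    """
    which = set(which)
    ref = ens.frames[0]

    # index atoms of the reference roster by (chain, resid, name)
    atom_idx: dict[tuple, int] = {}
    for i in range(ref.n_atoms):
        atom_idx[(ref.chain_ids[i], int(ref.residue_ids[i]), ref.atom_names[i])] = i

    # residues per chain in order of first appearance
    chain_res: dict = {}
    for i in range(ref.n_atoms):
        chain_res.setdefault(ref.chain_ids[i], [])
        rid = int(ref.residue_ids[i])
        if rid not in chain_res[ref.chain_ids[i]]:
            chain_res[ref.chain_ids[i]].append(rid)

    quads: list[tuple] = []   # (label, 4 atom indices)
    for chain, residues in chain_res.items():
        for pos, rid in enumerate(residues):
            def a(r, name):
                return atom_idx.get((chain, r, name))
            if "phi" in which and pos > 0:
                prev = residues[pos - 1]
                ids = (a(prev, "C"), a(rid, "N"), a(rid, "CA"), a(rid, "C"))
                if None not in ids:
                    quads.append(((chain, rid, "phi"), ids))
            if "psi" in which and pos < len(residues) - 1:
                nxt = residues[pos + 1]
                ids = (a(rid, "N"), a(rid, "CA"), a(rid, "C"), a(nxt, "N"))
                if None not in ids:
                    quads.append(((chain, rid, "psi"), ids))
            if "chi1" in which:
                gamma = next((g for g in _CHI1_GAMMA if a(rid, g) is not None), None)
                ids = (a(rid, "N"), a(rid, "CA"), a(rid, "CB"),
                       atom_idx.get((chain, rid, gamma)) if gamma else None)
                if None not in ids:
                    quads.append(((chain, rid, "chi1"), ids))

    labels = [q[0] for q in quads]
    angles = np.empty((ens.n_frames, len(quads)))
    for fi, frame in enumerate(ens.frames):
        c = frame.coords
        for j, (_, (i1, i2, i3, i4)) in enumerate(quads):
            angles[fi, j] = dihedral(c[i1], c[i2], c[i3], c[i4])

    grouping: dict = {}
    for j, (chain, rid, _) in enumerate(labels):
        grouping.setdefault((chain, rid), []).append(j)
    return TorsionSet(angles=angles, torsion_labels=labels, residue_grouping=grouping)
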