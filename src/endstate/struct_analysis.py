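"""Trajectory-level structural analytics.

Geometric hydrogen-bond detection and occupancy tables, Ramachandran-region
classification, interface heavy-atom contact and salt-bridge tracking, and
detection of a sustained dissociation event from the native-contact
fraction.

Default criteria (boundary inclusive unless noted): H-bond
donor–acceptor ≤ 3.5 Å with H–donor–acceptor angle ≤ 30°; heavy-atom
contact < 4.5 Å; salt bridge basic-N to acidic-O ≤ 4.0 Å.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .model_io import ChainSelection, Ensemble, StructureModel, TorsionSet

__all__ = [
    "HBondCriterion",
    "HBondRecord",
    "InterfaceReport",
    "detect_hbonds",
    "hbond_occupancy",
    "classify_rama",
    "rama_series",
    "interface_contacts",
    "dissociation_frame",
    "salt_bridges",
]

logger = logging.getLogger(__name__)

_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT", "H", "HN", "HA", "H1", "H2", "H3"}


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric H-bond criterion: distances in Å, angle in degrees."""

    max_distance: float = 3.5
    max_angle: float = 30.0
    covalent_dh: float = 1.25  # H assigned to the nearest N/O within this


@dataclass
class HBondRecord:
    """One donor→acceptor bond with its trajectory occupancy."""

    donor: tuple            # (chain, resid, atom_name)
    acceptor: tuple
    bond_class: str         # mainchain-mainchain / mainchain-sidechain / sidechain-sidechain
    occupancy: Fraction
    major: bool = False     # occupancy >= 80 %

    @property
    def occupancy_float(self) -> float:
        return float(self.occupancy)


def _atom_label(m: StructureModel, i: int) -> tuple:
    return (m.chain_ids[i], int(m.residue_ids[i]), str(m.atom_names[i]))


def _is_hydrogen(m: StructureModel, i: int) -> bool:
    el = str(m.elements[i]).upper()
    return el == "H" or (not el and str(m.atom_names[i]).startswith("H"))


def _polar_heavy(m: StructureModel, i: int) -> bool:
    return str(m.elements[i]).upper() in ("N", "O")


def detect_hbonds(frame: StructureModel, criterion: HBondCriterion = HBondCriterion()) -> list:
    """Hydrogen bonds in one frame as (donor_idx, hydrogen_idx, acceptor_idx).

    Donors are N/O atoms with a covalently attached hydrogen; acceptors are
    N/O atoms of a different residue.  A bond is reported iff the
    donor–acceptor distance is ≤ 3.5 Å and the H–donor–acceptor angle is
    ≤ 30° (both inclusive).  In a structure without hydrogens every polar
    heavy atom is treated as a potential donor and the criterion degrades
    to distance-only (logged once).
    """
    xyz = frame.coords
    h_idx = [i for i in range(frame.n_atoms) if _is_hydrogen(frame, i)]
    heavy_polar = [i for i in range(frame.n_atoms) if _polar_heavy(frame, i)]

    donors: list[tuple[int, int | None]] = []
    if h_idx:
        for h in h_idx:
            cands = [(np.linalg.norm(xyz[h] - xyz[j]), j) for j in heavy_polar]
            if not cands:
                continue
            dist, j = min(cands)
            if dist <= criterion.covalent_dh:
                donors.append((j, h))
    else:
        logger.warning("no hydrogens present: H-bond criterion degraded to distance-only")
        donors = [(j, None) for j in heavy_polar]

    bonds = []
    for d, h in donors:
        dres = (frame.chain_ids[d], int(frame.residue_ids[d]))
        for a in heavy_polar:
            if a == d:
                continue
            if (frame.chain_ids[a], int(frame.residue_ids[a])) == dres:
                continue
            if np.linalg.norm(xyz[d] - xyz[a]) > criterion.max_distance:
                continue
            if h is not None:
                v1 = xyz[h] - xyz[d]
                v2 = xyz[a] - xyz[d]
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                ang = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
                if ang > criterion.max_angle:
                    continue
            bonds.append((d, h, a))
    return bonds


def _bond_class(m: StructureModel, d: int, a: int) -> str:
    dm = str(m.atom_names[d]) in _BACKBONE_ATOMS
    am = str(m.atom_names[a]) in _BACKBONE_ATOMS
    if dm and am:
        return "mainchain-mainchain"
    if dm or am:
        return "mainchain-sidechain"
    return "sidechain-sidechain"


def hbond_occupancy(ens: Ensemble, report_threshold: float = 0.10,
                    criterion: HBondCriterion = HBondCriterion()) -> list[HBondRecord]:
    """Occupancy table over the trajectory.

    Occupancy is the exact rational frames-satisfying / total-frames; the
    union of bonds ever seen is filtered to occupancy strictly greater
    than ``report_threshold`` (default 10 %), and records at ≥ 80 % carry
    the "major" flag.
    """
    counts: dict = {}
    classes: dict = {}
    for frame in ens.frames:
        seen = set()
        for d, _h, a in detect_hbonds(frame, criterion):
            key = (_atom_label(frame, d), _atom_label(frame, a))
            seen.add(key)
            classes.setdefault(key, _bond_class(frame, d, a))
        for key in seen:
            counts[key] = counts.get(key, 0) + 1
    n = ens.n_frames
    records = []
    for key, c in sorted(counts.items()):
        occ = Fraction(c, n)
        if occ > Fraction(report_threshold).limit_denominator(10**6):
            records.append(HBondRecord(donor=key[0], acceptor=key[1],
                                       bond_class=classes[key], occupancy=occ,
                                       major=occ >= Fraction(4, 5)))
    return records


# ---------------------------------------------------------------------------
# Ramachandran regions

def _wrap_deg(a: float) -> float:
    """Reduce to (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def _in_open(a: float, lo: float, hi: float) -> bool:
    """Wrap-aware open-interval membership lo < a < hi (hi may exceed 180)."""
    span = (a - lo) % 360.0
    return 0.0 < span < (hi - lo)


def classify_rama(phi: float, psi: float) -> str:
    """Assign (φ, ψ) to a backbone conformational region.

    alpha:  −89 < φ < −39 and −66 < ψ < −16
    beta:   −180 < φ < −45 and 45 < ψ < 225 (wrap-aware in ψ)
    alphaL: −40 < φ < 70 and 30 < ψ < 140
    otherwise "other".  Checked in that order; each point maps to exactly
    one region.
    """
    phi, psi = _wrap_deg(phi), _wrap_deg(psi)
    if _in_open(phi, -89, -39) and _in_open(psi, -66, -16):
        return "alpha"
    if _in_open(phi, -180, -45) and _in_open(psi, 45, 225):
        return "beta"
    if _in_open(phi, -40, 70) and _in_open(psi, 30, 140):
        return "alphaL"
    return "other"


def _circular_mean_sd(deg: np.ndarray) -> tuple[float, float]:
    rad = np.deg2rad(deg)
    s, c = np.mean(np.sin(rad)), np.mean(np.cos(rad))
    mean = math.degrees(math.atan2(s, c))
    rbar = min(math.hypot(s, c), 1.0)
    sd = math.degrees(math.sqrt(max(-2.0 * math.log(rbar), 0.0))) if rbar > 0 else float("inf")
    return _wrap_deg(mean), sd


def rama_series(ts: TorsionSet, residue: tuple) -> dict:
    """Circular mean ± sd of a residue's (φ, ψ) and region assignments.

    ``residue`` is ``(chain_id, residue_id)``; the residue must have both
    phi and psi columns.  Means and standard deviations are circular
    statistics in degrees.
    """
    chain, rid = residue
    phi = ts.column(chain, rid, "phi")
    psi = ts.column(chain, rid, "psi")
    mphi, sphi = _circular_mean_sd(phi)
    mpsi, spsi = _circular_mean_sd(psi)
    return {
        "mean_phi": mphi, "sd_phi": sphi,
        "mean_psi": mpsi, "sd_psi": spsi,
        "region_of_mean": classify_rama(mphi, mpsi),
        "per_frame_regions": [classify_rama(a, b) for a, b in zip(phi, psi)],
    }


# ---------------------------------------------------------------------------
# Interface contacts, dissociation, salt bridges

@dataclass
class InterfaceReport:
    """Per-frame inter-group contact statistics."""

    contact_counts: np.ndarray        # heavy-atom pairs < cutoff per frame
    native_pairs: list                # residue pairs in contact at frame 0
    native_fraction: np.ndarray       # per frame, in [0, 1]
    cutoff: float
    salt_bridge_frames: list | None = None  # per-frame salt-bridge lists


def interface_contacts(ens: Ensemble, group_a: ChainSelection,
                       group_b: ChainSelection, cutoff: float = 4.5,
                       track_salt_bridges: bool = False) -> InterfaceReport:
    """Inter-group heavy-atom contacts per frame and the native-contact fraction.

    Native contacts are the residue pairs in contact (any heavy-atom pair
    strictly closer than ``cutoff``) at frame 0.  If frame 0 has no
    contacts, the native fraction is 0 everywhere (policy case).
    """
    f0 = ens.frames[0]
    ma, mb = group_a.mask(f0), group_b.mask(f0)
    if (ma & mb).any():
        raise ValueError("groups must be disjoint")
    heavy = np.array([not _is_hydrogen(f0, i) for i in range(f0.n_atoms)])
    ia = np.nonzero(ma & heavy)[0]
    ib = np.nonzero(mb & heavy)[0]

    res_a = [(f0.chain_ids[i], int(f0.residue_ids[i])) for i in ia]
    res_b = [(f0.chain_ids[i], int(f0.residue_ids[i])) for i in ib]

    counts = np.zeros(ens.n_frames, dtype=int)
    respair_sets = []
    for fi, frame in enumerate(ens.frames):
        d = np.linalg.norm(frame.coords[ia][:, None, :] - frame.coords[ib][None, :, :], axis=-1)
        close = d < cutoff
        counts[fi] = int(close.sum())
        pairs = {(res_a[x], res_b[y]) for x, y in zip(*np.nonzero(close))}
        respair_sets.append(pairs)

    native = sorted(respair_sets[0])
    if native:
        frac = np.array([len(s & set(native)) / len(native) for s in respair_sets])
    else:
        frac = np.zeros(ens.n_frames)
    sb = [salt_bridges(f) for f in ens.frames] if track_salt_bridges else None
    return InterfaceReport(contact_counts=counts, native_pairs=native,
                           native_fraction=frac, cutoff=cutoff,
                           salt_bridge_frames=sb)


def dissociation_frame(report: InterfaceReport, frac_threshold: float = 0.1,
                       window: int = 10) -> int | None:
    """First frame where the native fraction stays below threshold.

    Returns the first frame index ``i`` such that the native-contact
    fraction is < ``frac_threshold`` for ``window`` consecutive frames
    starting at ``i`` (or, near the trajectory end, for every remaining
    frame — a trajectory that ends dissociated reports the event);
    ``None`` if no sustained collapse occurs.
    """
    below = report.native_fraction < frac_threshold
    n = len(below)
    for i in range(n):
        if below[i:min(i + window, n)].all():
            return i
    return None


_BASIC_ATOMS = {"ARG": ("NH1", "NH2", "NE"), "LYS": ("NZ",)}
_ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}


def salt_bridges(frame: StructureModel, cutoff: float = 4.0) -> list:
    """Basic–acidic residue pairs with any N–O distance ≤ cutoff (inclusive).

    Basic groups: Arg NH1/NH2/NE, Lys NZ; acidic: Asp OD1/OD2, Glu OE1/OE2.
    Returned as ((chain, resid, resname), (chain, resid, resname)) pairs.
    """
    basics: dict = {}
    acidics: dict = {}
    for i in range(frame.n_atoms):
        rn = str(frame.residue_names[i]).upper()
        an = str(frame.atom_names[i])
        key = (frame.chain_ids[i], int(frame.residue_ids[i]), rn)
        if rn in _BASIC_ATOMS and an in _BASIC_ATOMS[rn]:
            basics.setdefault(key, []).append(i)
        elif rn in _ACIDIC_ATOMS and an in _ACIDIC_ATOMS[rn]:
            acidics.setdefault(key, []).append(i)
    out = []
    for bk, bidx in basics.items():
        for ak, aidx in acidics.items():
            d = np.linalg.norm(frame.coords[bidx][:, None, :] - frame.coords[aidx][None, :, :], axis=-1)
            if d.min() <= cutoff:
                out.append((bk, ak))
    return sorted(out)
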