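"""Configurational entropy of torsional degrees of freedom.

The solute conformational entropy is estimated nonparametrically from an
ensemble of torsion angles with the Kozachenko–Leonenko k-nearest-neighbour
estimator on the d-torus (per-angle minimum-image wrap, Euclidean norm
across dimensions), and combined across residues either as a plain sum of
per-residue joint entropies (correlations kept only within each residue)
or with the maximum-information spanning tree (MIST), which subtracts the
largest tree of pairwise mutual informations.

Entropies are computed in nats; 1 nat × R (1.987 cal mol⁻¹ K⁻¹) gives
entropy units (e.u.).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma, gammaln

from .constants import Constants, DEFAULT_CONSTANTS, R_CAL
from .model_io import TorsionSet

__all__ = [
    "EntropyEstimate",
    "MISTResult",
    "DuplicateSampleError",
    "nn_entropy",
    "residue_entropy",
    "mutual_information",
    "mist",
    "delta_s_conf",
]

TWO_PI = 2.0 * math.pi


class DuplicateSampleError(ValueError):
    """Duplicate samples give a zero nearest-neighbour distance."""


@dataclass(frozen=True)
class EntropyEstimate:
    """A differential-entropy estimate with its estimator settings.

    ``value`` is in nats; :attr:`eu` converts to cal·mol⁻¹·K⁻¹ by
    multiplying by the gas constant R = 1.987.
    """

    value: float
    k_used: int
    n_samples: int
    dimension: int
    method: str = "nn_joint"
    standard_error: float | None = None

    @property
    def eu(self) -> float:
        return self.value * R_CAL

    def minus_T_dS_kcal(self, T: float = 300.0) -> float:
        """−T·S in kcal/mol (useful when the value is already a ΔS)."""
        return -T * self.eu / 1000.0


@dataclass
class MISTResult:
    """Marginal entropies, pairwise MIs and the chosen spanning tree."""

    group_keys: list
    marginals: dict            # group key -> EntropyEstimate
    pairwise_mi: dict          # frozenset{key_a, key_b} -> raw MI (nats)
    tree_edges: list           # [(key_a, key_b, clipped MI), ...]
    combined: float            # nats

    @property
    def marginal_sum(self) -> float:
        return sum(e.value for e in self.marginals.values())


def _ball_log_volume(d: int) -> float:
    """ln of the unit d-ball volume π^{d/2} / Γ(d/2 + 1)."""
    return 0.5 * d * math.log(math.pi) - gammaln(0.5 * d + 1.0)


def _knn_distances(x: np.ndarray, k: int, jitter: bool) -> np.ndarray:
    """k-th neighbour torus distances for every sample (periodic KD-tree)."""
    x = np.mod(x, TWO_PI)
    # boxsize requires data strictly inside [0, boxsize)
    x[x >= TWO_PI] = 0.0
    tree = cKDTree(x, boxsize=TWO_PI)
    dist, _ = tree.query(x, k=k + 1, workers=-1)
    r = dist[:, k]
    if np.any(r <= 0.0):
        if not jitter:
            raise DuplicateSampleError(
                "duplicate samples (zero k-NN distance); pass jitter=True")
        rng = np.random.default_rng(0)  # deterministic jitter
        x = np.mod(x + rng.uniform(0.0, 1e-8, size=x.shape), TWO_PI)
        tree = cKDTree(x, boxsize=TWO_PI)
        dist, _ = tree.query(x, k=k + 1, workers=-1)
        r = dist[:, k]
    return r


def nn_entropy(samples: np.ndarray, k: int = 10, jitter: bool = False,
               n_bootstrap: int = 0) -> EntropyEstimate:
    """Kozachenko–Leonenko entropy of angular samples (radians), in nats.

    S = ψ(n) − ψ(k) + ln V_d + (d/n) Σ_i ln r_{i,k} with r the wrap-around
    (torus) distance to the k-th nearest neighbour and V_d the unit d-ball
    volume.  Requires ``n > k``.  ``n_bootstrap > 0`` adds a standard error
    from that many contiguous-block bootstrap replicates (10 blocks).
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, d = x.shape
    if n <= k:
        raise ValueError(f"need n > k (got n={n}, k={k})")
    r = _knn_distances(x, k, jitter)
    value = float(digamma(n) - digamma(k) + _ball_log_volume(d)
                  + d * np.mean(np.log(r)))
    se = None
    if n_bootstrap > 0:
        blocks = np.array_split(np.arange(n), 10)
        rng = np.random.default_rng(12345)
        reps = []
        for _ in range(n_bootstrap):
            idx = np.concatenate([blocks[j] for j in rng.integers(0, len(blocks), len(blocks))])
            reps.append(nn_entropy(x[idx], k=k, jitter=True).value)
        se = float(np.std(reps, ddof=1))
    return EntropyEstimate(value=value, k_used=k, n_samples=n, dimension=d,
                           method="nn_joint", standard_error=se)


def residue_entropy(ts: TorsionSet, k: int = 10, jitter: bool = False) -> EntropyEstimate:
    """Sum of per-residue joint entropies (intra-residue correlations only).

    Each residue's torsions enter one joint k-NN estimate; residues are then
    summed, i.e. inter-residue correlations are deliberately ignored — this
    can only overestimate the true joint entropy.
    """
    rad = ts.radians()
    total = 0.0
    dim = 0
    for cols in ts.residue_grouping.values():
        est = nn_entropy(rad[:, cols], k=k, jitter=jitter)
        total += est.value
        dim += est.dimension
    return EntropyEstimate(value=total, k_used=k, n_samples=ts.n_frames,
                           dimension=dim, method="residue_sum")


def mutual_information(x: np.ndarray, y: np.ndarray, k: int = 10,
                       jitter: bool = False) -> float:
    """I(x; y) = S(x) + S(y) − S(x, y) in nats (raw, may be slightly < 0).

    x and y are angle samples in radians; each may be 1-D or a column block.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.ndim == 1:
        x = x[:, None]
    if y.ndim == 1:
        y = y[:, None]
    if len(x) != len(y):
        raise ValueError("x and y must have equal sample counts")
    sx = nn_entropy(x, k=k, jitter=jitter).value
    sy = nn_entropy(y, k=k, jitter=jitter).value
    sxy = nn_entropy(np.hstack([x, y]), k=k, jitter=jitter).value
    return sx + sy - sxy


def mist(ts: TorsionSet, grouping: dict | None = None, k: int = 10,
         jitter: bool = False) -> MISTResult:
    """Maximum-information-spanning-tree entropy over torsion groups.

    All pairwise mutual informations between groups are estimated, the
    maximum-weight spanning tree is taken (MI clipped at 0 for edge
    weights; raw values retained in the report), and
    combined = Σ group entropies − Σ tree-edge MIs.
    """
    grouping = ts.residue_grouping if grouping is None else grouping
    keys = list(grouping.keys())
    if len(keys) < 2:
        raise ValueError("MIST needs at least 2 groups")
    rad = ts.radians()
    marginals = {
        key: nn_entropy(rad[:, grouping[key]], k=k, jitter=jitter) for key in keys
    }
    joint_cache: dict = {}
    pairwise: dict = {}
    G = nx.Graph()
    G.add_nodes_from(keys)
    for a in range(len(keys)):
        for b in range(a + 1, len(keys)):
            ka, kb = keys[a], keys[b]
            cols = list(grouping[ka]) + list(grouping[kb])
            sxy = nn_entropy(rad[:, cols], k=k, jitter=jitter).value
            mi = marginals[ka].value + marginals[kb].value - sxy
            pairwise[frozenset((ka, kb))] = mi
            G.add_edge(ka, kb, weight=max(mi, 0.0))
    tree = nx.maximum_spanning_tree(G, weight="weight")
    edges = [(u, v, tree[u][v]["weight"]) for u, v in tree.edges()]
    combined = sum(e.value for e in marginals.values()) - sum(w for _, _, w in edges)
    return MISTResult(group_keys=keys, marginals=marginals, pairwise_mi=pairwise,
                      tree_edges=edges, combined=float(combined))


def _entropy_by_method(ts: TorsionSet, method: str, k: int, jitter: bool) -> float:
    if method == "residue_sum":
        return residue_entropy(ts, k=k, jitter=jitter).value
    if method == "mist":
        if len(ts.residue_grouping) < 2:
            return residue_entropy(ts, k=k, jitter=jitter).value
        return mist(ts, k=k, jitter=jitter).combined
    if method == "nn_joint":
        return nn_entropy(ts.radians(), k=k, jitter=jitter).value
    raise ValueError(f"unknown method {method!r}")


def delta_s_conf(complex_ts: TorsionSet, part_ts_list: list[TorsionSet],
                 k: int = 10, method: str = "residue_sum",
                 consts: Constants = DEFAULT_CONSTANTS,
                 jitter: bool = False) -> dict:
    """Conformational entropy change of association, ΔS = S_complex − Σ S_parts.

    Returns ΔS in e.u. (cal mol⁻¹ K⁻¹) and −TΔS in kcal/mol at
    ``consts.T``.  The complex and parts must expose comparable torsion
    rosters (same total torsion count).
    """
    n_parts_torsions = sum(ts.n_torsions for ts in part_ts_list)
    if n_parts_torsions != complex_ts.n_torsions:
        raise ValueError(
            f"parts have {n_parts_torsions} torsions, complex has {complex_ts.n_torsions}")
    s_complex = _entropy_by_method(complex_ts, method, k, jitter)
    s_parts = sum(_entropy_by_method(ts, method, k, jitter) for ts in part_ts_list)
    ds_nats = s_complex - s_parts
    ds_eu = ds_nats * consts.gas_constant
    return {
        "dS_nats": float(ds_nats),
        "dS_eu": float(ds_eu),
        "minus_TdS_kcal": float(-consts.T * ds_eu / 1000.0),
        "method": method, "k": k, "T": consts.T,
    }
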