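"""Nearest-neighbour entropy, mutual information and MIST against
closed-form and quadrature truths."""

import math

import numpy as np
import pytest

from endstate import (
    EnsembleSpec, delta_s_conf, gen_torsion_ensemble, mist,
    mutual_information, nn_entropy, residue_entropy, von_mises_entropy,
)
from endstate.constants import R_CAL
from endstate.entropy_conf import DuplicateSampleError
from endstate.model_io import TorsionSet
from endstate.synthetic import _wrap_rad

LN2PI = math.log(2 * math.pi)


def _chain_spec(n_frames=5000, seed=0, kc=1.0, n_angles=6):
    return EnsembleSpec(
        n_frames=n_frames, seed=seed,
        torsion_spec=[{"kappa": 2.0, "mean_deg": -60.0}]
        + [{"kappa": 0.0, "mean_deg": 0.0}] * (n_angles - 1),
        dependency_tree=[(i, i + 1, kc) for i in range(n_angles - 1)],
    )


class TestNNEntropy:
    def test_uniform_circle(self, rng):
        x = rng.uniform(-math.pi, math.pi, size=50000)
        assert nn_entropy(x, k=10).value == pytest.approx(LN2PI, abs=0.02)

    def test_von_mises_kappa2(self, rng):
        x = rng.vonmises(0.0, 2.0, size=50000)
        assert nn_entropy(x, k=10).value == pytest.approx(von_mises_entropy(2.0), abs=0.02)
        assert von_mises_entropy(2.0) == pytest.approx(1.2663, abs=1e-4)

    def test_two_independent_uniforms(self, rng):
        x = rng.uniform(-math.pi, math.pi, size=(50000, 2))
        assert nn_entropy(x, k=10).value == pytest.approx(2 * LN2PI, abs=0.03)

    def test_wrap_around_matters(self, rng):
        """A distribution at the ±180° seam is handled by the torus metric."""
        x = _wrap_rad(rng.vonmises(math.pi, 8.0, size=20000))
        assert nn_entropy(x, k=10).value == pytest.approx(von_mises_entropy(8.0), abs=0.03)

    def test_consistency_bias_shrinks_with_n(self):
        """Mean |bias| over seeds decreases 500 → 5000 → 50000."""
        for kappa in (0.0, 2.0, 8.0):
            truth = von_mises_entropy(kappa)
            biases = []
            for n in (500, 5000, 50000):
                errs = [nn_entropy(np.random.default_rng(s).vonmises(0, kappa, n), k=10).value - truth
                        for s in range(4)]
                biases.append(abs(float(np.mean(errs))))
            assert biases[2] < 0.02
            assert biases[2] <= biases[0] + 0.005

    def test_k_robustness(self):
        ts, _ = gen_torsion_ensemble(EnsembleSpec(
            n_frames=5000, seed=1, torsion_spec=[{"kappa": 2.0, "mean_deg": 0.0}]))
        a = nn_entropy(ts.radians(), k=5).value
        b = nn_entropy(ts.radians(), k=10).value
        assert abs(a - b) < 0.05

    def test_duplicates_raise_or_jitter(self):
        x = np.zeros(100)
        with pytest.raises(DuplicateSampleError):
            nn_entropy(x, k=3)
        est = nn_entropy(x, k=3, jitter=True)  # deterministic jitter path
        assert np.isfinite(est.value)

    def test_sample_size_guard(self):
        with pytest.raises(ValueError):
            nn_entropy(np.zeros(5), k=10)

    def test_unit_conversion_exact(self, rng):
        est = nn_entropy(rng.uniform(-math.pi, math.pi, 2000), k=10)
        assert est.eu == pytest.approx(est.value * 1.987, rel=1e-12)


class TestResidueEntropy:
    def test_single_torsion_residues_equal_sum_of_marginals(self):
        ts, _ = gen_torsion_ensemble(EnsembleSpec(
            n_frames=3000, seed=2,
            torsion_spec=[{"kappa": 2.0, "mean_deg": 0.0},
                          {"kappa": 4.0, "mean_deg": 90.0}]))
        total = residue_entropy(ts, k=10).value
        rad = ts.radians()
        expect = sum(nn_entropy(rad[:, [j]], k=10).value for j in range(2))
        assert total == pytest.approx(expect, abs=1e-12)

    def test_tightly_coupled_pair_joint_below_marginal_sum(self, rng):
        """φ with χ = φ + tiny noise: joint ≈ 1-D + noise entropy, far
        below the sum of marginals."""
        n = 5000
        phi = rng.uniform(-math.pi, math.pi, n)
        chi = _wrap_rad(phi + rng.vonmises(0.0, 100.0, n))
        deg = np.rad2deg(np.column_stack([phi, chi]))
        deg[deg <= -180] = 180.0
        ts = TorsionSet(deg, [("A", 1, "phi"), ("A", 1, "chi1")], {("A", 1): [0, 1]})
        joint = residue_entropy(ts, k=10).value
        truth = LN2PI + von_mises_entropy(100.0)
        marg_sum = sum(nn_entropy(np.deg2rad(deg[:, [j]]), k=10).value for j in range(2))
        assert joint == pytest.approx(truth, abs=0.1)
        assert joint < marg_sum - 1.0

    def test_residue_sum_overestimates_coupled_truth(self):
        ts, man = gen_torsion_ensemble(_chain_spec(seed=3, kc=4.0))
        assert residue_entropy(ts, k=10).value >= man["true_joint_entropy_nats"] - 0.05


class TestMutualInformation:
    def test_independent_uniforms_near_zero(self, rng):
        x = rng.uniform(-math.pi, math.pi, 5000)
        y = rng.uniform(-math.pi, math.pi, 5000)
        assert abs(mutual_information(x, y, k=10)) < 0.02

    def test_duplicated_signal_diverges(self, rng):
        x = rng.uniform(-math.pi, math.pi, 5000)
        assert mutual_information(x, x.copy(), k=10) > 2.0

    def test_von_mises_pair_closed_form(self, rng):
        """Uniform root, child = root + VM(0, 4) noise: the child marginal
        is uniform (circular convolution), so I = ln 2π − H_vm(4), which a
        2-D quadrature of the joint confirms."""
        n = 5000
        x = rng.uniform(-math.pi, math.pi, n)
        y = _wrap_rad(x + rng.vonmises(0.0, 4.0, n))
        truth = LN2PI - von_mises_entropy(4.0)
        # quadrature check of the closed form: joint entropy = ln2π + H_vm
        from scipy.integrate import quad
        from scipy.stats import vonmises
        rv = vonmises(4.0)
        h_cond, _ = quad(lambda u: -rv.pdf(u) * math.log(rv.pdf(u)), -math.pi, math.pi)
        assert LN2PI + h_cond == pytest.approx(2 * LN2PI - truth, abs=1e-8)
        assert mutual_information(x, y, k=10) == pytest.approx(truth, abs=0.05)


class TestMIST:
    def test_independent_groups(self):
        ts, _ = gen_torsion_ensemble(EnsembleSpec(
            n_frames=5000, seed=4,
            torsion_spec=[{"kappa": 2.0, "mean_deg": 0.0}] * 3))
        res = mist(ts, k=10)
        assert res.combined == pytest.approx(res.marginal_sum, abs=0.05)
        assert all(w < 0.05 for _, _, w in res.tree_edges)

    def test_tree_truth_recovered(self):
        ts, man = gen_torsion_ensemble(_chain_spec(seed=0))
        res = mist(ts, k=10)
        assert res.combined == pytest.approx(man["true_joint_entropy_nats"], abs=0.05)

    @pytest.mark.parametrize("seed,kc", [(0, 1.0), (1, 4.0), (2, 2.0)])
    def test_mist_never_above_marginal_sum(self, seed, kc):
        ts, _ = gen_torsion_ensemble(_chain_spec(n_frames=2000, seed=seed, kc=kc))
        res = mist(ts, k=10)
        assert res.combined <= residue_entropy(ts, k=10).value + 1e-9

    def test_tree_edge_count_and_identity(self):
        ts, _ = gen_torsion_ensemble(_chain_spec(n_frames=2000, seed=5))
        res = mist(ts, k=10)
        assert len(res.tree_edges) == len(res.group_keys) - 1
        expect = res.marginal_sum - sum(w for _, _, w in res.tree_edges)
        assert res.combined == pytest.approx(expect, abs=1e-12)


class TestDeltaSConf:
    def test_identical_distributions_near_zero(self):
        a, _ = gen_torsion_ensemble(_chain_spec(n_frames=3000, seed=6))
        b, _ = gen_torsion_ensemble(_chain_spec(n_frames=3000, seed=7))
        res = delta_s_conf(a, [b], k=10)
        assert abs(res["dS_nats"]) < 0.1

    def test_stiffening_gives_negative_ds(self):
        loose = EnsembleSpec(n_frames=3000, seed=8,
                             torsion_spec=[{"kappa": 2.0, "mean_deg": 0.0}] * 4)
        tight = EnsembleSpec(n_frames=3000, seed=9,
                             torsion_spec=[{"kappa": 8.0, "mean_deg": 0.0}] * 4)
        ts_l, _ = gen_torsion_ensemble(loose)
        ts_t, _ = gen_torsion_ensemble(tight)
        res = delta_s_conf(ts_t, [ts_l], k=10)
        assert res["dS_nats"] < 0
        # von Mises entropy is monotone decreasing in κ
        assert von_mises_entropy(8.0) < von_mises_entropy(2.0)

    def test_unit_conversion_path(self):
        """ΔS = −6.7 e.u. at 300 K corresponds to −TΔS = 2.01 kcal/mol."""
        ds_eu = -6.7
        assert -300.0 * ds_eu / 1000.0 == pytest.approx(2.01, abs=1e-12)
        # the module reports the same conversion
        a, _ = gen_torsion_ensemble(_chain_spec(n_frames=2000, seed=10))
        b, _ = gen_torsion_ensemble(_chain_spec(n_frames=2000, seed=11))
        res = delta_s_conf(a, [b], k=10)
        assert res["minus_TdS_kcal"] == pytest.approx(-300.0 * res["dS_eu"] / 1000.0, rel=1e-12)
        assert res["dS_eu"] == pytest.approx(res["dS_nats"] * R_CAL, rel=1e-12)
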