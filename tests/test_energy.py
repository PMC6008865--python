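"""Solute potential and GB/SA solvation against analytic oracles."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from endstate import (
    ChainSelection, Constants, Ensemble, EnsembleSpec, StructureModel,
    ToyTopology, apolar, association_enthalpy, ensemble_enthalpy,
    frame_energy, gb_polar, gb_radii, gen_multimer_ensemble, sample_surface,
    solute_potential,
)
from endstate.constants import COULOMB_KCAL
from endstate.energy import SingularityError


def _ion(radius=2.0, charge=1.0, pos=(0.0, 0.0, 0.0)):
    m = StructureModel(["X"], ["X"], ["ION"], [1], ["A"], [pos])
    t = ToyTopology([charge], [0.0], [0.0], [radius])
    return m, t


def _pair(r, charges=(1.0, 1.0), sigma=0.0, eps=0.0, radius=1.5):
    m = StructureModel(["X", "Y"], ["X", "X"], ["ION", "ION"], [1, 2], ["A", "A"],
                       [[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
    t = ToyTopology(list(charges), [sigma] * 2, [eps] * 2, [radius] * 2)
    return m, t


class TestSolutePotential:
    def test_coulomb_unit_charges(self):
        m, t = _pair(3.32)
        rec = solute_potential(m, t)
        assert rec.U_coulomb == pytest.approx(COULOMB_KCAL / 3.32, rel=1e-12)
        assert rec.U_coulomb == pytest.approx(100.02, abs=0.01)

    @pytest.mark.parametrize("factor,expect", [(1.0, 0.0), (2 ** (1 / 6), -1.0)])
    def test_lj_root_and_minimum(self, factor, expect):
        sigma, eps = 3.4, 0.25
        m, t = _pair(factor * sigma, charges=(0.0, 0.0), sigma=sigma, eps=eps)
        rec = solute_potential(m, t)
        assert rec.U_lj == pytest.approx(expect * eps, abs=1e-10)

    def test_all_zero_parameters(self):
        m, t = _pair(5.0, charges=(0.0, 0.0))
        rec = solute_potential(m, t)
        assert rec.U_coulomb == rec.U_lj == rec.U_covalent == 0.0

    def test_excluded_pair_skipped(self):
        m, t = _pair(3.32)
        t2 = ToyTopology(t.charges, t.lj_sigma, t.lj_epsilon, t.radii,
                         exclusions=frozenset([frozenset((0, 1))]))
        assert solute_potential(m, t2).U_coulomb == 0.0

    def test_overlap_raises(self):
        m, t = _pair(0.005)
        with pytest.raises(SingularityError):
            solute_potential(m, t)


class TestSurface:
    def test_isolated_sphere_sasa(self):
        m, t = _ion(radius=1.5, charge=0.0)
        s = sample_surface(m, t, 960)
        assert s.total_area == pytest.approx(4 * math.pi * 2.9 ** 2, rel=0.02)

    def test_coincident_atoms_count_once(self):
        m = StructureModel(["X", "Y"], ["X", "X"], ["ION", "ION"], [1, 2],
                           ["A", "A"], [[0, 0, 0], [0, 0, 0]],)
        t = ToyTopology([0.0, 0.0], [0.0] * 2, [0.0] * 2, [1.5] * 2,
                        exclusions=frozenset([frozenset((0, 1))]))
        s = sample_surface(m, t, 960)
        assert s.total_area == pytest.approx(4 * math.pi * 2.9 ** 2, rel=0.02)

    def test_buried_atom_zero_sasa(self):
        m = StructureModel(["X", "Y"], ["X", "X"], ["ION", "ION"], [1, 2],
                           ["A", "A"], [[0, 0, 0], [0, 0, 0]])
        t = ToyTopology([0.0, 0.0], [0.0] * 2, [0.0] * 2, [1.0, 5.0],
                        exclusions=frozenset([frozenset((0, 1))]))
        s = sample_surface(m, t, 240)
        assert s.per_atom_area()[0] == 0.0


class TestBornRadii:
    @pytest.mark.parametrize("radius", [1.0, 2.0, 4.0])
    def test_isolated_ion_radius(self, radius):
        m, t = _ion(radius=radius)
        surf = sample_surface(m, t, 960, probe_radius=0.0)
        born = gb_radii(m, surf, topo=t)
        assert born[0] == pytest.approx(radius, rel=0.03)

    def test_burial_increases_radius(self):
        # central atom caged by six neighbours
        pos = [[0, 0, 0]] + [list(3.2 * np.eye(3)[i] * s) for i in range(3) for s in (1, -1)]
        n = len(pos)
        m = StructureModel([f"X{i}" for i in range(n)], ["X"] * n, ["ION"] * n,
                           list(range(1, n + 1)), ["A"] * n, pos)
        t = ToyTopology([0.0] * n, [0.0] * n, [0.0] * n, [1.7] * n)
        surf = sample_surface(m, t, 480, probe_radius=0.0)
        born = gb_radii(m, surf, topo=t)
        assert born[0] > 1.7 * 1.05

    def test_convergence_with_sampling_density(self):
        m, t = _pair(2.5, charges=(1.0, 0.0), radius=1.6)
        ref = gb_radii(m, sample_surface(m, t, 3840, probe_radius=0.0), topo=t)
        errs = []
        for npts in (240, 960):
            b = gb_radii(m, sample_surface(m, t, npts, probe_radius=0.0), topo=t)
            errs.append(abs(b - ref).max())
        assert errs[1] <= errs[0]


class TestGBPolar:
    @pytest.mark.parametrize("radius,charge", [(1.0, 1.0), (2.0, 1.0), (4.0, -2.0)])
    def test_born_ion_oracle(self, radius, charge):
        m, t = _ion(radius=radius, charge=charge)
        surf = sample_surface(m, t, 960, probe_radius=0.0)
        born = gb_radii(m, surf, topo=t)
        analytic = -(COULOMB_KCAL / 2) * (1 - 1 / 78.5) * charge ** 2 / radius
        assert gb_polar(m, t, born) == pytest.approx(analytic, rel=0.03)

    def test_single_ion_printed_value(self):
        m, t = _ion(radius=2.0, charge=1.0)
        assert gb_polar(m, t, np.array([2.0])) == pytest.approx(-81.96, abs=0.01)

    def test_zero_charges_zero_energy(self):
        m, t = _ion(charge=0.0)
        assert gb_polar(m, t, np.array([2.0])) == 0.0

    def test_additivity_limit_far_apart(self):
        """Pairwise GB tends to the sum of isolated Born energies; the
        residual at finite r is the screened Coulomb cross term, −k'(q²/r)."""
        m1, t1 = _ion(radius=2.0)
        single = gb_polar(m1, t1, np.array([2.0]))
        kp = COULOMB_KCAL * (1 - 1 / 78.5)
        for r in (50.0, 1e4):
            m, t = _pair(r, radius=2.0)
            pair = gb_polar(m, t, np.array([2.0, 2.0]))
            assert pair - 2 * single == pytest.approx(-kp / r, rel=1e-3)
        assert abs(-kp / 1e4) < 0.05  # vanishes in the true r → ∞ limit

    def test_always_negative_for_charged_system(self):
        m, t = _ion(radius=3.0, charge=-1.5)
        assert gb_polar(m, t, np.array([3.0])) < 0

    def test_more_polar_solvent_more_negative(self):
        m, t = _ion()
        e_water = gb_polar(m, t, np.array([2.0]), Constants(eps_out=78.5))
        e_mid = gb_polar(m, t, np.array([2.0]), Constants(eps_out=20.0))
        assert e_water < e_mid < 0


class TestApolar:
    def test_gamma_times_area(self):
        class S:  # minimal stand-in with the surface interface
            total_area = 1000.0
        assert apolar(S()) == pytest.approx(5.0)

    def test_linearity(self):
        class S:
            total_area = 123.4
        class S2:
            total_area = 246.8
        assert apolar(S2()) == pytest.approx(2 * apolar(S()))


class TestEnsembleAverages:
    def test_identical_frames_zero_sem(self, toy_multimer):
        model, topo, _ = toy_multimer
        ens = Ensemble(frames=[model.with_coords(model.coords, model_id=i) for i in (1, 2, 3)])
        res = ensemble_enthalpy(ens, topo, n_surface_points=120)
        assert res["sem"] == pytest.approx(0.0, abs=1e-12)
        single = frame_energy(model, topo, n_surface_points=120).total
        assert res["mean"] == pytest.approx(single, abs=1e-9)

    def test_two_frame_mean(self, multimer_ensemble):
        ens, topo, _ = multimer_ensemble
        two = Ensemble(frames=ens.frames[:2])
        e1 = frame_energy(ens.frames[0], topo, n_surface_points=120).total
        e2 = frame_energy(ens.frames[1], topo, n_surface_points=120).total
        res = ensemble_enthalpy(two, topo, n_surface_points=120)
        assert res["mean"] == pytest.approx((e1 + e2) / 2, abs=1e-9)


class TestAssociation:
    def test_identity_partition_zero(self, multimer_ensemble):
        ens, topo, _ = multimer_ensemble
        res = association_enthalpy(ens, topo, [ChainSelection(["A", "B", "C", "D"])],
                                   n_surface_points=120)
        assert res["dH"] == pytest.approx(0.0, abs=1e-12)

    def test_detaching_covalent_cancels_and_terms_sum(self, multimer_ensemble, sel_dimers):
        ens, topo, _ = multimer_ensemble
        res = association_enthalpy(ens, topo, sel_dimers, n_surface_points=120)
        assert res["decomposition"]["U_covalent"] == 0.0
        assert res["dH"] == pytest.approx(sum(res["decomposition"].values()), abs=1e-9)

    def test_infinite_separation_single_mode(self, toy_multimer):
        """ΔU terms of association equal the direct inter-chain sums."""
        model, topo, _ = toy_multimer
        from endstate import select
        sub_a = select(model, ChainSelection(["A"]))
        sub_b = select(model, ChainSelection(["B"]))
        mask_a = ChainSelection(["A"]).mask(model)
        topo_a = topo.subset(np.nonzero(mask_a)[0])
        mask_b = ChainSelection(["B"]).mask(model)
        topo_b = topo.subset(np.nonzero(mask_b)[0])
        complex_ab = select(model, ChainSelection(["A", "B"]))
        mask_ab = ChainSelection(["A", "B"]).mask(model)
        topo_ab = topo.subset(np.nonzero(mask_ab)[0])
        res = association_enthalpy(
            Ensemble(frames=[complex_ab]), topo_ab,
            [(Ensemble(frames=[sub_a]), topo_a), (Ensemble(frames=[sub_b]), topo_b)],
            mode="single", n_surface_points=120)
        # direct inter-chain nonbonded sums
        inter_c = inter_lj = 0.0
        na = sub_a.n_atoms
        cab = complex_ab.coords
        for i in range(na):
            for j in range(na, complex_ab.n_atoms):
                r = np.linalg.norm(cab[i] - cab[j])
                inter_c += COULOMB_KCAL * topo_ab.charges[i] * topo_ab.charges[j] / r
                sig = 0.5 * (topo_ab.lj_sigma[i] + topo_ab.lj_sigma[j])
                eps = math.sqrt(topo_ab.lj_epsilon[i] * topo_ab.lj_epsilon[j])
                sr6 = (sig / r) ** 6
                inter_lj += 4 * eps * (sr6 * sr6 - sr6)
        assert res["decomposition"]["U_coulomb"] == pytest.approx(inter_c, abs=1e-9)
        assert res["decomposition"]["U_lj"] == pytest.approx(inter_lj, abs=1e-9)
        assert res["decomposition"]["U_covalent"] == pytest.approx(0.0, abs=1e-12)

    def test_partition_error(self, multimer_ensemble):
        ens, topo, _ = multimer_ensemble
        from endstate.energy import PartitionError
        with pytest.raises(PartitionError):
            association_enthalpy(ens, topo, [ChainSelection(["A", "B"])],
                                 n_surface_points=120)


class TestRigidMotionInvariance:
    def test_all_terms_invariant(self, multimer_ensemble, rng):
        ens, topo, _ = multimer_ensemble
        m = ens.frames[0]
        e1 = frame_energy(m, topo, n_surface_points=120)
        R = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        m2 = m.with_coords(m.coords @ R.T + rng.normal(size=3) * 10)
        e2 = frame_energy(m2, topo, n_surface_points=120)
        for key, v in e1.as_dict().items():
            assert abs(v - e2.as_dict()[key]) < 1e-6, key
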