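import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from cgphase import forcefields as ff
from cgphase import topology as topo
from cgphase import energetics as en
from cgphase.units import COULOMB_KE
from conftest import assert_forces_match

AA = "ARNDCQEGHILKMFPSTWYV"


class TestBox:
    def test_minimum_image(self):
        box = en.Box((10.0, 10.0, 10.0))
        np.testing.assert_allclose(box.minimum_image(np.array([9.0, -9.0, 4.0])),
                                   [-1.0, 1.0, 4.0])

    def test_non_periodic_axis(self):
        box = en.Box((10.0, 10.0, 10.0), periodic=(True, True, False))
        np.testing.assert_allclose(box.minimum_image(np.array([9.0, 0.0, 9.0])),
                                   [-1.0, 0.0, 9.0])

    def test_invalid_lengths(self):
        with pytest.raises(en.BoxError):
            en.Box((0.0, 1.0, 1.0))


class TestPairPotential:
    def test_debye_huckel_zero_charge(self):
        assert en.evaluate_pair_potential(
            "debye_huckel", {"q1": 0.0, "q2": 1.0, "debye_length": 1.0}, 0.5
        ) == 0.0

    @pytest.mark.parametrize("form,params", [
        ("ashbaugh_hatch", {"epsilon": 0.8368, "sigma": 0.6, "lambda": 0.5}),
        ("excluded_volume", {"epsilon": 0.8368, "sigma": 0.6}),
        ("moff_contact", {"epsilon_rep": 0.8368, "sigma": 0.6,
                          "epsilon_ij": -0.4}),
    ])
    def test_zero_beyond_cutoff_and_continuous(self, form, params):
        rc = 2.0
        assert en.evaluate_pair_potential(form, params, rc + 0.1, cutoff=rc) == 0.0
        just_inside = en.evaluate_pair_potential(form, params, rc - 1e-7, cutoff=rc)
        assert abs(just_inside) < 1e-5

    def test_wang_frenkel_minimum_is_minus_epsilon(self):
        eps, sigma = 0.95, 0.55
        res = minimize_scalar(
            lambda r: en.evaluate_pair_potential(
                "wang_frenkel", {"epsilon": eps, "sigma": sigma}, r),
            bounds=(0.9 * sigma, 3 * sigma), method="bounded",
            options={"xatol": 1e-12})
        assert res.fun == pytest.approx(-eps, rel=1e-9)

    def test_wang_frenkel_vanishes_at_range(self):
        p = {"epsilon": 1.0, "sigma": 0.5}
        assert en.evaluate_pair_potential("wang_frenkel", p, 1.5) == 0.0
        assert abs(en.evaluate_pair_potential("wang_frenkel", p, 1.5 - 1e-8)) < 1e-6

    def test_unknown_form(self):
        with pytest.raises(ff.ForceFieldError):
            en.evaluate_pair_potential("lennard_jones_9_3", {}, 1.0)

    def test_nonpositive_r(self):
        with pytest.raises(ValueError):
            en.evaluate_pair_potential("excluded_volume",
                                       {"epsilon": 1.0, "sigma": 0.5}, 0.0)


class TestEnergyBreakdown:
    def test_single_free_bead(self):
        mol = topo.chain_topology("A", "HPS")
        st = en.SystemState(np.array([[5.0, 5.0, 5.0]]), np.zeros((1, 3)),
                            en.Box.cubic(10.0))
        bd, f = en.compute_energy_forces(mol, ff.load_hps("KR"), st)
        assert bd.total == 0.0
        np.testing.assert_array_equal(f, 0.0)

    def test_two_charged_beads_closed_form(self):
        mol = topo.chain_topology("K", "HPS")
        system = topo.SystemTopology(entries=[(mol, 2)])
        a = ff.load_hps("KR")
        r = 1.3
        pos = np.array([[5.0, 5.0, 5.0], [5.0, 5.0, 5.0 + r]])
        st = en.SystemState(pos, np.zeros_like(pos), en.Box.cubic(12.0))
        bd, _ = en.compute_energy_forces(system, a, st)
        table = a.pair_tables[0]
        expected_pair = en.evaluate_pair_potential(
            "ashbaugh_hatch", table.params("p:K", "p:K"), r,
            cutoff=a.pair_cutoff)
        es = a.electrostatics
        expected_dh = en.evaluate_pair_potential(
            "debye_huckel", {"q1": 1.0, "q2": 1.0, "dielectric": es.dielectric,
                             "debye_length": es.debye_length},
            r, cutoff=es.cutoff)
        assert bd.pair == pytest.approx(expected_pair, rel=1e-12)
        assert bd.electrostatic == pytest.approx(expected_dh, rel=1e-12)

    def test_total_is_sum_of_terms(self, toy_idp):
        top, a, st = toy_idp
        bd, _ = en.compute_energy_forces(top, a, st)
        s = bd.bond + bd.angle + bd.fan_bond + bd.pair + bd.electrostatic
        assert bd.total == pytest.approx(s, rel=1e-12)

    def test_overlap_raises(self):
        mol = topo.chain_topology("A", "HPS")
        system = topo.SystemTopology(entries=[(mol, 2)])
        pos = np.array([[5.0, 5.0, 5.0], [5.0, 5.0, 5.0 + 5e-5]])
        st = en.SystemState(pos, np.zeros_like(pos), en.Box.cubic(10.0))
        with pytest.raises(en.OverlapError):
            en.compute_energy_forces(system, ff.load_hps("KR"), st)


class TestForces:
    def test_finite_difference_toy_idp(self, toy_idp):
        top, a, st = toy_idp
        fn = en.make_force_callable(top, a, st.box, method="brute")
        assert_forces_match(fn, st.positions)

    def test_net_force_zero(self, toy_idp):
        top, a, st = toy_idp
        _, f = en.compute_energy_forces(top, a, st)
        scale = max(1.0, np.abs(f).max())
        np.testing.assert_allclose(f.sum(axis=0) / scale, 0.0, atol=1e-12)

    def test_translation_invariance(self, toy_idp):
        top, a, st = toy_idp
        bd1, _ = en.compute_energy_forces(top, a, st)
        st2 = st.copy()
        st2.positions += np.array([1.7, -2.3, 0.9])
        bd2, _ = en.compute_energy_forces(top, a, st2)
        assert bd2.total == pytest.approx(bd1.total, rel=1e-10)

    def test_lattice_translation_of_one_molecule(self):
        mol = topo.chain_topology("MKVE", "HPS")
        system = topo.SystemTopology(entries=[(mol, 2)])
        a = ff.load_hps("Urry")
        rng = np.random.default_rng(3)
        pos = np.vstack([topo.build_straight_chain("MKVE") + 4.0,
                         topo.build_straight_chain("MKVE") + 5.2])
        pos += rng.normal(0, 0.02, pos.shape)
        box = en.Box.cubic(10.0)
        st = en.SystemState(pos, np.zeros_like(pos), box)
        bd1, _ = en.compute_energy_forces(system, a, st, method="brute")
        st2 = st.copy()
        st2.positions[4:] += np.array([10.0, -10.0, 20.0])  # whole lattice vecs
        bd2, _ = en.compute_energy_forces(system, a, st2, method="brute")
        assert bd2.total == pytest.approx(bd1.total, rel=1e-10)


class TestNeighborList:
    def test_two_distant_beads_empty(self):
        mol = topo.chain_topology("A", "HPS")
        system = topo.SystemTopology(entries=[(mol, 2)])
        cs = en.CompiledSystem(system, ff.load_hps("KR"))
        pos = np.array([[1.0, 1.0, 1.0], [10.0, 10.0, 10.0]])
        st = en.SystemState(pos, np.zeros_like(pos), en.Box.cubic(21.0))
        nl = cs.build_neighbor_list(st, cutoff=3.5, skin=0.3)
        assert len(nl.pairs) == 0

    def test_listed_equals_brute_random_gas(self):
        mol = topo.chain_topology("K", "HPS")
        box = en.Box.cubic(12.0)
        system, pos = topo.replicate_into_box(
            mol, np.zeros((1, 3)), 200, box, 0.4, seed=8)
        st = en.SystemState(pos, np.zeros_like(pos), box)
        a = ff.load_hps("Urry")
        bd_b, f_b = en.compute_energy_forces(system, a, st, method="brute")
        bd_n, f_n = en.compute_energy_forces(system, a, st,
                                             method="neighbor_list")
        assert bd_n.total == pytest.approx(bd_b.total, rel=1e-12)
        np.testing.assert_allclose(f_n, f_b, atol=1e-10)

    def test_excluded_pairs_never_listed(self, toy_idp):
        top, a, st = toy_idp
        cs = en.CompiledSystem(top, a)
        nl = cs.build_neighbor_list(st)
        listed = {tuple(p) for p in nl.pairs}
        assert listed.isdisjoint(cs.exclusions)
        # 1-2 and 1-3 neighbors are excluded by construction
        assert (0, 1) in cs.exclusions and (0, 2) in cs.exclusions
        assert (0, 3) not in cs.exclusions

    def test_box_too_small_raises(self):
        mol = topo.chain_topology("A", "HPS")
        st = en.SystemState(np.array([[1.0, 1.0, 1.0]]), np.zeros((1, 3)),
                            en.Box.cubic(6.0))
        cs = en.CompiledSystem(topo.SystemTopology.single(mol),
                               ff.load_hps("KR"))
        with pytest.raises(en.BoxError):
            cs.build_neighbor_list(st, cutoff=3.5, skin=0.3)


def test_salt_to_zero_limit_approaches_coulomb():
    """As salt -> 0 the screened interaction tends to Coulomb / eps_r."""
    r, rc = 1.0, 50.0
    epsr = 80.0
    coulomb_trunc = COULOMB_KE / epsr * (1.0 / r - 1.0 / rc)
    errs = []
    for salt in (10.0, 0.1, 1e-4):
        ld = ff.debye_length(salt, 300.0, epsr)
        u = en.evaluate_pair_potential(
            "debye_huckel", {"q1": 1.0, "q2": 1.0, "dielectric": epsr,
                             "debye_length": ld}, r, cutoff=rc)
        errs.append(abs(u - coulomb_trunc) / coulomb_trunc)
    assert errs[0] > errs[1] > errs[2]
    assert errs[2] < 5e-3


def test_energy_breakdown_export(tmp_path, toy_idp):
    top, a, st = toy_idp
    bd, _ = en.compute_energy_forces(top, a, st)
    path = tmp_path / "energies.tsv"
    en.export_energy_breakdown([bd, bd], path)
    import pandas as pd
    df = pd.read_csv(path, sep="\t", index_col=0)
    assert df.loc[0, "total"] == pytest.approx(bd.total, abs=1e-5)
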