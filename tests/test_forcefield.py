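"""Force-field terms: closed forms, analytic forces, topology construction."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from rigidflex.forcefield import (ForceFieldParams, RestraintSpec,
                                  angle_energy, bond_energy, build_topology,
                                  go_contact_energy, repulsive_energy,
                                  restraint_energy, total_energy_forces)
from rigidflex.structure_io import Residue, Structure

PARAMS = ForceFieldParams()


class TestClosedForms:
    """Each published potential reproduces its closed form exactly."""

    @pytest.mark.parametrize("b, expected", [(3.8, 0.0), (4.8, 50.0),
                                             (2.8, 50.0)])
    def test_bond(self, b, expected):
        assert bond_energy(b, PARAMS)[0] == pytest.approx(expected, abs=1e-12)

    def test_angle(self):
        assert angle_energy(PARAMS.alpha_0, PARAMS)[0] == 0.0
        v, _ = angle_energy(PARAMS.alpha_0 + 0.5, PARAMS)
        assert v == pytest.approx(1.75 * 0.25, abs=1e-12)

    def test_repulsion(self):
        assert repulsive_energy(4.0, PARAMS)[0] == pytest.approx(2.0)
        assert repulsive_energy(8.0, PARAMS)[0] == pytest.approx(2.0 / 4096)
        grid = np.linspace(3.0, 12.0, 40)
        vals = [repulsive_energy(r, PARAMS)[0] for r in grid]
        assert np.all(np.diff(vals) < 0)
        with pytest.raises(ValueError):
            repulsive_energy(0.0, PARAMS)

    def test_go_contact(self):
        v, dv = go_contact_energy(6.0, 6.0, PARAMS)
        assert v == pytest.approx(-PARAMS.go_epsilon, abs=1e-12)
        assert dv == pytest.approx(0.0, abs=1e-12)
        far, _ = go_contact_energy(5 * 6.0, 6.0, PARAMS)
        assert abs(far) < 1e-3

    def test_sigmoid_restraint(self):
        assert restraint_energy(25.0, PARAMS)[0] == pytest.approx(5.0)
        near_zero, _ = restraint_energy(0.0, PARAMS)
        assert near_zero == pytest.approx(10.0 / (1 + np.exp(12.5)), rel=1e-9)
        assert near_zero < 1e-4
        # force decays to ~zero far beyond the bound
        _, force_far = restraint_energy(50.0, PARAMS)
        assert abs(force_far) < 1e-4

    @pytest.mark.parametrize("fn, x", [
        (lambda v, p: bond_energy(v, p), 4.3),
        (lambda v, p: angle_energy(v, p), 1.1),
        (lambda v, p: repulsive_energy(v, p), 5.2),
        (lambda v, p: go_contact_energy(v, 6.0, p), 6.7),
        (lambda v, p: restraint_energy(v, p), 27.0),
    ])
    def test_scalar_derivatives_match_finite_difference(self, fn, x):
        h = 1e-6
        _, dv = fn(x, PARAMS)
        fd = (fn(x + h, PARAMS)[0] - fn(x - h, PARAMS)[0]) / (2 * h)
        assert dv == pytest.approx(fd, rel=1e-6, abs=1e-9)


class TestBuildTopology:
    def _chain_structure(self, present):
        res = [Residue(i, "ALA",
                       np.array([3.8 * i, 0.0, 0.0]) if i in present else None)
               for i in range(1, 11)]
        return Structure(chains=["A"], residues={"A": res})

    def test_counting_with_internal_gap(self):
        st = self._chain_structure(present={1, 2, 3, 7, 8, 9, 10})
        topo = build_topology(st, {"A": (1, 10)})
        assert topo.n_beads == 10
        assert int(topo.flexible.sum()) == 3
        assert len(topo.bond_ij) == 9
        # angle terms only on consecutive triples touching residues 4-6
        expected_triples = {(1, 2, 3), (2, 3, 4), (3, 4, 5), (4, 5, 6),
                            (5, 6, 7)}  # 0-based starts
        got = {tuple(t) for t in topo.angle_ijk}
        assert got == expected_triples

    def test_native_contacts_match_double_loop(self, core_topology):
        ref = core_topology.reference
        keys = core_topology.keys
        expected = set()
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                if abs(keys[j][1] - keys[i][1]) < 3:
                    continue
                if np.linalg.norm(ref[i] - ref[j]) <= PARAMS.go_cutoff:
                    expected.add((i, j))
        assert {tuple(c) for c in core_topology.contact_ij} == expected
        assert int(core_topology.flexible.sum()) == 0

    def test_empty_chain_errors(self):
        st = self._chain_structure(present=set(range(1, 11)))
        with pytest.raises(ValueError, match="zero residues"):
            build_topology(st, {"A": (5, 4)})

    def test_flexible_override(self):
        st = self._chain_structure(present=set(range(1, 11)))
        topo = build_topology(st, {"A": (1, 10)},
                              flexible_override={"A": [(4, 6)]})
        assert int(topo.flexible.sum()) == 3


class TestTotalEnergyForces:
    def test_forces_are_negative_gradient(self, toy_topology, rng):
        """Central finite differences across random configurations."""
        from rigidflex.engine import initialize_flexible

        base = initialize_flexible(toy_topology, seed=8)
        restraints = [RestraintSpec(index=1, i=0, j=70)]
        h = 1e-5
        for _ in range(25):
            x = base + rng.normal(0, 0.2, base.shape)
            _, f = total_energy_forces(toy_topology, x, restraints)
            for _ in range(4):
                i = rng.integers(toy_topology.n_beads)
                d = rng.integers(3)
                xp, xm = x.copy(), x.copy()
                xp[i, d] += h
                xm[i, d] -= h
                ep, _ = total_energy_forces(toy_topology, xp, restraints)
                em, _ = total_energy_forces(toy_topology, xm, restraints)
                fd = -(ep - em) / (2 * h)
                assert f[i, d] == pytest.approx(fd, rel=1e-5, abs=1e-5)

    def test_energy_invariant_under_rigid_motion(self, toy_topology):
        from rigidflex.engine import initialize_flexible

        x = initialize_flexible(toy_topology, seed=2)
        e0, _ = total_energy_forces(toy_topology, x)
        rot = Rotation.random(random_state=11).as_matrix()
        e1, _ = total_energy_forces(toy_topology,
                                    x @ rot.T + np.array([5.0, -3.0, 12.0]))
        assert e1 == pytest.approx(e0, abs=1e-8)

    def test_restraint_additivity(self, core_topology):
        x = core_topology.reference.copy()
        e0, _ = total_energy_forces(core_topology, x)
        spec = RestraintSpec(index=1, i=0, j=59)
        l = float(np.linalg.norm(x[0] - x[59]))
        e1, _ = total_energy_forces(core_topology, x, [spec])
        assert e1 - e0 == pytest.approx(restraint_energy(l, PARAMS)[0],
                                        abs=1e-10)

    def test_core_energy_is_pure_go_sum(self, core_topology):
        """With no flexible beads and no restraints the total reduces to
        the Gō core terms, reproduced by an independent per-term loop."""
        x = core_topology.reference.copy()
        total, _ = total_energy_forces(core_topology, x)
        manual = 0.0
        for (i, j), b0 in zip(core_topology.bond_ij, core_topology.bond_b0):
            b = float(np.linalg.norm(x[i] - x[j]))
            manual += PARAMS.k_b * (b - b0) ** 2
        for (i, j), r0 in zip(core_topology.contact_ij,
                              core_topology.contact_r0):
            manual += go_contact_energy(float(np.linalg.norm(x[i] - x[j])),
                                        r0, PARAMS)[0]
        for i, j in core_topology.nonbonded_ij:
            r = float(np.linalg.norm(x[i] - x[j]))
            if r < PARAMS.nonbonded_cutoff:
                manual += repulsive_energy(r, PARAMS)[0]
        assert len(core_topology.angle_ijk) == 0
        assert total == pytest.approx(manual, abs=1e-9)

    def test_relaxed_core_is_near_stationary(self, core_topology):
        from scipy.optimize import minimize

        def fun(flat):
            e, f = total_energy_forces(core_topology, flat.reshape(-1, 3))
            return e, -f.ravel()

        res = minimize(fun, core_topology.reference.ravel(), jac=True,
                       method="L-BFGS-B",
                       options={"gtol": 1e-10, "ftol": 1e-16,
                                "maxiter": 20000})
        _, f = total_energy_forces(core_topology, res.x.reshape(-1, 3))
        assert np.abs(f).max() < 1e-5

    def test_shape_and_nan_errors(self, core_topology):
        with pytest.raises(ValueError, match="shape"):
            total_energy_forces(core_topology, np.zeros((3, 3)))
        bad = core_topology.reference.copy()
        bad[5, 1] = np.nan
        with pytest.raises(FloatingPointError):
            total_energy_forces(core_topology, bad)


def test_params_validation():
    with pytest.raises(ValueError):
        ForceFieldParams(k_b=-1.0)
    with pytest.raises(ValueError):
        ForceFieldParams(n_active=0)


def test_topology_json_round_trip(tmp_path, toy_topology):
    p = tmp_path / "topo.json"
    toy_topology.to_json(p)
    back = __import__("rigidflex.forcefield", fromlist=["CGTopology"]) \
        .CGTopology.from_json(p)
    assert back.keys == toy_topology.keys
    np.testing.assert_array_equal(back.flexible, toy_topology.flexible)
    np.testing.assert_array_equal(back.bond_ij, toy_topology.bond_ij)
    np.testing.assert_allclose(back.contact_r0, toy_topology.contact_r0)
    from rigidflex.engine import initialize_flexible
    x = initialize_flexible(toy_topology, seed=4)
    e1, _ = total_energy_forces(toy_topology, x)
    e2, _ = total_energy_forces(back, x)
    assert e1 == pytest.approx(e2, abs=1e-12)
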