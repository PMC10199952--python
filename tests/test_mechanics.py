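"""Mechanics: pair energies vs finite-difference oracles, force assembly,
overdamped integration, growth and division."""

import math

import numpy as np
import pytest

import morphosim.mechanics as M
from morphosim.mechanics import (INTERNAL, MEMBRANE, CellPhase, CellState,
                                 MechParams, MorseParams, NodeSet, PairCache,
                                 SpringParams, StabilityError, pair_energy,
                                 step_mechanics, total_energy, total_forces)

from conftest import single_cell


def fd_force(cls, r, params, h=1e-6):
    """Central-difference force oracle: -dU/dr from the energy alone."""
    up, _ = pair_energy(cls, r + h, params)
    um, _ = pair_energy(cls, r - h, params)
    return -(up - um) / (2 * h)


# Morse classes with an explicit parameter set used in examples: U0=1, xi=0.2
_EX = MechParams(adh=MorseParams(1.0, 0.5, 0.2, 2.0))


class TestPairEnergy:
    @pytest.mark.parametrize("cls,r_zero", [
        ("II", MechParams().ii.r_eq),
        ("MI", MechParams().mi.r_eq),
        ("Adh", MechParams().adh.r_eq),
        ("MMS", MechParams().mms.l0),
    ])
    def test_zero_force_at_equilibrium(self, cls, r_zero):
        _, f = pair_energy(cls, r_zero, MechParams())
        assert abs(float(f)) < 1e-12

    def test_repulsion_below_equilibrium(self):
        # Morse with U0=1, xi=0.2 at r = 0.9 r_eq: positive (repulsive) force
        _, f = pair_energy("Adh", 0.9 * 0.5, _EX)
        assert float(f) > 0

    @pytest.mark.parametrize("cls", ["II", "MI", "Adh", "MMD", "MMS"])
    def test_force_matches_energy_gradient(self, cls):
        """force = -dU/dr to 1e-6 over a grid of separations."""
        p = _EX if cls == "Adh" else MechParams()
        spec = getattr(p, cls.lower()) if cls != "MMS" else p.mms
        r_ref = spec.l0 if cls == "MMS" else spec.r_eq
        for r in np.linspace(0.5 * r_ref, 1.8 * r_ref, 23):
            if cls != "MMS" and abs(r - spec.cutoff) < 1e-3:
                continue    # energy is truncated at the cutoff
            if spec_has_kink(cls, spec, r):
                continue
            _, f = pair_energy(cls, r, p)
            assert float(f) == pytest.approx(fd_force(cls, r, p), abs=1e-6)

    def test_mmd_is_repulsive_only(self):
        p = MechParams()
        r = np.linspace(p.mmd.r_eq, 3 * p.mmd.r_eq, 11)
        u, f = pair_energy("MMD", r, p)
        assert np.all(u == 0) and np.all(f == 0)
        _, f_in = pair_energy("MMD", 0.5 * p.mmd.r_eq, p)
        assert float(f_in) > 0

    def test_unknown_class_rejected(self):
        with pytest.raises(Exception):
            pair_energy("XX", 1.0, MechParams())

    def test_negative_separation_rejected(self):
        with pytest.raises(ValueError):
            pair_energy("II", -0.1, MechParams())


def spec_has_kink(cls, spec, r):
    """Skip finite differencing across the repulsive-only truncation point."""
    return getattr(spec, "repulsive_only", False) and abs(r - spec.r_eq) < 1e-3


class TestTotalForces:
    def test_isolated_node_feels_nothing(self):
        nodes = NodeSet([[0.0, 0.0]], [INTERNAL], [0], [-1])
        f = total_forces(nodes, MechParams())
        assert np.allclose(f, 0)

    def test_internal_pair_at_equilibrium(self):
        p = MechParams()
        r = p.ii.r_eq
        nodes = NodeSet([[0, 0], [r, 0]], [INTERNAL, INTERNAL], [0, 0], [-1, -1])
        f = total_forces(nodes, p)
        assert np.allclose(f, 0, atol=1e-12)

    def test_forces_equal_numerical_energy_gradient(self):
        """On a 5-node toy cell every force component equals the negative
        gradient of the total energy to 1e-6 (central differences)."""
        pos = np.array([[0.0, 0.0], [0.9, 0.1], [0.5, 0.8],
                        [-0.4, 0.7], [-0.2, -0.6]])
        nodes = NodeSet(pos, [INTERNAL, MEMBRANE, MEMBRANE, MEMBRANE, MEMBRANE],
                        [0] * 5, [-1, 0, 1, 2, 3])
        p = MechParams()
        f = total_forces(nodes, p)
        h = 1e-7
        for i in range(5):
            for k in range(2):
                for sgn, store in ((+1, "up"), (-1, "dn")):
                    nn = nodes.copy()
                    nn.pos[i, k] += sgn * h
                    if sgn > 0:
                        e_up = total_energy(nn, p)
                    else:
                        e_dn = total_energy(nn, p)
                assert f[i, k] == pytest.approx(-(e_up - e_dn) / (2 * h), abs=1e-5)

    def test_newtons_third_law_net_zero(self, honeycomb):
        nodes, cells = honeycomb
        f = total_forces(nodes, MechParams(), cells)
        assert np.allclose(f.sum(axis=0), 0, atol=1e-9)


class TestStepMechanics:
    def test_zero_force_leaves_positions(self):
        p = MechParams()
        r = p.ii.r_eq
        nodes = NodeSet([[0, 0], [r, 0]], [INTERNAL, INTERNAL], [0, 0], [-1, -1])
        before = nodes.pos.copy()
        step_mechanics(nodes, p)
        assert np.allclose(nodes.pos, before)

    def test_spring_pair_matches_overdamped_closed_form(self):
        """Two membrane nodes under a pure spring relax toward l0 like
        x(t) = l0 + (x0 - l0) exp(-2kt/eta); the discrete trajectory matches
        to first order in dt."""
        k, l0, eta = 4.0, 1.0, 1.0
        p = MechParams(mms=SpringParams(k, l0),
                       mi=MorseParams(0.0, 0.5, 0.2, 0.01),
                       mmd=MorseParams(0.0, 0.1, 0.1, 0.01),
                       adh=MorseParams(0.0, 0.1, 0.1, 0.01),
                       dt_mech=1e-3)
        x0 = 1.5
        nodes = NodeSet([[0, 0], [x0, 0]], [MEMBRANE, MEMBRANE], [0, 0], [0, 1])
        cache = PairCache()
        n_steps = 400
        for _ in range(n_steps):
            step_mechanics(nodes, p, cache=cache)
        t = n_steps * p.dt_mech
        sep = nodes.pos[1, 0] - nodes.pos[0, 0]
        expected = l0 + (x0 - l0) * math.exp(-2 * k * t / eta)
        assert sep == pytest.approx(expected, rel=5e-3)

    def test_center_of_mass_fixed_under_internal_forces(self, honeycomb):
        nodes, cells = honeycomb
        com0 = nodes.pos.mean(axis=0)
        p = MechParams(dt_mech=5e-4)
        cache = PairCache()
        for _ in range(20):
            step_mechanics(nodes, p, cells, cache)
        assert np.allclose(nodes.pos.mean(axis=0), com0, atol=1e-9)

    def test_displacement_guard_raises(self):
        p = MechParams(dt_mech=50.0)   # absurd step
        nodes, _ = single_cell()
        with pytest.raises(StabilityError):
            step_mechanics(nodes, p)


class TestRelaxation:
    def test_isolated_cell_relaxes_to_near_disc(self):
        """A perturbed polygonal cell reaches an isoperimetric ratio within
        5% of a disc at mechanical equilibrium."""
        import morphosim.io as io
        rng = np.random.default_rng(1)
        nodes, cells = io.make_initial_tissue(1, rng=rng, relax_steps=0)
        M.relax(nodes, MechParams(), 4000, cells)
        assert M.isoperimetric_ratio(nodes, 0) > 0.95


class TestGrowth:
    def test_zero_rate_adds_nothing(self, rng):
        nodes, cell = single_cell()
        cell.g = 0.0
        n0 = len(nodes)
        M.grow_cell(cell, nodes, MechParams(), 100.0, rng)
        assert len(nodes) == n0

    def test_doubling_time_is_inverse_rate(self):
        """With rate anchored to the birth count, the expected time for the
        internal count to double is 1/g (linear node addition)."""
        g = 1.1e-4
        times = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            nodes, cell = single_cell(n_internal=20)
            cell.g = g
            cell.n_internal_birth = 20
            p = MechParams(growth_cap_factor=2.0)
            t, dt = 0.0, 50.0
            while len(nodes.nodes_of(0, INTERNAL)) < 40 and t < 5 / g:
                M.grow_cell(cell, nodes, p, dt, rng)
                t += dt
            times.append(t)
        assert np.mean(times) == pytest.approx(1.0 / g, rel=0.15)

    def test_growth_deterministic_under_seed(self):
        out = []
        for _ in range(2):
            rng = np.random.default_rng(7)
            nodes, cell = single_cell(n_internal=10)
            cell.g = 0.01
            cell.n_internal_birth = 10
            for _ in range(200):
                M.grow_cell(cell, nodes, MechParams(), 1.0, rng)
            out.append(nodes.pos.copy())
        assert np.array_equal(out[0], out[1])

    def test_internal_count_never_decreases(self, rng):
        nodes, cell = single_cell(n_internal=5)
        cell.g = 0.05
        cell.n_internal_birth = 5
        prev = 5
        for _ in range(100):
            M.grow_cell(cell, nodes, MechParams(), 1.0, rng)
            cur = len(nodes.nodes_of(0, INTERNAL))
            assert cur >= prev
            prev = cur


class TestDivision:
    def _mature_cell(self, rng, n_internal=20):
        nodes, cell = single_cell(n_mem=16, n_internal=n_internal, radius=1.2)
        cell.n_internal_birth = n_internal // 2
        return nodes, cell

    def test_unflagged_cell_unchanged(self, rng):
        nodes, cell = self._mature_cell(rng)
        out = M.advance_cycle_and_divide(cell, nodes, False, 0.0,
                                         MechParams(), rng, next_cell_id=1)
        assert out == [cell] and cell.phase == CellPhase.INTERPHASE

    def test_split_conserves_internal_nodes_and_area(self, rng):
        nodes, cell = self._mature_cell(rng, n_internal=20)
        p = MechParams(mitotic_duration=5.0)
        area0 = M.cell_polygon_area(nodes, 0)
        out = M.advance_cycle_and_divide(cell, nodes, True, 0.0, p, rng, 1)
        assert cell.phase == CellPhase.MITOTIC
        out = M.advance_cycle_and_divide(cell, nodes, False, 10.0, p, rng, 1)
        assert len(out) == 2
        d0, d1 = out
        n0 = len(nodes.nodes_of(d0.cell_id, INTERNAL))
        n1 = len(nodes.nodes_of(d1.cell_id, INTERNAL))
        assert n0 + n1 == 20
        a0 = M.cell_polygon_area(nodes, d0.cell_id)
        a1 = M.cell_polygon_area(nodes, d1.cell_id)
        assert 0.35 * area0 <= a0 <= 0.65 * area0
        assert 0.35 * area0 <= a1 <= 0.65 * area0
        assert (a0 + a1) == pytest.approx(area0, rel=0.10)
        nodes.validate()

    def test_daughters_inherit_generation_and_decayed_rate(self, rng):
        nodes, cell = self._mature_cell(rng)
        cell.generation = 3
        cell.g = 0.01
        p = MechParams(mitotic_duration=0.0, generation_decay=0.9)
        M.advance_cycle_and_divide(cell, nodes, True, 0.0, p, rng, 1)
        out = M.advance_cycle_and_divide(cell, nodes, False, 0.0, p, rng, 1)
        assert len(out) == 2
        for d in out:
            assert d.generation == 4
            assert d.g == pytest.approx(0.01 * 0.9)
            assert d.dpp_div_memory < 0   # fresh memory

    def test_too_few_internal_nodes_refused(self, rng):
        nodes, cell = single_cell(n_internal=1)
        out = M.advance_cycle_and_divide(cell, nodes, True, 0.0,
                                         MechParams(), rng, 1)
        assert out == [cell] and cell.phase == CellPhase.INTERPHASE


class TestNodeSetInvariants:
    def test_validate_accepts_good_cell(self):
        nodes, _ = single_cell()
        nodes.validate()

    def test_validate_rejects_open_membrane(self):
        nodes, _ = single_cell(n_mem=12)
        nodes.membrane_order[nodes.membrane_order == 5] = 7   # break the cycle
        with pytest.raises(ValueError):
            nodes.validate()

    def test_constant_node_count_without_growth(self, honeycomb):
        nodes, cells = honeycomb
        n0 = len(nodes)
        cache = PairCache()
        for _ in range(200):
            step_mechanics(nodes, MechParams(), cells, cache, clip=True)
        assert len(nodes) == n0
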