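"""Constant-pH sampler: acceptance rule, bookkeeping, dynamics."""

import math

import numpy as np
import pytest

import ampholyte.engine as eng
from ampholyte.engine import (
    ConstantPHSimulation,
    ProtocolConfig,
    SystemState,
    acceptance_probability,
    run_constant_pH,
)
from ampholyte.forcefield import ForceFieldParams

from ampholyte.observables import correlated_error
from ampholyte.synthetic import initial_configuration, make_scenario


# -- acceptance probability ---------------------------------------------------

@pytest.mark.parametrize(
    "dU, pH, pKA, xi, expected",
    [
        (0.0, 7.0, 7.0, +1, 1.0),
        (0.0, 8.0, 7.0, -1, 0.1),
        (math.log(10.0), 8.0, 7.0, +1, 1.0),
        (2.0, 7.0, 7.0, +1, math.exp(-2.0)),
    ],
)
def test_acceptance_probability_values(dU, pH, pKA, xi, expected):
    assert acceptance_probability(dU, pH, pKA, xi) == pytest.approx(expected, rel=1e-12)


def test_acceptance_probability_rejects_bad_direction():
    with pytest.raises(ValueError):
        acceptance_probability(0.0, 7.0, 7.0, 0)


# -- reaction-move bookkeeping ------------------------------------------------

def _fresh_sim(seed=0, pH=7.0, ff=None, cycles=10):
    sc = make_scenario("Lys5-Asp5", "KKKKKDDDDD", n_chains=1)
    ff = ff or ForceFieldParams()
    topo = sc.build_topology()
    state = initial_configuration(sc, rng=seed, ff=ff)
    cfg = ProtocolConfig(pH=pH, seed=seed, cycles=cycles)
    return topo, state, ConstantPHSimulation(topo, state, ff, cfg)


def test_reaction_move_delta_energy_matches_total_energy(monkeypatch):
    """Incremental dU of every accepted proposal equals the full-energy change."""
    topo, state, sim = _fresh_sim(seed=5)
    captured = []

    def capture(dU, pH, pKA, xi):
        captured.append(dU)
        return 1.0  # force acceptance to exercise both directions

    monkeypatch.setattr(eng, "acceptance_probability", capture)
    for _ in range(25):
        e_before = sim.potential_energy()
        accepted = sim.reaction_move()
        e_after = sim.potential_energy()
        if accepted:
            assert captured[-1] == pytest.approx(e_after - e_before, abs=1e-9)


def test_electroneutrality_and_h_count_after_every_move():
    topo, state, sim = _fresh_sim(seed=6, pH=7.0)
    for _ in range(200):
        sim.reaction_move()
        assert state.total_charge(topo) == pytest.approx(0.0, abs=1e-12)
        # H+ inventory identity (fully protonated reference, offset 0)
        n_ia = int(state.ionised[topo.acid_sites].sum())
        n_nb = int((~state.ionised[topo.base_sites]).sum())
        assert state.n_h == n_ia + n_nb


def test_rejected_move_restores_state():
    topo, state, sim = _fresh_sim(seed=7, pH=-20.0)  # deprotonation never accepted
    before_q = sim.q.copy()
    before_ion = state.ionised.copy()
    before_nh = state.n_h
    rejected_seen = 0
    for _ in range(50):
        if not sim.reaction_move():
            rejected_seen += 1
            np.testing.assert_array_equal(sim.q, before_q)
            np.testing.assert_array_equal(state.ionised, before_ion)
            assert state.n_h == before_nh
        else:  # accepted protonations do change the state; re-baseline
            before_q = sim.q.copy()
            before_ion = state.ionised.copy()
            before_nh = state.n_h
    assert rejected_seen > 0


def test_single_site_two_state_statistics(ff_ideal):
    """Non-interacting single acid reproduces the two-state partition function."""
    sc = make_scenario("single-acid", "D", n_chains=1)
    topo = sc.build_topology()
    for dpH, expected in [(0.0, 0.5), (1.0, 10.0 / 11.0)]:
        state = initial_configuration(sc, rng=3, ff=ff_ideal)
        cfg = ProtocolConfig(
            pH=3.65 + dpH, seed=11, cycles=4000, md_steps_per_cycle=5
        )
        res = run_constant_pH(topo, state, ff_ideal, cfg, record_energy=False)
        mean, se, _ = correlated_error(res.production("alpha_acid"))
        assert mean == pytest.approx(expected, abs=3 * max(se, 1e-3))


# -- Langevin dynamics --------------------------------------------------------

def test_velocity_verlet_conserves_energy_without_thermostat(ff_ideal):
    """gamma = 0, no noise: the symplectic integrator drifts only at O(dt^2)."""
    sc = make_scenario("dimer", "a", n_chains=1)
    topo = sc.build_topology()
    state = initial_configuration(sc, rng=1, ff=ff_ideal)
    # stretch the bond slightly and give no velocities
    state.velocities[:] = 0.0
    state.positions[1] = state.positions[0] + np.array([0.40, 0.0, 0.0])
    cfg = ProtocolConfig(pH=6.0, seed=1, gamma=0.0, cycles=1)
    sim = ConstantPHSimulation(topo, state, ff_ideal, cfg)
    n = sim.n
    e0 = sim.potential_energy() + 0.5 * float(np.sum(state.velocities[:n] ** 2))
    for _ in range(100):
        sim.run_md(100)
    e1 = sim.potential_energy() + 0.5 * float(np.sum(state.velocities[:n] ** 2))
    assert e1 == pytest.approx(e0, abs=5e-3)  # ~ (kh/2) (dt^2-level error)


def test_thermostat_equipartition(ff_ideal):
    """Free-particle ensemble at gamma=1: <v_a^2> -> kBT/m = 1."""
    sc = make_scenario("ideal-gas", "ab", n_chains=4)
    topo = sc.build_topology()
    state = initial_configuration(sc, rng=2, ff=ff_ideal)
    cfg = ProtocolConfig(pH=6.0, seed=3, cycles=1, reaction_moves_per_cycle=0)
    sim = ConstantPHSimulation(topo, state, ff_ideal, cfg)
    n = sim.n
    state.velocities[:n] = sim.rng.standard_normal((n, 3))
    samples = []
    for _ in range(300):
        sim.run_md(20)
        samples.append((state.velocities[:n] ** 2).mean())
    v2 = float(np.mean(samples[50:]))
    assert v2 == pytest.approx(1.0, rel=0.05)


def test_fixed_seed_bit_reproducibility(ff_default):
    sc = make_scenario("Lys5-Asp5", "KKKKKDDDDD", n_chains=1)
    topo = sc.build_topology()

    def one_run():
        state = initial_configuration(sc, rng=9, ff=ff_default)
        cfg = ProtocolConfig(pH=7.0, seed=21, cycles=30)
        return run_constant_pH(topo, state, ff_default, cfg, record_energy=True)

    r1, r2 = one_run(), one_run()
    for key in r1.series:
        np.testing.assert_array_equal(r1.series[key], r2.series[key])


def test_run_result_hdf5_roundtrip(tmp_path, ff_ideal):
    sc = make_scenario("tiny", "ab", n_chains=1)
    topo = sc.build_topology()
    state = initial_configuration(sc, rng=0, ff=ff_ideal)
    cfg = ProtocolConfig(pH=6.0, seed=0, cycles=20, md_steps_per_cycle=5)
    res = run_constant_pH(topo, state, ff_ideal, cfg)
    path = tmp_path / "run.h5"
    res.to_hdf5(path)
    back = eng.RunResult.from_hdf5(path)
    assert back.cfg == res.cfg
    for key in res.series:
        np.testing.assert_array_equal(back.series[key], res.series[key])


def test_protocol_config_validation():
    with pytest.raises(ValueError):
        ProtocolConfig(cycles=0)
    with pytest.raises(ValueError):
        ProtocolConfig(equilibration_fraction=1.0)


def test_functional_wrappers_and_xyz_dump(tmp_path, ff_ideal):
    """reaction_move/langevin_step wrappers mutate the state; XYZ frames parse."""
    from ampholyte.engine import langevin_step, reaction_move

    sc = make_scenario("tiny", "ab", n_chains=1)
    topo = sc.build_topology()
    state = initial_configuration(sc, rng=4, ff=ff_ideal)
    rng = np.random.default_rng(0)
    flips = sum(
        reaction_move(state, topo, ff_ideal, pH=6.0, rng=rng)[1] for _ in range(40)
    )
    assert flips > 0
    before = state.positions.copy()
    langevin_step(state, topo, ff_ideal, ProtocolConfig(pH=6.0, seed=1), rng)
    assert not np.array_equal(before, state.positions)

    state = initial_configuration(sc, rng=4, ff=ff_ideal)
    xyz = tmp_path / "traj.xyz"
    run_constant_pH(
        topo, state, ff_ideal,
        ProtocolConfig(pH=6.0, seed=2, cycles=30, md_steps_per_cycle=5),
        xyz_path=xyz, xyz_every=10,
    )
    lines = xyz.read_text().splitlines()
    # frames have varying particle counts (the free H+ pool fluctuates)
    i = n_frames = 0
    while i < len(lines):
        n_frame = int(lines[i])
        assert lines[i + 1].startswith("cycle=")
        el, x, y, z = lines[i + 2].split()
        assert el == "C"
        float(x), float(y), float(z)
        i += n_frame + 2
        n_frames += 1
    assert n_frames == 3


def test_topology_debug_table_lists_beads_and_bonds():
    from ampholyte.synthetic import make_scenario

    topo = make_scenario("t", "KD", n_chains=1).build_topology()
    text = topo.debug_table()
    assert "# bond_i" in text
    assert text.count("\n") >= topo.n_slots + len(topo.bonds)
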