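"""Residue table, topology construction, and interaction potentials."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ampholyte.forcefield import (
    ForceFieldParams,
    coulomb_energy,
    forces,
    harmonic_energy,
    total_energy,
    wca_energy,
)
from ampholyte.residues import DEFAULT_RESIDUES, load_residue_table, write_residue_table
from ampholyte.topology import (
    BOND_LENGTH_CC,
    PeptideSpec,
    build_topology,
)


# -- residue registry ---------------------------------------------------------

REFERENCE_ROWS = {
    "D": (3.65, 0.327, "acid"),
    "E": (4.25, 0.436, "acid"),
    "H": (6.00, 0.453, "base"),
    "Y": (10.07, 0.648, "acid"),
    "K": (10.54, 0.589, "base"),
    "a": (6.00, 0.355, "acid"),
    "b": (6.00, 0.355, "base"),
}


def test_builtin_registry_matches_reference_parameters():
    assert set(DEFAULT_RESIDUES) == set(REFERENCE_ROWS)
    for code, (pka, blen, kind) in REFERENCE_ROWS.items():
        res = DEFAULT_RESIDUES[code]
        assert res.pKA == pka
        assert res.bond_length_sidechain == blen
        assert res.group_type == kind
        assert res.ionized_valency == (-1 if kind == "acid" else +1)


def test_shipped_table_roundtrip(tmp_path):
    table = load_residue_table()
    assert table == dict(DEFAULT_RESIDUES)
    out = tmp_path / "residues.tsv"
    write_residue_table(table, out)
    assert load_residue_table(out) == table


# -- topology -----------------------------------------------------------------

def test_topology_counts_diblock():
    topo = build_topology(PeptideSpec("KKKKKDDDDD"))
    assert topo.n_peptide_beads == 20
    cc = [m for m in range(len(topo.bond_b0)) if topo.bond_b0[m] == BOND_LENGTH_CC]
    side = [m for m in range(len(topo.bond_b0)) if topo.bond_b0[m] != BOND_LENGTH_CC]
    assert len(cc) == 9 and len(side) == 10
    assert topo.n_sites == 10
    assert len(topo.acid_sites) == 5 and len(topo.base_sites) == 5


def test_topology_single_hypothetical_residue():
    topo = build_topology(PeptideSpec("a"))
    assert topo.n_peptide_beads == 2
    assert len(topo.bonds) == 1
    assert topo.bond_b0[0] == pytest.approx(0.355)


def test_topology_ordering_chain_major_backbone_first():
    topo = build_topology(PeptideSpec("KD", n_chains=2))
    # chain 0: C0 A/B1 C2 A/B3; chain 1 follows
    assert list(topo.chain[:4]) == [0, 0, 0, 0]
    assert list(topo.chain[4:]) == [1, 1, 1, 1]
    assert list(topo.kind[::2]) == [0, 0, 0, 0]  # backbone at even indices


def test_topology_rejects_bad_input():
    with pytest.raises(ValueError):
        build_topology(PeptideSpec(""))
    with pytest.raises(KeyError, match="X"):
        build_topology(PeptideSpec("KXD"))


def test_spec_helpers_reproduce_reference_patterns():
    assert PeptideSpec.diblock("D", "K", 5).sequence == "KKKKKDDDDD"
    assert PeptideSpec.alternating("D", "K", 5).sequence == "KDKDKDKDKD"
    assert PeptideSpec.diblock("Y", "H", 5, acid_first=True).sequence == "YYYYYHHHHH"
    assert PeptideSpec.alternating("a", "b", 5, acid_first=True).sequence == "ababababab"


def test_with_ions_slots_and_charges():
    topo = build_topology(PeptideSpec("KKKKKDDDDD")).with_ions(10)
    assert topo.n_salt_pairs == 10
    # one fixed neutralising anion per basic side chain (the peptide-salt counterions)
    assert topo.n_extra_anions == 5
    assert topo.h_capacity == 10
    # fully protonated start: bases ionised, acids neutral, no free H+
    q = topo.charges(topo.site_valency > 0, n_h=0)
    assert q.sum() == pytest.approx(0.0)
    # fully deprotonated end state balances through the free H+ pool
    q2 = topo.charges(topo.site_valency < 0, n_h=10)
    assert q2.sum() == pytest.approx(0.0)
    topo2 = build_topology(PeptideSpec("KKK")).with_ions(0)
    assert topo2.n_extra_anions == 3


# -- scalar potentials --------------------------------------------------------

@pytest.mark.parametrize(
    "r, b, kh, expected",
    [(0.5, 0.5, 400.0, 0.0), (0.6, 0.5, 400.0, 2.0), (0.4, 0.5, 400.0, 2.0)],
)
def test_harmonic_energy_values(r, b, kh, expected):
    assert harmonic_energy(r, b, kh) == pytest.approx(expected, abs=1e-12)


@given(dr=st.floats(0, 0.1), b=st.floats(0.1, 1.0), kh=st.floats(1.0, 1e3))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_harmonic_energy_symmetric_nonneg(dr, b, kh):
    assert harmonic_energy(b + dr, b, kh) == pytest.approx(
        harmonic_energy(b - dr, b, kh), rel=1e-9, abs=1e-12
    )
    assert harmonic_energy(b + dr, b, kh) >= 0.0


def test_wca_energy_reference_points():
    assert wca_energy(0.355) == pytest.approx(1.0, abs=1e-12)  # r = sigma -> eps
    assert wca_energy(0.5) == 0.0  # beyond cutoff
    val = wca_energy(0.4)  # residual shift at the 0.4 nm cutoff
    assert 0.0 <= val <= 1e-2
    with pytest.raises(ValueError):
        wca_energy(0.0)


def test_wca_strictly_decreasing_below_minimum():
    r = np.linspace(0.2, 2 ** (1 / 6) * 0.355, 100)
    u = wca_energy(r)
    assert np.all(np.diff(u) < 0)


def test_wca_exact_cutoff_option_continuous():
    ff = ForceFieldParams(exact_wca_cutoff=True)
    rc = ff.wca_cutoff
    assert rc == pytest.approx(2 ** (1 / 6) * 0.355)
    assert wca_energy(rc - 1e-9, r_cut=rc) == pytest.approx(0.0, abs=1e-6)


@pytest.mark.parametrize(
    "r, zi, zj, expected",
    [(0.71, 1, 1, 1.0), (0.71, 1, -1, -1.0), (1.42, 1, 1, 0.5)],
)
def test_coulomb_energy_values(r, zi, zj, expected):
    assert coulomb_energy(r, zi, zj) == pytest.approx(expected, abs=1e-12)


# -- assembled energies and forces -------------------------------------------

def test_total_energy_zero_for_trivial_state(ff_default):
    """Neutral beads beyond the cutoff with relaxed bonds have zero energy."""
    from ampholyte.engine import SystemState

    topo = build_topology(PeptideSpec("a")).with_ions(0)
    L = 10.0
    pos = np.zeros((topo.n_slots, 3))
    pos[0] = (1.0, 1.0, 1.0)
    pos[1] = (1.355, 1.0, 1.0)  # side-chain bond at rest length
    state = SystemState(
        positions=pos,
        velocities=np.zeros_like(pos),
        images=np.zeros_like(pos, dtype=np.int64),
        ionised=np.zeros(1, dtype=bool),
        n_h=0,
        box_length=L,
    )
    # bond at rest, both beads neutral, 0.355 nm < 0.4 nm so WCA contributes
    e = total_energy(state, topo, ff_default)
    assert e == pytest.approx(wca_energy(0.355), abs=1e-10)
    ff_nowca = ForceFieldParams(epsilon_wca=0.0)
    assert total_energy(state, topo, ff_nowca) == pytest.approx(0.0, abs=1e-12)


def test_translation_invariance(small_system, ff_default):
    sc, topo, state = small_system
    e0 = total_energy(state, topo, ff_default)
    shifted = state.copy()
    shift = np.array([0.37 * sc.box_length, -1.2, 2.9])
    shifted.positions = (shifted.positions + shift) % sc.box_length
    assert total_energy(shifted, topo, ff_default) == pytest.approx(e0, rel=1e-9)


def test_forces_are_negative_gradient(small_system, ff_default, rng):
    sc, topo, state = small_system
    f = forces(state, topo, ff_default)
    n = state.n_active(topo)
    h = 1e-6
    for _ in range(12):
        i = int(rng.integers(n))
        a = int(rng.integers(3))
        s = state.copy()
        s.positions[i, a] += h
        ep = total_energy(s, topo, ff_default)
        s.positions[i, a] -= 2 * h
        em = total_energy(s, topo, ff_default)
        fd = -(ep - em) / (2 * h)
        assert fd == pytest.approx(f[i, a], rel=1e-4, abs=1e-4)


def test_bonded_pair_at_rest_has_zero_bonded_force(ff_ideal):
    """Isolated dimer at the rest length: no net force without nonbonded terms."""
    from ampholyte.engine import SystemState

    topo = build_topology(PeptideSpec("a")).with_ions(0)
    pos = np.zeros((topo.n_slots, 3))
    pos[0] = (2.0, 2.0, 2.0)
    pos[1] = (2.355, 2.0, 2.0)
    state = SystemState(pos, np.zeros_like(pos), np.zeros_like(pos, dtype=np.int64),
                        np.zeros(1, dtype=bool), 0, 10.0)
    f = forces(state, topo, ff_ideal)
    assert np.allclose(f, 0.0, atol=1e-12)


def test_newtons_third_law_for_charged_pair():
    from ampholyte.ewald import EwaldSolver

    L = 20.0
    pos = np.array([[4.0, 4.0, 4.0], [6.0, 4.0, 4.0]])
    solver = EwaldSolver(L, 0.71, accuracy=1e-6)
    # like charges repel along the separation axis with equal opposite forces
    f = solver.forces(pos, np.array([1.0, -1.0]))
    np.testing.assert_allclose(f[0], -f[1], atol=1e-10)
    assert f[0][0] > 0.0 and f[1][0] < 0.0  # attraction for +/-
    f2 = solver.forces(np.array([[4.0, 4.0, 4.0], [6.0, 4.0, 4.0],
                                 [5.0, 9.0, 9.0], [5.0, 9.0, 11.0]]),
                       np.array([1.0, 1.0, -1.0, -1.0]))
    np.testing.assert_allclose(f2.sum(axis=0), 0.0, atol=1e-10)
    assert f2[0][0] < 0.0 and f2[1][0] > 0.0  # like charges repel


def test_forcefield_params_validation():
    with pytest.raises(ValueError):
        ForceFieldParams(k_h=-1.0)
    with pytest.raises(ValueError):
        ForceFieldParams(bjerrum_length=-0.1)
    with pytest.raises(ValueError):
        ForceFieldParams(temperature=0.0)
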