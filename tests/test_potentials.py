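"""Restraint energies, r^-6 averaging, tensor fits, violation reports."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gmxnmr import (
    AlignmentTensor,
    ConverterConfig,
    DihedralRestraint,
    DistanceRestraint,
    OrientationRestraint,
    back_calculate_all,
    dihedral_energy,
    distance_energy,
    effective_distance,
    fit_alignment_tensor,
    violations,
)

R = DistanceRestraint(label=0, pairs=[(1, 2)], r0=0.20, r1=0.30, r2=0.40)
K = 1000.0


@pytest.mark.parametrize("r,expected", [
    (0.25, 0.0),                       # flat region
    (0.35, 0.5 * K * 0.05 ** 2),       # harmonic wall: 1.25
    (0.50, 0.5 * K * 0.1 * (1.0 - 0.4 - 0.3)),  # linear tail: 15
    (0.15, 0.5 * K * 0.05 ** 2),       # below lower bound
])
def test_flat_bottom_distance_energy_branches(r, expected):
    assert distance_energy(r, R, K) == pytest.approx(expected)


@pytest.mark.parametrize("edge", [0.20, 0.30, 0.40])
def test_distance_energy_continuous_at_branch_points(edge):
    eps = 1e-9
    lo = distance_energy(edge - eps, R, K)
    hi = distance_energy(edge + eps, R, K)
    assert abs(hi - lo) < 1e-4


def test_linear_tail_matches_harmonic_wall_at_r2():
    assert distance_energy(R.r2, R, K) == pytest.approx(0.5 * K * (R.r2 - R.r1) ** 2)


D = DihedralRestraint(atoms=(1, 2, 3, 4), phi0=-70.0, dphi=30.0)


@pytest.mark.parametrize("phi,expected", [
    (-70.0, 0.0),
    (-80.0, 0.0),   # inside the well
    (-110.0, 0.5 * K * math.radians(10.0) ** 2),  # 10 deg outside: ~15.23
    (-40.0, 0.0),   # well edge
])
def test_flat_bottom_dihedral_energy(phi, expected):
    assert dihedral_energy(phi, D, K) == pytest.approx(expected)


@settings(deadline=None, max_examples=60)
@given(phi=st.floats(-720, 720, allow_nan=False))
def test_dihedral_energy_periodic_in_360(phi):
    assert dihedral_energy(phi + 360.0, D, K) == pytest.approx(
        dihedral_energy(phi, D, K), abs=1e-8)


def test_dihedral_energy_continuous_at_well_edges():
    for edge in (D.phi0 - D.dphi, D.phi0 + D.dphi):
        assert abs(dihedral_energy(edge + 1e-9, D, K)
                   - dihedral_energy(edge - 1e-9, D, K)) < 1e-6


def test_effective_distance_examples():
    assert effective_distance([0.4] * 9, "mean") == pytest.approx(0.4)
    expect = ((0.3 ** -6 + 0.6 ** -6) / 2) ** (-1 / 6)
    assert effective_distance([0.3, 0.6], "mean") == pytest.approx(expect)
    with pytest.raises(ValueError):
        effective_distance([], "mean")


@settings(deadline=None, max_examples=60)
@given(st.lists(st.floats(0.05, 2.0), min_size=1, max_size=12))
def test_effective_distance_bounds(ds):
    mean = effective_distance(ds, "mean")
    total = effective_distance(ds, "sum")
    assert min(ds) - 1e-12 <= mean <= max(ds) + 1e-12
    assert total <= mean + 1e-12
    assert total <= min(ds) + 1e-12


def _random_orientation_problem(n, seed, tensor):
    rng = np.random.default_rng(seed)
    structure = {}
    restraints = []
    for k in range(n):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        i, j = 2 * k + 1, 2 * k + 2
        structure[i] = np.zeros(3) + k
        structure[j] = structure[i] + 0.1 * v
        obs = 6.083 * float(v @ tensor @ v)
        restraints.append(OrientationRestraint(atoms=(i, j), experiment=1,
                                               label=k + 1, obs=obs))
    return structure, restraints


def test_alignment_tensor_recovered_from_noiseless_couplings():
    true = np.array([[1.1, 0.4, -0.3], [0.4, -0.7, 0.2], [-0.3, 0.2, -0.4]])
    structure, restraints = _random_orientation_problem(20, 11, true)
    tensor = fit_alignment_tensor(structure, restraints)
    assert not tensor.underdetermined
    assert np.linalg.norm(tensor.matrix - true) / np.linalg.norm(true) < 1e-8
    assert np.trace(tensor.matrix) == 0.0
    assert np.allclose(tensor.matrix, tensor.matrix.T)
    # least-squares residuals vanish here
    calc = back_calculate_all(structure, restraints, tensor)
    assert np.allclose(calc, [r.obs for r in restraints], atol=1e-10)


def test_zero_couplings_give_zero_tensor():
    structure, restraints = _random_orientation_problem(12, 3, np.zeros((3, 3)))
    tensor = fit_alignment_tensor(structure, restraints)
    assert np.allclose(tensor.matrix, 0.0)


def test_underdetermined_fit_is_flagged():
    true = np.diag([1.0, -0.5, -0.5])
    structure, restraints = _random_orientation_problem(4, 5, true)
    tensor = fit_alignment_tensor(structure, restraints)
    assert tensor.underdetermined


def test_violation_report_aggregates():
    structure = {1: np.zeros(3), 2: np.array([0.25, 0, 0]),
                 3: np.zeros(3), 4: np.array([0.35, 0, 0])}
    satisfied = DistanceRestraint(label=0, pairs=[(1, 2)], r0=0.2, r1=0.3, r2=0.4)
    above = DistanceRestraint(label=1, pairs=[(3, 4)], r0=0.2, r1=0.3, r2=0.4)
    rep = violations(structure, distances=[satisfied, above])
    assert rep.distance[0] == 0.0
    assert rep.distance[1] == pytest.approx(0.05)
    assert rep.mean_distance == pytest.approx(0.05 / 2)
    # energy zero iff violation zero
    assert rep.distance_energy[0] == 0.0 and rep.distance_energy[1] > 0.0


def test_dihedral_violation_ten_degrees_outside_well():
    structure = {1: np.array([0.0, 0.1, 0.0]), 2: np.zeros(3),
                 3: np.array([0.1, 0.0, 0.0]), 4: np.array([0.1, -0.1, 0.0])}
    from gmxnmr import dihedral_angle

    phi = dihedral_angle(structure[1], structure[2], structure[3], structure[4])
    rest = DihedralRestraint(atoms=(1, 2, 3, 4),
                             phi0=(phi - 40.0 + 180.0) % 360.0 - 180.0, dphi=30.0)
    rep = violations(structure, dihedrals=[rest])
    assert rep.dihedral[0] == pytest.approx(10.0)


def test_missing_atoms_excluded_and_counted():
    structure = {1: np.zeros(3), 2: np.array([0.25, 0, 0])}
    ok = DistanceRestraint(label=0, pairs=[(1, 2)], r0=0.2, r1=0.3, r2=0.4)
    gone = DistanceRestraint(label=1, pairs=[(1, 99)], r0=0.2, r1=0.3, r2=0.4)
    rep = violations(structure, distances=[ok, gone])
    assert rep.excluded["distance"] == 1
    assert set(rep.distance) == {0}


def test_constructed_satisfaction_is_reported_clean():
    """A fixture built with no violated records yields all-zero aggregates."""
    from gmxnmr import FixtureSpec, convert, make_peptide, make_star, parse_star, read_topology

    spec = FixtureSpec(seed=5, n_satisfied=12, n_violated=0, n_dihedrals=3, n_rdc=6)
    ens, top = make_peptide(spec)
    star, _ = make_star(spec, ens)
    cfg = ConverterConfig()
    res = convert(parse_star(star), read_topology(top), cfg)
    rep = violations(ens.models[0], res.distances, res.dihedrals,
                     res.orientations, cfg)
    assert rep.mean_distance == 0.0
    assert rep.mean_dihedral == 0.0
    assert rep.mean_orientation == pytest.approx(0.0, abs=1e-6)
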