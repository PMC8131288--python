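"""Restraint construction: units, labels, circular averaging, writers."""
import pytest

from gmxnmr import (
    AtomSpec,
    ConverterConfig,
    DihedralRestraint,
    DistanceRestraint,
    OrientationRestraint,
    RawDistanceRecord,
    build_distance,
    circular_interval,
    convert,
    write_itp,
    write_mdp_fragment,
)
from gmxnmr.topology_map import Miss


def _record(members, lower=1.8, upper=5.0, rid=1):
    return RawDistanceRecord(restraint_id=rid, members=members,
                             lower_bound=lower, upper_bound=upper)


def test_bounds_converted_angstrom_to_nm_with_margin(topindex, config):
    a = AtomSpec("1", 1, "ALA", "H")
    b = AtomSpec("1", 2, "GLY", "H")
    built = build_distance(_record([(a, b)]), 0, topindex, config)
    assert (built.r0, built.r1, built.r2) == pytest.approx((0.18, 0.50, 0.60))


def test_methyl_methyl_record_becomes_nine_pairs_one_label(topindex, config):
    a = AtomSpec("1", 1, "ALA", "MB")
    b = AtomSpec("1", 3, "ILE", "MD")
    built = build_distance(_record([(a, b)]), 4, topindex, config)
    assert len(built.pairs) == 9
    assert built.label == 4
    assert len({built.label}) == 1
    assert len(set(built.pairs)) == 9


def test_or_members_expand_under_one_label(topindex, config):
    a1 = AtomSpec("1", 1, "ALA", "MB")
    b1 = AtomSpec("1", 2, "GLY", "H")
    a2 = AtomSpec("1", 4, "LEU", "MD1")
    b2 = AtomSpec("1", 5, "SER", "H")
    built = build_distance(_record([(a1, b1), (a2, b2)]), 0, topindex, config)
    assert len(built.pairs) == 6  # 3x1 + 3x1


def test_unresolvable_atom_skips_whole_restraint(topindex, config):
    a = AtomSpec("1", 1, "ALA", "MB")
    b = AtomSpec("1", 2, "GLY", "HZ99")
    built = build_distance(_record([(a, b)]), 0, topindex, config)
    assert isinstance(built, Miss)
    assert "HZ99" in built.reason


@pytest.mark.parametrize("lower,upper,phi0,dphi", [
    (-100.0, -40.0, -70.0, 30.0),   # plain arithmetic midpoint
    (170.0, -170.0, 180.0, 10.0),   # arc through the +/-180 seam
    (-60.0, -60.0, -60.0, 0.0),     # degenerate interval
    (40.0, 100.0, 70.0, 30.0),
])
def test_circular_midpoint_of_angle_interval(lower, upper, phi0, dphi):
    got_phi0, got_dphi = circular_interval(lower, upper)
    assert got_phi0 == pytest.approx(phi0)
    assert got_dphi == pytest.approx(dphi)


def test_circular_midpoint_matches_unit_vector_mean():
    """Independent oracle: mean of the two bound unit vectors on the circle."""
    import numpy as np

    for lower, upper in [(170.0, -170.0), (-100.0, -40.0), (100.0, 170.0)]:
        width = (upper - lower) % 360.0
        vecs = [np.array([np.cos(np.radians(a)), np.sin(np.radians(a))])
                for a in (lower, lower + width)]
        mean = np.mean(vecs, axis=0)
        expect = np.degrees(np.arctan2(mean[1], mean[0]))
        got, _ = circular_interval(lower, upper)
        assert (got - expect) % 360.0 == pytest.approx(0.0, abs=1e-9)


def test_full_circle_dihedral_interval_rejected():
    with pytest.raises(ValueError, match="full circle"):
        circular_interval(0.0, 360.0)


def test_conversion_pipeline_counts_and_labels(violated_system, config):
    res = convert(violated_system["sets"], violated_system["index"], config)
    spec = violated_system["spec"]
    assert len(res.distances) == spec.n_satisfied + spec.n_violated
    assert [r.label for r in res.distances] == list(range(len(res.distances)))
    assert res.skipped == {"distance": 0, "dihedral": 0, "orientation": 0}
    # orientation labels numbered consecutively within the experiment
    assert [r.label for r in res.orientations] == list(range(1, spec.n_rdc + 1))
    assert {r.experiment for r in res.orientations} == {1}
    # unit sanity on everything emitted
    for r in res.distances:
        assert 0.0 < r.r2 <= 10.0 and 0.0 <= r.r0 <= r.r1 <= r.r2
    for r in res.dihedrals:
        assert -180.0 < r.phi0 <= 180.0 and r.dphi >= 0.0


def test_labels_stay_consecutive_when_a_restraint_is_skipped(violated_system, config):
    sets = violated_system["sets"]
    bad = RawDistanceRecord(
        restraint_id=999,
        members=[(AtomSpec("1", 1, "ALA", "H"), AtomSpec("1", 2, "GLY", "HZ99"))],
        lower_bound=1.8, upper_bound=5.0)
    sets_with_bad = type(sets)(
        distances=sets.distances[:3] + [bad] + sets.distances[3:],
        dihedrals=[], orientations=[], source_label="x")
    res = convert(sets_with_bad, violated_system["index"], config)
    assert res.skipped["distance"] == 1
    assert [r.label for r in res.distances] == list(range(len(res.distances)))


GOLDEN_DISRE = """\
; distance restraints generated from demo (force field: amber)
[ distance_restraints ]
;   ai    aj  type label type'      low      up1      up2      fac
     1     7     1     0     1   0.1800   0.5000   0.6000    1.000
     2     7     1     0     1   0.1800   0.5000   0.6000    1.000
"""


def test_itp_writers_are_byte_exact():
    r = DistanceRestraint(label=0, pairs=[(1, 7), (2, 7)], r0=0.18, r1=0.5, r2=0.6)
    assert write_itp([r], "distance", "demo", "amber") == GOLDEN_DISRE
    assert write_itp([], "distance").splitlines()[1] == "[ distance_restraints ]"
    d = DihedralRestraint(atoms=(1, 2, 3, 4), phi0=-70.0, dphi=30.0)
    out = write_itp([d], "dihedral")
    assert out.splitlines()[-1] == (
        "     1     2     3     4     1  -70.000   30.000    1.000")
    o = OrientationRestraint(atoms=(5, 6), experiment=1, label=1, obs=9.1)
    out = write_itp([o], "orientation")
    assert "     5     6     1     1     1     3    6.083    9.100    1.000" in out


def test_conversion_is_deterministic(violated_system, config):
    runs = []
    for _ in range(2):
        res = convert(violated_system["sets"], violated_system["index"], config)
        runs.append(write_itp(res.distances, "distance", "f", "amber")
                    + write_itp(res.dihedrals, "dihedral")
                    + write_itp(res.orientations, "orientation"))
    assert runs[0] == runs[1]


def test_mdp_fragment_carries_recommended_constants():
    frag = write_mdp_fragment(ConverterConfig())
    assert "disre-fc                 = 1000" in frag
    assert "disre-tau                = 500" in frag
    assert "orire-fc                 = 10" in frag
    zero = write_mdp_fragment(ConverterConfig(k_dr=0, tau_dr=0, k_dihr=0, k_or=0))
    for line in zero.splitlines():
        if not line.startswith(("#", ";")):
            assert "=" in line
    assert "disre-fc                 = 0" in zero
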