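"""NMR-STAR restraint reading: loop extraction, OR grouping, robustness."""
import pytest

from gmxnmr import RestraintSets, StarSyntaxError, parse_star

THREE_ROW_NOE = """\
data_test
save_dist
   _Gen_dist_constraint_list.Sf_category general_distance_constraints
   loop_
      _Gen_dist_constraint.ID
      _Gen_dist_constraint.Entity_assembly_ID_1
      _Gen_dist_constraint.Comp_index_ID_1
      _Gen_dist_constraint.Comp_ID_1
      _Gen_dist_constraint.Atom_ID_1
      _Gen_dist_constraint.Entity_assembly_ID_2
      _Gen_dist_constraint.Comp_index_ID_2
      _Gen_dist_constraint.Comp_ID_2
      _Gen_dist_constraint.Atom_ID_2
      _Gen_dist_constraint.Distance_lower_bound_val
      _Gen_dist_constraint.Distance_upper_bound_val
      1 1 1 ALA MB 1 3 ILE MD 1.8 5.0
      2 1 2 GLY H  1 4 LEU H  1.8 4.0
      2 1 2 GLY H  1 4 LEU HA 1.8 4.0
   stop_
save_
"""


def test_or_members_grouped_by_restraint_id():
    """Rows sharing one constraint ID are OR alternatives of one record."""
    sets = parse_star(THREE_ROW_NOE)
    assert len(sets.distances) == 2
    assert [len(r.members) for r in sets.distances] == [1, 2]
    rec = sets.distances[1]
    assert rec.restraint_id == 2
    assert {m[1].atom_id for m in rec.members} == {"H", "HA"}
    assert rec.lower_bound == 1.8 and rec.upper_bound == 4.0


def test_no_restraint_loops_yield_empty_lists():
    sets = parse_star("data_empty\nsave_x\n_Entry.ID 1\nsave_\n")
    assert sets.distances == [] and sets.dihedrals == [] and sets.orientations == []


def test_unparsable_row_skipped_and_counted():
    """Count conservation: parsed rows = records kept + warnings logged."""
    text = THREE_ROW_NOE.replace("1.8 5.0", "oops 5.0")
    sets = parse_star(text)
    assert len(sets.distances) == 1
    assert len(sets.warnings) == 1
    assert "skipped" in sets.warnings[0]
    n_rows = 3
    n_member_rows = sum(len(r.members) for r in sets.distances)
    assert n_member_rows + len(sets.warnings) == n_rows


def test_missing_entity_column_defaults_to_single_chain():
    text = THREE_ROW_NOE.replace("      _Gen_dist_constraint.Entity_assembly_ID_1\n", "")
    text = text.replace("      _Gen_dist_constraint.Entity_assembly_ID_2\n", "")
    text = text.replace("1 1 1 ALA MB 1 3 ILE MD 1.8 5.0", "1 1 ALA MB 3 ILE MD 1.8 5.0")
    text = text.replace("2 1 2 GLY H  1 4 LEU H  1.8 4.0", "2 2 GLY H  4 LEU H  1.8 4.0")
    text = text.replace("2 1 2 GLY H  1 4 LEU HA 1.8 4.0", "2 2 GLY H  4 LEU HA 1.8 4.0")
    sets = parse_star(text)
    assert {m[0].chain_label for r in sets.distances for m in r.members} == {"A"}


def test_target_tolerance_bounds_converted_at_parse_time():
    text = """\
data_t
save_d
   loop_
      _Gen_dist_constraint.ID
      _Gen_dist_constraint.Comp_index_ID_1
      _Gen_dist_constraint.Comp_ID_1
      _Gen_dist_constraint.Atom_ID_1
      _Gen_dist_constraint.Comp_index_ID_2
      _Gen_dist_constraint.Comp_ID_2
      _Gen_dist_constraint.Atom_ID_2
      _Gen_dist_constraint.Distance_val
      _Gen_dist_constraint.Distance_val_err
      1 1 ALA H 2 GLY H 3.0 0.5
   stop_
save_
"""
    rec = parse_star(text).distances[0]
    assert rec.lower_bound == pytest.approx(2.5)
    assert rec.upper_bound == pytest.approx(3.5)
    assert rec.target == pytest.approx(3.0)


def test_dihedral_and_rdc_loops_extracted(violated_system):
    sets = violated_system["sets"]
    spec = violated_system["spec"]
    assert len(sets.distances) == spec.n_satisfied + spec.n_violated
    assert len(sets.dihedrals) == spec.n_dihedrals + spec.n_violated_dihedrals
    assert len(sets.orientations) == spec.n_rdc
    assert all(r.angle_name == "PHI" for r in sets.dihedrals)
    assert all(r.experiment_id == 1 for r in sets.orientations)


def test_quoted_values_and_comments_tolerated():
    text = THREE_ROW_NOE.replace("ALA MB", "ALA 'MB'") + "# trailing comment\n"
    sets = parse_star(text)
    assert sets.distances[0].members[0][0].atom_id == "MB"


def test_malformed_star_names_save_frame():
    bad = THREE_ROW_NOE.replace("      2 1 2 GLY H  1 4 LEU HA 1.8 4.0\n",
                                "      2 1 2 GLY H  1 4 LEU HA 1.8\n")
    with pytest.raises(StarSyntaxError, match="dist"):
        parse_star(bad)


def test_debug_round_trip_preserves_all_records(violated_system):
    sets = violated_system["sets"]
    again = RestraintSets.from_json(sets.to_json())
    assert again == sets
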