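import pytest

from gmxnmr import (
    ConverterConfig,
    FixtureSpec,
    make_peptide,
    make_star,
    parse_star,
    read_topology,
)


@pytest.fixture(scope="session")
def basic_spec():
    return FixtureSpec(seed=2021, n_models=5, n_satisfied=10)


@pytest.fixture(scope="session")
def peptide(basic_spec):
    return make_peptide(basic_spec)


@pytest.fixture(scope="session")
def ensemble(peptide):
    return peptide[0]


@pytest.fixture(scope="session")
def topindex(peptide):
    return read_topology(peptide[1])


@pytest.fixture(scope="session")
def config():
    return ConverterConfig()


@pytest.fixture(scope="session")
def violated_spec():
    return FixtureSpec(seed=77, n_models=3, n_satisfied=8, n_violated=2,
                       violation_magnitude=0.05, n_dihedrals=2,
                       n_violated_dihedrals=1, dihedral_violation=10.0, n_rdc=6)


@pytest.fixture(scope="session")
def violated_system(violated_spec):
    ens, top = make_peptide(violated_spec)
    star, truth = make_star(violated_spec, ens)
    return {"spec": violated_spec, "ensemble": ens, "topology": top,
            "star": star, "truth": truth, "sets": parse_star(star, "fixture"),
            "index": read_topology(top)}
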