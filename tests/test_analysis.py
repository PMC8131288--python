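"""Superposition-free distance RMSD and min-over-models scoring."""
import numpy as np
import pytest

from gmxnmr import (
    Ensemble,
    StructureModel,
    distance_rmsd,
    min_model_rmsd,
    perturb,
    rmsd_timeseries,
)


def _model(mid, coords):
    return StructureModel(model_id=mid, coordinates={i + 1: np.asarray(c, float)
                                                     for i, c in enumerate(coords)})


def _rigid(model, seed):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.normal(size=3)
    return StructureModel(model_id=model.model_id,
                          coordinates={i: q @ xyz + t
                                       for i, xyz in model.coordinates.items()})


def test_identical_structures_have_zero_rmsd(ensemble):
    m = ensemble.models[0]
    assert distance_rmsd(m, m) == 0.0


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_invariance_under_rigid_motions(ensemble, seed):
    m = ensemble.models[0]
    moved = _rigid(m, seed)
    assert distance_rmsd(moved, m) == pytest.approx(0.0, abs=1e-10)


def test_three_atom_toy_against_brute_force():
    """One side of an equilateral triangle stretched 0.3 -> 0.4 nm."""
    ref = _model(1, [(0, 0, 0), (0.3, 0, 0), (0.15, 0.3 * np.sqrt(3) / 2, 0)])
    frame = _model(1, [(0, 0, 0), (0.4, 0, 0),
                       (0.2, np.sqrt(0.09 - 0.04), 0)])
    # brute force over the three pairs
    def dists(m):
        xyz = m.array()
        return [np.linalg.norm(xyz[i] - xyz[j]) for i in range(3) for j in range(i + 1, 3)]
    brute = np.sqrt(np.mean((np.array(dists(frame)) - np.array(dists(ref))) ** 2))
    assert brute == pytest.approx(np.sqrt(0.1 ** 2 / 3))
    assert distance_rmsd(frame, ref) == pytest.approx(brute)


def test_symmetry(ensemble):
    a, b = ensemble.models[0], ensemble.models[1]
    assert distance_rmsd(a, b) == pytest.approx(distance_rmsd(b, a))


def test_fewer_than_two_atoms_is_an_error():
    a = _model(1, [(0, 0, 0)])
    with pytest.raises(ValueError):
        distance_rmsd(a, a)


def test_min_over_models_picks_the_matching_model(ensemble):
    frame = ensemble.models[1]
    assert min_model_rmsd(frame, ensemble) == 0.0
    single = Ensemble(models=[ensemble.models[0]], atom_names=ensemble.atom_names)
    assert min_model_rmsd(frame, single) == pytest.approx(
        distance_rmsd(frame, ensemble.models[0]))


def test_min_over_models_bounded_by_every_model(ensemble):
    frame = perturb(ensemble.models[0], 0.05, seed=9)
    best = min_model_rmsd(frame, ensemble)
    for model in ensemble.models:
        assert best <= distance_rmsd(frame, model) + 1e-15


def test_timeseries_of_the_ensemble_against_itself_is_zero(ensemble):
    series = rmsd_timeseries(ensemble.models, ensemble, dt=2.0)
    assert [t for t, _ in series] == [2.0 * k for k in range(len(ensemble))]
    assert all(v == 0.0 for _, v in series)
    assert rmsd_timeseries([], ensemble) == []


def test_interpolation_toward_a_model_is_monotone(ensemble):
    target = ensemble.models[0]
    start = perturb(target, 0.2, seed=4)
    frames = []
    for lam in np.linspace(0, 1, 6):
        coords = {i: (1 - lam) * start[i] + lam * target[i]
                  for i in target.coordinates}
        frames.append(StructureModel(model_id=1, coordinates=coords))
    series = [v for _, v in rmsd_timeseries(frames, ensemble)]
    assert all(b <= a + 1e-12 for a, b in zip(series, series[1:]))
    assert series[-1] == 0.0


def test_heavy_subset_excludes_hydrogens(ensemble):
    heavy = ensemble.subset("heavy")
    assert heavy
    assert all(not ensemble.atom_names[i].startswith("H") for i in heavy)
    backbone = ensemble.subset("backbone")
    assert set(ensemble.atom_names[i] for i in backbone) == {"N", "CA", "C"}
    assert len(ensemble.subset("all")) == len(ensemble.models[0].indices)
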