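import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from nbdlink import (
    CoreSelection,
    ResidueMap,
    RigidTransform,
    Structure,
    SuperpositionError,
    graft_monomer_into_dimer,
    kabsch_fit,
    superpose_on_core,
)
from nbdlink.crosslink import interprotomer_distance
from nbdlink.synthetic import SyntheticDimerSpec, helix_fold, make_toy_dimer, perturb_copy


def _points(n, seed):
    return np.random.default_rng(seed).normal(scale=5.0, size=(n, 3))


def _random_transform(seed):
    rng = np.random.default_rng(seed)
    return RigidTransform(Rotation.random(rng=rng).as_matrix(), rng.normal(scale=10.0, size=3))


# --- kabsch_fit ----------------------------------------------------------

def test_identical_point_sets_give_zero_rmsd_identity_transform():
    P = _points(8, 0)
    res = kabsch_fit(P, P)
    assert res.rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(res.transform.rotation, np.eye(3), atol=1e-9)
    assert np.allclose(res.transform.translation, 0.0, atol=1e-9)


def test_known_transform_recovered_exactly():
    P = _points(6, 1)
    R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    t = np.array([1.0, 2.0, 3.0])
    Q = P @ R.T + t
    res = kabsch_fit(P, Q)
    assert res.rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(res.transform.rotation, R, atol=1e-9)
    assert np.allclose(res.transform.translation, t, atol=1e-9)


def test_mirror_image_yields_proper_rotation_and_positive_rmsd():
    P = _points(10, 2)
    Q = P * np.array([-1.0, 1.0, 1.0])  # reflection
    res = kabsch_fit(P, Q)
    assert res.rmsd > 0.5
    assert np.linalg.det(res.transform.rotation) == pytest.approx(1.0, abs=1e-8)


def test_fewer_than_three_points_rejected():
    P = _points(2, 3)
    with pytest.raises(SuperpositionError):
        kabsch_fit(P, P)


def test_collinear_points_flagged_degenerate():
    P = np.outer(np.arange(5, dtype=float), [1.0, 0.0, 0.0])
    res = kabsch_fit(P, P + np.array([0.0, 1.0, 0.0]))
    assert res.degenerate
    assert res.rmsd == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("seed", range(5))
def test_rmsd_invariant_under_common_rigid_motion(seed):
    P, Q = _points(12, seed), _points(12, seed + 100)
    base = kabsch_fit(P, Q).rmsd
    tf = _random_transform(seed + 200)
    moved = kabsch_fit(tf.apply(P), tf.apply(Q)).rmsd
    assert moved == pytest.approx(base, abs=1e-6)


@pytest.mark.parametrize("seed", range(5))
def test_fit_never_worse_than_untransformed_pairing(seed):
    P, Q = _points(9, seed), _points(9, seed + 50)
    raw = float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))
    assert kabsch_fit(P, Q).rmsd <= raw + 1e-12


@pytest.mark.parametrize("seed", range(3))
def test_agrees_with_scipy_align_vectors(seed):
    # independent least-squares route: scipy's Wahba solver on centred clouds
    P, Q = _points(20, seed), _points(20, seed + 7)
    res = kabsch_fit(P, Q)
    rot, rssd = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
    assert np.allclose(res.transform.rotation, rot.as_matrix(), atol=1e-8)
    assert res.rmsd == pytest.approx(rssd / np.sqrt(len(P)), abs=1e-8)


# --- CoreSelection -------------------------------------------------------

def test_core_selection_parse_roundtrip_and_membership():
    core = CoreSelection.parse("342-352,358-406,500-505,530-536,545-561")
    assert str(core) == "342-352,358-406,500-505,530-536,545-561"
    assert 361 in core and 357 not in core
    assert len(core.positions()) == 11 + 49 + 6 + 7 + 17


def test_core_selection_rejects_overlap_and_descending():
    with pytest.raises(ValueError):
        CoreSelection([(10, 5)])
    with pytest.raises(ValueError):
        CoreSelection([(1, 10), (5, 20)])


# --- superpose_on_core ---------------------------------------------------

def _monomer_from(dimer, chain="A", id="mono"):
    return Structure(id, [chain], [r for r in dimer.residues if r.chain_id == chain])


def test_self_superposition_is_exact(plain_dimer):
    dimer, _ = plain_dimer
    mono = _monomer_from(dimer)
    rmap = ResidueMap.identity(range(1, 46))
    res = superpose_on_core(mono, dimer, "A", rmap, CoreSelection([(1, 45)]))
    assert res.rmsd == pytest.approx(0.0, abs=1e-9)
    assert res.n_atoms == 45


def test_unmapped_and_missing_core_residues_are_dropped(plain_dimer):
    dimer, _ = plain_dimer
    mono = _monomer_from(dimer)
    rmap = ResidueMap.identity(range(1, 41))  # 41-45 unmapped
    res = superpose_on_core(mono, dimer, "A", rmap, CoreSelection([(1, 45)]))
    assert res.n_atoms == 40
    assert res.selection_query == list(range(1, 41))


def test_insufficient_overlap_raises(plain_dimer):
    dimer, _ = plain_dimer
    mono = _monomer_from(dimer)
    rmap = ResidueMap.identity([1, 2])
    with pytest.raises(SuperpositionError):
        superpose_on_core(mono, dimer, "A", rmap, CoreSelection([(1, 2)]))


def test_noisy_rigid_perturbation_recovered(plain_dimer):
    dimer, _ = plain_dimer
    mono = _monomer_from(dimer)
    pert, applied = perturb_copy(mono, 25.0, [4.0, -3.0, 6.0], 0.2, seed=1)
    rmap = ResidueMap.identity(range(1, 46))
    res = superpose_on_core(pert, dimer, "A", rmap, CoreSelection([(1, 45)]))
    # recovered transform should invert the applied one
    residual = Rotation.from_matrix(res.transform.rotation @ applied.rotation)
    assert np.degrees(residual.magnitude()) < 1.0
    assert 0.1 <= res.rmsd <= 0.4
    assert res.n_atoms >= 30


# --- grafting ------------------------------------------------------------

def test_self_graft_reproduces_template_protomers(plain_dimer):
    dimer, _ = plain_dimer
    mono = _monomer_from(dimer)
    rmap = ResidueMap.identity(range(1, 46))
    comp = graft_monomer_into_dimer(mono, dimer, ("A", "B"), rmap, CoreSelection([(1, 45)]))
    assert comp.chains == ["Q1", "Q2"]
    for i in range(1, 46):
        assert np.linalg.norm(comp.ca_coord("Q1", i) - dimer.ca_coord("A", i)) < 1e-6
        assert np.linalg.norm(comp.ca_coord("Q2", i) - dimer.ca_coord("B", i)) < 1e-6
    assert max(comp.metadata["fit_rmsd"]) < 1e-9


def test_graft_recovers_planted_interprotomer_distances(plain_dimer):
    dimer, _ = plain_dimer
    # noise-free copy of the fold, renumbered identically
    mono = _monomer_from(dimer)
    rmap = ResidueMap.identity(range(1, 46))
    comp = graft_monomer_into_dimer(mono, dimer, ("A", "B"), rmap, CoreSelection([(1, 45)]))
    for i, j in [(3, 3), (10, 20), (44, 2)]:
        want = interprotomer_distance(dimer, "A", "B", i, j)
        got = interprotomer_distance(comp, "Q1", "Q2", i, j)
        assert got == pytest.approx(want, abs=1e-6)


@settings(max_examples=15, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_self_graft_identity_property_over_random_dimers(seed):
    tf = _random_transform(seed)
    spec = SyntheticDimerSpec(n_residues=20, protomer_transform=tf, seed=seed)
    dimer, _ = make_toy_dimer(spec)
    mono = _monomer_from(dimer)
    rmap = ResidueMap.identity(range(1, 21))
    comp = graft_monomer_into_dimer(mono, dimer, ("A", "B"), rmap, CoreSelection([(1, 20)]))
    dev = max(
        np.linalg.norm(comp.ca_coord("Q1", i) - dimer.ca_coord("A", i)) for i in range(1, 21)
    )
    assert dev < 1e-6
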