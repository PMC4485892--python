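import numpy as np
import pytest

from nbdlink import (
    Conformation,
    CoreSelection,
    CrosslinkError,
    CrosslinkObservation,
    DistanceRecord,
    ResidueMap,
    ResiduePairSpec,
    RigidTransform,
    Structure,
    classify_crosslink,
    double_mutant_governing_distance,
    governing_distance_from_records,
    interprotomer_distance,
    pair_distance_in_conformation,
    score_concordance,
)
from nbdlink.datasets import discriminate_conformations, load_observations, load_reference_distances
from nbdlink.synthetic import SyntheticDimerSpec, make_toy_dimer


@pytest.fixture
def translated_dimer():
    """Chain B is chain A shifted 10 Å along x: every same-residue distance is 10."""
    tf = RigidTransform(np.eye(3), np.array([10.0, 0.0, 0.0]))
    spec = SyntheticDimerSpec(n_residues=20, protomer_transform=tf, seed=0)
    dimer, _ = make_toy_dimer(spec)
    return dimer


# --- interprotomer_distance ---------------------------------------------

def test_planted_translation_distance(translated_dimer):
    assert interprotomer_distance(translated_dimer, "A", "B", 5, 5) == pytest.approx(10.0)


def test_distance_is_symmetric(toy_dimer):
    s, _ = toy_dimer
    d1 = interprotomer_distance(s, "A", "B", 25, 30)
    d2 = interprotomer_distance(s, "B", "A", 30, 25)
    assert d1 == pytest.approx(d2)


def test_same_chain_and_missing_residue_rejected(translated_dimer):
    with pytest.raises(CrosslinkError):
        interprotomer_distance(translated_dimer, "A", "A", 1, 2)
    with pytest.raises(KeyError):
        interprotomer_distance(translated_dimer, "A", "B", 1, 999)


# --- pair distances and the minimum-over-pairings rule -------------------

def test_single_mutant_distance_matches_planted_truth(toy_dimer):
    s, truth = toy_dimer
    conf = Conformation(label="toy", dimer=s, chain_pair=("A", "B"))
    for (a, b), info in truth["pairs"].items():
        if a == b:
            rec = pair_distance_in_conformation(ResiduePairSpec(a, b), conf)
            assert rec.distance == pytest.approx(info["target"], abs=1e-6)
            assert rec.route == "direct-homolog"


def test_double_mutant_takes_minimum_pairing(toy_dimer):
    s, truth = toy_dimer
    conf = Conformation(label="toy", dimer=s, chain_pair=("A", "B"))
    rec = double_mutant_governing_distance(ResiduePairSpec(25, 30), conf)
    info = truth["pairs"][(25, 30)]
    assert rec.distance == pytest.approx(info["governing"], abs=1e-6)
    for d in info["pairings"].values():
        assert rec.distance <= d + 1e-9


def test_planted_homotypic_pairing_governs_when_shortest():
    spec = SyntheticDimerSpec(n_residues=30, planted_pairs=[(8, 8, 5.0)], seed=4)
    s, _ = make_toy_dimer(spec)
    conf = Conformation(label="toy", dimer=s, chain_pair=("A", "B"))
    # (8,15): the a–a′ pairing was planted at 5 Å, far below anything else
    rec = double_mutant_governing_distance(ResiduePairSpec(8, 15), conf)
    assert rec.distance == pytest.approx(5.0, abs=1e-6)
    assert rec.pairing_detail == "8@A–8@B"


def test_double_mutant_guard_on_single(toy_dimer):
    s, _ = toy_dimer
    conf = Conformation(label="toy", dimer=s, chain_pair=("A", "B"))
    with pytest.raises(CrosslinkError):
        double_mutant_governing_distance(ResiduePairSpec(10, 10), conf)


# --- graft route ----------------------------------------------------------

def _template_numbering_conformation(graft_positions=frozenset()):
    """Template dimer renumbered +100; query monomer in query numbering.

    Query position 5 is deliberately absent from the residue map, so it can
    only be measured through the grafted composite.
    """
    spec = SyntheticDimerSpec(n_residues=40, seed=9, first_residue=101,
                              structure_id="template-dimer")
    dimer, _ = make_toy_dimer(spec)
    mono_spec = SyntheticDimerSpec(n_residues=40, seed=9, first_residue=1,
                                   structure_id="query-mono")
    mono_dimer, _ = make_toy_dimer(mono_spec)
    monomer = Structure("query-mono", ["A"],
                        [r for r in mono_dimer.residues if r.chain_id == "A"])
    rmap = ResidueMap("query", "template", {i: i + 100 for i in range(1, 41) if i != 5})
    return Conformation(
        label="tmpl", dimer=dimer, chain_pair=("A", "B"), rmap=rmap,
        monomer=monomer, core=CoreSelection([(10, 40)]),
        graft_positions=graft_positions,
    )


def test_unmapped_position_falls_back_to_graft_route():
    conf = _template_numbering_conformation()
    rec = pair_distance_in_conformation(ResiduePairSpec(5, 5), conf)
    assert rec.route == "grafted-monomer"
    want = interprotomer_distance(conf.dimer, "A", "B", 105, 105)
    assert rec.distance == pytest.approx(want, abs=1e-6)


def test_mapped_position_uses_direct_route_and_agrees_with_graft():
    conf = _template_numbering_conformation()
    direct = pair_distance_in_conformation(ResiduePairSpec(20, 20), conf)
    assert direct.route == "direct-homolog"
    forced = _template_numbering_conformation(graft_positions=frozenset({20}))
    grafted = pair_distance_in_conformation(ResiduePairSpec(20, 20), forced)
    assert grafted.route == "grafted-monomer"
    assert grafted.distance == pytest.approx(direct.distance, abs=1e-6)


def test_position_neither_mapped_nor_covered_raises():
    conf = _template_numbering_conformation()
    conf = Conformation(label=conf.label, dimer=conf.dimer, chain_pair=conf.chain_pair,
                        rmap=conf.rmap, monomer=None, core=None)
    with pytest.raises(CrosslinkError):
        pair_distance_in_conformation(ResiduePairSpec(5, 5), conf)


# --- classification -------------------------------------------------------

def _rec(dist, conf="c"):
    return DistanceRecord(ResiduePairSpec(1, 1), conf, "direct-homolog", dist)


def test_cold_threshold_is_strictly_under_14():
    assert classify_crosslink(_rec(9.3), 4).compatible
    assert not classify_crosslink(_rec(14.0), 4).compatible
    assert not classify_crosslink(_rec(20.1), 4).compatible


def test_warm_threshold_admits_more_distant_pairs():
    assert classify_crosslink(_rec(20.1), 21).compatible
    assert classify_crosslink(_rec(14.1), 21).compatible
    assert not classify_crosslink(_rec(21.0), 21).compatible


def test_unknown_temperature_rejected():
    with pytest.raises(CrosslinkError):
        classify_crosslink(_rec(5.0), 37)


@pytest.mark.parametrize("d1,d2", [(5.0, 6.0), (13.9, 14.1), (20.0, 50.0)])
def test_classification_is_monotone_in_distance_and_temperature(d1, d2):
    assert d1 < d2
    c1, c2 = classify_crosslink(_rec(d1), 4), classify_crosslink(_rec(d2), 4)
    assert not (not c1.compatible and c2.compatible)  # lower distance never worse
    cold, warm = classify_crosslink(_rec(d1), 4), classify_crosslink(_rec(d1), 21)
    assert not (cold.compatible and not warm.compatible)  # warmer never stricter


# --- concordance ----------------------------------------------------------

def test_full_agreement_scores_all_concordant():
    obs = [CrosslinkObservation(ResiduePairSpec(1, 1), 4, "clear"),
           CrosslinkObservation(ResiduePairSpec(2, 2), 4, "none")]
    calls = [classify_crosslink(DistanceRecord(o.mutant, "c", "direct-homolog", d), 4)
             for o, d in zip(obs, [9.0, 30.0])]
    rep = score_concordance(calls, obs)
    assert rep.n_concordant == rep.n_observations == 2
    assert rep.discordant == []


def test_weak_outcome_counts_as_positive():
    obs = [CrosslinkObservation(ResiduePairSpec(1, 1), 4, "weak")]
    call = classify_crosslink(DistanceRecord(obs[0].mutant, "c", "direct-homolog", 30.0), 4)
    rep = score_concordance([call], obs)
    assert rep.discordant == ["1/1"]


def test_missing_call_and_empty_observations_rejected():
    obs = [CrosslinkObservation(ResiduePairSpec(1, 1), 4, "clear")]
    with pytest.raises(CrosslinkError):
        score_concordance([], obs)
    with pytest.raises(CrosslinkError):
        score_concordance([], [])


# --- discrimination on the packaged prediction table ----------------------

def test_sandwich_dimer_concordance_is_8_of_9_with_E520C_discordant():
    res = discriminate_conformations(load_reference_distances(), load_observations(4))
    rep, _ = res["2HYD-sandwich"]
    assert (rep.n_concordant, rep.n_observations) == (8, 9)
    assert rep.discordant == ["E520C"]


def test_inward_closed_concordance_is_5_of_9():
    res = discriminate_conformations(load_reference_distances(), load_observations(4))
    rep, _ = res["3B5X-inward-closed"]
    assert (rep.n_concordant, rep.n_observations) == (5, 9)
    assert set(rep.discordant) == {"S516C", "P383C", "E520C", "S361C/K486C"}


def test_warm_observations_all_concordant_with_sandwich():
    res = discriminate_conformations(load_reference_distances(), load_observations(21))
    rep, _ = res["2HYD-sandwich"]
    assert (rep.n_concordant, rep.n_observations) == (3, 3)


def test_governing_distance_from_tabulated_records():
    records = load_reference_distances()
    rec = governing_distance_from_records(
        records, ResiduePairSpec(383, 520, "P383C/E520C"), "2HYD-sandwich")
    assert rec.distance == pytest.approx(7.0)
    assert rec.pairing_detail == "P383/E520"
    rec = governing_distance_from_records(
        records, ResiduePairSpec(361, 486, "S361C/K486C"), "3B5X-inward-closed")
    assert rec.distance == pytest.approx(22.45)
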