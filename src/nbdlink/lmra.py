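"""The LmrA study assembled from deposited structures.

Given the deposited coordinate files — the LmrA NBD monomer (1MV5), the
Sav1866 transporter dimer (2HYD, the head-to-tail "sandwich" candidate) and
the nucleotide-free *V. cholerae* MsbA dimer (3B5X, the inward-facing closed
candidate) — this module reproduces the full distance-prediction analysis
for the nine cysteine-scanning residue pairings, using the LmrA NBD chain
sequence (author numbering) as the query.

S361 sits on the A-loop, where the Sav1866 A-loop is one residue longer than
LmrA's and the sequence equivalence is ambiguous; in the sandwich template
it is therefore always measured on the grafted 1MV5 composite (core-subdomain
fit) rather than through the alignment.
"""

from __future__ import annotations

from pathlib import Path

from .crosslink import Conformation, DistanceRecord, ResiduePairSpec, governing_distance
from .mapping import ResidueMap, map_structures
from .structures import Structure, chain_sequence, read_structure
from .superpose import CoreSelection, DEFAULT_CORE

__all__ = [
    "LMRA_POSITIONS",
    "STUDY_PAIRS",
    "SANDWICH_ID",
    "INWARD_CLOSED_ID",
    "build_study_conformations",
    "predict_study_distances",
]

#: Engineered cysteine positions, LmrA author numbering → wild-type residue.
LMRA_POSITIONS = {361: "S", 383: "P", 433: "A", 435: "M", 486: "K", 516: "S", 520: "E"}

SANDWICH_ID = "2HYD-sandwich"
INWARD_CLOSED_ID = "3B5X-inward-closed"


def _label(a: int, b: int) -> str:
    return f"{LMRA_POSITIONS[a]}{a}/{LMRA_POSITIONS[b]}{b}"


#: The nine tabulated pairings: seven homotypic rows plus the two
#: cross-pairings realised by the double mutants.
STUDY_PAIRS = [
    ResiduePairSpec(433, 433, _label(433, 433)),
    ResiduePairSpec(435, 435, _label(435, 435)),
    ResiduePairSpec(516, 516, _label(516, 516)),
    ResiduePairSpec(361, 486, _label(361, 486)),
    ResiduePairSpec(361, 361, _label(361, 361)),
    ResiduePairSpec(486, 486, _label(486, 486)),
    ResiduePairSpec(383, 520, _label(383, 520)),
    ResiduePairSpec(383, 383, _label(383, 383)),
    ResiduePairSpec(520, 520, _label(520, 520)),
]


def _dimer_chain_pair(dimer: Structure) -> tuple[str, str]:
    """The two chains of one transporter: the first two protein chains."""
    if len(dimer.chains) < 2:
        raise ValueError(f"{dimer.id!r} has {len(dimer.chains)} chain(s); need a dimer")
    return (dimer.chains[0], dimer.chains[1])


def build_study_conformations(
    lmra_nbd: str | Path | Structure,
    sandwich_dimer: str | Path | Structure,
    inward_dimer: str | Path | Structure,
    core: CoreSelection = DEFAULT_CORE,
    sandwich_chains: tuple[str, str] | None = None,
    inward_chains: tuple[str, str] | None = None,
) -> list[Conformation]:
    """Build the two candidate conformations with alignment-derived maps.

    The query sequence is the Cα-resolved chain of the LmrA NBD structure in
    its author numbering, so every residue map is keyed by the same numbers
    the mutants use.
    """
    monomer = lmra_nbd if isinstance(lmra_nbd, Structure) else read_structure(lmra_nbd)
    query_seq = chain_sequence(monomer, monomer.chains[0])

    confs = []
    for struct, label, chains, graft in (
        (sandwich_dimer, SANDWICH_ID, sandwich_chains, frozenset({361})),
        (inward_dimer, INWARD_CLOSED_ID, inward_chains, frozenset()),
    ):
        dimer = struct if isinstance(struct, Structure) else read_structure(struct)
        chain_pair = chains or _dimer_chain_pair(dimer)
        rmap = map_structures(
            query_seq,
            chain_sequence(dimer, chain_pair[0]),
            query_id=monomer.id,
            template_id=dimer.id,
        )
        confs.append(
            Conformation(
                label=label,
                dimer=dimer,
                chain_pair=chain_pair,
                rmap=rmap,
                monomer=monomer,
                core=core,
                graft_positions=graft,
            )
        )
    return confs


def predict_study_distances(conformations: list[Conformation]) -> list[DistanceRecord]:
    """One DistanceRecord per tabulated pairing per conformation (min-pairing rule
    applies within each row's own positions: a row a/b reports min(a–b′, b–a′))."""
    from .crosslink import pair_distance_in_conformation

    records = []
    for conf in conformations:
        for pair in STUDY_PAIRS:
            records.append(pair_distance_in_conformation(pair, conf))
    return records
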