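"""Synthetic dimer fixtures with planted ground truth.

The generator stands in for crystal-structure inputs so that every pipeline
stage — parsing, mapping, superposition, grafting, distance measurement,
classification, concordance — is testable offline against known answers.
Protomers are deterministic helix-like Cα traces (3.8 Å consecutive spacing)
so fixtures look structure-like to the parser; they are not physically
realistic proteins and carry no side chains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .crosslink import CrosslinkObservation, ResiduePairSpec, DEFAULT_THRESHOLDS
from .structures import AtomRecord, ResidueRecord, Structure
from .superpose import RigidTransform

__all__ = [
    "SyntheticDimerSpec",
    "GenerationError",
    "helix_fold",
    "make_toy_dimer",
    "perturb_copy",
    "make_observation_table",
]

_AA_CYCLE = "ADEFGHIKLMNPQRSTVWY"  # no C: the study protein is cysteine-less


class GenerationError(ValueError):
    pass


@dataclass
class SyntheticDimerSpec:
    n_residues: int = 60
    protomer_transform: RigidTransform | None = None
    planted_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    seed: int = 0
    first_residue: int = 1
    structure_id: str = "toy-dimer"

    def __post_init__(self) -> None:
        if self.protomer_transform is None:
            # default placement: 180° flip about z plus a lateral offset,
            # loosely evoking a two-fold symmetric dimer
            self.protomer_transform = RigidTransform(
                Rotation.from_euler("z", 180, degrees=True).as_matrix(),
                np.array([30.0, 0.0, 0.0]),
            )


def helix_fold(n_residues: int, first_residue: int = 1) -> dict[int, np.ndarray]:
    """Idealised α-helical Cα trace: radius 2.3 Å, rise 1.5 Å, 100°/residue."""
    coords = {}
    for i in range(n_residues):
        theta = math.radians(100.0 * i)
        coords[first_residue + i] = np.array(
            [2.3 * math.cos(theta), 2.3 * math.sin(theta), 1.5 * i]
        )
    return coords


def _residue(chain_id: str, num: int, coord: np.ndarray) -> ResidueRecord:
    return ResidueRecord(
        chain_id=chain_id,
        seq_number=num,
        insertion_code="",
        aa_code=_AA_CYCLE[num % len(_AA_CYCLE)],
        atoms=[AtomRecord(name="CA", element="C", coord=coord)],
    )


def make_toy_dimer(spec: SyntheticDimerSpec) -> tuple[Structure, dict]:
    """Build a two-chain Cα dimer with planted cross-protomer distances.

    Chain A carries the fold; chain B is the rigidly placed second protomer.
    For each planted triple ``(res_a, res_b, d)`` the chain-B copy of
    ``res_b`` is re-placed so that the a(A)–b(B) Cα distance equals ``d``
    exactly; for a hetero pair the chain-B copy of ``res_a`` is pushed 10 Å
    further out so the planted pairing is the governing one.  Each residue
    may appear in at most one planted pair.  Returns the structure and a
    ground-truth table measured on the final coordinates.
    """
    foldA = helix_fold(spec.n_residues, spec.first_residue)
    tf = spec.protomer_transform
    foldB = {num: tf.apply(c) for num, c in foldA.items()}

    max_dev = max(np.linalg.norm(foldA[n] - foldB[n]) for n in foldA)
    if max_dev < 1e-6:
        raise GenerationError("protomer transform is the identity: the chains coincide")

    rng = np.random.default_rng(spec.seed)
    used: set[int] = set()
    for res_a, res_b, d in spec.planted_pairs:
        if d <= 0 or not np.isfinite(d):
            raise GenerationError(f"planted distance for ({res_a},{res_b}) must be positive, got {d}")
        for r in {res_a, res_b}:
            if r not in foldA:
                raise GenerationError(f"planted residue {r} outside 1..{spec.n_residues} numbering")
            if r in used:
                raise GenerationError(f"residue {r} appears in more than one planted pair")
            used.add(r)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        foldB[res_b] = foldA[res_a] + d * u
        if res_a != res_b:
            foldB[res_a] = foldA[res_b] + (d + 10.0) * u

    residues = [_residue("A", n, c) for n, c in sorted(foldA.items())]
    residues += [_residue("B", n, c) for n, c in sorted(foldB.items())]
    structure = Structure(id=spec.structure_id, chains=["A", "B"], residues=residues)

    truth: dict = {"pairs": {}, "spec": spec}
    for res_a, res_b, d in spec.planted_pairs:
        pairings = {}
        for p1, p2 in {(res_a, res_b), (res_b, res_a), (res_a, res_a), (res_b, res_b)}:
            pairings[(p1, p2)] = float(np.linalg.norm(foldA[p1] - foldB[p2]))
        measured = pairings[(res_a, res_b)]
        if abs(measured - d) > 1e-6:
            raise GenerationError(
                f"internal check failed: planted ({res_a},{res_b}) measures {measured:.6f}, wanted {d}"
            )
        truth["pairs"][(res_a, res_b)] = {
            "target": float(d),
            "pairings": pairings,
            "governing": min(pairings.values()),
        }
    return structure, truth


def perturb_copy(
    s: Structure,
    rotation_deg: float,
    translation: Sequence[float],
    noise_sigma: float,
    seed: int,
    axis: Sequence[float] = (1.0, 2.0, 3.0),
) -> tuple[Structure, RigidTransform]:
    """Rigid motion + i.i.d. Gaussian coordinate noise applied to every atom.

    The rigid motion is fully determined by (rotation_deg, axis, translation);
    the seed controls only the noise draw, so different seeds give different
    coordinates under the same underlying motion.  Returns the perturbed copy
    and the applied rigid transform.
    """
    if noise_sigma < 0:
        raise GenerationError(f"noise_sigma must be ≥ 0, got {noise_sigma}")
    rng = np.random.default_rng(seed)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    R = Rotation.from_rotvec(np.radians(rotation_deg) * axis).as_matrix()
    tf = RigidTransform(R, np.asarray(translation, dtype=float))

    import copy as _copy

    out = _copy.deepcopy(s)
    out.id = f"{s.id}-perturbed"
    for r in out.residues:
        for a in r.atoms:
            a.coord = tf.apply(a.coord) + rng.normal(0.0, noise_sigma, size=3)
    return out, tf


def make_observation_table(
    truth_distances: Mapping[tuple[int, int], float],
    thresholds: Mapping[float, float] = DEFAULT_THRESHOLDS,
    flip_rate: float = 0.0,
    seed: int = 0,
    temperature: float = 4.0,
) -> list[CrosslinkObservation]:
    """Observations implied by ground-truth distances under the threshold rule.

    Outcome is ``clear`` iff the governing distance is strictly under the
    temperature's cutoff, then flipped (clear↔none) with probability
    ``flip_rate`` to emulate experimental noise.
    """
    if not (0.0 <= flip_rate < 0.5):
        raise GenerationError(f"flip_rate must be in [0, 0.5), got {flip_rate}")
    cutoff = {float(t): v for t, v in thresholds.items()}.get(float(temperature))
    if cutoff is None:
        raise GenerationError(f"no threshold for temperature {temperature}")
    rng = np.random.default_rng(seed)
    obs = []
    for (a, b), dist in truth_distances.items():
        positive = dist < cutoff
        if rng.random() < flip_rate:
            positive = not positive
        obs.append(
            CrosslinkObservation(
                mutant=ResiduePairSpec(a, b),
                temperature=float(temperature),
                outcome="clear" if positive else "none",
            )
        )
    return obs
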