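"""Rigid-body Cα superposition (Kabsch) and monomer→dimer grafting.

A query NBD monomer is placed into a candidate dimer by least-squares fitting
its core-subdomain Cα atoms onto each protomer of the template in turn.  The
core subdomain is the RecA-like structurally conserved part of the NBD; using
it as the fitting frame keeps the fit insensitive to mobile peripheral
elements (A-loop, helical subdomain, D-helix).
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .mapping import ResidueMap
from .structures import Structure

__all__ = [
    "RigidTransform",
    "SuperpositionResult",
    "CoreSelection",
    "SuperpositionError",
    "kabsch_fit",
    "superpose_on_core",
    "graft_monomer_into_dimer",
    "DEFAULT_CORE",
]

log = logging.getLogger(__name__)


class SuperpositionError(ValueError):
    pass


@dataclass
class RigidTransform:
    """Proper rotation + translation; applies as ``R @ x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.rotation.shape != (3, 3):
            raise SuperpositionError("rotation must be 3×3")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-8):
            raise SuperpositionError("rotation is not orthogonal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-8):
            raise SuperpositionError("rotation has det ≠ +1 (improper)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_atoms: int
    selection_query: list[int] = field(default_factory=list)
    selection_template: list[int] = field(default_factory=list)
    degenerate: bool = False


@dataclass
class CoreSelection:
    """Inclusive residue-number intervals, in query numbering."""

    ranges: list[tuple[int, int]]

    def __post_init__(self) -> None:
        for (a, b) in self.ranges:
            if a > b:
                raise ValueError(f"range {a}-{b} is descending")
        for (a1, b1), (a2, b2) in zip(self.ranges, self.ranges[1:]):
            if a2 <= b1:
                raise ValueError("core ranges overlap or are out of order")

    def __contains__(self, pos: int) -> bool:
        return any(a <= pos <= b for a, b in self.ranges)

    def positions(self) -> list[int]:
        return [p for a, b in self.ranges for p in range(a, b + 1)]

    @classmethod
    def parse(cls, text: str) -> "CoreSelection":
        """Parse "342-352,358-406,..." into a CoreSelection."""
        ranges = []
        for part in text.split(","):
            lo, _, hi = part.strip().partition("-")
            ranges.append((int(lo), int(hi or lo)))
        return cls(ranges)

    def __str__(self) -> str:
        return ",".join(f"{a}-{b}" for a, b in self.ranges)


#: NBD core-subdomain fitting frame in LmrA numbering.
DEFAULT_CORE = CoreSelection([(342, 352), (358, 406), (500, 505), (530, 536), (545, 561)])


def kabsch_fit(coords_mobile: np.ndarray, coords_target: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of paired point sets.

    Returns the proper rotation + translation minimising the RMSD of
    ``R @ mobile + t`` against ``target``.  Reflections are excluded by the
    standard determinant correction; near-degenerate (e.g. collinear) point
    sets are flagged but still produce a transform.
    """
    P = np.asarray(coords_mobile, dtype=float)
    Q = np.asarray(coords_target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise SuperpositionError(f"point sets must both be N×3, got {P.shape} vs {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise SuperpositionError(f"need at least 3 point pairs, got {n}")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cp, Q - cq
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    transform = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(P) - Q) ** 2, axis=1))))
    # rank < 3 covariance ⇒ rotation about the deficient axis is unconstrained
    degenerate = bool(np.sum(S > 1e-9 * max(S[0], 1.0)) < 3)
    return SuperpositionResult(transform=transform, rmsd=rmsd, n_atoms=n, degenerate=degenerate)


def _paired_core_coords(
    mobile: Structure,
    target: Structure,
    target_chain: str,
    rmap: ResidueMap,
    core: CoreSelection,
    mobile_chain: str | None = None,
) -> tuple[np.ndarray, np.ndarray, list[int], list[int]]:
    mchain = mobile_chain or mobile.chains[0]
    target_res = {
        (r.seq_number): r for r in target.chain_residues(target_chain) if r.ca is not None
    }
    mobile_res = {
        (r.seq_number): r for r in mobile.chain_residues(mchain) if r.ca is not None
    }
    sel_q, sel_t, pm, pt = [], [], [], []
    dropped = []
    for pos in core.positions():
        if pos not in rmap:
            dropped.append(pos)
            continue
        tpos = rmap[pos]
        if pos not in mobile_res or tpos not in target_res:
            dropped.append(pos)
            continue
        sel_q.append(pos)
        sel_t.append(tpos)
        pm.append(mobile_res[pos].ca.coord)
        pt.append(target_res[tpos].ca.coord)
    if dropped:
        log.warning(
            "core fit %s→%s chain %s: dropped %d unmatched core residues: %s",
            mobile.id, target.id, target_chain, len(dropped), dropped,
        )
    return np.array(pm), np.array(pt), sel_q, sel_t


def superpose_on_core(
    mobile: Structure,
    target: Structure,
    target_chain: str,
    rmap: ResidueMap,
    core: CoreSelection,
    mobile_chain: str | None = None,
) -> SuperpositionResult:
    """Fit the mobile monomer's core-subdomain Cαs onto one target protomer.

    The fitted selection is the intersection of the core ranges, the residue
    map, and Cα-resolved residues on both sides; anything else is dropped
    with a logged warning (disordered loops are routine in crystal structures).
    """
    pm, pt, sel_q, sel_t = _paired_core_coords(mobile, target, target_chain, rmap, core, mobile_chain)
    if len(sel_q) < 3:
        raise SuperpositionError(
            f"only {len(sel_q)} usable core residue pairs between {mobile.id!r} "
            f"and {target.id!r} chain {target_chain!r}; need ≥ 3"
        )
    res = kabsch_fit(pm, pt)
    res.selection_query = sel_q
    res.selection_template = sel_t
    return res


def graft_monomer_into_dimer(
    monomer: Structure,
    dimer: Structure,
    chain_pair: tuple[str, str],
    rmap: ResidueMap,
    core: CoreSelection,
    monomer_chain: str | None = None,
) -> Structure:
    """Place the monomer once per template protomer; composite chains Q1/Q2.

    Each protomer is fitted independently (identical for a symmetric
    template).  The composite keeps query residue numbering, so downstream
    distance measurements address it with query positions directly.
    """
    mchain = monomer_chain or monomer.chains[0]
    fits: list[SuperpositionResult] = []
    new_residues = []
    for i, tchain in enumerate(chain_pair, start=1):
        fit = superpose_on_core(monomer, dimer, tchain, rmap, core, mobile_chain=mchain)
        fits.append(fit)
        for r in monomer.chain_residues(mchain):
            rc = copy.deepcopy(r)
            rc.chain_id = f"Q{i}"
            for a in rc.atoms:
                a.coord = fit.transform.apply(a.coord)
            new_residues.append(rc)
    composite = Structure(
        id=f"{monomer.id}@{dimer.id}",
        chains=["Q1", "Q2"],
        residues=new_residues,
        metadata={
            "template": dimer.id,
            "template_chains": list(chain_pair),
            "fit_rmsd": [f.rmsd for f in fits],
            "fit_n_atoms": [f.n_atoms for f in fits],
        },
    )
    return composite
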