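"""Minimal Cα-centric macromolecular structure model backed by gemmi.

Everything downstream of this module works on alpha-carbon geometry: the
cross-link proximity metric is the Euclidean Cα–Cα distance, and rigid-body
fits use Cα selections only.  The model therefore keeps a flat, ordered list
of residues, each carrying its author-assigned number (mutant positions such
as A433 or S516 are author numbers, never sequential indices) and whatever
atoms the input provided.
"""

from __future__ import annotations

import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "Structure",
    "StructureError",
    "read_structure",
    "chain_sequence",
    "write_structure",
    "fetch_structure",
]

_AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_AA1_TO_3 = {v: k for k, v in _AA3_TO_1.items()}
_AA1_TO_3["X"] = "UNK"


class StructureError(ValueError):
    """Raised for unparseable, empty, or internally inconsistent structures."""


@dataclass
class AtomRecord:
    name: str
    element: str
    coord: np.ndarray  # 3-vector, Å
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise StructureError(f"atom {self.name!r}: coord must be a finite 3-vector")
        if not (0.0 <= self.occupancy <= 1.0):
            raise StructureError(f"atom {self.name!r}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class ResidueRecord:
    chain_id: str
    seq_number: int
    insertion_code: str
    aa_code: str
    atoms: list[AtomRecord] = field(default_factory=list)
    res_name: str = ""  # three-letter name, kept for faithful output

    def __post_init__(self) -> None:
        if not self.res_name:
            self.res_name = _AA1_TO_3.get(self.aa_code, "UNK")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> AtomRecord | None:
        return self.atom("CA")


@dataclass
class Structure:
    """Ordered residues of one model, grouped implicitly by chain."""

    id: str
    chains: list[str]
    residues: list[ResidueRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chains:
            raise StructureError(f"structure {self.id!r} has no chains")
        seen: set[tuple[str, int, str]] = set()
        for r in self.residues:
            if r.key in seen:
                raise StructureError(f"duplicate residue {r.key} in structure {self.id!r}")
            seen.add(r.key)

    def chain_residues(self, chain_id: str) -> list[ResidueRecord]:
        if chain_id not in self.chains:
            raise KeyError(f"chain {chain_id!r} not in structure {self.id!r} (has {self.chains})")
        return [r for r in self.residues if r.chain_id == chain_id]

    def residue(self, chain_id: str, seq_number: int, insertion_code: str = "") -> ResidueRecord:
        for r in self.residues:
            if r.key == (chain_id, seq_number, insertion_code):
                return r
        raise KeyError(
            f"residue {seq_number}{insertion_code} of chain {chain_id!r} "
            f"not found in structure {self.id!r}"
        )

    def ca_coord(self, chain_id: str, seq_number: int, insertion_code: str = "") -> np.ndarray:
        res = self.residue(chain_id, seq_number, insertion_code)
        ca = res.ca
        if ca is None:
            raise KeyError(
                f"residue {seq_number}{insertion_code} of chain {chain_id!r} has no Cα"
            )
        return ca.coord


def _resolve_altloc(atoms: Iterable[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc label."""
    by_name: dict[str, list[AtomRecord]] = {}
    for a in atoms:
        by_name.setdefault(a.name, []).append(a)
    resolved = []
    for name, group in by_name.items():
        best = min(group, key=lambda a: (-a.occupancy, a.altloc))
        best.altloc = ""
        resolved.append(best)
    return resolved


def read_structure(path_or_text: str | Path, model_index: int = 0, id: str | None = None) -> Structure:
    """Parse a PDB-format source into a :class:`Structure`.

    ``path_or_text`` may be a filesystem path or raw PDB text.  Only the
    selected model is kept (the first by default; deposited crystal structures
    have one).  HETATM records and waters are excluded; alternate locations
    are resolved to the highest-occupancy conformer.
    """
    src_id = id
    if isinstance(path_or_text, Path) or (
        isinstance(path_or_text, str) and "\n" not in path_or_text
    ):
        p = Path(path_or_text)
        if not p.exists():
            raise StructureError(f"no such file: {p}")
        text = p.read_text()
        src_id = src_id or p.stem
    else:
        text = str(path_or_text)
        src_id = src_id or "structure"
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse PDB source: {exc}") from exc
    st.setup_entities()
    if len(st) == 0 or model_index >= len(st):
        raise StructureError(f"no model {model_index} in {src_id!r}")
    model = st[model_index]

    chains: list[str] = []
    residues: list[ResidueRecord] = []
    for chain in model:
        chain_added = False
        for res in chain:
            het = res.het_flag  # 'A' for ATOM, 'H' for HETATM
            if het != "A" or res.name == "HOH":
                continue
            atoms = [
                AtomRecord(
                    name=a.name,
                    element=a.element.name,
                    coord=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=min(max(a.occ, 0.0), 1.0),
                    altloc=a.altloc if a.altloc != "\x00" else "",
                )
                for a in res
            ]
            if not atoms:
                continue
            rec = ResidueRecord(
                chain_id=chain.name,
                seq_number=res.seqid.num,
                insertion_code=res.seqid.icode.strip(),
                aa_code=_AA3_TO_1.get(res.name, "X"),
                atoms=_resolve_altloc(atoms),
                res_name=res.name,
            )
            residues.append(rec)
            chain_added = True
        if chain_added and chain.name not in chains:
            chains.append(chain.name)
    if not residues:
        raise StructureError(f"structure {src_id!r} contains no protein residues")
    return Structure(id=src_id, chains=chains, residues=residues)


def chain_sequence(s: Structure, chain_id: str) -> list[tuple[int, str]]:
    """(author number, one-letter code) for each Cα-resolved residue, in chain order.

    Numbering gaps are preserved as jumps — callers that align this sequence
    must carry the numbering list alongside the letters.
    """
    out = [(r.seq_number, r.aa_code) for r in s.chain_residues(chain_id) if r.ca is not None]
    return out


def write_structure(s: Structure, path: str | Path) -> None:
    """Write ``s`` as PDB via gemmi; round-trips chain ids, author numbering and Cα coords."""
    if not s.residues:
        raise StructureError("refusing to write a structure with no residues")
    st = gemmi.Structure()
    st.name = s.id
    model = gemmi.Model("1")
    for chain_id in s.chains:
        chain = gemmi.Chain(chain_id)
        for r in s.chain_residues(chain_id):
            res = gemmi.Residue()
            res.name = r.res_name
            res.seqid = gemmi.SeqId(r.seq_number, r.insertion_code or " ")
            res.het_flag = "A"
            for a in r.atoms:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.element = gemmi.Element(a.element or a.name[:1])
                atom.pos = gemmi.Position(*a.coord)
                atom.occ = a.occupancy
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


_PDB_URL = "https://files.rcsb.org/download/{}.pdb"


def fetch_structure(pdb_id: str, cache_dir: str | Path, timeout: float = 30.0) -> Path:
    """Download a PDB entry by 4-character accession into ``cache_dir``.

    Purely opt-in: every other operation in the package is offline.  Returns
    the cached path; an existing cached file is never re-downloaded.
    """
    pdb_id = pdb_id.lower()
    if len(pdb_id) != 4:
        raise ValueError(f"{pdb_id!r} is not a 4-character PDB accession")
    cache = Path(cache_dir)
    cache.mkdir(parents=True, exist_ok=True)
    dest = cache / f"{pdb_id}.pdb"
    if dest.exists():
        return dest
    url = _PDB_URL.format(pdb_id.upper())
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        data = resp.read()
    dest.write_bytes(data)
    return dest
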