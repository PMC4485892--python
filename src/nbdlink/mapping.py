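"""Residue equivalences between a query NBD and a template by global alignment.

The pipeline needs to know, for every LmrA position carrying an engineered
cysteine, which residue of the template dimer (Sav1866, MsbA) sits at the
structurally equivalent position.  A pairwise Needleman–Wunsch alignment with
affine gaps (BLOSUM62, open 10, extend 0.5 by default) supplies the
equivalences; a packaged reference table of the published pairings acts as a
regression guard (`validate_against_reference`), since the downstream science
depends on the pairings, not on any particular aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "AlignmentResult",
    "ResidueMap",
    "MappingError",
    "align_global",
    "build_residue_map",
    "validate_against_reference",
    "map_structures",
    "read_fasta",
]

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


class MappingError(ValueError):
    pass


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    matrix_name: str
    gap_open: float
    gap_extend: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise MappingError("aligned sequences differ in length")

    @property
    def seq_a(self) -> str:
        return self.aligned_a.replace("-", "")

    @property
    def seq_b(self) -> str:
        return self.aligned_b.replace("-", "")


@dataclass
class ResidueMap:
    """One-to-one partial mapping query residue number → template residue number."""

    query_id: str
    template_id: str
    pairs: dict[int, int] = field(default_factory=dict)
    unmapped: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        items = sorted(self.pairs.items())
        tmpl = [t for _, t in items]
        if len(set(tmpl)) != len(tmpl):
            raise MappingError("residue map is not one-to-one")
        if any(b >= d for (_, b), (_, d) in zip(items, items[1:])):
            raise MappingError("residue map is not monotone increasing")

    def __contains__(self, query_pos: int) -> bool:
        return query_pos in self.pairs

    def __getitem__(self, query_pos: int) -> int:
        try:
            return self.pairs[query_pos]
        except KeyError:
            raise KeyError(
                f"query position {query_pos} has no equivalent in template "
                f"{self.template_id!r}"
            ) from None

    @classmethod
    def identity(cls, positions: Iterable[int], query_id: str = "query",
                 template_id: str = "template") -> "ResidueMap":
        return cls(query_id, template_id, {p: p for p in positions})


def align_global(
    seq_a: str,
    seq_b: str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    match: float = 1.0,
    mismatch: float = -1.0,
) -> AlignmentResult:
    """Optimal global alignment with affine gap penalties (given as positive costs).

    ``matrix_name`` is a Biopython substitution-matrix name, or ``"simple"``
    for plain match/mismatch scoring (useful for hand-checkable examples).
    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.
    """
    for name, seq in (("seq_a", seq_a), ("seq_b", seq_b)):
        if not seq:
            raise MappingError(f"{name} is empty")
        bad = set(seq.upper()) - _AA_ALPHABET
        if bad:
            raise MappingError(f"{name} contains non-amino-acid letters {sorted(bad)}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if matrix_name == "simple":
        aligner.match_score = match
        aligner.mismatch_score = mismatch
    else:
        try:
            matrix = substitution_matrices.load(matrix_name)
        except FileNotFoundError as exc:
            raise MappingError(f"unknown substitution matrix {matrix_name!r}") from exc
        aligner.substitution_matrix = matrix
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]  # deterministic first optimum
    gapped_a, gapped_b = _gapped_strings(aln)
    return AlignmentResult(
        aligned_a=gapped_a,
        aligned_b=gapped_b,
        score=float(aln.score),
        matrix_name=matrix_name,
        gap_open=float(gap_open),
        gap_extend=float(gap_extend),
    )


def _gapped_strings(aln) -> tuple[str, str]:
    # Alignment.__getitem__ gives the gapped row for each sequence.
    return str(aln[0]), str(aln[1])


def build_residue_map(
    aln: AlignmentResult,
    numbering_a: Sequence[int],
    numbering_b: Sequence[int],
    query_id: str = "query",
    template_id: str = "template",
) -> ResidueMap:
    """Turn an alignment plus author-numbering lists into a ResidueMap.

    Each (non-gap, non-gap) column yields one pair; query positions in gap
    columns go to ``unmapped``.
    """
    if len(numbering_a) != len(aln.seq_a):
        raise MappingError(
            f"numbering_a has {len(numbering_a)} entries for {len(aln.seq_a)} residues"
        )
    if len(numbering_b) != len(aln.seq_b):
        raise MappingError(
            f"numbering_b has {len(numbering_b)} entries for {len(aln.seq_b)} residues"
        )
    pairs: dict[int, int] = {}
    unmapped: set[int] = set()
    ia = ib = 0
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if ca != "-" and cb != "-":
            pairs[numbering_a[ia]] = numbering_b[ib]
        elif ca != "-":
            unmapped.add(numbering_a[ia])
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
    return ResidueMap(query_id=query_id, template_id=template_id, pairs=pairs, unmapped=unmapped)


@dataclass
class ValidationReport:
    matched: list[tuple[int, int]]
    mismatched: list[tuple[int, int, int | None]]  # (query, expected, got-or-None-if-mapped-elsewhere)
    missing: list[tuple[int, int]]  # reference pairs absent from the map

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatched)

    @property
    def ok(self) -> bool:
        return not self.mismatched and not self.missing


def validate_against_reference(
    rmap: ResidueMap, reference_pairs: Iterable[tuple[int, int]]
) -> ValidationReport:
    """Compare a computed map against curated (query, template) reference pairs."""
    matched, mismatched, missing = [], [], []
    for q, t in reference_pairs:
        if q in rmap.pairs:
            if rmap.pairs[q] == t:
                matched.append((q, t))
            else:
                mismatched.append((q, t, rmap.pairs[q]))
        else:
            missing.append((q, t))
    return ValidationReport(matched=matched, mismatched=mismatched, missing=missing)


def map_structures(
    query_numbered_seq: Sequence[tuple[int, str]],
    template_numbered_seq: Sequence[tuple[int, str]],
    query_id: str = "query",
    template_id: str = "template",
    **align_kwargs,
) -> ResidueMap:
    """Align two (number, letter) sequences (e.g. from chain_sequence) into a map."""
    nums_a = [n for n, _ in query_numbered_seq]
    nums_b = [n for n, _ in template_numbered_seq]
    seq_a = "".join(c for _, c in query_numbered_seq)
    seq_b = "".join(c for _, c in template_numbered_seq)
    aln = align_global(seq_a, seq_b, **align_kwargs)
    return build_residue_map(aln, nums_a, nums_b, query_id=query_id, template_id=template_id)


def read_fasta(path: str | Path) -> dict[str, str]:
    """id → sequence for every record in a FASTA file."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
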