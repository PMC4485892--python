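"""End-to-end orchestration: structures + sequences + observations → reports.

A run is described by one declarative YAML config.  The stages are:

1. read the query sequence, the monomer structure (if grafting is needed)
   and each candidate dimer template;
2. build a residue map per template by global alignment of the query
   sequence against the template chain sequence (or take numbering as
   shared, for synthetic templates built in query numbering);
3. measure the governing inter-protomer Cα–Cα distance for every mutant in
   every conformation (minimum-over-pairings rule; unmapped or explicitly
   listed positions via the grafted composite);
4. classify each mutant under the temperature-appropriate distance
   threshold and score concordance with the observed outcomes.

Outputs are three TSVs (distances, calls, concordance) plus a JSON-lines run
log; identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import crosslink as xl
from .crosslink import Conformation, CrosslinkObservation, DistanceRecord, ResiduePairSpec
from .datasets import read_observations
from .mapping import ResidueMap, align_global, build_residue_map, read_fasta
from .structures import Structure, read_structure
from .superpose import CoreSelection, DEFAULT_CORE

__all__ = ["ConformationConfig", "RunConfig", "PipelineError", "run_pipeline", "render_distance_table"]


class PipelineError(RuntimeError):
    pass


@dataclass
class ConformationConfig:
    label: str
    structure: str
    chain_pair: tuple[str, str]
    graft_positions: list[int] = field(default_factory=list)
    identity_numbering: bool = False  # template already in query numbering


@dataclass
class RunConfig:
    conformations: list[ConformationConfig]
    observations: str
    output_dir: str
    query_sequence: str | None = None  # FASTA; required unless all templates share numbering
    monomer: str | None = None
    core_selection: str = str(DEFAULT_CORE)
    thresholds: dict[float, float] = field(default_factory=lambda: dict(xl.DEFAULT_THRESHOLDS))
    alignment: dict = field(default_factory=lambda: {"matrix_name": "BLOSUM62", "gap_open": 10.0, "gap_extend": 0.5})
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.conformations:
            raise PipelineError("config must declare at least one conformation")
        self.thresholds = {float(k): float(v) for k, v in self.thresholds.items()}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        confs = [
            ConformationConfig(
                label=c["label"],
                structure=c["structure"],
                chain_pair=tuple(c["chain_pair"]),
                graft_positions=list(c.get("graft_positions", [])),
                identity_numbering=bool(c.get("identity_numbering", False)),
            )
            for c in raw.pop("conformations")
        ]
        base = Path(path).parent
        cfg = cls(conformations=confs, **raw)
        # resolve paths relative to the config file
        cfg.observations = str((base / cfg.observations))
        if cfg.query_sequence:
            cfg.query_sequence = str(base / cfg.query_sequence)
        if cfg.monomer:
            cfg.monomer = str(base / cfg.monomer)
        cfg.output_dir = str(base / cfg.output_dir)
        for c in cfg.conformations:
            c.structure = str(base / c.structure)
        return cfg


def _mutant_specs(observations: Sequence[CrosslinkObservation]) -> list[ResiduePairSpec]:
    seen: dict[str, ResiduePairSpec] = {}
    for o in observations:
        seen.setdefault(o.mutant.label, o.mutant)
    return list(seen.values())


def _distance_rows(specs: Sequence[ResiduePairSpec]) -> list[ResiduePairSpec]:
    """Expand mutants into the tabulated row set: one a/a row per position and
    one a/b row per double mutant, preserving first-appearance order."""
    rows: dict[str, ResiduePairSpec] = {}
    for spec in specs:
        if not spec.is_single:
            rows.setdefault(f"{spec.pos_a}/{spec.pos_b}", ResiduePairSpec(spec.pos_a, spec.pos_b))
        for p in spec.positions:
            rows.setdefault(f"{p}/{p}", ResiduePairSpec(p, p))
    return list(rows.values())


def _build_conformation(cc: ConformationConfig, cfg: RunConfig, log: list[dict]) -> Conformation:
    dimer = read_structure(cc.structure)
    rmap: ResidueMap | None = None
    if not cc.identity_numbering:
        if not cfg.query_sequence:
            raise PipelineError(
                f"conformation {cc.label!r} needs a residue map but no query_sequence is configured"
            )
        seqs = read_fasta(cfg.query_sequence)
        qid, qseq = next(iter(seqs.items()))
        from .structures import chain_sequence

        tseq = chain_sequence(dimer, cc.chain_pair[0])
        aln = align_global(qseq, "".join(c for _, c in tseq), **cfg.alignment)
        rmap = build_residue_map(
            aln,
            list(range(1, len(qseq) + 1)),
            [n for n, _ in tseq],
            query_id=qid,
            template_id=dimer.id,
        )
        log.append({
            "stage": "alignment", "conformation": cc.label,
            "score": aln.score, "matrix": aln.matrix_name,
            "gap_open": aln.gap_open, "gap_extend": aln.gap_extend,
            "n_pairs": len(rmap.pairs), "n_unmapped": len(rmap.unmapped),
        })
    monomer = read_structure(cfg.monomer) if cfg.monomer else None
    conf = Conformation(
        label=cc.label,
        dimer=dimer,
        chain_pair=cc.chain_pair,
        rmap=rmap,
        monomer=monomer,
        core=CoreSelection.parse(cfg.core_selection),
        graft_positions=frozenset(cc.graft_positions),
    )
    return conf


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute a configured run; returns the in-memory results and writes TSVs.

    All outputs are buffered and written only after every stage has
    succeeded, so a failed run leaves no partial output files.
    """
    log: list[dict] = []
    observations = read_observations(cfg.observations)
    if not observations:
        raise PipelineError(f"no observations in {cfg.observations}")
    temps = sorted({o.temperature for o in observations})
    missing = [t for t in temps if t not in cfg.thresholds]
    if missing:
        raise PipelineError(
            f"observations contain temperatures {missing} with no configured threshold"
        )
    log.append({"stage": "config", "thresholds": {str(k): v for k, v in cfg.thresholds.items()},
                "core_selection": cfg.core_selection, "seed": cfg.seed})

    mutants = _mutant_specs(observations)
    conformations = [_build_conformation(cc, cfg, log) for cc in cfg.conformations]

    records: list[DistanceRecord] = []
    calls_rows: list[dict] = []
    concordance_rows: list[dict] = []
    for conf in conformations:
        try:
            for row_spec in _distance_rows(mutants):
                records.append(xl.pair_distance_in_conformation(row_spec, conf))
            if conf._composite is not None:
                log.append({
                    "stage": "graft", "conformation": conf.label,
                    **{k: v for k, v in conf.composite.metadata.items() if k != "template"},
                })
            for temp in temps:
                group = [o for o in observations if o.temperature == temp]
                group_calls = []
                for o in group:
                    rec = xl.governing_distance(o.mutant, conf)
                    call = xl.classify_crosslink(rec, temp, cfg.thresholds)
                    group_calls.append(call)
                    calls_rows.append({
                        "mutant": o.mutant.label,
                        "conformation": conf.label,
                        "temperature_C": temp,
                        "governing_distance_A": round(call.governing_distance, 2),
                        "threshold_A": call.threshold_used,
                        "predicted": call.predicted,
                        "observed": o.outcome,
                        "pairing": rec.pairing_detail,
                    })
                rep = xl.score_concordance(group_calls, group)
                concordance_rows.append({
                    "conformation": conf.label,
                    "temperature_C": temp,
                    "n_observations": rep.n_observations,
                    "n_concordant": rep.n_concordant,
                    "discordant": ";".join(rep.discordant) or "-",
                })
        except xl.CrosslinkError as exc:
            raise PipelineError(f"conformation {conf.label!r}: {exc}") from exc

    dist_rows = [
        {
            "pair": r.pair.label,
            "conformation": r.conformation_id,
            "route": r.route,
            "pairing": r.pairing_detail,
            "distance_A": round(r.distance, 2),
        }
        for r in records
    ]

    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(dist_rows).to_csv(outdir / "distances.tsv", sep="\t", index=False, float_format="%.2f")
    pd.DataFrame(calls_rows).to_csv(outdir / "calls.tsv", sep="\t", index=False, float_format="%.2f")
    pd.DataFrame(concordance_rows).to_csv(outdir / "concordance.tsv", sep="\t", index=False)
    with open(outdir / "run_log.jsonl", "w") as fh:
        for entry in log:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")

    return {
        "records": records,
        "calls": calls_rows,
        "concordance": concordance_rows,
        "log": log,
    }


def render_distance_table(records: Sequence[DistanceRecord], pair_order: Sequence[str] | None = None) -> pd.DataFrame:
    """Wide comparison table: one row per pair label, one distance column per
    conformation, with the template-pairing annotation alongside."""
    conf_ids = sorted({r.conformation_id for r in records})
    by_key = {(r.pair.label, r.conformation_id): r for r in records}
    labels = list(pair_order) if pair_order else []
    for r in records:
        if r.pair.label not in labels:
            labels.append(r.pair.label)
    labels = [l for l in labels if any((l, c) in by_key for c in conf_ids)]
    rows = []
    for label in labels:
        row: dict = {"pair": label}
        for conf in conf_ids:
            r = by_key.get((label, conf))
            row[f"{conf}_pairing"] = r.pairing_detail if r else "-"
            row[f"{conf}_distance_A"] = round(r.distance, 2) if r else float("nan")
        rows.append(row)
    cols = ["pair"] + [f"{c}_{suffix}" for c in conf_ids for suffix in ("pairing", "distance_A")]
    return pd.DataFrame(rows, columns=cols)
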