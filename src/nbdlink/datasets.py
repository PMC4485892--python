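"""Packaged reference datasets for the LmrA NBD cross-linking study.

Three small TSVs ship with the package:

* ``reference_distances.tsv`` — the predicted inter-protomer Cα–Cα distances
  for the nine LmrA residue pairings in the two candidate conformations
  (the head-to-tail "sandwich" dimer, templated on Sav1866/2HYD, and the
  inward-facing closed arrangement of *V. cholerae* MsbA/3B5X), with the
  template residue pairing and the prediction route for each cell.  These
  serve both as inputs for conformation scoring when the deposited structures
  are not on disk and as the regression reference when they are.
* ``reference_equivalences.tsv`` — the curated query↔template residue
  equivalences underlying those distances (e.g. LmrA A433 ↔ Sav1866 I425).
* ``crosslink_observations.tsv`` — observed cross-linking outcomes for the
  nine cysteine constructs at 4 °C and the three single mutants at 21 °C.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .crosslink import (
    CompatibilityCall,
    ConcordanceReport,
    CrosslinkObservation,
    DistanceRecord,
    ResiduePairSpec,
    DEFAULT_THRESHOLDS,
    classify_crosslink,
    governing_distance_from_records,
    score_concordance,
)

__all__ = [
    "load_reference_distances",
    "load_reference_equivalences",
    "reference_pairs",
    "load_observations",
    "read_observations",
    "discriminate_conformations",
    "CANONICAL_PAIR_ORDER",
]

#: Row order of the published prediction table, used for stable report layout.
CANONICAL_PAIR_ORDER = [
    "A433/A433", "M435/M435", "S516/S516", "S361/K486", "S361/S361",
    "K486/K486", "P383/E520", "P383/P383", "E520/E520",
]


def _data_path(name: str) -> Path:
    return Path(resources.files("nbdlink.data") / name)


def load_reference_distances(path: str | Path | None = None) -> list[DistanceRecord]:
    df = pd.read_csv(path or _data_path("reference_distances.tsv"), sep="\t")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            DistanceRecord(
                pair=ResiduePairSpec(int(row.pos_a), int(row.pos_b), row.pair_label),
                conformation_id=row.conformation,
                route=row.route,
                distance=float(row.distance),
                pairing_detail=row.template_pair,
            )
        )
    return records


def load_reference_equivalences(path: str | Path | None = None) -> pd.DataFrame:
    return pd.read_csv(path or _data_path("reference_equivalences.tsv"), sep="\t")


def reference_pairs(template_id: str) -> list[tuple[int, int]]:
    """(query, template) residue-number pairs curated for one template."""
    df = load_reference_equivalences()
    sub = df[df.template_id == template_id]
    if sub.empty:
        raise KeyError(f"no reference equivalences for template {template_id!r}")
    return [(int(q), int(t)) for q, t in zip(sub.query_pos, sub.template_pos)]


def read_observations(path: str | Path, temperature: float | None = None) -> list[CrosslinkObservation]:
    """Read a cross-linking observation TSV, optionally filtered by temperature."""
    df = pd.read_csv(path, sep="\t")
    obs = [
        CrosslinkObservation(
            mutant=ResiduePairSpec(int(r.pos_a), int(r.pos_b), r.mutant_label),
            temperature=float(r.temperature_C),
            outcome=r.outcome,
        )
        for r in df.itertuples(index=False)
    ]
    if temperature is not None:
        obs = [o for o in obs if o.temperature == float(temperature)]
    return obs


def load_observations(temperature: float | None = None) -> list[CrosslinkObservation]:
    return read_observations(_data_path("crosslink_observations.tsv"), temperature)


def discriminate_conformations(
    records: Sequence[DistanceRecord],
    observations: Sequence[CrosslinkObservation],
    thresholds: Mapping[float, float] = DEFAULT_THRESHOLDS,
) -> dict[str, tuple[ConcordanceReport, list[CompatibilityCall]]]:
    """Score every conformation in ``records`` against the observations.

    For each observed mutant the governing distance is taken as the minimum
    over the tabulated pairings among its positions, classified under the
    temperature-appropriate threshold, and compared with the observed
    outcome.  Observations at different temperatures are scored within their
    own threshold and pooled into one report per conformation.
    """
    conf_ids = sorted({r.conformation_id for r in records})
    out: dict[str, tuple[ConcordanceReport, list[CompatibilityCall]]] = {}
    for conf_id in conf_ids:
        calls: list[CompatibilityCall] = []
        reports: list[ConcordanceReport] = []
        for temp in sorted({o.temperature for o in observations}):
            group = [o for o in observations if o.temperature == temp]
            group_calls = []
            for o in group:
                rec = governing_distance_from_records(records, o.mutant, conf_id)
                group_calls.append(classify_crosslink(rec, temp, thresholds))
            reports.append(score_concordance(group_calls, group))
            calls.extend(group_calls)
        merged = ConcordanceReport(
            conformation_id=conf_id,
            n_observations=sum(r.n_observations for r in reports),
            n_concordant=sum(r.n_concordant for r in reports),
            discordant=[m for r in reports for m in r.discordant],
        )
        out[conf_id] = (merged, calls)
    return out
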