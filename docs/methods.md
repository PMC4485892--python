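# Methods

## Model and assumptions

The package treats conformational discrimination by sulfhydryl cross-linking
as a geometric classification problem. Given a candidate dimer arrangement
of the two NBDs, every engineered cysteine construct defines a set of
inter-protomer residue pairings; the construct is predicted to form a
disulfide iff the shortest of those pairings is within cross-linking range.
The assumptions are:

* **Cα geometry is sufficient.** Distances are measured between Cα atoms,
  not Sγ or Cβ; this matches how such predictions are tabulated, avoids
  rotamer modelling, and tolerates Cα-only deposited coordinates (the MsbA
  entry used as the inward-closed template is a Cα trace). Side-chain reach
  and flexibility are absorbed into the threshold, not modelled.
* **Minimum-over-pairings.** A homodimer duplicates each substitution, so a
  single mutant can form one cross-link (a–a′) and a double mutant any of
  a–b′, b–a′, a–a′, b–b′. The governing distance is the minimum: a disulfide
  forms at the shortest achievable pairing. For an asymmetric template the
  a–b′ and b–a′ distances differ; the minimising pairing is recorded.
* **Sharp temperature-dependent threshold.** A construct is compatible iff
  its governing distance is *strictly* below the cutoff for the reaction
  temperature. At 4 °C, where thermal motion is minimal, the cutoff is 14 Å.
  At 21 °C increased domain motion brings more distant pairs into transient
  contact; the default 21 Å cutoff is a package calibration chosen to admit
  the distances observed to cross-link only at the higher temperature
  (14.1 Å and 20.1 Å) while excluding clearly distal pairs, and is exposed
  as configuration, not hard-coded.
* **Binary outcomes.** Weak and clear cross-linked products both count as
  positive; band intensity is not modelled.

## Residue mapping

Query↔template equivalences come from pairwise global alignment
(Needleman–Wunsch with affine gaps; BLOSUM62, gap open 10, gap extend 0.5 by
default; a gap of length L costs `open + (L−1)·extend`). The aligner is
Biopython's `PairwiseAligner`; its first optimum is deterministic, and its
score is pinned by an independent Gotoh dynamic-programming oracle in the
test suite. Because the downstream science depends on the *pairings* rather
than on any particular aligner, the curated equivalence table shipped with
the package acts as a regression guard (`validate_against_reference`): a
parameter change that silently shifted an equivalence would be caught, and a
genuine disagreement is reported, never auto-corrected.

Maps are one-to-one and monotone by construction; query positions aligned to
gaps are recorded as unmapped and automatically routed through structural
grafting.

## Superposition and grafting

Rigid-body fits use the closed-form Kabsch solution (SVD with determinant
correction, so reflections are excluded) on Cα coordinates, unweighted.
Near-degenerate point sets (rank-deficient covariance, e.g. collinear Cαs)
are flagged in the result rather than rejected. Scipy's independent Wahba
solver cross-checks the rotation in tests.

Grafting places a query monomer once per template protomer: the fit is
restricted to the conserved core subdomain (default LmrA 342–352, 358–406,
500–505, 530–536, 545–561, configurable as a range string), intersected with
the residue map and with Cα-resolved residues on both sides; missing core
residues are dropped pairwise with a logged warning, and fewer than three
surviving pairs is an error. Both protomers are fitted independently — for a
symmetric template the two fits coincide, for an asymmetric one this is the
more general choice. Composite chains are relabelled Q1/Q2 and keep query
numbering, so mixed measurements (a grafted position against a directly
mapped one on the opposite protomer) are taken in a single frame.

The A-loop position S361 has no unambiguous sequence equivalent in the
sandwich template (that A-loop is one residue longer), so the sandwich
conformation lists it as a forced-graft position; in the MsbA template it
maps directly (to K354).

## Synthetic data

`make_toy_dimer` builds two-chain Cα dimers from an idealised helical trace
(radius 2.3 Å, rise 1.5 Å, 100°/residue → 3.8 Å consecutive spacing), places
protomer 2 by a configurable rigid transform, and then re-places designated
chain-B residues so that each planted cross-protomer distance holds exactly
(verified internally to 1e-6 Å; an identity protomer transform, a
non-positive target, or a residue reused across planted pairs is a
generation error). Ground truth is measured on the final coordinates, so the
minimum-pairing rule is testable even where planting perturbs the
unconstrained pairings. `perturb_copy` applies a deterministic rigid motion
plus seeded isotropic Gaussian noise; `make_observation_table` converts
ground-truth distances into outcomes under the threshold rule with an
optional seeded flip rate.

What the fixtures do **not** emulate: realistic protein packing, side
chains, disorder, crystallographic error correlated along the chain, or
intensity-graded outcomes. Passing synthetic tests therefore demonstrates
correctness of the geometry, classification and scoring machinery, not the
adequacy of the thresholds for any particular real protein.

## Numerical choices

* Alternate locations resolve to the highest-occupancy conformer, ties by
  altloc label order; HETATM and waters are excluded; only the first model
  of multi-model files is read. Author residue numbering is preserved
  throughout (all mutant labels are author numbers).
* PDB output stores 3 decimals, so file round-trips preserve coordinates to
  1e-3 Å; in-memory pipelines are exact to 1e-6 Å and tested at that level.
* Threshold comparison is strict (`<`); a governing distance exactly at the
  cutoff is incompatible.
* Report TSVs print distances at 2 decimals; the run log keeps full
  precision. Row and key orders are fixed, making reruns byte-identical.
* Template chain pairs default to the first two protein chains of the
  deposited entry and are configurable; the choice is logged.

## Problem sizes

Synthetic fixtures use 20–60 residues per protomer and seven planted
distances (mirroring the nine-row study layout); noise calibration uses 500
simulated constructs at a 20% flip rate; alignment oracles run on random
pairs of length ≤ 12, where exhaustive dynamic programming is an independent
ground truth. The full deposited-structure analysis (three PDB entries, two
conformations, nine pairings) runs in seconds once the coordinate files are
cached locally.

## Known limitations

* Cα–Cα distance is a proxy: no Cβ/Sγ option, no cysteine rotamer sampling,
  no cross-linking kinetics. The E520C single-mutant cross-link, which
  disagrees with the sandwich-dimer prediction (23.3 Å), is *reported* as a
  discordance; the mobility of the D-helix that plausibly explains it is
  outside the model.
* The mapping is sequence-based pairwise alignment, not structure-guided or
  progressive multiple alignment; the curated equivalence table is the
  safeguard.
* Deposited-coordinate reproduction requires the PDB files on disk; the
  package ships only the curated tables, and the fetch helper is strictly
  opt-in.
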