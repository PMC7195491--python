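# Methods

## Model and assumptions

`negcon` operates on a heterophilic paralog family partitioned into
interaction-specificity subgroups on each side (labelled DIP and Dpr), with
a bijective cognate map between sides. A negative constraint for a
non-cognate pair (DIP-i, Dpr-j) on one side of the interface is a
family-wide interfacial position whose residues, when introduced into the
cognate complex, destabilize it — certified jointly by an energy filter
over mutational ΔΔG scans and an evolutionary filter over ortholog
subfamily alignments. The underlying assumptions are that (a) the primary
determinants of specificity are interfacial, (b) orthologs within a
subfamily conserve interaction specificity, so divergence *between*
subfamilies that is conserved *within* them marks specificity-relevant
positions, and (c) the scan engine's replicate-mean ΔΔG is a usable proxy
for the true destabilization, with its self-mutation spread setting the
resolution limit.

Directionality: Dpr-side constraints of pair (DIP-i, Dpr-j) are identified
by mutating the Dpr protomer of DIP-i's cognate templates into Dpr-j
residues, and by comparing the Dpr subfamily cognate to DIP-i against
Dpr-j in the evolutionary filter; DIP-side constraints are the mirror
image over Dpr-j's cognate templates.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| ΔΔG threshold | 0.05 (inclusive) | kcal/mol | equals the self-mutation spread of the scan engine; below it a "destabilization" is indistinguishable from run noise |
| entropy cutoff | 0.23 | base-21 entropy | just above log₂₁2 ≈ 0.2277, so a clean two-state column still counts as conserved |
| property / size cutoffs | 90 | % | near-unanimity of occurrence-weighted cross-pairs |
| temperature (K_D conversion) | 298.15 | K | binding assays at 25 °C |
| gas constant | 1.9872 × 10⁻³ | kcal mol⁻¹ K⁻¹ | — |

Entropy always uses log base 21 regardless of how many symbols are
observed, with 0·log 0 ≡ 0; comparisons use the strict inequalities as
stated (S < 0.23, percent > 90) at full double precision, and the ΔΔG
comparison is inclusive (≥ 0.05).

## Design choices where the procedure was open

- **"Different in identity"** for non-degenerate conserved columns is
  judged on modal-residue sets: every amino acid tied for the maximum
  frequency (gap excluded from modality); the condition requires the two
  sets to be disjoint. This reduces to consensus comparison when modes are
  unique and is conservative under ties.
- **Gap handling in the percent differences**: gaps pair with nothing and
  frequencies are *not* renormalized over the 20 amino acids, so gap-rich
  columns cannot reach the 90% cutoffs — fail-safe for constraint calling.
  The renormalized variant is available behind
  `EvoFilterParams(renormalize_gaps=True)`.
- **Pairwise identity with gaps**: columns gapped in both rows are excluded
  from numerator and denominator; gap against residue counts as mismatch.
- **Coverage is fail-closed**: the energy filter certifies an "every
  member, every template" claim, so a missing template × member
  combination fails the position. Members sharing the template's wild-type
  residue at a position generate no mutation and are exempt; a position
  where every combination is exempt is reported not-applicable
  (`EnergyVerdict.applicable = False`), never passed.
- **The threshold applies to the replicate mean**, which defines ΔΔG;
  per-run values are carried for diagnostics only.
- **Cutoff monotonicity** is stated in the tightening direction: lowering
  the entropy cutoff or raising the percent or ΔΔG cutoffs never turns a
  rejected position into an accepted one.
- **Interfacial assignment** uses strictly positive per-residue change in
  accessible surface area; negative values are rejected at parse time.
- Alignment columns are 0-based internally; family positions and residue
  numbers are 1-based in every file interface.

## Synthetic scenarios

The generator emulates the statistical contract the filters assume, not
protein physics or phylogeny. Each position gets a class:

- `conserved_core` — one residue shared by all subgroups (the hydrophobic
  core plus invariant polar positions of a real interface);
- `identity_divergent` / `property_divergent` / `size_divergent` — each
  subgroup carries its own conserved residue, drawn from pools ordered so
  consecutive subgroups match the class contract (same property class for
  identity divergence, alternating property classes, size ranks ≥ 2
  apart). With more subgroups than any single property∩size class holds
  (the largest has three amino acids), assignments spill into neighbouring
  pools; pairs that then fall into the same property or size class are
  still caught by the identity condition, so planted positions remain
  recoverable. Residues are always distinct across subgroups;
- `neutral` — each member draws a uniform random residue.

Ortholog rows are the member sequence with i.i.d. per-residue substitution
to a uniform random amino acid at rate ε (default 0.02, emulating the
~84% within-subfamily ortholog identity regime); the member's own
(noise-free) row anchors each MSA and defines template wild types and
mutation targets. ΔΔG records draw 10 runs from N(μ, 0.05²) with μ = 1.0
kcal/mol at planted constraints — within the observed destabilizing range
of real scans — and μ = 0 elsewhere, except a `stabilizing_fraction`
(default 0.1) of null cells drawn at −0.5 kcal/mol to emulate the
stabilizing mutations real scans report. Constraints are planted jointly
(divergent and destabilizing) because calls require both filters;
`decouple_filters=True` suppresses the energy effect to probe each
filter's marginal behaviour. All draws flow from one seeded generator
(`numpy` PCG64); identical seeds give byte-identical artifacts.

The default 33-position plan places a six-position conserved core,
identity-divergent positions 7 and 29, a property-divergent position 10
and a size-divergent position 31 — 4 planted constraints per side, 8 per
non-cognate pair, matching the scale (~7 per pair) seen in real families.

**What passing tests do and do not show.** The generator's columns are
i.i.d. across positions and its noise is memoryless, so recovery results
demonstrate the correctness and calibration of the filters under their own
statistical assumptions — not performance on real families, where
alignment errors, phylogenetic correlation between orthologs, scan-engine
bias and non-additive energetics all intrude.

## Numerical and degenerate-input conventions

Frequency profiles must sum to 1 within 1e-9 and are computed as exact
counts over rows; an all-gap column has an empty modal set and can never
satisfy the identity condition. `min_ddg` over an empty record set is NaN
(reported with `applicable=False`). Duplicate sequence ids, duplicate ΔΔG
record keys, self-mutation rows, ragged alignments and out-of-alphabet
symbols are hard errors at parse time. Percent comparisons are made at
full precision with no rounding.

## Problem sizes used in validation

The recovery and null checks run the full pipeline at the default
conditions (7×7 subgroups, 3 members/subgroup, 4 orthologs/member, 33
positions, 3 templates per cognate pair — 2772 evaluated cells and ~25,000
ΔΔG records per scenario) over 20 seeds each, with a single noiseless
determinized variant that must recover the planted truth exactly. Oracle
equivalence checks compare the percent differences and the energy filter
against naive enumerations on 1,000 random instances each.

## Known limitations

- The scan engine itself (structure repair, mutational model building,
  interaction-energy decomposition) is out of scope; the package consumes
  its tabulated output.
- External specificity-position predictors are consumed only through the
  consensus combiner; their scoring is not reimplemented.
- Physical-origin annotation of constraints (clash, cavity, Coulombic
  repulsion, unsatisfied charge) required manual structural inspection in
  the motivating study and is a free-text column, never computed.
- The evolutionary filter compares exactly two subfamilies at a time; no
  correction is made for phylogenetic non-independence of orthologs.
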