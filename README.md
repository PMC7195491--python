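# negcon

Negative-constraint discovery on paralog protein–protein interfaces.

## The problem

Large paralog families of cell-surface receptors — the *Drosophila* DIPs and
Dprs are the motivating case — partition into interaction-specificity
subgroups: each DIP subgroup binds strongly to exactly one cognate Dpr
subgroup, although all family members share essentially the same fold and
interface. With seven subgroups per side there are 7 × 7 = 49 possible
subgroup combinations and only 7 cognate ones, so 42 non-cognate
combinations must be kept apart. Specificity of this kind is enforced by
**negative constraints**: individual interfacial residues that selectively
destabilize binding to non-cognate partners while being tolerated (or
favorable) in the cognate complex.

`negcon` implements the two-filter protocol that identifies such residues,
and a synthetic-scenario generator with planted ground truth so the whole
pipeline can be validated without any structural scan or sequence download.
It is aimed at computational structural biologists studying specificity in
paralog families.

## The method

For a non-cognate pair (DIP-i, Dpr-j), each family-wide interfacial
position (numbered 1..33 here) is tested on each side of the interface:

**Energy filter.** An external mutational-scan engine (e.g. FoldX; running
it is out of scope — its output table is the input) provides the change in
binding free energy ΔΔG when the cognate complex is mutated, position by
position, into the residues of the non-cognate subgroup's members. A ΔΔG
is the mean over replicate runs. The position passes iff

ΔΔG ≥ 0.05 kcal mol⁻¹

for *every* member of the non-cognate subgroup on *every* template complex
of the cognate subgroup. The threshold equals the spread observed when
mutating an interfacial residue into itself (0.00 ± 0.05 kcal mol⁻¹).
Missing template × member combinations fail the position; members that
already share the template's wild-type residue are exempt.

**Evolutionary filter.** The position must also be divergent between the
two subfamilies' ortholog alignments, by at least one of:

1. *identity*: both columns conserved — Shannon entropy
   S = −Σᵢ fᵢ log₂₁ fᵢ < 0.23 over the 21-symbol alphabet (20 amino acids
   + gap) — with different modal residues;
2. *biophysical property*: Σₖₗ f_aaᵢₖ · f_aaⱼₗ · 100% > 90%, summed over
   cross-column amino-acid pairs from different property classes
   (hydrophobic / polar / positive / negative);
3. *size*: the larger of the two directional sums (aaᵢ strictly larger,
   aaᵢ strictly smaller, over classes tiny < small < medium < large <
   bulky) > 90%.

A **negative constraint** is a position that passes both filters.
Predictions are compared with binding measurements through
ΔΔG = RT·ln(K_D,mut / K_D,wt).

## Worked example

```sh
python examples/simulate_and_recover.py
```

simulates the default study conditions — 7 subgroups per side, 3 members
per subgroup, 4 orthologs per member, 33 interfacial positions of which
four are divergent and carry a planted 1.0 kcal/mol destabilizing effect,
3 templates per cognate pair, run noise 0.05 kcal/mol, substitution noise
0.02 — and prints:

```
subgroup pairs      : 49 total, 42 non-cognate
positions evaluated : 2772 (504 not applicable)
energy filter pass  : 336
evo filter pass     : 656
accepted calls      : 336 (planted truth: 336)
precision=1.000  recall=1.000
```

2772 = 42 pairs × 2 sides × 33 positions; the 504 not-applicable cells are
conserved-core positions where every non-cognate member already carries the
wild-type residue, so no mutation exists. All 336 planted constraints
(42 pairs × 2 sides × 4 divergent positions) are recovered and nothing
else is called: the energy filter alone leaves some spurious evolutionary
acceptances (656 > 336), and the conjunction removes them.

Other examples: `pair_combinatorics.py` (49/42 enumeration),
`evolutionary_filter.py` (the three conditions on hand-built columns),
`energy_filter.py` (strict coverage semantics), `kd_conversion.py`
(K_D → ΔΔG). The `negcon` command exposes the same operations as
subcommands (`simulate`, `energy-filter`, `evo-filter`, `pairs`, `call`,
`consensus`, `convert-kd`, `run`).

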