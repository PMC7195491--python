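"""Score evolutionary divergence between two subfamily alignment columns.

Two subfamilies that conserve different residues at a position — here a
lysine column against a glutamate column — satisfy both the
conserved-and-different identity condition (base-21 entropy 0 on each side)
and the biophysical-property condition (a positive against a negative
charge gives a 100% weighted difference), so the position is accepted.

At the second position subgroup i mixes G/W/A against a conserved V: the
column is not conserved (entropy 0.34 > 0.23), every pair is hydrophobic
(property 0%), and the size differences split between the two directions
(G and A smaller than V, W larger), capping at 75% — below the 90% cutoff,
so the position is rejected.
"""

from negcon import evaluate_evo_filter
from negcon.msa import AlignedSubfamily


def subfamily(name: str, rows: list[str]) -> AlignedSubfamily:
    return AlignedSubfamily(
        family_side="Dpr", subgroup_id=name,
        sequence_ids=tuple(f"{name}_{i}" for i in range(len(rows))),
        rows=tuple(rows),
    )


msa_i = subfamily("blue", ["KG", "KG", "KW", "KA"])
msa_j = subfamily("purple", ["EV", "EV", "EV", "EV"])

for position in (1, 2):
    v = evaluate_evo_filter(msa_i, msa_j, position)
    print(f"position {position}: entropy_i={v.entropy_i:.4f} "
          f"entropy_j={v.entropy_j:.4f} identity={v.identity_condition} "
          f"property={v.property_percent:.1f}% size={v.size_percent:.1f}% "
          f"-> accepted={v.accepted}")
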