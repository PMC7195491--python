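"""Enumerate DIP/Dpr subgroup combinations from the published registry.

Seven DIP subgroups crossed with seven Dpr subgroups give 49 possible
combinations; the seven cognate pairings bind strongly, leaving 42
non-cognate combinations that must each be kept apart by negative
constraints.
"""

from negcon import enumerate_subgroup_pairs, fly_registry

registry = fly_registry()
all_pairs, cognate, noncognate = enumerate_subgroup_pairs(registry)

print(f"total subgroup combinations : {len(all_pairs)}")
print(f"cognate (strong binding)    : {len(cognate)}")
print(f"non-cognate (to explain)    : {len(noncognate)}")
print()
print("cognate pairings:")
for dip_sg, dpr_sg in cognate:
    print(f"  {dip_sg:16s} <-> {dpr_sg}")
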