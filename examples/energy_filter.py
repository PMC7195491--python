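"""Apply the energy filter to a hand-built ΔΔG table at one position.

A position counts as a candidate negative constraint for a non-cognate
subgroup pair only when mutating the cognate complex into each non-cognate
member's residue is destabilizing (ΔΔG >= 0.05 kcal/mol, the self-mutation
spread of the scan engine) on every template complex.  One near-neutral
record — or one missing template/member combination — fails the position.
"""

from negcon import DDGRecord, energy_filter_position

def record(template: str, member: str, ddg: float) -> DDGRecord:
    return DDGRecord(
        template_id=template, template_subgroup="dpr-blue", side="Dpr",
        family_position=31, wt_residue="V", mut_residue="K",
        source_subgroup="dpr-purple", source_member=member, ddg=ddg,
    )

templates = {"T_blue_1", "T_blue_2"}
members = {"Dpr11", "Dpr16"}

full = [
    record("T_blue_1", "Dpr11", 0.82), record("T_blue_1", "Dpr16", 1.21),
    record("T_blue_2", "Dpr11", 0.31), record("T_blue_2", "Dpr16", 0.05),
]
v = energy_filter_position(full, ("alpha", "purple"), "Dpr", 31,
                           templates, members)
print(f"complete, all destabilizing : passed={v.passed} min_ddg={v.min_ddg}")

weak = full[:-1] + [record("T_blue_2", "Dpr16", 0.04)]
v = energy_filter_position(weak, ("alpha", "purple"), "Dpr", 31,
                           templates, members)
print(f"one record below threshold  : passed={v.passed} min_ddg={v.min_ddg}")

v = energy_filter_position(full[:-1], ("alpha", "purple"), "Dpr", 31,
                           templates, members)
print(f"one combination missing     : passed={v.passed} "
      f"coverage_complete={v.coverage_complete}")
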