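"""Convert measured dissociation constants into binding free-energy shifts.

ΔΔG = RT·ln(Kd_mut / Kd_wt) at 25 °C; positive values mean weakened
binding.  The first case reproduces a published double-mutant shift of a
cognate complex (7.9 μM weakened to 131 μM, about +1.66 kcal/mol); the
second shows that a 50-fold weakening approaches the ~2.5 kcal/mol gap
separating cognate from undetectable non-cognate binding.
"""

from negcon import KdPair, kd_to_ddg

for label, wt, mut in [
    ("double mutant, 7.9 -> 131 uM", 7.9, 131.0),
    ("50-fold weakening, 10 -> 500 uM", 10.0, 500.0),
]:
    ddg = kd_to_ddg(KdPair(kd_wt=wt, kd_mut=mut))
    print(f"{label:34s}: ddG = {ddg:+.2f} kcal/mol")
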