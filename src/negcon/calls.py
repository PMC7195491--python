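"""Final negative-constraint calling and experimental-comparison utilities.

The caller intersects the two filters: a position becomes a negative
constraint for a non-cognate subgroup pair on one side of the interface
only when it passes the energy filter (every mutation destabilizing on
every template) *and* the evolutionary filter (conserved-and-different,
property, or size divergence between the two subfamilies).

Also provided: non-cognate pair enumeration from the subgroup registry,
a consensus combiner for external sequence-method predictions, and the
thermodynamic conversion of dissociation-constant ratios to ΔΔG for
comparison with binding measurements.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .energy import EnergyVerdict
from .evo import EvoVerdict
from .registry import SubgroupRegistry

#: gas constant, kcal mol^-1 K^-1
R_KCAL = 1.9872e-3


@dataclass(frozen=True)
class ConstraintCall:
    #: (DIP subgroup, Dpr subgroup) non-cognate combination
    pair: tuple[str, str]
    side: str
    family_position: int
    energy: EnergyVerdict
    evo: EvoVerdict
    accepted: bool

    def __post_init__(self) -> None:
        if self.accepted != (self.energy.passed and self.evo.accepted):
            raise ValueError("accepted must equal energy.passed AND evo.accepted")


@dataclass(frozen=True)
class KdPair:
    """Wild-type and mutant dissociation constants, same concentration unit."""

    kd_wt: float
    kd_mut: float
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.kd_wt <= 0 or self.kd_mut <= 0:
            raise ValueError("dissociation constants must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (Kelvin)")


@dataclass(frozen=True)
class MethodPredictions:
    method_names: tuple[str, ...]
    predicted: dict[int, frozenset[str]]

    def __post_init__(self) -> None:
        known = set(self.method_names)
        for pos, methods in self.predicted.items():
            unknown = set(methods) - known
            if unknown:
                raise ValueError(
                    f"position {pos}: unknown method labels {sorted(unknown)}"
                )


def enumerate_subgroup_pairs(
    registry: SubgroupRegistry,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], list[tuple[str, str]]]:
    """All, cognate and non-cognate (DIP subgroup, Dpr subgroup) combinations."""
    all_pairs = list(
        itertools.product(registry.dip_subgroups, registry.dpr_subgroups)
    )
    cognate = list(registry.cognate_map.items())
    cognate_set = set(cognate)
    noncognate = [p for p in all_pairs if p not in cognate_set]
    return all_pairs, cognate, noncognate


def call_negative_constraints(
    energy_verdicts: list[EnergyVerdict],
    evo_verdicts: list[EvoVerdict],
    evo_key_map: dict[tuple[tuple[str, str], str, int], tuple[str, str]] | None = None,
) -> list[ConstraintCall]:
    """Intersect the two filters into one call per energy-verdict key.

    Energy verdicts drive the keying, mirroring the pipeline order (the
    evolutionary filter is applied to positions the energy filter surfaces);
    a missing evolutionary verdict for an energy-passing key is a pipeline
    ordering violation and a hard error.  Evolutionary verdicts are keyed by
    (subgroup_i, subgroup_j, family_position); when the compared subfamily
    labels differ from the pair labels (the verdict compares the cognate-side
    subfamily against the non-cognate one), *evo_key_map* maps each
    (pair, side, family_position) call key to its (subgroup_i, subgroup_j).
    """
    evo_index: dict[tuple[str, str, int], EvoVerdict] = {
        (v.subgroup_i, v.subgroup_j, v.family_position): v for v in evo_verdicts
    }

    calls: list[ConstraintCall] = []
    seen: set[tuple] = set()
    for ev in energy_verdicts:
        key = (ev.pair, ev.side, ev.family_position)
        if key in seen:
            raise ValueError(f"duplicate energy verdict key {key}")
        seen.add(key)
        if evo_key_map is not None:
            evo_sub = evo_key_map[(ev.pair, ev.side, ev.family_position)]
        else:
            evo_sub = ev.pair
        verdict = evo_index.get((evo_sub[0], evo_sub[1], ev.family_position))
        if verdict is None:
            if ev.passed:
                raise ValueError(
                    f"no evolutionary verdict for energy-passing key {key}: "
                    "pipeline ordering violated"
                )
            continue
        accepted = ev.passed and verdict.accepted
        calls.append(
            ConstraintCall(
                pair=ev.pair, side=ev.side, family_position=ev.family_position,
                energy=ev, evo=verdict, accepted=accepted,
            )
        )
    return calls


def consensus_combiner(preds: MethodPredictions, min_methods: int = 3) -> set[int]:
    """Positions predicted by at least *min_methods* of the external methods."""
    if not 1 <= min_methods <= len(preds.method_names):
        raise ValueError(
            f"min_methods must be in 1..{len(preds.method_names)}, got {min_methods}"
        )
    return {
        pos for pos, methods in preds.predicted.items() if len(methods) >= min_methods
    }


def kd_to_ddg(pair: KdPair) -> float:
    """ΔΔG = R·T·ln(Kd_mut / Kd_wt), kcal/mol; positive = weakened binding.

    Any common concentration unit cancels in the ratio.
    """
    return R_KCAL * pair.temperature * math.log(pair.kd_mut / pair.kd_wt)


def write_constraint_report(calls: list[ConstraintCall], path: str | Path) -> None:
    """Tab-separated per-position report, accepted or not, sorted by key.

    Non-accepted positions are kept with their diagnostic values so both
    filters can be audited.
    """
    keys = [(c.pair, c.side, c.family_position) for c in calls]
    if len(set(keys)) != len(keys):
        dup = next(k for k in keys if keys.count(k) > 1)
        raise ValueError(f"duplicate constraint-call key {dup}")
    rows = [
        {
            "subgroup_i": c.pair[0],
            "subgroup_j": c.pair[1],
            "side": c.side,
            "family_position": c.family_position,
            "min_ddg": c.energy.min_ddg,
            "entropy_i": c.evo.entropy_i,
            "entropy_j": c.evo.entropy_j,
            "property_percent": c.evo.property_percent,
            "size_percent": c.evo.size_percent,
            "accepted": c.accepted,
        }
        for c in sorted(calls, key=lambda c: (c.pair, c.side, c.family_position))
    ]
    columns = [
        "subgroup_i", "subgroup_j", "side", "family_position", "min_ddg",
        "entropy_i", "entropy_j", "property_percent", "size_percent", "accepted",
    ]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
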