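"""Energy filter over per-mutation binding ΔΔG tables.

Each :class:`DDGRecord` holds the predicted change in binding free energy
(kcal/mol, replicate mean over mutational-scan runs) when one interfacial
residue of a cognate template complex is mutated to the residue a member of
another specificity subgroup carries at the same family-wide position.

A position passes the filter for a non-cognate subgroup pair on one side
only if the mutation is destabilizing — ΔΔG at or above a threshold whose
default, 0.05 kcal/mol, equals the spread observed when mutating a residue
into itself — for *every* template complex of the cognate subgroup and
*every* contributing member of the other subgroup.  Missing combinations
fail the position (the "every" is strict), except combinations where the
member already shares the template's wild-type residue, which generate no
mutation and are exempt.  A position where all combinations are exempt is
not applicable and is never reported as passed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .msa import AMINO_ACIDS, SIDES


@dataclass(frozen=True)
class DDGRecord:
    template_id: str
    template_subgroup: str
    side: str
    family_position: int
    wt_residue: str
    mut_residue: str
    source_subgroup: str
    source_member: str
    #: replicate-mean binding ΔΔG, kcal/mol; positive = destabilizing
    ddg: float
    run_values: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        for name in ("wt_residue", "mut_residue"):
            aa = getattr(self, name)
            if aa not in AMINO_ACIDS:
                raise ValueError(f"{name} {aa!r} is not a standard amino acid")
        if self.wt_residue == self.mut_residue:
            raise ValueError(
                f"template {self.template_id!r} position {self.family_position}: "
                f"self-mutation {self.wt_residue}->{self.mut_residue} is not a mutation"
            )
        if self.family_position < 1:
            raise ValueError("family_position must be >= 1")
        if self.run_values is not None:
            mean = sum(self.run_values) / len(self.run_values)
            if abs(mean - self.ddg) > 1e-9:
                raise ValueError(
                    f"ddg {self.ddg} does not equal the run mean {mean}"
                )


@dataclass(frozen=True)
class EnergyFilterParams:
    #: destabilization threshold, kcal/mol (inclusive)
    ddg_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.ddg_threshold < 0:
            raise ValueError("ddg_threshold must be >= 0")


@dataclass(frozen=True)
class EnergyVerdict:
    pair: tuple[str, str]
    side: str
    family_position: int
    n_records: int
    min_ddg: float
    coverage_complete: bool
    passed: bool
    #: False when every (template, member) combination is exempt because the
    #: member shares the wild-type residue: nothing to evaluate.
    applicable: bool = True


def aggregate_runs(run_values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation of replicate runs.

    The mean over runs defines the binding ΔΔG; sd is 0 for a single run.
    """
    if len(run_values) == 0:
        raise ValueError("cannot aggregate an empty run list")
    arr = np.asarray(run_values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return mean, sd


_KEY = ("template_id", "side", "family_position", "mut_residue", "source_member")


def read_ddg_table(path: str | Path) -> list[DDGRecord]:
    """Read a tab-separated ΔΔG table into validated records, order preserved.

    Optional ``run_values`` column holds semicolon-separated per-run values.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = [
        "template_id", "template_subgroup", "side", "family_position",
        "wt_residue", "mut_residue", "source_subgroup", "source_member", "ddg",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing ΔΔG table columns {missing}")
    records: list[DDGRecord] = []
    seen: set[tuple] = set()
    for row in df.itertuples():
        runs = None
        if "run_values" in df.columns:
            raw = getattr(row, "run_values")
            if isinstance(raw, str) and raw.strip():
                runs = tuple(float(v) for v in raw.split(";"))
        rec = DDGRecord(
            template_id=str(row.template_id),
            template_subgroup=str(row.template_subgroup),
            side=str(row.side),
            family_position=int(row.family_position),
            wt_residue=str(row.wt_residue).upper(),
            mut_residue=str(row.mut_residue).upper(),
            source_subgroup=str(row.source_subgroup),
            source_member=str(row.source_member),
            ddg=float(row.ddg),
            run_values=runs,
        )
        key = (rec.template_id, rec.side, rec.family_position,
               rec.mut_residue, rec.source_member)
        if key in seen:
            raise ValueError(f"{path}: duplicate ΔΔG record key {key}")
        seen.add(key)
        records.append(rec)
    return records


def write_ddg_table(records: Iterable[DDGRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "template_id": r.template_id,
            "template_subgroup": r.template_subgroup,
            "side": r.side,
            "family_position": r.family_position,
            "wt_residue": r.wt_residue,
            "mut_residue": r.mut_residue,
            "source_subgroup": r.source_subgroup,
            "source_member": r.source_member,
            "ddg": repr(r.ddg),
            "run_values": ";".join(repr(v) for v in r.run_values)
            if r.run_values is not None else "",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def energy_filter_position(
    records: Sequence[DDGRecord],
    pair: tuple[str, str],
    side: str,
    family_position: int,
    expected_templates: set[str],
    expected_members: set[str],
    params: EnergyFilterParams = EnergyFilterParams(),
    exempt_pairs: set[tuple[str, str]] | None = None,
) -> EnergyVerdict:
    """Strict all-templates, all-members verdict at one position.

    *records* must be pre-filtered to this (pair, side, position).
    *exempt_pairs* lists (template_id, source_member) combinations where the
    member's residue equals the template's wild type, so no mutation exists.
    """
    exempt = exempt_pairs or set()
    for rec in records:
        if rec.template_id not in expected_templates:
            raise ValueError(
                f"record references template {rec.template_id!r} outside the "
                f"expected set {sorted(expected_templates)}"
            )
    required = {
        (t, m)
        for t in expected_templates
        for m in expected_members
        if (t, m) not in exempt
    }
    present = {(r.template_id, r.source_member) for r in records}
    if not required:
        return EnergyVerdict(
            pair=pair, side=side, family_position=family_position,
            n_records=len(records), min_ddg=math.nan,
            coverage_complete=True, passed=False, applicable=False,
        )
    coverage = required <= present
    min_ddg = min((r.ddg for r in records), default=math.nan)
    passed = (
        coverage
        and len(records) >= 1
        and min_ddg >= params.ddg_threshold
    )
    return EnergyVerdict(
        pair=pair, side=side, family_position=family_position,
        n_records=len(records), min_ddg=min_ddg,
        coverage_complete=coverage, passed=passed, applicable=True,
    )
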