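"""End-to-end orchestration: simulate → energy filter → evo filter → call.

The stages run in the protocol's order: the energy filter scans the ΔΔG
table for positions destabilizing on every template and member, and the
evolutionary filter then decides whether the position's divergence between
the two subfamilies is conserved across orthologs; final calls are the
conjunction.

For a non-cognate pair (DIP-i, Dpr-j):

* Dpr-side calls scan the templates of DIP-i's cognate complex, mutating
  the Dpr protomer into Dpr-j residues, and compare the Dpr subfamily
  cognate to DIP-i against Dpr-j in the evolutionary filter;
* DIP-side calls do the mirror image with the templates of Dpr-j's cognate
  complex.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import pandas as pd

from .calls import ConstraintCall, call_negative_constraints, enumerate_subgroup_pairs, write_constraint_report
from .energy import (
    DDGRecord,
    EnergyFilterParams,
    EnergyVerdict,
    energy_filter_position,
    read_ddg_table,
)
from .evo import EvoFilterParams, EvoVerdict, evaluate_evo_filter
from .msa import DIP, DPR, AlignedSubfamily, read_aligned_fasta
from .registry import SubgroupRegistry, read_registry
from .simulate import (
    ScenarioConfig,
    TemplateComplex,
    TruthManifest,
    generate_ddg_records,
    generate_scenario,
    generate_subfamily_msas,
    read_templates_table,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunSummary:
    n_pairs_total: int
    n_pairs_cognate: int
    n_pairs_noncognate: int
    n_positions: int
    n_positions_evaluated: int
    n_not_applicable: int
    n_energy_pass: int
    n_evo_pass: int
    n_accepted: int
    seed: int | None
    ddg_threshold: float
    entropy_cutoff: float
    property_cutoff: float
    size_cutoff: float


@dataclass(frozen=True)
class PipelineResult:
    calls: list[ConstraintCall]
    energy_verdicts: list[EnergyVerdict]
    evo_verdicts: list[EvoVerdict]
    summary: RunSummary


def _member_sequences_from_msas(
    msas: list[AlignedSubfamily], registry: SubgroupRegistry
) -> dict[tuple[str, str, str], str]:
    """Canonical member rows (sequence id == member label) from each MSA."""
    lookup: dict[tuple[str, str, str], str] = {}
    for msa in msas:
        members = set(registry.members(msa.family_side, msa.subgroup_id))
        for sid, row in zip(msa.sequence_ids, msa.rows):
            if sid in members:
                lookup[(msa.family_side, msa.subgroup_id, sid)] = row
    return lookup


def apply_filters(
    msas: list[AlignedSubfamily],
    registry: SubgroupRegistry,
    records: list[DDGRecord],
    templates: tuple[TemplateComplex, ...],
    energy_params: EnergyFilterParams = EnergyFilterParams(),
    evo_params: EvoFilterParams = EvoFilterParams(),
    seed: int | None = None,
) -> PipelineResult:
    """Run both filters over every non-cognate pair, side and position."""
    n_positions = msas[0].length
    msa_by = {(m.family_side, m.subgroup_id): m for m in msas}
    member_seq = _member_sequences_from_msas(msas, registry)
    cognate = registry.cognate_map
    cognate_inv = {v: k for k, v in cognate.items()}

    all_pairs, cognate_pairs, noncognate = enumerate_subgroup_pairs(registry)
    logger.info("pairs: %d total, %d cognate, %d non-cognate",
                len(all_pairs), len(cognate_pairs), len(noncognate))

    # --- group ΔΔG records by (pair, side, position)
    grouped: dict[tuple[tuple[str, str], str, int], list[DDGRecord]] = {}
    for rec in records:
        if rec.side == DPR:
            pair = (cognate_inv[rec.template_subgroup], rec.source_subgroup)
        else:
            pair = (rec.source_subgroup, cognate[rec.template_subgroup])
        grouped.setdefault((pair, rec.side, rec.family_position), []).append(rec)

    templates_of_dip: dict[str, list[TemplateComplex]] = {}
    for t in templates:
        templates_of_dip.setdefault(t.dip_subgroup, []).append(t)

    # --- energy filter
    energy_verdicts: list[EnergyVerdict] = []
    n_na = 0
    for d_sg, p_sg in noncognate:
        for side in (DIP, DPR):
            if side == DPR:
                tmpl_list = templates_of_dip[d_sg]
                source_sg = p_sg
            else:
                tmpl_list = templates_of_dip[cognate_inv[p_sg]]
                source_sg = d_sg
            members = set(registry.members(side, source_sg))
            expected_templates = {t.template_id for t in tmpl_list}
            for p in range(1, n_positions + 1):
                exempt: set[tuple[str, str]] = set()
                for t in tmpl_list:
                    protomer = t.dip_member if side == DIP else t.dpr_member
                    protomer_sg = t.dip_subgroup if side == DIP else t.dpr_subgroup
                    wt = member_seq[(side, protomer_sg, protomer)][p - 1]
                    for m in members:
                        if member_seq[(side, source_sg, m)][p - 1] == wt:
                            exempt.add((t.template_id, m))
                verdict = energy_filter_position(
                    grouped.get(((d_sg, p_sg), side, p), []),
                    pair=(d_sg, p_sg),
                    side=side,
                    family_position=p,
                    expected_templates=expected_templates,
                    expected_members=members,
                    params=energy_params,
                    exempt_pairs=exempt,
                )
                if not verdict.applicable:
                    n_na += 1
                    logger.debug(
                        "not-applicable: pair=%s side=%s position=%d "
                        "(all members share wild type)", (d_sg, p_sg), side, p,
                    )
                energy_verdicts.append(verdict)
    logger.info("energy filter: %d verdicts, %d passed, %d not applicable",
                len(energy_verdicts),
                sum(v.passed for v in energy_verdicts), n_na)

    # --- evolutionary filter
    evo_verdicts: list[EvoVerdict] = []
    evo_key_map: dict[tuple[tuple[str, str], str, int], tuple[str, str]] = {}
    evo_cache: dict[tuple[str, str, str, int], EvoVerdict] = {}
    for d_sg, p_sg in noncognate:
        for side in (DIP, DPR):
            if side == DPR:
                i_sub, j_sub = cognate[d_sg], p_sg
            else:
                i_sub, j_sub = cognate_inv[p_sg], d_sg
            for p in range(1, n_positions + 1):
                key = (side, i_sub, j_sub, p)
                if key not in evo_cache:
                    evo_cache[key] = evaluate_evo_filter(
                        msa_by[(side, i_sub)], msa_by[(side, j_sub)], p, evo_params
                    )
                evo_key_map[((d_sg, p_sg), side, p)] = (i_sub, j_sub)
    evo_verdicts = list(evo_cache.values())
    logger.info("evolutionary filter: %d verdicts, %d accepted",
                len(evo_verdicts), sum(v.accepted for v in evo_verdicts))

    # --- conjunction
    calls = call_negative_constraints(energy_verdicts, evo_verdicts, evo_key_map)
    n_accepted = sum(c.accepted for c in calls)
    logger.info("calls: %d accepted of %d evaluated", n_accepted, len(calls))

    summary = RunSummary(
        n_pairs_total=len(all_pairs),
        n_pairs_cognate=len(cognate_pairs),
        n_pairs_noncognate=len(noncognate),
        n_positions=n_positions,
        n_positions_evaluated=len(calls),
        n_not_applicable=n_na,
        n_energy_pass=sum(v.passed for v in energy_verdicts),
        n_evo_pass=sum(v.accepted for v in evo_verdicts),
        n_accepted=n_accepted,
        seed=seed,
        ddg_threshold=energy_params.ddg_threshold,
        entropy_cutoff=evo_params.entropy_cutoff,
        property_cutoff=evo_params.property_cutoff,
        size_cutoff=evo_params.size_cutoff,
    )
    return PipelineResult(
        calls=calls,
        energy_verdicts=energy_verdicts,
        evo_verdicts=evo_verdicts,
        summary=summary,
    )


def run_scenario(
    config: ScenarioConfig,
    energy_params: EnergyFilterParams = EnergyFilterParams(),
    evo_params: EvoFilterParams = EvoFilterParams(),
) -> tuple[PipelineResult, TruthManifest]:
    """Generate a synthetic scenario in memory and run both filters on it."""
    msas, registry, _, manifest = generate_subfamily_msas(config)
    records = generate_ddg_records(config, registry, manifest)
    result = apply_filters(
        msas, registry, records, manifest.templates,
        energy_params, evo_params, seed=config.seed,
    )
    return result, manifest


def score_against_truth(
    calls: list[ConstraintCall], manifest: TruthManifest
) -> tuple[float, float]:
    """Precision and recall of accepted calls against planted constraints.

    An empty prediction set has precision 1 by convention; an empty truth
    set has recall 1.
    """
    predicted = {
        (c.pair[0], c.pair[1], c.side, c.family_position)
        for c in calls
        if c.accepted
    }
    truth = set(manifest.planted_constraints)
    tp = len(predicted & truth)
    precision = tp / len(predicted) if predicted else 1.0
    recall = tp / len(truth) if truth else 1.0
    return precision, recall


def _write_energy_table(verdicts: list[EnergyVerdict], path: Path) -> None:
    rows = [
        {
            "subgroup_i": v.pair[0], "subgroup_j": v.pair[1], "side": v.side,
            "family_position": v.family_position, "n_records": v.n_records,
            "min_ddg": v.min_ddg, "coverage_complete": v.coverage_complete,
            "applicable": v.applicable, "passed": v.passed,
        }
        for v in verdicts
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_evo_table(verdicts: list[EvoVerdict], path: Path) -> None:
    pd.DataFrame([asdict(v) for v in verdicts]).to_csv(path, sep="\t", index=False)


def load_scenario_inputs(
    in_dir: str | Path,
) -> tuple[list[AlignedSubfamily], SubgroupRegistry, list[DDGRecord], tuple[TemplateComplex, ...]]:
    """Read the file set written by :func:`negcon.simulate.generate_scenario`."""
    in_dir = Path(in_dir)
    registry = read_registry(in_dir / "registry.tsv")
    msas = []
    for path in sorted(in_dir.glob("msa_*.fasta")):
        _, side, sg = path.stem.split("_", 2)
        msas.append(read_aligned_fasta(path, side, sg))
    if not msas:
        raise FileNotFoundError(f"no msa_*.fasta files under {in_dir}")
    records = read_ddg_table(in_dir / "ddg_table.tsv")
    templates = read_templates_table(in_dir / "templates.tsv")
    return msas, registry, records, templates


def call_from_files(
    in_dir: str | Path,
    out_dir: str | Path,
    energy_params: EnergyFilterParams = EnergyFilterParams(),
    evo_params: EvoFilterParams = EvoFilterParams(),
    seed: int | None = None,
) -> PipelineResult:
    """Run the filters on an existing scenario file set and write reports."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    msas, registry, records, templates = load_scenario_inputs(in_dir)
    result = apply_filters(
        msas, registry, records, templates, energy_params, evo_params, seed=seed
    )
    _write_energy_table(result.energy_verdicts, out / "energy_verdicts.tsv")
    _write_evo_table(result.evo_verdicts, out / "evo_verdicts.tsv")
    write_constraint_report(result.calls, out / "constraint_report.tsv")
    (out / "run_summary.json").write_text(
        json.dumps(asdict(result.summary), indent=1, sort_keys=True)
    )
    return result


def run_pipeline(
    config: ScenarioConfig,
    out_dir: str | Path,
    energy_params: EnergyFilterParams = EnergyFilterParams(),
    evo_params: EvoFilterParams = EvoFilterParams(),
) -> PipelineResult:
    """Simulate a scenario to *out_dir*, then filter, call and report.

    The filtering stage re-reads the files the simulation stage wrote, so a
    later run from the same intermediate files reproduces the same report.
    """
    out = Path(out_dir)
    generate_scenario(config, out)
    return call_from_files(out, out, energy_params, evo_params, seed=config.seed)
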