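"""Seeded synthetic scenarios with planted ground-truth negative constraints.

The generator emulates the statistical structure the two filters assume:

* subfamily MSAs with controlled within-subgroup conservation and
  between-subgroup divergence.  Each family-wide position is assigned a
  class — a conserved core residue shared by all subgroups; identity-,
  property- or size-divergent positions where each subgroup carries its own
  conserved residue; or neutral positions with near-uniform residues.
  Ortholog rows are the member sequence with per-residue substitution noise;

* per-mutation binding ΔΔG records for every non-cognate subgroup pair,
  with replicate runs drawn around a planted destabilizing mean at
  constraint positions and around zero (occasionally a negative,
  stabilizing mean) elsewhere.  The default run spread, 0.05 kcal/mol,
  matches the spread observed when mutating an interfacial residue into
  itself; the default planted effect, 1.0 kcal/mol, sits inside the
  observed destabilizing range.

Constraints are planted jointly — a planted position is both evolutionarily
divergent and energetically destabilizing, since a final call requires both
filters — unless ``decouple_filters`` is set, which suppresses the energy
effect so each filter's marginal behaviour can be probed.

All randomness flows from a single integer seed; identical seeds give
byte-identical artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .energy import DDGRecord, write_ddg_table
from .msa import (
    AMINO_ACIDS,
    DIP,
    DPR,
    AlignedSubfamily,
    PositionMap,
    PositionMapEntry,
    write_aligned_fasta,
    write_position_map,
)
from .registry import SubgroupRegistry, write_registry

CONSERVED_CORE = "conserved_core"
IDENTITY_DIVERGENT = "identity_divergent"
PROPERTY_DIVERGENT = "property_divergent"
SIZE_DIVERGENT = "size_divergent"
NEUTRAL = "neutral"

POSITION_CLASSES = (
    CONSERVED_CORE, IDENTITY_DIVERGENT, PROPERTY_DIVERGENT, SIZE_DIVERGENT, NEUTRAL,
)
DIVERGENT_CLASSES = (IDENTITY_DIVERGENT, PROPERTY_DIVERGENT, SIZE_DIVERGENT)

# Residue pools indexed by subgroup (consecutive, rotated per position, so
# assignments are always distinct across subgroups).
_CORE_POOL = "LIVFQN"          # hydrophobic core plus conserved Gln/Asn flavour
_IDENTITY_POOL = "MILVFACGPW"  # hydrophobic; first three share size class too
_PROPERTY_POOL = "LSKEITRDVN"  # cycles hydrophobic/polar/positive/negative
_SIZE_POOL = "GEWAVFSQYT"      # cycles size ranks tiny/medium/bulky
#: ΔΔG mean for the stabilizing fraction of null positions, kcal/mol
_STABILIZING_MEAN = -0.5


def default_position_plan(n_positions: int) -> dict[int, str]:
    """Class assignment used when a scenario gives none.

    For the canonical 33-position interface: a six-position conserved core,
    identity-divergent positions 7 and 29, a property-divergent position 10
    and a size-divergent position 31, all else neutral.  Shorter interfaces
    get one position per class in order, the rest neutral.
    """
    plan = {p: NEUTRAL for p in range(1, n_positions + 1)}
    if n_positions >= 31:
        for p in (1, 2, 3, 4, 5, 6):
            plan[p] = CONSERVED_CORE
        plan[7] = IDENTITY_DIVERGENT
        plan[29] = IDENTITY_DIVERGENT
        plan[10] = PROPERTY_DIVERGENT
        plan[31] = SIZE_DIVERGENT
    else:
        for offset, cls in enumerate(
            (CONSERVED_CORE, IDENTITY_DIVERGENT, PROPERTY_DIVERGENT, SIZE_DIVERGENT)
        ):
            if offset < n_positions:
                plan[offset + 1] = cls
    return plan


@dataclass(frozen=True)
class ScenarioConfig:
    n_subgroups_per_side: int = 7
    members_per_subgroup: int = 3
    orthologs_per_member: int = 4
    n_positions: int = 33
    templates_per_cognate_pair: int = 3
    position_plan: dict[int, str] | None = None
    #: per-residue probability of substitution to a uniform random amino acid
    substitution_noise: float = 0.02
    #: planted destabilizing mean, kcal/mol
    ddg_effect_mean: float = 1.0
    #: per-run spread, kcal/mol (self-mutation spread of the scan engine)
    ddg_run_sd: float = 0.05
    #: probability a null (pair, side, position) cell gets a stabilizing mean
    stabilizing_fraction: float = 0.1
    n_runs: int = 10
    #: plant evolutionary divergence without the energetic effect
    decouple_filters: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positions < 1:
            raise ValueError("n_positions must be >= 1")
        if self.ddg_run_sd < 0:
            raise ValueError("ddg_run_sd must be >= 0")
        for name in ("substitution_noise", "stabilizing_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.n_subgroups_per_side < 1 or self.members_per_subgroup < 1:
            raise ValueError("need at least one subgroup and one member per side")
        if self.n_subgroups_per_side > len(_IDENTITY_POOL):
            raise ValueError(
                f"at most {len(_IDENTITY_POOL)} subgroups per side supported"
            )
        if self.position_plan is not None:
            bad = [p for p in self.position_plan if not 1 <= p <= self.n_positions]
            if bad:
                raise ValueError(
                    f"position_plan keys {bad} outside 1..{self.n_positions}"
                )
            bad_cls = {c for c in self.position_plan.values()} - set(POSITION_CLASSES)
            if bad_cls:
                raise ValueError(f"unknown position classes {sorted(bad_cls)}")

    def resolved_plan(self) -> dict[int, str]:
        if self.position_plan is None:
            return default_position_plan(self.n_positions)
        plan = {p: NEUTRAL for p in range(1, self.n_positions + 1)}
        plan.update(self.position_plan)
        return plan


@dataclass(frozen=True)
class TemplateComplex:
    template_id: str
    dip_subgroup: str
    dpr_subgroup: str
    dip_member: str
    dpr_member: str


@dataclass(frozen=True)
class TruthManifest:
    """Planted ground truth plus the internal state needed to replay it."""

    #: accepted-call ground truth: (dip_subgroup, dpr_subgroup, side, position)
    planted_constraints: frozenset[tuple[str, str, str, int]]
    position_classes: dict[int, str]
    #: canonical (noise-free) member sequences, keyed (side, subgroup, member)
    member_sequences: dict[tuple[str, str, str], str]
    templates: tuple[TemplateComplex, ...]
    config: ScenarioConfig

    def template_wt(self, template: TemplateComplex, side: str, position: int) -> str:
        member = template.dip_member if side == DIP else template.dpr_member
        sg = template.dip_subgroup if side == DIP else template.dpr_subgroup
        return self.member_sequences[(side, sg, member)][position - 1]


def _subgroup_ids(config: ScenarioConfig) -> tuple[list[str], list[str]]:
    n = config.n_subgroups_per_side
    return [f"dip{g}" for g in range(1, n + 1)], [f"dpr{g}" for g in range(1, n + 1)]


def _class_residue(cls: str, subgroup_index: int, position: int, side: str) -> str:
    pool = {
        CONSERVED_CORE: _CORE_POOL,
        IDENTITY_DIVERGENT: _IDENTITY_POOL,
        PROPERTY_DIVERGENT: _PROPERTY_POOL,
        SIZE_DIVERGENT: _SIZE_POOL,
    }[cls]
    offset = (position - 1) + (3 if side == DPR else 0)
    if cls == CONSERVED_CORE:
        return pool[offset % len(pool)]
    return pool[(subgroup_index + offset) % len(pool)]


def generate_subfamily_msas(
    config: ScenarioConfig,
) -> tuple[list[AlignedSubfamily], SubgroupRegistry, PositionMap, TruthManifest]:
    """Build subgroup MSAs, registry, position map and the truth manifest."""
    rng = np.random.default_rng([config.seed, 0])
    plan = config.resolved_plan()
    dip_ids, dpr_ids = _subgroup_ids(config)

    dip_groups = {
        sg: tuple(f"{sg.upper()}m{m}" for m in range(1, config.members_per_subgroup + 1))
        for sg in dip_ids
    }
    dpr_groups = {
        sg: tuple(f"{sg.upper()}m{m}" for m in range(1, config.members_per_subgroup + 1))
        for sg in dpr_ids
    }
    registry = SubgroupRegistry(
        dip_subgroups=dip_groups,
        dpr_subgroups=dpr_groups,
        cognate_map=dict(zip(dip_ids, dpr_ids)),
    )

    member_sequences: dict[tuple[str, str, str], str] = {}
    aa_list = list(AMINO_ACIDS)
    for side, subgroups in ((DIP, dip_groups), (DPR, dpr_groups)):
        for gi, (sg, members) in enumerate(subgroups.items()):
            for member in members:
                seq = []
                for p in range(1, config.n_positions + 1):
                    cls = plan[p]
                    if cls == NEUTRAL:
                        seq.append(aa_list[rng.integers(len(aa_list))])
                    else:
                        seq.append(_class_residue(cls, gi, p, side))
                member_sequences[(side, sg, member)] = "".join(seq)

    msas: list[AlignedSubfamily] = []
    for side, subgroups in ((DIP, dip_groups), (DPR, dpr_groups)):
        for sg, members in subgroups.items():
            ids: list[str] = []
            rows: list[str] = []
            for member in members:
                base = member_sequences[(side, sg, member)]
                ids.append(member)
                rows.append(base)
                for k in range(config.orthologs_per_member):
                    noisy = [
                        aa_list[rng.integers(len(aa_list))]
                        if rng.random() < config.substitution_noise
                        else ch
                        for ch in base
                    ]
                    ids.append(f"{member}|orth{k + 1}")
                    rows.append("".join(noisy))
            msas.append(
                AlignedSubfamily(
                    family_side=side,
                    subgroup_id=sg,
                    sequence_ids=tuple(ids),
                    rows=tuple(rows),
                    reference_id=members[0],
                )
            )

    # identity column map with a pretend-UniProt residue offset, one block
    # per distinct protein id
    unique_proteins = {m for (_, _, m) in member_sequences}
    entries = tuple(
        PositionMapEntry(p, member, p + 30, p - 1)
        for member in sorted(unique_proteins)
        for p in range(1, config.n_positions + 1)
    )
    pmap = PositionMap(entries=entries)

    templates: list[TemplateComplex] = []
    for gi, (d_sg, p_sg) in enumerate(zip(dip_ids, dpr_ids), start=1):
        for t in range(config.templates_per_cognate_pair):
            m = t % config.members_per_subgroup
            templates.append(
                TemplateComplex(
                    template_id=f"T{gi}_{t + 1}",
                    dip_subgroup=d_sg,
                    dpr_subgroup=p_sg,
                    dip_member=dip_groups[d_sg][m],
                    dpr_member=dpr_groups[p_sg][m],
                )
            )

    divergent_positions = [p for p, cls in plan.items() if cls in DIVERGENT_CLASSES]
    planted: set[tuple[str, str, str, int]] = set()
    cognate = set(registry.cognate_map.items())
    for d_sg in dip_ids:
        for p_sg in dpr_ids:
            if (d_sg, p_sg) in cognate:
                continue
            for side in (DIP, DPR):
                for p in divergent_positions:
                    planted.add((d_sg, p_sg, side, p))

    manifest = TruthManifest(
        planted_constraints=frozenset(planted),
        position_classes=plan,
        member_sequences=member_sequences,
        templates=tuple(templates),
        config=config,
    )
    return msas, registry, pmap, manifest


def generate_ddg_records(
    config: ScenarioConfig,
    registry: SubgroupRegistry,
    manifest: TruthManifest,
) -> list[DDGRecord]:
    """Replicate-run ΔΔG records for every non-cognate pair, side and position.

    For the Dpr side of non-cognate pair (DIP-i, Dpr-j): on every template
    complex of DIP-i's cognate pair, the template's Dpr protomer is mutated
    at each position to the residue each Dpr-j member carries there;
    likewise on the DIP side with the roles swapped.  Mutations into the
    wild type generate no record.
    """
    if config.templates_per_cognate_pair < 1:
        raise ValueError("templates_per_cognate_pair must be >= 1")
    rng = np.random.default_rng([config.seed, 1])
    templates_of_dip = {}
    for t in manifest.templates:
        templates_of_dip.setdefault(t.dip_subgroup, []).append(t)

    cognate = registry.cognate_map
    cognate_inv = {v: k for k, v in cognate.items()}
    records: list[DDGRecord] = []
    for d_sg in registry.dip_subgroups:
        for p_sg in registry.dpr_subgroups:
            if cognate.get(d_sg) == p_sg:
                continue
            # (templates of the cognate complex scanned, side, source subgroup)
            jobs = (
                (templates_of_dip[d_sg], DPR, p_sg),
                (templates_of_dip[cognate_inv[p_sg]], DIP, d_sg),
            )
            for tmpl_list, side, source_sg in jobs:
                members = registry.members(side, source_sg)
                for p in range(1, config.n_positions + 1):
                    is_planted = (
                        not config.decouple_filters
                        and (d_sg, p_sg, side, p) in manifest.planted_constraints
                    )
                    if is_planted:
                        mu = config.ddg_effect_mean
                    elif rng.random() < config.stabilizing_fraction:
                        mu = _STABILIZING_MEAN
                    else:
                        mu = 0.0
                    for tmpl in tmpl_list:
                        wt = manifest.template_wt(tmpl, side, p)
                        tmpl_sg = tmpl.dip_subgroup if side == DIP else tmpl.dpr_subgroup
                        for member in members:
                            mut = manifest.member_sequences[(side, source_sg, member)][p - 1]
                            if mut == wt:
                                continue
                            runs = mu + config.ddg_run_sd * rng.standard_normal(
                                config.n_runs
                            )
                            records.append(
                                DDGRecord(
                                    template_id=tmpl.template_id,
                                    template_subgroup=tmpl_sg,
                                    side=side,
                                    family_position=p,
                                    wt_residue=wt,
                                    mut_residue=mut,
                                    source_subgroup=source_sg,
                                    source_member=member,
                                    ddg=float(runs.mean()),
                                    run_values=tuple(float(v) for v in runs),
                                )
                            )
    return records


def write_templates_table(templates: tuple[TemplateComplex, ...], path: str | Path) -> None:
    pd.DataFrame([asdict(t) for t in templates]).to_csv(path, sep="\t", index=False)


def read_templates_table(path: str | Path) -> tuple[TemplateComplex, ...]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return tuple(
        TemplateComplex(
            template_id=r.template_id,
            dip_subgroup=r.dip_subgroup,
            dpr_subgroup=r.dpr_subgroup,
            dip_member=r.dip_member,
            dpr_member=r.dpr_member,
        )
        for r in df.itertuples()
    )


def write_truth_manifest(manifest: TruthManifest, path: str | Path) -> None:
    payload = {
        "planted_constraints": sorted(
            list(t) for t in manifest.planted_constraints
        ),
        "position_classes": {str(k): v for k, v in manifest.position_classes.items()},
        "member_sequences": {
            "|".join(k): v for k, v in manifest.member_sequences.items()
        },
        "templates": [asdict(t) for t in manifest.templates],
        "config": {
            k: v for k, v in asdict(manifest.config).items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth_manifest(path: str | Path) -> TruthManifest:
    payload = json.loads(Path(path).read_text())
    cfg = dict(payload["config"])
    if cfg.get("position_plan") is not None:
        cfg["position_plan"] = {int(k): v for k, v in cfg["position_plan"].items()}
    config = ScenarioConfig(**cfg)
    return TruthManifest(
        planted_constraints=frozenset(
            (a, b, side, int(p)) for a, b, side, p in payload["planted_constraints"]
        ),
        position_classes={int(k): v for k, v in payload["position_classes"].items()},
        member_sequences={
            tuple(k.split("|")): v for k, v in payload["member_sequences"].items()
        },
        templates=tuple(
            TemplateComplex(**t) for t in payload["templates"]
        ),
        config=config,
    )


def generate_scenario(config: ScenarioConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete scenario file set loadable by the package readers."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    msas, registry, pmap, manifest = generate_subfamily_msas(config)
    records = generate_ddg_records(config, registry, manifest)

    paths: dict[str, Path] = {}
    for msa in msas:
        p = out / f"msa_{msa.family_side}_{msa.subgroup_id}.fasta"
        write_aligned_fasta(msa, p)
        paths[f"msa:{msa.family_side}:{msa.subgroup_id}"] = p
    paths["registry"] = out / "registry.tsv"
    write_registry(registry, paths["registry"])
    paths["position_map"] = out / "position_map.tsv"
    write_position_map(pmap, paths["position_map"])
    paths["ddg_table"] = out / "ddg_table.tsv"
    write_ddg_table(records, paths["ddg_table"])
    paths["templates"] = out / "templates.tsv"
    write_templates_table(manifest.templates, paths["templates"])
    paths["truth"] = out / "truth_manifest.json"
    write_truth_manifest(manifest, paths["truth"])
    return paths
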