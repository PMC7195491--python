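"""Subgroup membership registry and cognate DIP↔Dpr pairing.

A heterophilic paralog family is partitioned into interaction-specificity
subgroups on each side; the cognate map is a bijection pairing each DIP
subgroup with the single Dpr subgroup its members bind strongly.

The plain-text format is tab-separated and diffable::

    dip     alpha   DIP-alpha
    dpr     blue    Dpr6,Dpr10
    cognate alpha   blue
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .msa import DIP, DPR


@dataclass(frozen=True)
class SubgroupRegistry:
    dip_subgroups: dict[str, tuple[str, ...]]
    dpr_subgroups: dict[str, tuple[str, ...]]
    #: DIP subgroup id -> cognate Dpr subgroup id (bijection)
    cognate_map: dict[str, str]

    def __post_init__(self) -> None:
        for side_name, groups in (("DIP", self.dip_subgroups), ("Dpr", self.dpr_subgroups)):
            seen: dict[str, str] = {}
            for sg, members in groups.items():
                if not members:
                    raise ValueError(f"{side_name} subgroup {sg!r} has no members")
                for m in members:
                    if m in seen:
                        raise ValueError(
                            f"protein {m!r} appears in {side_name} subgroups "
                            f"{seen[m]!r} and {sg!r}"
                        )
                    seen[m] = sg
        for d, p in self.cognate_map.items():
            if d not in self.dip_subgroups:
                raise ValueError(f"cognate pair references unknown DIP subgroup {d!r}")
            if p not in self.dpr_subgroups:
                raise ValueError(f"cognate pair references unknown Dpr subgroup {p!r}")
        if len(set(self.cognate_map.values())) != len(self.cognate_map):
            raise ValueError("cognate map is not one-to-one")

    def members(self, side: str, subgroup_id: str) -> tuple[str, ...]:
        groups = self.dip_subgroups if side == DIP else self.dpr_subgroups
        return groups[subgroup_id]

    def subgroup_of(self, side: str, protein_id: str) -> str:
        groups = self.dip_subgroups if side == DIP else self.dpr_subgroups
        for sg, members in groups.items():
            if protein_id in members:
                return sg
        raise KeyError(f"{protein_id!r} not found in any {side} subgroup")

    def cognate_dpr(self, dip_subgroup: str) -> str:
        return self.cognate_map[dip_subgroup]

    def cognate_dip(self, dpr_subgroup: str) -> str:
        inv = {v: k for k, v in self.cognate_map.items()}
        return inv[dpr_subgroup]


def read_registry(path: str | Path) -> SubgroupRegistry:
    dip: dict[str, tuple[str, ...]] = {}
    dpr: dict[str, tuple[str, ...]] = {}
    cognate: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
        kind, key, value = parts
        if kind == "dip":
            dip[key] = tuple(m.strip() for m in value.split(","))
        elif kind == "dpr":
            dpr[key] = tuple(m.strip() for m in value.split(","))
        elif kind == "cognate":
            cognate[key] = value
        else:
            raise ValueError(f"{path}:{lineno}: unknown record kind {kind!r}")
    return SubgroupRegistry(dip_subgroups=dip, dpr_subgroups=dpr, cognate_map=cognate)


def write_registry(reg: SubgroupRegistry, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sg, members in reg.dip_subgroups.items():
            fh.write(f"dip\t{sg}\t{','.join(members)}\n")
        for sg, members in reg.dpr_subgroups.items():
            fh.write(f"dpr\t{sg}\t{','.join(members)}\n")
        for d, p in reg.cognate_map.items():
            fh.write(f"cognate\t{d}\t{p}\n")


def fly_registry() -> SubgroupRegistry:
    """The seven-by-seven Drosophila DIP/Dpr specificity subgroups.

    Membership and cognate pairings follow the published interactome: the
    green DIP-theta/eta/iota group binds Dpr1-5, DIP-kappa binds Dpr7,
    blue DIP-alpha binds Dpr6/10, DIP-beta/lambda binds Dpr8/9/21, purple
    DIP-gamma binds Dpr11/15/16/17, DIP-delta binds Dpr12 and
    DIP-epsilon/zeta binds Dpr13/14/18/19/20.
    """
    dip = {
        "theta-eta-iota": ("DIP-theta", "DIP-eta", "DIP-iota"),
        "kappa": ("DIP-kappa",),
        "alpha": ("DIP-alpha",),
        "beta-lambda": ("DIP-beta", "DIP-lambda"),
        "gamma": ("DIP-gamma",),
        "delta": ("DIP-delta",),
        "epsilon-zeta": ("DIP-epsilon", "DIP-zeta"),
    }
    dpr = {
        "dpr1-5": ("Dpr1", "Dpr2", "Dpr3", "Dpr4", "Dpr5"),
        "dpr7": ("Dpr7",),
        "dpr6-10": ("Dpr6", "Dpr10"),
        "dpr8-9-21": ("Dpr8", "Dpr9", "Dpr21"),
        "dpr11-15-16-17": ("Dpr11", "Dpr15", "Dpr16", "Dpr17"),
        "dpr12": ("Dpr12",),
        "dpr13-14-18-19-20": ("Dpr13", "Dpr14", "Dpr18", "Dpr19", "Dpr20"),
    }
    cognate = {
        "theta-eta-iota": "dpr1-5",
        "kappa": "dpr7",
        "alpha": "dpr6-10",
        "beta-lambda": "dpr8-9-21",
        "gamma": "dpr11-15-16-17",
        "delta": "dpr12",
        "epsilon-zeta": "dpr13-14-18-19-20",
    }
    return SubgroupRegistry(dip_subgroups=dip, dpr_subgroups=dpr, cognate_map=cognate)
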