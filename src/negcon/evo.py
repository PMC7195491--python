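"""Evolutionary filter: per-position divergence between two subfamilies.

A family-wide interfacial position is accepted as evolutionarily supported
when at least one of three conditions holds for the two subfamily alignment
columns being compared:

1. *identity*: both columns are conserved (base-21 Shannon entropy below a
   cutoff, 0.23 by default) and their modal residues differ;
2. *biophysical property*: the occurrence-weighted fraction of cross-column
   amino-acid pairs drawn from different property classes (hydrophobic,
   polar, positively charged, negatively charged) exceeds a percent cutoff
   (90% by default);
3. *size*: the larger of the two directional occurrence-weighted fractions
   of cross-column pairs from different size classes (tiny < small < medium
   < large < bulky) exceeds the same style of cutoff.

Entropy uses logarithm base 21 so that a uniform column over the 20 amino
acids plus gap scores exactly 1; a fully conserved column scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msa import (
    ALPHABET,
    AMINO_ACIDS,
    AlignedSubfamily,
    FrequencyProfile,
    column_frequency_profile,
)

#: Biophysical property classes over the 20 amino acids.
PROPERTY_GROUPS: dict[str, frozenset[str]] = {
    "hydrophobic": frozenset("IVLMFWACGP"),
    "polar": frozenset("STQNHY"),
    "positive": frozenset("KR"),
    "negative": frozenset("ED"),
}

#: Volume-based size classes, strictly ordered tiny < small < medium < large < bulky.
SIZE_GROUPS: tuple[tuple[str, frozenset[str]], ...] = (
    ("tiny", frozenset("GAS")),
    ("small", frozenset("CDPNT")),
    ("medium", frozenset("EVQH")),
    ("large", frozenset("MILKR")),
    ("bulky", frozenset("FYW")),
)


def _check_partition() -> None:
    all_prop = frozenset().union(*PROPERTY_GROUPS.values())
    all_size = frozenset().union(*(s for _, s in SIZE_GROUPS))
    assert all_prop == frozenset(AMINO_ACIDS) and all_size == frozenset(AMINO_ACIDS)


_check_partition()


def property_of(aa: str) -> str:
    for name, group in PROPERTY_GROUPS.items():
        if aa in group:
            return name
    raise KeyError(f"{aa!r} is not a standard amino acid")


def size_rank(aa: str) -> int:
    for rank, (_, group) in enumerate(SIZE_GROUPS):
        if aa in group:
            return rank
    raise KeyError(f"{aa!r} is not a standard amino acid")


def _property_codes() -> np.ndarray:
    names = list(PROPERTY_GROUPS)
    return np.array([names.index(property_of(aa)) for aa in AMINO_ACIDS])


def _size_ranks() -> np.ndarray:
    return np.array([size_rank(aa) for aa in AMINO_ACIDS])


_PROP = _property_codes()
_SIZE = _size_ranks()
# 20x20 masks over amino-acid pairs (i-row, j-column)
_DIFF_PROPERTY = _PROP[:, None] != _PROP[None, :]
_I_LARGER = _SIZE[:, None] > _SIZE[None, :]
_I_SMALLER = _SIZE[:, None] < _SIZE[None, :]


@dataclass(frozen=True)
class EvoFilterParams:
    entropy_cutoff: float = 0.23
    property_cutoff: float = 90.0
    size_cutoff: float = 90.0
    #: renormalize amino-acid frequencies over the 20 residues after dropping
    #: the gap before computing percent differences (off by default: gap-rich
    #: columns then cannot reach the cutoffs, which is fail-safe).
    renormalize_gaps: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.entropy_cutoff <= 1:
            raise ValueError("entropy_cutoff must be in (0, 1]")
        for name in ("property_cutoff", "size_cutoff"):
            v = getattr(self, name)
            if not 0 < v <= 100:
                raise ValueError(f"{name} must be in (0, 100]")


@dataclass(frozen=True)
class EvoVerdict:
    family_position: int
    subgroup_i: str
    subgroup_j: str
    entropy_i: float
    entropy_j: float
    identity_condition: bool
    property_percent: float
    size_percent: float
    accepted: bool


def shannon_entropy(profile: FrequencyProfile) -> float:
    """Base-21 Shannon entropy of a column profile, in [0, 1].

    0·log 0 is taken as 0; a single-symbol column scores 0 and a uniform
    column over all 21 symbols scores exactly 1.
    """
    f = profile.freqs
    if abs(f.sum() - 1.0) > 1e-6:
        raise ValueError("frequencies do not sum to 1")
    nz = f[f > 0]
    s = float(-(nz * (np.log(nz) / np.log(len(ALPHABET)))).sum())
    # clip the tiny negative round-off (and -0.0) of a degenerate column
    if s <= 0.0:
        return 0.0
    return min(s, 1.0)


def identity_condition(
    profile_i: FrequencyProfile,
    profile_j: FrequencyProfile,
    params: EvoFilterParams = EvoFilterParams(),
) -> bool:
    """Both columns conserved (S below cutoff) and different in identity.

    Identity difference is judged on modal-residue sets (every amino acid
    tied for the maximum frequency, gap excluded): the condition requires
    the two sets to be disjoint.
    """
    if shannon_entropy(profile_i) >= params.entropy_cutoff:
        return False
    if shannon_entropy(profile_j) >= params.entropy_cutoff:
        return False
    modes_i = profile_i.modal_residues()
    modes_j = profile_j.modal_residues()
    if not modes_i or not modes_j:
        return False
    return modes_i.isdisjoint(modes_j)


def _aa_freqs(profile: FrequencyProfile, renormalize: bool) -> np.ndarray:
    f = profile.amino_acid_freqs
    if renormalize:
        total = f.sum()
        if total > 0:
            f = f / total
    return f


def property_difference(
    profile_i: FrequencyProfile,
    profile_j: FrequencyProfile,
    renormalize_gaps: bool = False,
) -> float:
    """Occurrence-weighted percent of cross-column pairs differing in property.

    Sums f_i(k)·f_j(l)·100 over amino-acid pairs (k, l) whose property
    classes differ; same-class pairs and any pair involving a gap contribute
    nothing.
    """
    fi = _aa_freqs(profile_i, renormalize_gaps)
    fj = _aa_freqs(profile_j, renormalize_gaps)
    return float(fi @ _DIFF_PROPERTY @ fj * 100.0)


def size_difference(
    profile_i: FrequencyProfile,
    profile_j: FrequencyProfile,
    renormalize_gaps: bool = False,
) -> float:
    """Max of the two directional occurrence-weighted size-class differences.

    One direction sums pairs where the i-column residue sits in a strictly
    larger size class than the j-column residue; the other sums the strictly
    smaller pairs.  Same-class pairs and gaps contribute to neither, so a
    column pair whose differences split between directions cannot reach a
    high cutoff.
    """
    fi = _aa_freqs(profile_i, renormalize_gaps)
    fj = _aa_freqs(profile_j, renormalize_gaps)
    larger = float(fi @ _I_LARGER @ fj * 100.0)
    smaller = float(fi @ _I_SMALLER @ fj * 100.0)
    return max(larger, smaller)


def evaluate_profiles(
    profile_i: FrequencyProfile,
    profile_j: FrequencyProfile,
    family_position: int,
    subgroup_i: str,
    subgroup_j: str,
    params: EvoFilterParams = EvoFilterParams(),
) -> EvoVerdict:
    """Full three-condition verdict for one pair of column profiles."""
    ent_i = shannon_entropy(profile_i)
    ent_j = shannon_entropy(profile_j)
    ident = identity_condition(profile_i, profile_j, params)
    prop = property_difference(profile_i, profile_j, params.renormalize_gaps)
    size = size_difference(profile_i, profile_j, params.renormalize_gaps)
    accepted = ident or prop > params.property_cutoff or size > params.size_cutoff
    return EvoVerdict(
        family_position=family_position,
        subgroup_i=subgroup_i,
        subgroup_j=subgroup_j,
        entropy_i=ent_i,
        entropy_j=ent_j,
        identity_condition=ident,
        property_percent=prop,
        size_percent=size,
        accepted=accepted,
    )


def evaluate_evo_filter(
    msa_i: AlignedSubfamily,
    msa_j: AlignedSubfamily,
    family_position: int,
    params: EvoFilterParams = EvoFilterParams(),
) -> EvoVerdict:
    """Verdict at one family-wide position of two interfacial-column MSAs.

    Both alignments must already be restricted to family-wide columns in the
    same order; *family_position* is 1-based.
    """
    if msa_i.length != msa_j.length:
        raise ValueError(
            f"alignment lengths differ: {msa_i.length} vs {msa_j.length}"
        )
    if not 1 <= family_position <= msa_i.length:
        raise ValueError(
            f"family position {family_position} out of range 1..{msa_i.length}"
        )
    col = family_position - 1
    return evaluate_profiles(
        column_frequency_profile(msa_i, col),
        column_frequency_profile(msa_j, col),
        family_position,
        msa_i.subgroup_id,
        msa_j.subgroup_id,
        params,
    )
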