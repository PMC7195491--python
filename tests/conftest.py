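import numpy as np
import pytest

from negcon.msa import ALPHABET, AlignedSubfamily, FrequencyProfile


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def make_profile(freq_map: dict[str, float], column: int = 0,
                 n_sequences: int = 100) -> FrequencyProfile:
    """Profile from explicit symbol->frequency map (rest zero)."""
    freqs = np.zeros(len(ALPHABET))
    for sym, f in freq_map.items():
        freqs[ALPHABET.index(sym)] = f
    return FrequencyProfile(column=column, freqs=freqs, n_sequences=n_sequences)


def random_profile(rng: np.random.Generator, concentration: float = 0.3,
                   with_gap: bool = True) -> FrequencyProfile:
    """Random sparse-ish profile over the 21-symbol alphabet."""
    n = len(ALPHABET) if with_gap else len(ALPHABET) - 1
    raw = rng.dirichlet(np.full(n, concentration))
    freqs = np.zeros(len(ALPHABET))
    freqs[:n] = raw
    return FrequencyProfile(column=0, freqs=freqs, n_sequences=50)


def make_msa(rows: list[str], side: str = "DIP", subgroup: str = "sg",
             reference_id: str | None = None) -> AlignedSubfamily:
    return AlignedSubfamily(
        family_side=side,
        subgroup_id=subgroup,
        sequence_ids=tuple(f"seq{i}" for i in range(len(rows))),
        rows=tuple(rows),
        reference_id=reference_id,
    )
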