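import random

import pytest

from peptidespace.digestion import CleavageRule
from peptidespace.sequence_io import ProteinRecord, Section
from peptidespace.synthetic_data import SyntheticConfig, generate

# ---------------------------------------------------------------------------
# Independent brute-force digestion oracle: enumerate every pair of cleavage
# sites (plus the sequence ends) and keep spans with <= m internal sites.
# Shares no code with peptidespace.digestion.


def oracle_sites(seq: str, rule: str) -> set[int]:
    n = len(seq)
    sites = {0, n}
    for i, aa in enumerate(seq):
        if aa in "KR":
            if rule == "trypsin_p" or i + 1 == n or seq[i + 1] != "P":
                sites.add(i + 1)
    return sites


def oracle_digest(
    seq: str,
    rule: str = "trypsin",
    missed_cleavages: int = 0,
    min_length: int = 6,
    max_length: int | None = None,
) -> set[tuple[str, int]]:
    sites = oracle_sites(seq, rule)
    out = set()
    for a in sites:
        for b in sites:
            if b <= a:
                continue
            internal = sum(1 for s in sites if a < s < b)
            if internal > missed_cleavages:
                continue
            pep = seq[a:b]
            if len(pep) < min_length:
                continue
            if max_length is not None and len(pep) > max_length:
                continue
            out.add((pep, a))
    return out


def random_protein_sequence(rng: random.Random, max_len: int = 200) -> str:
    # K/R/P enriched to exercise cleavage sites and the proline exception;
    # occasional U and ambiguity codes.
    alphabet = "ACDEFGHIKLMNPQRSTVWY" + "KKRRPP" + "UXBZ"
    n = rng.randint(1, max_len)
    return "".join(rng.choice(alphabet) for _ in range(n))


@pytest.fixture(scope="session")
def rng():
    return random.Random(20120)


@pytest.fixture
def simple_records():
    return [
        ProteinRecord("P00001", Section.reviewed, "A1 one", "MAAAAAKCCCCCCR"),
        ProteinRecord("P00002", Section.reviewed, "A2 two", "AAAAAKCCCCCCR"),
        ProteinRecord("P00003", Section.unreviewed, "A3 three", "DDDDDDKEEEEEEK"),
    ]


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Default-conditions synthetic proteome, shared across tests."""
    return generate(SyntheticConfig(seed=42, n_entries=50))
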