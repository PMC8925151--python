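import itertools

import pytest
from hypothesis import HealthCheck, settings

from repeatarray import ANCESTRAL_UNIT_NT, MinisatelliteAllele, partition_allele

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def mutate(seq: str, *changes: tuple[int, str]) -> str:
    """Return seq with 0-based positions replaced by the given bases."""
    s = list(seq)
    for pos, base in changes:
        s[pos] = base
    return "".join(s)


@pytest.fixture(scope="session")
def anc_unit() -> str:
    return ANCESTRAL_UNIT_NT


@pytest.fixture
def make_allele():
    """Factory for alleles built from explicit unit sequences."""

    counter = itertools.count(1)

    def _make(
        unit_seqs,
        allele_id=None,
        individual_id=None,
        population="ANV",
        hemisphere="SH",
    ):
        i = next(counter)
        return MinisatelliteAllele(
            allele_id=allele_id or f"al{i}",
            individual_id=individual_id or f"ind{i}",
            population=population,
            hemisphere=hemisphere,
            units=partition_allele("".join(unit_seqs), len(unit_seqs[0])),
        )

    return _make


@pytest.fixture(scope="session")
def unit_alphabet(anc_unit):
    """Three 84-nt unit types: ancestral, a masked-codon variant, a 2-mismatch variant.

    u_hv differs from the ancestor only inside contact codon 16 (nt 46-48),
    so it is identical to it under masking; u_far differs at two slow sites.
    """
    u0 = anc_unit
    u_hv = mutate(anc_unit, (46, "T"))
    u_far = mutate(anc_unit, (0, "G"), (80, "C"))
    return u0, u_hv, u_far
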