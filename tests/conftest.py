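import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from hlapop.genotype_io import (
    AmbiguousGenotype,
    GenotypePair,
    PopulationSample,
    QuestionnaireMetadata,
)
from hlapop.nomenclature import parse_allele_name


def gp(a: str, b: str) -> GenotypePair:
    return GenotypePair(parse_allele_name(a), parse_allele_name(b))


def make_sample(candidate_lists, locus="A", metadata=None):
    """Build a single-locus sample from lists of 'a+b' pair strings."""
    genotypes = []
    for i, cands in enumerate(candidate_lists):
        pairs = [gp(*c.split("+")) for c in cands]
        genotypes.append(
            AmbiguousGenotype(
                individual_id=f"IND{i:03d}", locus_set=[locus], candidates=pairs
            )
        )
    return PopulationSample(
        genotypes=genotypes,
        metadata=metadata or QuestionnaireMetadata(),
        locus_set=[locus],
    )


def unambiguous_from_counts(counts, locus="A"):
    """Sample with given genotype counts: {(allele_a, allele_b): n}."""
    lists = []
    for (a, b), n in counts.items():
        lists.extend([[f"{a}+{b}"]] * n)
    return make_sample(lists, locus=locus)


@pytest.fixture
def toy_kit():
    """Two-probe kit over three alleles: P1 reacts with A1 only, P2 with
    A2 and A3 — the classic worked interpretation example."""
    from hlapop.typing_interpretation import KitDescription

    a1, a2, a3 = (parse_allele_name(f"A*{i:02d}") for i in (1, 2, 3))
    return KitDescription(
        kit_id="TOY",
        locus="A",
        probes=[("P1", frozenset({a1})), ("P2", frozenset({a2, a3}))],
        allele_universe=frozenset({a1, a2, a3}),
    )
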