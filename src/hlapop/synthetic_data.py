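"""Fully synthetic population samples, typing kits and reactivity data.

The generator draws what the downstream analyses assume: independent
individuals (no first-degree relatives) with genotype probabilities

    P(aa) = p_a^2 + f p_a (1 - p_a),      P(ab) = 2 p_a p_b (1 - f)

— Hardy-Weinberg proportions when the inbreeding coefficient f is 0 — and
then degrades the typing the way real technologies do: either by pushing
every genotype through a probe kit and re-interpreting the reactivity
pattern (kit-masked ambiguity, the reverse-SSO mechanism), or by merging
each genotype's pair with a random extra pair at a given rate (a cheap
kit-free stress test).  The true genotype is always among the candidates.

All questionnaire metadata attached to synthetic samples is clearly
fictional; the generator never imitates a real population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from hlapop.genotype_io import (
    AmbiguousGenotype,
    GenotypePair,
    PopulationSample,
    QuestionnaireMetadata,
)
from hlapop.nomenclature import AlleleName, parse_allele_name
from hlapop.typing_interpretation import (
    KitDescription,
    interpret_pattern,
    predict_pattern,
)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic generator.

    ``frequencies`` may be an explicit list (summing to 1) or ``None``, in
    which case a symmetric Dirichlet(``dirichlet_concentration``) draw over
    ``k_alleles`` alleles is used.  ``inbreeding_f`` defaults to 0 (HWE).
    """

    N: int = 100
    k_alleles: int = 8
    frequencies: list | None = None
    dirichlet_concentration: float = 1.0
    inbreeding_f: float = 0.0
    locus: str = "A"
    ambiguity_mode: str = "none"       # none | kit | random_merge
    random_merge_rate: float = 0.0
    seed: int | None = 0

    def __post_init__(self):
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        if self.frequencies is not None:
            f = np.asarray(self.frequencies, dtype=float)
            if f.ndim != 1 or f.size < 1 or np.any(f < 0) or abs(f.sum() - 1) > 1e-9:
                raise ValueError("frequencies must be non-negative and sum to 1")
            self.k_alleles = f.size
        if not 0.0 <= self.inbreeding_f <= 1.0:
            raise ValueError(f"inbreeding_f must be in [0,1], got {self.inbreeding_f}")
        if not 0.0 <= self.random_merge_rate <= 1.0:
            raise ValueError("random_merge_rate must be in [0,1]")


def _synthetic_metadata(cfg: GeneratorConfig) -> QuestionnaireMetadata:
    return QuestionnaireMetadata(
        study_type="anthropology_field",
        population_name="Synthetica (fictional benchmark population)",
        alternative_names=["SimPop"],
        latitude=0.0,
        longitude=0.0,
        language="none (synthetic)",
        linguistic_family="none (synthetic)",
        first_degree_relatives_excluded=True,
        ethics_statement="synthetic data; no human subjects involved",
        typing_technique=f"simulated ({cfg.ambiguity_mode})",
        n_individuals=cfg.N,
    )


def default_alleles(locus: str, k: int) -> list[AlleleName]:
    """k synthetic second-field allele names at one locus."""
    return [parse_allele_name(f"{locus}*{g:02d}:01") for g in range(1, k + 1)]


def generate_genotypes(cfg: GeneratorConfig) -> PopulationSample:
    """Draw N independent genotypes under the (possibly inbred) HWE model.

    Deterministic given ``cfg.seed``.  Returns an unambiguous sample unless
    ``ambiguity_mode='random_merge'`` (kit masking is a separate step, see
    :func:`mask_with_kit`).  The true allele frequencies and inbreeding
    coefficient are attached as ``sample.true_frequencies`` and
    ``sample.true_inbreeding_f`` for recovery checks.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.frequencies is not None:
        p = np.asarray(cfg.frequencies, dtype=float)
    else:
        p = rng.dirichlet(np.full(cfg.k_alleles, cfg.dirichlet_concentration))
    k = p.size
    alleles = default_alleles(cfg.locus, k)

    # genotype probability vector over unordered pairs (i <= j)
    pairs = [(i, j) for i in range(k) for j in range(i, k)]
    f = cfg.inbreeding_f
    probs = np.array([
        p[i] ** 2 + f * p[i] * (1 - p[i]) if i == j else 2 * p[i] * p[j] * (1 - f)
        for i, j in pairs
    ])
    probs = probs / probs.sum()
    draws = rng.choice(len(pairs), size=cfg.N, p=probs)

    genotypes = []
    for ind, d in enumerate(draws):
        i, j = pairs[d]
        true_pair = GenotypePair(alleles[i], alleles[j])
        candidates = [true_pair]
        if cfg.ambiguity_mode == "random_merge" and rng.random() < cfg.random_merge_rate:
            extra_d = int(rng.integers(0, len(pairs)))
            a, b = pairs[extra_d]
            extra = GenotypePair(alleles[a], alleles[b])
            if extra != true_pair:
                candidates.append(extra)
        genotypes.append(AmbiguousGenotype(
            individual_id=f"SIM{ind:05d}",
            locus_set=[cfg.locus],
            candidates=candidates,
            source="pair_list" if len(candidates) > 1 else "unambiguous",
        ))
    sample = PopulationSample(
        genotypes=genotypes, metadata=_synthetic_metadata(cfg),
        locus_set=[cfg.locus],
    )
    sample.true_frequencies = {a.serialize(): float(pi) for a, pi in zip(alleles, p)}
    sample.true_inbreeding_f = f
    return sample


def mask_with_kit(s: PopulationSample, kit: KitDescription) -> PopulationSample:
    """Replace each genotype by the ambiguous genotype its kit reactivity
    pattern implies.  The true genotype is always among the candidates
    (the forward model is deterministic)."""
    genotypes = []
    for g in s.genotypes:
        if g.ambiguous:
            raise ValueError(
                f"{g.individual_id}: kit masking expects unambiguous input genotypes")
        pattern = predict_pattern(g.candidates[0], kit)
        masked = interpret_pattern(pattern, kit, individual_id=g.individual_id)
        genotypes.append(masked)
    out = PopulationSample(
        genotypes=genotypes, metadata=s.metadata, locus_set=list(s.locus_set))
    for attr in ("true_frequencies", "true_inbreeding_f"):
        if hasattr(s, attr):
            setattr(out, attr, getattr(s, attr))
    return out


def generate_kit(
    alleles,
    n_probes: int,
    seed: int | None = 0,
    kit_id: str = "SIMKIT",
    max_attempts: int = 100,
) -> KitDescription:
    """Random probe panel over the given alleles.

    Each allele reacts with each probe with probability 1/2; panels are
    re-drawn until every allele has a distinct probe signature, or up to
    ``max_attempts`` — after which the kit is returned as-is and carries
    unresolvable allele groups (useful for ambiguity stress tests).
    """
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    alleles = list(alleles)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max_attempts):
        matrix = rng.integers(0, 2, size=(len(alleles), n_probes))
        signatures = {tuple(row) for row in matrix}
        best = matrix
        if len(signatures) == len(alleles):
            break
    probes = []
    for pj in range(n_probes):
        reactive = frozenset(a for a, row in zip(alleles, best) if row[pj])
        probes.append((f"P{pj + 1:02d}", reactive))
    return KitDescription(
        kit_id=kit_id,
        locus=alleles[0].locus,
        probes=probes,
        allele_universe=frozenset(alleles),
    )
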