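"""Interpretation of probe-reactivity patterns against a typing-kit description.

Reverse SSO typing reports, for each probe of a kit, whether it hybridized
with the sample.  The forward model is deterministic and dominant-positive: a
probe is positive iff it reacts with at least one of the two alleles carried
(union rule, no probe noise).  Interpretation inverts this: the ambiguous
genotype implied by a pattern is the set of all unordered allele pairs over
the kit's allele universe whose predicted pattern matches — in most cases
more than one pair, which is where typing ambiguity comes from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from pathlib import Path

from hlapop.errors import KitError, UninterpretablePatternError
from hlapop.genotype_io import AmbiguousGenotype, GenotypePair
from hlapop.nomenclature import AlleleName, parse_allele_name


@dataclass(frozen=True)
class ReactivityPattern:
    """Probe calls for one individual: probe_id -> positive?"""

    probe_calls: tuple  # tuple of (probe_id, bool), fixed probe order

    @classmethod
    def from_dict(cls, calls: dict) -> "ReactivityPattern":
        return cls(tuple(sorted((k, bool(v)) for k, v in calls.items())))

    def as_dict(self) -> dict:
        return dict(self.probe_calls)

    def signature(self) -> tuple:
        return tuple(v for _, v in self.probe_calls)

    def hamming(self, other: "ReactivityPattern") -> int:
        return sum(a != b for a, b in zip(self.signature(), other.signature()))


@dataclass
class KitDescription:
    """A probe panel: what a typing technology can in principle distinguish."""

    kit_id: str
    locus: str
    probes: list  # list of (probe_id, frozenset of AlleleName)
    allele_universe: frozenset

    _pattern_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        ids = [pid for pid, _ in self.probes]
        if len(set(ids)) != len(ids):
            raise KitError(f"kit {self.kit_id!r}: duplicate probe ids")
        for pid, reactive in self.probes:
            stray = set(reactive) - set(self.allele_universe)
            if stray:
                raise KitError(
                    f"kit {self.kit_id!r} probe {pid!r}: reactive alleles outside "
                    f"universe: {sorted(str(a) for a in stray)}"
                )

    @property
    def probe_ids(self) -> list:
        return [pid for pid, _ in self.probes]

    def resolves_all_pairs(self) -> bool:
        """True if no two distinct unordered pairs share a predicted pattern."""
        seen = {}
        for pair in self._all_pairs():
            sig = predict_pattern(pair, self).signature()
            if sig in seen and seen[sig] != pair:
                return False
            seen[sig] = pair
        return True

    def _all_pairs(self):
        universe = sorted(self.allele_universe, key=lambda a: a.sort_key())
        for a, b in combinations_with_replacement(universe, 2):
            yield GenotypePair(a, b)

    @classmethod
    def from_tsv(cls, path) -> "KitDescription":
        """Read ``probe_id<TAB>comma-separated allele names`` with a
        '#'-comment header carrying ``kit_id=`` and ``locus=``."""
        kit_id, locus = Path(path).stem, ""
        probes = []
        universe = set()
        for line in Path(path).read_text().splitlines():
            if line.startswith("#"):
                for tok in line.lstrip("# ").split():
                    if tok.startswith("kit_id="):
                        kit_id = tok.split("=", 1)[1]
                    elif tok.startswith("locus="):
                        locus = tok.split("=", 1)[1]
                continue
            if not line.strip():
                continue
            pid, alleles = line.split("\t")
            reactive = frozenset(parse_allele_name(t.strip()) for t in alleles.split(","))
            probes.append((pid.strip(), reactive))
            universe |= reactive
        if not locus and universe:
            locus = next(iter(universe)).locus
        return cls(kit_id=kit_id, locus=locus, probes=probes,
                   allele_universe=frozenset(universe))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# kit_id={self.kit_id} locus={self.locus}\n")
            for pid, reactive in self.probes:
                names = ",".join(
                    a.serialize() for a in sorted(reactive, key=lambda x: x.sort_key())
                )
                fh.write(f"{pid}\t{names}\n")


def predict_pattern(pair: GenotypePair, kit: KitDescription) -> ReactivityPattern:
    """Forward model: probe positive iff it reacts with either allele."""
    for a in pair.alleles():
        if a not in kit.allele_universe:
            raise KitError(
                f"allele {a.serialize()} outside the universe of kit {kit.kit_id!r}"
            )
    cached = kit._pattern_cache.get(pair)
    if cached is not None:
        return cached
    calls = tuple(
        sorted(
            (pid, pair.allele1 in reactive or pair.allele2 in reactive)
            for pid, reactive in kit.probes
        )
    )
    pattern = ReactivityPattern(calls)
    kit._pattern_cache[pair] = pattern
    return pattern


def interpret_pattern(
    pattern: ReactivityPattern, kit: KitDescription, individual_id: str = ""
) -> AmbiguousGenotype:
    """All unordered allele pairs over the kit universe (homozygotes allowed)
    whose predicted pattern equals the observed one.

    Raises :class:`UninterpretablePatternError` carrying the nearest
    interpretable patterns (minimum Hamming distance) when no pair matches.
    """
    observed_ids = set(pattern.as_dict())
    if observed_ids != set(kit.probe_ids):
        raise KitError(
            f"pattern probes {sorted(observed_ids)} do not cover kit probes "
            f"{sorted(kit.probe_ids)}"
        )
    candidates = []
    predicted = {}
    for pair in kit._all_pairs():
        pred = predict_pattern(pair, kit)
        predicted.setdefault(pred, pair)
        if pred == pattern:
            candidates.append(pair)
    if not candidates:
        ranked = sorted(
            ((pattern.hamming(p), p) for p in predicted),
            key=lambda t: (t[0], t[1].signature()),
        )
        best = [t for t in ranked if t[0] == ranked[0][0]] if ranked else []
        raise UninterpretablePatternError(pattern, best)
    return AmbiguousGenotype(
        individual_id=individual_id,
        locus_set=[kit.locus],
        candidates=candidates,
        source="kit_interpretation",
    )
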