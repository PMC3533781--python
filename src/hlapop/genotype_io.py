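"""Ambiguity-preserving genotype representation and I/O.

A typing result at one locus is, in general, not a single allele pair but a
*list of allele pairs required to explain the genotype*.  This module stores
that list verbatim, reads and writes it in two dialects, expands NMDP-style
abbreviation codes (MACs), and quantifies the spurious pairs that independent
per-chromosome code expansion introduces.

Canonical text dialect — genotype-list (GL) strings:

* ``/``  separates allele-level ambiguity (``A*01:01/A*01:02``),
* ``+``  separates the two alleles of one genotype,
* ``|``  separates alternative whole-genotype explanations,
* ``^``  separates loci.

``A*01:01+A*02:01|A*01:02+A*02:02`` therefore means *exactly* those two
pairs, not the four-pair cross-product — which is precisely the distinction
that makes pair lists preferable to abbreviation codes.

Homozygotes are always written with explicit duplication
(``A*01:01+A*01:01``), never as a bare single allele, removing the
homozygote-versus-blank ambiguity.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from hlapop.errors import GenotypeParseError, UnknownCodeError
from hlapop.nomenclature import AlleleName, parse_allele_name


@dataclass(frozen=True)
class GenotypePair:
    """An unordered pair of alleles at one locus; {a,b} == {b,a}."""

    allele1: AlleleName
    allele2: AlleleName

    def __post_init__(self):
        if self.allele2.sort_key() < self.allele1.sort_key():
            a1, a2 = self.allele2, self.allele1
            object.__setattr__(self, "allele1", a1)
            object.__setattr__(self, "allele2", a2)

    @property
    def locus(self) -> str:
        return self.allele1.locus

    @property
    def homozygous(self) -> bool:
        return self.allele1 == self.allele2

    def alleles(self) -> tuple[AlleleName, AlleleName]:
        return (self.allele1, self.allele2)

    def serialize(self) -> str:
        return f"{self.allele1.serialize()}+{self.allele2.serialize()}"

    def sort_key(self):
        return (self.allele1.sort_key(), self.allele2.sort_key())

    def __str__(self):
        return self.serialize()


# a candidate explanation: one pair (single locus) or a tuple of per-locus pairs
Candidate = "GenotypePair | tuple[GenotypePair, ...]"


@dataclass
class AmbiguousGenotype:
    """One individual's typing at one or more loci: a non-empty, duplicate-free
    set of candidate genotype explanations."""

    individual_id: str
    locus_set: list[str]
    candidates: list
    source: str = "pair_list"  # pair_list | code_expansion | kit_interpretation | unambiguous

    def __post_init__(self):
        if not self.candidates:
            raise ValueError(f"individual {self.individual_id!r}: empty candidate set")
        seen, dedup = set(), []
        for c in self.candidates:
            if c not in seen:
                seen.add(c)
                dedup.append(c)
        self.candidates = dedup

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)

    @property
    def ambiguous(self) -> bool:
        return len(self.candidates) > 1

    def candidate_set(self) -> frozenset:
        return frozenset(self.candidates)

    def per_locus_pairs(self, c) -> tuple[GenotypePair, ...]:
        return c if isinstance(c, tuple) else (c,)

    def covered_loci(self, c) -> list[str]:
        return [p.locus for p in self.per_locus_pairs(c)]


@dataclass
class QuestionnaireMetadata:
    """Standardized population-sample metadata.

    Mirrors the population data questionnaire: type of study, population name
    and alternatives, geographic location as latitude/longitude, language and
    linguistic family, whether first-degree relatives were excluded (their
    inclusion biases frequency estimates and Hardy-Weinberg tests), an ethics
    statement, and the typing technique.
    """

    study_type: str = "anthropology_field"  # anthropology_field | registry | patients
    population_name: str = ""
    alternative_names: list[str] = field(default_factory=list)
    latitude: float | None = None
    longitude: float | None = None
    language: str = ""
    linguistic_family: str = ""
    first_degree_relatives_excluded: bool = True
    ethics_statement: str = ""
    typing_technique: str = ""
    n_individuals: int | None = None

    _STUDY_TYPES = ("anthropology_field", "registry", "patients")

    def violations(self, n_genotypes: int | None = None) -> list[str]:
        out = []
        if self.study_type not in self._STUDY_TYPES:
            out.append(f"unknown study_type {self.study_type!r}")
        if self.latitude is not None and not -90 <= self.latitude <= 90:
            out.append(f"latitude {self.latitude} outside [-90, 90]")
        if self.longitude is not None and not -180 <= self.longitude <= 180:
            out.append(f"longitude {self.longitude} outside [-180, 180]")
        if (
            self.n_individuals is not None
            and n_genotypes is not None
            and self.n_individuals != n_genotypes
        ):
            out.append(
                f"metadata n_individuals={self.n_individuals} but sample has "
                f"{n_genotypes} genotypes"
            )
        if not self.first_degree_relatives_excluded:
            out.append("first-degree relatives not excluded")
        return out


@dataclass
class PopulationSample:
    """Genotypes plus questionnaire metadata for one population sample."""

    genotypes: list[AmbiguousGenotype]
    metadata: QuestionnaireMetadata = field(default_factory=QuestionnaireMetadata)
    locus_set: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.locus_set and self.genotypes:
            self.locus_set = list(self.genotypes[0].locus_set)

    @property
    def n_individuals(self) -> int:
        return len(self.genotypes)

    def observed_alleles(self) -> list[AlleleName]:
        """Union of alleles appearing anywhere, including inside ambiguity
        sets, in first-appearance order."""
        seen, out = set(), []
        for g in self.genotypes:
            for c in g.candidates:
                for p in g.per_locus_pairs(c):
                    for a in p.alleles():
                        if a not in seen:
                            seen.add(a)
                            out.append(a)
        return out

    def ambiguity_fraction(self) -> float:
        if not self.genotypes:
            return 0.0
        return sum(g.ambiguous for g in self.genotypes) / len(self.genotypes)


# ---------------------------------------------------------------------------
# GL-string parsing / serialization


def _parse_side(side: str, text: str) -> list[AlleleName]:
    names = []
    for tok in side.split("/"):
        tok = tok.strip()
        if not tok:
            raise GenotypeParseError(f"empty allele segment in {text!r}")
        names.append(parse_allele_name(tok))
    return names


def _parse_locus_part(part: str, text: str) -> list[GenotypePair]:
    candidates: list[GenotypePair] = []
    for alt in part.split("|"):
        alt = alt.strip()
        if not alt:
            raise GenotypeParseError(f"empty genotype alternative in {text!r}")
        sides = alt.split("+")
        if len(sides) != 2:
            raise GenotypeParseError(
                f"genotype {alt!r} must have exactly two '+'-separated sides "
                f"(found {len(sides)})"
            )
        left, right = (_parse_side(s, text) for s in sides)
        for a, b in product(left, right):
            if a.locus != b.locus:
                raise GenotypeParseError(
                    f"mixed loci {a.locus}/{b.locus} inside one pair in {text!r}"
                )
            candidates.append(GenotypePair(a, b))
    loci = {p.locus for p in candidates}
    if len(loci) > 1:
        raise GenotypeParseError(
            f"mixed loci {sorted(loci)} inside one genotype in {text!r}"
        )
    seen, dedup = set(), []
    for p in candidates:
        if p not in seen:
            seen.add(p)
            dedup.append(p)
    return dedup


def parse_genotype_string(text: str, individual_id: str = "") -> AmbiguousGenotype:
    """Parse a genotype-list string into an :class:`AmbiguousGenotype`.

    The candidate set is the cross-product expansion of ``/`` lists within
    each ``+`` pair, unioned over ``|`` alternatives, de-duplicated.  With
    several ``^``-separated loci the candidates are tuples of per-locus pairs
    (the cross product across loci: GL strings cannot express cross-locus
    ambiguity coupling).
    """
    if not text or not text.strip():
        raise GenotypeParseError("empty genotype string")
    locus_parts = text.strip().split("^")
    per_locus = [_parse_locus_part(p, text) for p in locus_parts]
    loci = [pairs[0].locus for pairs in per_locus]
    if len(set(loci)) != len(loci):
        raise GenotypeParseError(f"duplicate locus among '^' segments in {text!r}")
    if len(per_locus) == 1:
        candidates: list = list(per_locus[0])
    else:
        candidates = [tuple(combo) for combo in product(*per_locus)]
    source = "pair_list" if len(candidates) > 1 else "unambiguous"
    return AmbiguousGenotype(
        individual_id=individual_id, locus_set=loci, candidates=candidates,
        source=source,
    )


def _try_factor(pairs: Sequence[GenotypePair]) -> str | None:
    """Return a '/'+'+' factored form iff its expansion equals the pair set."""
    pair_set = set(pairs)
    alleles = sorted(
        {a for p in pairs for a in p.alleles()}, key=lambda a: a.sort_key()
    )
    partners = {
        a: sorted(
            {
                (p.allele2 if p.allele1 == a else p.allele1)
                for p in pairs
                if a in p.alleles()
            },
            key=lambda x: x.sort_key(),
        )
        for a in alleles
    }
    p0 = pairs[0]
    for left_anchor, right_anchor in ((p0.allele1, p0.allele2), (p0.allele2, p0.allele1)):
        left = partners[right_anchor]
        right = partners[left_anchor]
        expansion = {GenotypePair(a, b) for a in left for b in right}
        if expansion == pair_set:
            return "/".join(a.serialize() for a in left) + "+" + "/".join(
                b.serialize() for b in right
            )
    return None


def serialize_genotype(g: AmbiguousGenotype, style: str = "pair_list") -> str:
    """Serialize to GL-string text.

    ``pair_list`` emits ``|``-separated explicit pairs (the recommended,
    always-lossless form).  ``factored`` emits a ``/``+``+`` factoring per
    locus only when its expansion equals the candidate set exactly, else it
    falls back to the pair list — a factored form must never add spurious
    pairs.
    """
    if style not in ("pair_list", "factored"):
        raise ValueError(f"unknown style {style!r}")
    n_loci = len(g.locus_set)
    per_locus: list[list[GenotypePair]] = [[] for _ in range(n_loci)]
    for c in g.candidates:
        for i, p in enumerate(g.per_locus_pairs(c)):
            if p not in per_locus[i]:
                per_locus[i].append(p)
    parts = []
    for pairs in per_locus:
        text = None
        if style == "factored":
            text = _try_factor(pairs)
        if text is None:
            text = "|".join(p.serialize() for p in pairs)
        parts.append(text)
    return "^".join(parts)


# ---------------------------------------------------------------------------
# Validation


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def to_text(self) -> str:
        if self.ok:
            return "OK: no violations\n"
        return "\n".join(f"VIOLATION: {v}" for v in self.violations) + "\n"

    def to_json(self) -> str:
        return json.dumps({"ok": self.ok, "violations": self.violations}, indent=2)


def validate_sample(
    s: PopulationSample,
    strict: bool = False,
    mac_table: "MacTable | None" = None,
) -> ValidationReport:
    """Check a sample against the reporting guidelines.

    Flags per-genotype violations (duplicate ids, locus mismatches, empty
    candidate sets, NMDP-style codes where an explicit pair list is required)
    and metadata violations.  Genotypic data should be complete and include
    all ambiguities as pair lists; abbreviation codes should be avoided.
    With ``strict=True`` a non-empty report raises ``ValueError``.
    """
    report = ValidationReport()
    seen_ids = set()
    for g in s.genotypes:
        if g.individual_id in seen_ids:
            report.violations.append(f"duplicate individual_id {g.individual_id!r}")
        seen_ids.add(g.individual_id)
        if not g.candidates:
            report.violations.append(f"{g.individual_id}: empty candidate set")
            continue
        for c in g.candidates:
            if g.covered_loci(c) != list(g.locus_set):
                report.violations.append(
                    f"{g.individual_id}: candidate {c} does not cover locus set "
                    f"{g.locus_set}"
                )
        if g.source == "code_expansion":
            report.violations.append(
                f"{g.individual_id}: NMDP code present; explicit pair lists "
                "should be provided instead"
            )
        if tuple(g.locus_set) != tuple(s.locus_set):
            report.violations.append(
                f"{g.individual_id}: locus set {g.locus_set} differs from "
                f"sample locus set {s.locus_set}"
            )
    report.violations.extend(s.metadata.violations(n_genotypes=s.n_individuals))
    if strict and not report.ok:
        raise ValueError("sample validation failed:\n" + report.to_text())
    return report


# ---------------------------------------------------------------------------
# File conversion (tabular <-> GL string)

DIALECTS = ("tabular", "glstring")


def read_sample(
    path,
    dialect: str,
    metadata: QuestionnaireMetadata | None = None,
    mac_table: "MacTable | None" = None,
) -> PopulationSample:
    """Read a sample file in the ``tabular`` (CSV/TSV ``id,locus,genotype``,
    one row per individual per locus) or ``glstring`` (``id<TAB>glstring``)
    dialect.  With ``mac_table`` given, simple ``x+y`` typings whose alleles
    end in an abbreviation code are expanded through :func:`expand_mac`."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    path = Path(path)

    def parse_one(text: str, ind: str) -> AmbiguousGenotype:
        if mac_table is not None and "|" not in text and "^" not in text:
            try:
                return parse_genotype_string(text, individual_id=ind)
            except (ValueError, GenotypeParseError):
                return expand_mac(text, mac_table, individual_id=ind)
        return parse_genotype_string(text, individual_id=ind)

    genotypes: list[AmbiguousGenotype] = []
    if dialect == "glstring":
        for ln, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                ind, gl = line.split("\t")
                genotypes.append(parse_one(gl, ind.strip()))
            except (ValueError, GenotypeParseError) as exc:
                raise GenotypeParseError(f"{path} line {ln}: {exc}") from exc
    else:
        with open(path, newline="") as fh:
            sniff = fh.read(4096)
            fh.seek(0)
            delim = "\t" if sniff.count("\t") >= sniff.count(",") else ","
            reader = csv.DictReader(fh, delimiter=delim)
            required = {"id", "locus", "genotype"}
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                raise GenotypeParseError(
                    f"{path}: tabular dialect requires columns id, locus, genotype"
                )
            per_ind: dict[str, dict[str, str]] = {}
            for ln, row in enumerate(reader, start=2):
                try:
                    per_ind.setdefault(row["id"], {})[row["locus"]] = row["genotype"]
                except KeyError as exc:
                    raise GenotypeParseError(f"{path} row {ln}: missing column {exc}") from exc
            for ind, by_locus in per_ind.items():
                gl = "^".join(by_locus[loc] for loc in by_locus)
                try:
                    genotypes.append(parse_one(gl, ind))
                except GenotypeParseError as exc:
                    raise GenotypeParseError(f"{path} individual {ind!r}: {exc}") from exc
    return PopulationSample(genotypes=genotypes, metadata=metadata or QuestionnaireMetadata())


def write_sample(s: PopulationSample, path, dialect: str, style: str = "pair_list") -> int:
    """Write a sample; returns the number of individuals written."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    path = Path(path)
    if dialect == "glstring":
        with open(path, "w") as fh:
            for g in s.genotypes:
                fh.write(f"{g.individual_id}\t{serialize_genotype(g, style)}\n")
    else:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "locus", "genotype"])
            for g in s.genotypes:
                text = serialize_genotype(g, style)
                for locus, part in zip(g.locus_set, text.split("^")):
                    writer.writerow([g.individual_id, locus, part])
    return s.n_individuals


def convert_format(path_in, dialect_in: str, path_out, dialect_out: str) -> int:
    """Loss-free file conversion between dialects; candidate sets are
    identical after a round trip.  Returns the number of individuals."""
    sample = read_sample(path_in, dialect_in)
    return write_sample(sample, path_out, dialect_out)


# ---------------------------------------------------------------------------
# NMDP-style abbreviation (multiple allele code) expansion


@dataclass
class MacTable:
    """Abbreviation-code table: code text -> list of field values it stands
    for.  Codes abbreviate second-field lists, e.g. ``XX -> [01, 02]`` turns
    ``A*01:XX`` into ``A*01:01/A*01:02``."""

    entries: dict[str, list[str]]

    def __post_init__(self):
        for code, values in self.entries.items():
            if not code or not values:
                raise ValueError(f"code {code!r} maps to an empty list")

    @classmethod
    def from_tsv(cls, path) -> "MacTable":
        entries = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            code, values = line.split("\t")
            entries[code.strip()] = [v.strip() for v in values.split(",")]
        return cls(entries)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for code in sorted(self.entries):
                fh.write(f"{code}\t{','.join(self.entries[code])}\n")


def _expand_coded_allele(tok: str, table: MacTable) -> list[AlleleName]:
    tok = tok.strip()
    star = tok.find("*")
    if star >= 0 and ":" in tok:
        prefix, last = tok.rsplit(":", 1)
        if last.isalpha():
            if last not in table.entries:
                raise UnknownCodeError(last)
            return [parse_allele_name(f"{prefix}:{v}") for v in table.entries[last]]
    return [parse_allele_name(tok)]


def expand_mac(text: str, table: MacTable, individual_id: str = "") -> AmbiguousGenotype:
    """Expand abbreviation codes in a single-locus typing.

    Each coded allele is replaced by its allele list and the candidate set is
    the full cross-product of the two sides.  This is exactly the artificial
    ambiguity inflation that per-chromosome code expansion produces — it is
    reproduced faithfully here so that :func:`count_spurious_pairs` can
    measure it against a true pair list.
    """
    sides = text.split("+")
    if len(sides) != 2:
        raise GenotypeParseError(
            f"typing {text!r} must have exactly two '+'-separated sides"
        )
    left, right = (
        [a for tok in side.split("/") for a in _expand_coded_allele(tok, table)]
        for side in sides
    )
    candidates = []
    for a, b in product(left, right):
        p = GenotypePair(a, b)
        if p not in candidates:
            candidates.append(p)
    return AmbiguousGenotype(
        individual_id=individual_id,
        locus_set=[candidates[0].locus],
        candidates=candidates,
        source="code_expansion",
    )


def count_spurious_pairs(reported: AmbiguousGenotype, expanded: AmbiguousGenotype) -> int:
    """Number of spurious allele pairs the code expansion added on top of the
    reported pair list: ``|expanded| - |reported|``.

    Raises ``ValueError`` if the reported candidates are not contained in the
    expansion (then the two do not describe the same typing).
    """
    rep, exp = reported.candidate_set(), expanded.candidate_set()
    if not rep <= exp:
        missing = sorted(str(c) for c in rep - exp)
        raise ValueError(
            "reported pair list is not contained in the code expansion; "
            "missing from expansion: " + ", ".join(missing)
        )
    return len(exp) - len(rep)
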