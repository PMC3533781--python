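"""HLA allele nomenclature: parsing, resolution recoding, common allele pools.

Modern HLA allele names have the shape ``LOCUS*F1:F2:F3:F4`` with one to four
colon-separated numeric fields (allele group, protein, synonymous, non-coding)
and an optional trailing expression suffix (``N`` null, ``L`` low, ``S``
secreted, ``C`` cytoplasmic, ``A`` aberrant, ``Q`` questionable).  The number
of fields present is the *resolution* of the typing.  Heterogeneous sample
collections mix resolutions, so comparing them requires recoding every sample
onto a common allele pool — the finest partition of the observed alleles that
no sample's reporting contradicts.

Serology-era names and G/P groups are out of scope; the grammar is strictly
``LOCUS*\\d+(:\\d+){0,3}[NLSCAQ]?``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

from hlapop.errors import (
    AlleleParseError,
    MappingError,
    NullAlleleMergeWarning,
    SuffixLossWarning,
)

EXPRESSION_SUFFIXES = frozenset("NLSCAQ")

_NAME_RE = re.compile(
    r"^(?P<locus>[A-Z][A-Z0-9]*)\*"
    r"(?P<fields>\d+(?::\d+){0,3})"
    r"(?P<suffix>[NLSCAQ]?)$"
)


@dataclass(frozen=True, order=False)
class AlleleName:
    """A structured HLA allele designation.

    ``fields`` holds the numeric field values; ``field_texts`` preserves the
    original digit strings so that serialization round-trips leading zeros
    exactly.  Comparison and hashing are numeric (``A*02`` == ``A*2``).
    """

    locus: str
    fields: tuple[int, ...]
    expression_suffix: str | None = None
    raw: str = ""
    field_texts: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.fields:
            raise ValueError("AlleleName requires at least one field")
        if not self.field_texts:
            object.__setattr__(
                self, "field_texts", tuple(f"{v:02d}" for v in self.fields)
            )

    @property
    def resolution(self) -> int:
        """Number of fields present (1 = allele group ... 4 = full)."""
        return len(self.fields)

    def serialize(self) -> str:
        """Exact original text if parsed, canonical text if constructed."""
        if self.raw:
            return self.raw
        text = f"{self.locus}*" + ":".join(self.field_texts)
        return text + (self.expression_suffix or "")

    def sort_key(self):
        return (self.locus, self.fields, self.expression_suffix or "")

    def __eq__(self, other):
        if not isinstance(other, AlleleName):
            return NotImplemented
        return self.sort_key() == other.sort_key()

    def __hash__(self):
        return hash(self.sort_key())

    def __lt__(self, other):
        return self.sort_key() < other.sort_key()

    def __str__(self):
        return self.serialize()

    def __repr__(self):
        return f"AlleleName({self.serialize()!r})"


def parse_allele_name(text: str) -> AlleleName:
    """Parse an HLA allele name such as ``DRB1*14:54`` or ``A*24:02:01:02L``.

    Raises :class:`AlleleParseError` naming the offending token and position
    on malformed input.
    """
    if not isinstance(text, str) or not text:
        raise AlleleParseError(str(text), 0, "empty allele name")
    stripped = text.strip()
    m = _NAME_RE.match(stripped)
    if m is None:
        star = stripped.find("*")
        if star < 0:
            raise AlleleParseError(text, 0, "missing '*' locus separator")
        locus = stripped[:star]
        if not re.match(r"^[A-Z][A-Z0-9]*$", locus):
            raise AlleleParseError(text, 0, f"invalid locus token {locus!r}")
        rest = stripped[star + 1:]
        pos = star + 1
        for tok in rest.split(":"):
            body = tok
            if body and body[-1] in EXPRESSION_SUFFIXES:
                body = body[:-1]
            if not body.isdigit():
                raise AlleleParseError(text, pos, f"invalid field token {tok!r}")
            pos += len(tok) + 1
        raise AlleleParseError(text, 0, "does not match LOCUS*F1(:F2(:F3(:F4)))[NLSCAQ]")
    field_texts = tuple(m.group("fields").split(":"))
    return AlleleName(
        locus=m.group("locus"),
        fields=tuple(int(t) for t in field_texts),
        expression_suffix=m.group("suffix") or None,
        raw=stripped,
        field_texts=field_texts,
    )


def reduce_resolution(a: AlleleName, level: int) -> AlleleName:
    """Truncate an allele name to at most ``level`` fields.

    Truncation to a level at or above the current resolution is the identity.
    When fields are actually dropped the expression suffix no longer applies
    to the truncated group and is removed; a :class:`SuffixLossWarning` is
    emitted, specialised to :class:`NullAlleleMergeWarning` when a null (N)
    allele is merged into an expressed-allele group.
    """
    if level < 1:
        raise ValueError(f"resolution level must be >= 1, got {level}")
    if level >= a.resolution:
        return a
    suffix = a.expression_suffix
    if suffix == "N":
        warnings.warn(
            f"null-expression allele {a.serialize()} merged into expressed "
            f"group {a.locus}*{':'.join(a.field_texts[:level])}",
            NullAlleleMergeWarning,
            stacklevel=2,
        )
    elif suffix:
        warnings.warn(
            f"expression suffix {suffix!r} lost truncating {a.serialize()} "
            f"to {level} field(s)",
            SuffixLossWarning,
            stacklevel=2,
        )
    return AlleleName(
        locus=a.locus,
        fields=a.fields[:level],
        expression_suffix=None,
        raw="",
        field_texts=a.field_texts[:level],
    )


@dataclass
class AlleleMapping:
    """A total allele substitution map (the *transliterate* operation).

    ``entries`` maps source allele text to target allele text.  A valid
    mapping is idempotent: every image allele maps to itself (entries for
    image alleles may be omitted; they are treated as identity).
    """

    entries: dict[str, str]
    description: str = ""

    def apply(self, name: AlleleName) -> AlleleName:
        target = self.entries.get(name.serialize())
        if target is None:
            # numeric-equality fallback: entry keys may differ in zero padding
            for k, v in self.entries.items():
                if parse_allele_name(k) == name:
                    target = v
                    break
        if target is None:
            raise MappingError([name.serialize()])
        return parse_allele_name(target)

    def check_idempotent(self) -> bool:
        for target in self.entries.values():
            image = self.entries.get(target, target)
            if parse_allele_name(image) != parse_allele_name(target):
                return False
        return True

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            if self.description:
                fh.write(f"# {self.description}\n")
            for src in sorted(self.entries, key=lambda t: parse_allele_name(t).sort_key()):
                fh.write(f"{src}\t{self.entries[src]}\n")

    @classmethod
    def from_tsv(cls, path) -> "AlleleMapping":
        entries, desc = {}, []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                if line.lstrip().startswith("#"):
                    desc.append(line.lstrip("# "))
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"mapping line must have 2 tab-separated columns: {line!r}")
                entries[parts[0].strip()] = parts[1].strip()
        return cls(entries=entries, description=" ".join(desc))

    @classmethod
    def first_field(cls, alleles: Iterable[AlleleName]) -> "AlleleMapping":
        """Recode every allele to its first-field (allele group) name."""
        entries = {}
        for a in alleles:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                entries[a.serialize()] = reduce_resolution(a, 1).serialize()
        return cls(entries=entries, description="first-field (allele group) recoding")


@dataclass
class NonPbrWarning:
    allele: AlleleName
    populations: str


@dataclass
class NonPbrWarningList:
    """Alleles distinguished only outside the peptide-binding sites that
    nonetheless reach significant frequencies in some populations, so merging
    them silently can bias population statistics."""

    entries: list[NonPbrWarning] = field(default_factory=list)

    def lookup(self, name: AlleleName) -> NonPbrWarning | None:
        for e in self.entries:
            if e.allele == name:
                return e
        return None


def load_non_pbr_warning_list() -> NonPbrWarningList:
    """Load the packaged list of non-PBR-distinguished alleles with
    significant population frequencies."""
    text = resources.files("hlapop").joinpath("data/non_pbr_alleles.tsv").read_text()
    entries = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        allele_text, populations = line.split("\t")
        entries.append(NonPbrWarning(parse_allele_name(allele_text), populations))
    return NonPbrWarningList(entries)


def flag_non_pbr_distinctions(
    alleles: Iterable[AlleleName],
    warning_list: NonPbrWarningList | None = None,
) -> list[NonPbrWarning]:
    """Return the warning-list entry for each input allele present in it."""
    if warning_list is None:
        warning_list = load_non_pbr_warning_list()
    hits = []
    for a in alleles:
        e = warning_list.lookup(a)
        if e is not None:
            hits.append(e)
    return hits


def transliterate_sample(sample, mapping: AlleleMapping):
    """Apply an allele substitution map to every allele occurrence in a
    population sample.

    Candidate pairs made identical by the merge are de-duplicated; the number
    of individuals is unchanged and no ambiguity set is ever emptied.  Raises
    :class:`MappingError` listing *all* unmapped alleles if the mapping is not
    total on the sample.
    """
    from hlapop.genotype_io import AmbiguousGenotype, GenotypePair, PopulationSample

    by_key = {}
    for k in mapping.entries:
        by_key[parse_allele_name(k)] = mapping.entries[k]

    unmapped = {a.serialize() for a in sample.observed_alleles() if a not in by_key}
    if unmapped:
        raise MappingError(unmapped)

    def image(name: AlleleName) -> AlleleName:
        return parse_allele_name(by_key[name])

    new_genotypes = []
    for g in sample.genotypes:
        new_candidates = []
        for cand in g.candidates:
            pairs = cand if isinstance(cand, tuple) else (cand,)
            imgs = [GenotypePair(image(p.allele1), image(p.allele2)) for p in pairs]
            new_candidates.append(tuple(imgs) if isinstance(cand, tuple) else imgs[0])
        # preserve order, drop duplicates created by merging
        seen, dedup = set(), []
        for c in new_candidates:
            if c not in seen:
                seen.add(c)
                dedup.append(c)
        new_genotypes.append(
            AmbiguousGenotype(
                individual_id=g.individual_id,
                locus_set=g.locus_set,
                candidates=dedup,
                source=g.source,
            )
        )
    return PopulationSample(
        genotypes=new_genotypes, metadata=sample.metadata, locus_set=sample.locus_set
    )


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _is_field_prefix(a: AlleleName, b: AlleleName) -> bool:
    """True if ``a`` names an allele group covering ``b`` (or vice versa)."""
    if a.locus != b.locus:
        return False
    short, long_ = (a, b) if a.resolution <= b.resolution else (b, a)
    return long_.fields[: short.resolution] == short.fields


def build_common_pool(samples) -> AlleleMapping:
    """Compute the common allele pool of several samples of one locus.

    Distinct samples typed with distinct techniques do not resolve the same
    allele splits; before any comparison the data must be recoded onto the
    finest partition of the union of observed alleles that no sample's
    reporting contradicts.  Two alleles fall in the same pool class whenever
    some sample reports a name covering both (a lower-resolution name is a
    prefix of the finer splits it fails to separate); classes are the
    transitive closure of that relation and each class is named by the
    longest common field prefix of its members.

    Returns an :class:`AlleleMapping` from every observed allele to its pool
    class name.
    """
    samples = list(samples)
    if len(samples) < 2:
        raise ValueError("common pool requires at least 2 samples")
    loci = {tuple(s.locus_set) for s in samples}
    if len(loci) != 1:
        raise ValueError(f"samples typed at different loci: {sorted(loci)}")

    observed: list[AlleleName] = []
    seen = set()
    for s in samples:
        for a in s.observed_alleles():
            if a not in seen:
                seen.add(a)
                observed.append(a)
    uf = _UnionFind(observed)
    for i, a in enumerate(observed):
        for b in observed[i + 1:]:
            if _is_field_prefix(a, b):
                uf.union(a, b)

    classes: dict[AlleleName, list[AlleleName]] = {}
    for a in observed:
        classes.setdefault(uf.find(a), []).append(a)

    entries = {}
    for members in classes.values():
        prefix = members[0].fields
        texts = members[0].field_texts
        for m in members[1:]:
            n = 0
            while n < min(len(prefix), m.resolution) and prefix[n] == m.fields[n]:
                n += 1
            prefix, texts = prefix[:n], texts[:n]
        pool_name = AlleleName(
            locus=members[0].locus, fields=prefix, field_texts=texts
        ).serialize()
        for m in members:
            entries[m.serialize()] = pool_name
    return AlleleMapping(
        entries=entries,
        description=f"common allele pool of {len(samples)} samples",
    )
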