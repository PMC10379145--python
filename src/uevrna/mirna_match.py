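"""miRNA identifier parsing and stem/arm-aware list matching.

Literature tables name miRNAs inconsistently: with or without the species
prefix (``hsa-``), with or without the mature-arm suffix (``-3p``/``-5p``),
and sometimes as compound (``miR-200 b/c-3p``) or family (``miR-30s
(family)``) notations. This module parses those strings into structured
identifiers and matches them across lists.

Two matching policies exist for stem-only identifiers (no arm suffix):

``"precursor"``
    A stem-only identifier denotes the immature (precursor) miRNA and matches
    only stem-level identifiers, never a specific mature arm. This is the
    convention used when curated lists are compared against each other.
``"either_arm"``
    A stem-only identifier matches either mature arm. Useful when searching
    count matrices that quantify mature arms only, where the precursor-level
    feature may not exist.

Arm-bearing identifiers always require equal arms under both policies, and
the species prefix is ignored whenever one side lacks it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Sequence

from .data_model import DataError, LiteratureMirnaRecord, ConcordanceRecord, MirnaParseError

__all__ = [
    "MirnaIdentifier",
    "MatchResult",
    "ConcordanceSummary",
    "parse_mirna_id",
    "ids_match",
    "intersect_lists",
    "direction_concordance",
    "load_family_table",
    "expand_records",
]

STEM_POLICIES = ("precursor", "either_arm")

_CORE_RE = re.compile(r"^(mir|let)-?(\d+[a-z]*(?:-\d+)?)(?:-(3p|5p))?\*?$")
_PREFIX_RE = re.compile(r"^([a-z]{2,4})-(?=(?:mir|let))")
_ALT_PIECE_RE = re.compile(r"^([a-z])(?:-(3p|5p))?$")


@dataclass(frozen=True)
class MirnaIdentifier:
    """A parsed miRNA name: optional species prefix, stem, optional arm.

    The stem keeps any numeric variant suffix (``let-7f-1`` in
    ``let-7f-1-3p``); the arm is ``"3p"``, ``"5p"`` or ``None`` (stem-only,
    i.e. the precursor).
    """

    raw: str
    species_prefix: str | None
    stem: str
    arm: str | None

    def __post_init__(self) -> None:
        if not self.stem:
            raise MirnaParseError(self.raw, "empty stem")
        if self.arm not in (None, "3p", "5p"):
            raise MirnaParseError(self.raw, f"bad arm {self.arm!r}")

    @property
    def stem_key(self) -> str:
        return self.stem.lower()

    @property
    def canonical(self) -> str:
        """Lowercase, prefix-free form; the arm is retained when present."""
        return self.stem_key + (f"-{self.arm}" if self.arm else "")

    def __str__(self) -> str:  # pragma: no cover
        return self.canonical


@lru_cache(maxsize=1)
def load_family_table() -> Mapping[str, tuple[str, ...]]:
    """Packaged, editable miRNA family table: label -> member stems."""
    text = resources.files("uevrna.fixtures").joinpath("mirna_families.tsv").read_text()
    table: dict[str, tuple[str, ...]] = {}
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        label, members = line.split("\t")
        table[label.strip().lower()] = tuple(m.strip() for m in members.split(","))
    return table


def _parse_single(cleaned: str, raw: str) -> MirnaIdentifier:
    s = cleaned
    if s and s[0].isdigit():  # e.g. "628-5p" printed without the miR prefix
        s = "mir-" + s
    prefix = None
    m = _PREFIX_RE.match(s)
    if m:
        prefix = m.group(1)
        s = s[m.end():]
    m = _CORE_RE.match(s)
    if m is None:
        raise MirnaParseError(raw)
    kind, number, arm = m.groups()
    stem = ("miR" if kind == "mir" else "let") + "-" + number
    return MirnaIdentifier(raw=raw, species_prefix=prefix, stem=stem, arm=arm)


def _expand_compound(cleaned: str, raw: str) -> list[MirnaIdentifier]:
    """Expand alternation notation: ``mir-200 b/c-3p`` -> miR-200b-3p, miR-200c-3p."""
    pieces = cleaned.replace(" ", "").split("/")
    first = _parse_single(pieces[0], raw)
    m = re.match(r"^(.*-\d+)([a-z]*)$", first.stem, flags=re.IGNORECASE)
    if m is None or not m.group(2):
        raise MirnaParseError(raw, "compound notation without a lettered first member")
    base, first_letter = m.group(1), m.group(2)
    letters = [first_letter]
    arms = {first.arm} - {None}
    for piece in pieces[1:]:
        pm = _ALT_PIECE_RE.match(piece)
        if pm is None:
            raise MirnaParseError(raw, f"bad alternation piece {piece!r}")
        letters.append(pm.group(1))
        if pm.group(2):
            arms.add(pm.group(2))
    if len(arms) > 1:
        raise MirnaParseError(raw, f"conflicting arms {sorted(arms)}")
    arm = arms.pop() if arms else None
    return [
        MirnaIdentifier(raw=raw, species_prefix=first.species_prefix, stem=base + letter, arm=arm)
        for letter in letters
    ]


def parse_mirna_id(
    raw: str, families: Mapping[str, tuple[str, ...]] | None = None
) -> list[MirnaIdentifier]:
    """Parse a miRNA name into one or more structured identifiers.

    Plain names yield a single identifier; compound alternations
    (``miR-200 b/c-3p``) and family notations (``miR-29a/b/c family``,
    ``miR-30s (family)``) yield one identifier per member. Parsing is
    case-insensitive and deterministic. Unparseable strings raise
    :class:`~uevrna.data_model.MirnaParseError` carrying the raw text.
    """
    if not raw or not raw.strip():
        raise MirnaParseError(raw, "empty string")
    if families is None:
        families = load_family_table()
    cleaned = " ".join(raw.strip().split()).lower()
    # family notations: look up the full label, then the label with the
    # "family" decoration stripped
    for candidate in (cleaned, re.sub(r"\s*\(family\)$|\s+family$", "", cleaned)):
        if candidate in families:
            return [ident for member in families[candidate] for ident in parse_mirna_id(member, families)]
    cleaned = re.sub(r"\s*\(family\)$|\s+family$", "", cleaned)
    if "/" in cleaned:
        return _expand_compound(cleaned, raw)
    return [_parse_single(cleaned, raw)]


def ids_match(a: MirnaIdentifier, b: MirnaIdentifier, stem_policy: str = "either_arm") -> bool:
    """Whether two parsed identifiers denote the same miRNA.

    Stems must be equal (case-insensitive); species prefixes are compared
    only when both sides carry one. Arm handling follows ``stem_policy``
    (see module docstring). Symmetric and reflexive.
    """
    if stem_policy not in STEM_POLICIES:
        raise ValueError(f"stem_policy must be one of {STEM_POLICIES}")
    if a.stem_key != b.stem_key:
        return False
    if a.species_prefix and b.species_prefix and a.species_prefix.lower() != b.species_prefix.lower():
        return False
    if stem_policy == "precursor":
        return a.arm == b.arm
    return a.arm == b.arm or a.arm is None or b.arm is None


@dataclass(frozen=True)
class MatchResult:
    """Cross-list miRNA matches.

    ``matched_identifiers`` holds canonical (lowercase, prefix-free) strings;
    for each matched pair the more specific member is reported (arm-bearing
    over stem-only), and stem-only and arm-bearing forms remain distinct
    entries after deduplication.
    """

    pairs: tuple[tuple[MirnaIdentifier, MirnaIdentifier], ...]
    matched_identifiers: frozenset[str]
    unmatched_a: frozenset[str]
    unmatched_b: frozenset[str]


def expand_records(
    records: Sequence[LiteratureMirnaRecord],
    families: Mapping[str, tuple[str, ...]] | None = None,
) -> list[tuple[LiteratureMirnaRecord, MirnaIdentifier]]:
    """Parse and expand every record's identifier, keeping record provenance."""
    out: list[tuple[LiteratureMirnaRecord, MirnaIdentifier]] = []
    for record in records:
        for ident in parse_mirna_id(record.mirna_id_raw, families):
            out.append((record, ident))
    return out


def _more_specific(a: MirnaIdentifier, b: MirnaIdentifier) -> MirnaIdentifier:
    if a.arm and not b.arm:
        return a
    if b.arm and not a.arm:
        return b
    return a


def intersect_lists(
    list_a: Sequence[LiteratureMirnaRecord],
    list_b: Sequence[LiteratureMirnaRecord],
    stem_policy: str = "precursor",
    families: Mapping[str, tuple[str, ...]] | None = None,
) -> MatchResult:
    """All cross-list matches between two literature miRNA lists.

    Compound and family notations are expanded before matching. The default
    ``"precursor"`` policy treats stem-only identifiers as precursor-level
    names that do not match specific mature arms; pass
    ``stem_policy="either_arm"`` for the looser convention.
    """
    expanded_a = expand_records(list_a, families)
    expanded_b = expand_records(list_b, families)
    pairs: list[tuple[MirnaIdentifier, MirnaIdentifier]] = []
    matched: set[str] = set()
    hit_a: set[int] = set()
    hit_b: set[int] = set()
    for i, (_, ida) in enumerate(expanded_a):
        for j, (_, idb) in enumerate(expanded_b):
            if ids_match(ida, idb, stem_policy=stem_policy):
                pairs.append((ida, idb))
                matched.add(_more_specific(ida, idb).canonical)
                hit_a.add(i)
                hit_b.add(j)
    unmatched_a = frozenset(ida.canonical for i, (_, ida) in enumerate(expanded_a) if i not in hit_a)
    unmatched_b = frozenset(idb.canonical for j, (_, idb) in enumerate(expanded_b) if j not in hit_b)
    return MatchResult(
        pairs=tuple(pairs),
        matched_identifiers=frozenset(matched),
        unmatched_a=unmatched_a,
        unmatched_b=unmatched_b,
    )


@dataclass(frozen=True)
class ConcordanceSummary:
    n_concordant: int
    n_discordant: int
    discordant_ids: tuple[str, ...]


def direction_concordance(records: Sequence[ConcordanceRecord]) -> ConcordanceSummary:
    """Count miRNAs whose study and literature directions of change agree."""
    discordant = []
    n_concordant = 0
    for record in records:
        if not record.direction_study or not record.direction_literature:
            raise DataError(f"record {record.mirna_id} lacks a direction")
        if record.direction_study == record.direction_literature:
            n_concordant += 1
        else:
            discordant.append(record.mirna_id)
    return ConcordanceSummary(
        n_concordant=n_concordant,
        n_discordant=len(discordant),
        discordant_ids=tuple(discordant),
    )
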