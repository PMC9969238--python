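"""Core domain objects: sequence records, reference libraries, ranks.

A reference library joins each barcode sequence to its taxonomy (species,
genus, subfamily, family), its sequence-cluster id (BIN), and collection
metadata (country, coordinates, habitat, life stage).  Every downstream
analysis — distance summaries, threshold optimization, grading, audits —
consumes a :class:`ReferenceLibrary`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Iterable, Iterator, Optional

IUPAC_NUCLEOTIDES = frozenset("ACGTRYSWKMBDHVN-")
HABITATS = ("lentic", "lotic", "unknown")
LIFE_STAGES = ("larva", "pupa", "adult_male", "adult_female", "exuviae", "unknown")

#: Tokens that mark a provisional / coded species label rather than a
#: described Latin binomial ("Cricotopus sp. TP1", "Tanytarsus cf. gregarius").
CODED_NAME_TOKENS = frozenset({"sp", "sp.", "cf.", "cf", "nr.", "nr", "aff.", "aff"})


class Rank(IntEnum):
    """Identification resolution, ordered coarse to fine."""

    NONE = 0
    FAMILY = 1
    SUBFAMILY = 2
    GENUS = 3
    SPECIES = 4


@dataclass
class SequenceRecord:
    record_id: str
    sequence: str
    species_name: str = ""
    genus: str = ""
    subfamily: str = ""
    family: str = ""
    bin_id: str = ""
    country: str = ""
    habitat: str = "unknown"
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    life_stage: str = "unknown"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"record {self.record_id!r}: empty sequence")
        bad = set(self.sequence) - IUPAC_NUCLEOTIDES
        if bad:
            raise ValueError(
                f"record {self.record_id!r}: non-IUPAC characters {sorted(bad)}"
            )
        if self.habitat not in HABITATS:
            self.habitat = "unknown"
        if self.life_stage not in LIFE_STAGES:
            self.life_stage = "unknown"

    @property
    def ungapped(self) -> str:
        return self.sequence.replace("-", "")

    def copy(self, **changes) -> "SequenceRecord":
        return replace(self, **changes)


def is_strict_binomial(name: str) -> bool:
    """True for a two-token Latin binomial with no coded-name markers.

    Coded names ("Chironomus sp. TP3"), open nomenclature qualifiers
    ("cf.", "nr.", "aff.") and tokens containing digits all fail.
    """
    tokens = name.split()
    if len(tokens) != 2:
        return False
    for tok in tokens:
        if tok.lower() in CODED_NAME_TOKENS:
            return False
        if any(ch.isdigit() for ch in tok):
            return False
    return tokens[0][0].isupper() and tokens[0].isalpha() and tokens[1].isalpha()


def identification_rank(record: SequenceRecord, mode: str = "strict_public") -> Rank:
    """Finest taxonomic rank at which a record is identified.

    ``strict_public``: only a described Latin binomial counts as species
    level (public-database audit semantics).  ``permissive_local``: any
    non-empty species label, including coded provisional names, counts as a
    species-level hypothesis (within-library semantics, where coded names
    are distinct, stable taxa).
    """
    if mode not in ("strict_public", "permissive_local"):
        raise ValueError(f"unknown rank mode {mode!r}")
    name = record.species_name.strip()
    if name:
        if mode == "permissive_local" or is_strict_binomial(name):
            return Rank.SPECIES
    genus = record.genus.strip()
    if not genus and name:
        # derive genus from a coded name's leading capitalized token
        head = name.split()[0]
        if head[0].isupper() and head.isalpha():
            genus = head
    if genus:
        return Rank.GENUS
    if record.subfamily.strip():
        return Rank.SUBFAMILY
    if record.family.strip():
        return Rank.FAMILY
    return Rank.NONE


@dataclass
class ReferenceLibrary:
    """An ordered collection of barcode records with unique ids."""

    records: list[SequenceRecord] = field(default_factory=list)
    source_label: str = ""
    retrieval_date: Optional[str] = None

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dups = sorted({i for i in ids if i in seen or seen.add(i)})
            raise ValueError(f"duplicate record ids: {dups}")
        self._check_genus_consistency()

    def _check_genus_consistency(self) -> None:
        by_species: dict[str, set[str]] = {}
        for r in self.records:
            if r.species_name and r.genus:
                by_species.setdefault(r.species_name.lower(), set()).add(r.genus)
        for sp, genera in by_species.items():
            if len(genera) > 1:
                warnings.warn(
                    f"species {sp!r} appears under multiple genera: {sorted(genera)}",
                    stacklevel=3,
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, key):
        if isinstance(key, str):
            for r in self.records:
                if r.record_id == key:
                    return r
            raise KeyError(key)
        return self.records[key]

    @property
    def record_ids(self) -> list[str]:
        return [r.record_id for r in self.records]

    def species_labels(self, mode: str = "permissive_local") -> list[str]:
        """Per-record species label; empty string where the record has no
        usable species-level name under the given mode."""
        out = []
        for r in self.records:
            if identification_rank(r, mode) == Rank.SPECIES:
                out.append(r.species_name.strip())
            else:
                out.append("")
        return out

    def subset(self, ids: Iterable[str]) -> "ReferenceLibrary":
        wanted = set(ids)
        return ReferenceLibrary(
            records=[r for r in self.records if r.record_id in wanted],
            source_label=self.source_label,
            retrieval_date=self.retrieval_date,
        )
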