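"""Reading and writing barcode libraries: FASTA, specimen tables, QC.

Sequences arrive as FASTA; specimen metadata arrives as a tab-separated
table in BOLD-style columns (``processid``, ``species_name``, ``bin_uri``,
...).  The two are merged on record id into a :class:`ReferenceLibrary`.
Quality control screens for minimum length, ambiguous-base content, and
in-frame stop codons under the invertebrate mitochondrial genetic code.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .records import ReferenceLibrary, SequenceRecord

logger = logging.getLogger(__name__)

#: Default column mapping for BOLD-style specimen TSV files.
DEFAULT_DIALECT: dict[str, str] = {
    "record_id": "processid",
    "species_name": "species_name",
    "genus": "genus_name",
    "subfamily": "subfamily_name",
    "family": "family_name",
    "bin_id": "bin_uri",
    "country": "country",
    "latitude": "lat",
    "longitude": "lon",
    "habitat": "habitat",
    "life_stage": "life_stage",
}

#: Stop codons of the invertebrate mitochondrial code (NCBI table 5).
MITO_STOP_CODONS = frozenset({"TAA", "TAG"})


class FastaParseError(ValueError):
    pass


def read_fasta(path) -> list[tuple[str, str]]:
    """Parse a FASTA file into ``(record_id, sequence)`` pairs.

    The record id is the header token before the first whitespace;
    sequences are uppercased with wrapped lines concatenated.  Sequence
    data before any header is a parse error reported with its line number.
    """
    entries: list[tuple[str, str]] = []
    current_id: Optional[str] = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if current_id is not None:
                    entries.append((current_id, "".join(chunks)))
                header = line[1:].strip()
                if not header:
                    raise FastaParseError(f"{path}: empty FASTA header at line {lineno}")
                current_id = header.split()[0]
                chunks = []
            else:
                if current_id is None:
                    raise FastaParseError(
                        f"{path}: sequence data before first header at line {lineno}"
                    )
                chunks.append(line.upper())
    if current_id is not None:
        entries.append((current_id, "".join(chunks)))
    if not entries:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return entries


def write_fasta(path, entries: Sequence[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in entries:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_specimen_table(path, dialect: Optional[Mapping[str, str]] = None) -> dict[str, dict]:
    """Read a tab-separated specimen-metadata table keyed by record id.

    ``dialect`` maps internal field names to column names in the file;
    unmapped columns are preserved under an ``extras`` key.  Missing
    optional columns become empty strings / unknowns.
    """
    colmap = dict(DEFAULT_DIALECT)
    if dialect:
        colmap.update(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    id_col = colmap["record_id"]
    if id_col not in df.columns:
        raise ValueError(f"{path}: missing id column {id_col!r}")
    dup = df[id_col][df[id_col].duplicated()].tolist()
    if dup:
        raise ValueError(f"{path}: duplicated record ids: {sorted(set(dup))}")

    known_cols = set(colmap.values())
    rows: dict[str, dict] = {}
    for _, row in df.iterrows():
        meta: dict = {}
        for fieldname, col in colmap.items():
            if fieldname == "record_id":
                continue
            meta[fieldname] = row[col].strip() if col in df.columns else ""
        for numfield in ("latitude", "longitude"):
            val = meta.get(numfield, "")
            try:
                meta[numfield] = float(val) if val != "" else None
            except ValueError:
                meta[numfield] = None
        if not meta.get("habitat"):
            meta["habitat"] = "unknown"
        if not meta.get("life_stage"):
            meta["life_stage"] = "unknown"
        meta["extras"] = {c: row[c] for c in df.columns if c not in known_cols}
        rows[row[id_col].strip()] = meta
    return rows


def merge_metadata(
    sequences: Sequence[tuple[str, str]],
    metadata: Mapping[str, dict],
    source_label: str = "",
) -> ReferenceLibrary:
    """Join sequences to metadata rows on record id.

    Sequence-only records are kept with empty metadata (warned); rows of
    metadata without a sequence are dropped (warned) — a specimen without
    a barcode contributes nothing to a barcode library.
    """
    records = []
    missing_meta = []
    for rid, seq in sequences:
        meta = metadata.get(rid)
        if meta is None:
            missing_meta.append(rid)
            records.append(SequenceRecord(record_id=rid, sequence=seq))
        else:
            fields = {k: v for k, v in meta.items() if k != "extras"}
            records.append(SequenceRecord(record_id=rid, sequence=seq, **fields))
    if missing_meta:
        warnings.warn(
            f"{len(missing_meta)} sequence(s) without metadata kept with empty "
            f"taxonomy: {missing_meta[:5]}{'...' if len(missing_meta) > 5 else ''}",
            stacklevel=2,
        )
    orphan = sorted(set(metadata) - {rid for rid, _ in sequences})
    if orphan:
        warnings.warn(
            f"{len(orphan)} metadata row(s) without sequence dropped",
            stacklevel=2,
        )
    return ReferenceLibrary(records=records, source_label=source_label)


def find_reading_frame_and_stops(sequence: str, genetic_code: int = 5) -> tuple[int, int]:
    """Best forward reading frame and its stop-codon count.

    Translates the three forward frames under the invertebrate
    mitochondrial code (stops TAA and TAG only) and returns the frame with
    the fewest stop codons, ties broken to the lowest frame index.  Codons
    containing gaps or ambiguity characters are skipped.  Protein-coding
    barcodes in the correct frame have zero stops; any stop in the best
    frame flags a likely pseudogene, contaminant, or frameshift.
    """
    if genetic_code != 5:
        raise NotImplementedError("only the invertebrate mitochondrial code (5) is supported")
    seq = sequence.upper().replace("-", "")
    if len(seq) < 3:
        raise ValueError("sequence shorter than 3 ungapped bases")
    best = (0, len(seq))  # (frame, stop count)
    for frame in range(3):
        stops = 0
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if set(codon) <= {"A", "C", "G", "T"} and codon in MITO_STOP_CODONS:
                stops += 1
        if stops < best[1]:
            best = (frame, stops)
    return best


@dataclass
class QCReport:
    """Per-record QC status and the parameters that produced it.

    Statuses partition the input library: ``pass``, ``too_short``,
    ``too_ambiguous``, ``stop_codon`` (first failing check wins, in that
    order).
    """

    min_length: int
    max_ambiguous_fraction: float
    status: dict[str, str] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        out = {"pass": 0, "too_short": 0, "too_ambiguous": 0, "stop_codon": 0}
        for s in self.status.values():
            out[s] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"record_id": list(self.status), "status": list(self.status.values())}
        )

    def write(self, tsv_path, json_path=None) -> None:
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            summary = {
                "min_length": self.min_length,
                "max_ambiguous_fraction": self.max_ambiguous_fraction,
                "counts": self.counts,
            }
            Path(json_path).write_text(json.dumps(summary, indent=2) + "\n")


def qc_filter(
    library: ReferenceLibrary,
    min_length: int = 500,
    max_ambiguous_fraction: float = 0.01,
) -> tuple[ReferenceLibrary, QCReport]:
    """Screen a library for barcode compliance.

    Checks, in order: ungapped length >= ``min_length``; fraction of
    non-ACGT characters <= ``max_ambiguous_fraction``; zero stop codons in
    the best forward reading frame.  The first failing check is recorded.
    """
    report = QCReport(min_length=min_length, max_ambiguous_fraction=max_ambiguous_fraction)
    kept = []
    for rec in library:
        seq = rec.ungapped
        if len(seq) < min_length:
            report.status[rec.record_id] = "too_short"
            continue
        ambiguous = sum(1 for c in seq if c not in "ACGT")
        if ambiguous / len(seq) > max_ambiguous_fraction:
            report.status[rec.record_id] = "too_ambiguous"
            continue
        _, stops = find_reading_frame_and_stops(seq)
        if stops > 0:
            report.status[rec.record_id] = "stop_codon"
            continue
        report.status[rec.record_id] = "pass"
        kept.append(rec)
    filtered = ReferenceLibrary(
        records=kept, source_label=library.source_label,
        retrieval_date=library.retrieval_date,
    )
    return filtered, report


@dataclass
class HaplotypeGroup:
    representative: str
    members: list[str]

    @property
    def size(self) -> int:
        return len(self.members)


def collapse_haplotypes(library: ReferenceLibrary) -> list[HaplotypeGroup]:
    """Group records whose gap-stripped sequences are identical strings.

    The representative is the lexicographically smallest member id.
    Dereplication to haplotypes is the standard preparation for querying
    a library against an external database: identical sequences carry no
    extra information.
    """
    groups: dict[str, list[str]] = {}
    for rec in library:
        groups.setdefault(rec.ungapped, []).append(rec.record_id)
    out = [
        HaplotypeGroup(representative=min(ids), members=sorted(ids))
        for ids in groups.values()
    ]
    out.sort(key=lambda g: g.representative)
    return out
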