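"""Top-hit identity identification against a reference library.

Each query is aligned to every reference sequence with a global aligner
whose terminal gaps are free (semiglobal / overlap alignment), so
partial barcodes align to their containing region without penalty.
Identity is exact matches over alignment columns, terminal-gap columns
excluded, internal-gap columns counted as mismatches.  The query takes
the taxonomy of its single best hit; the assignment is scored at a rank
(species / genus / subfamily) across an identity-threshold sweep:
below-threshold hits are *unmatched*, hits lacking a name at the rank
are *insufficient*, otherwise *correct* or *incorrect* against the
query's own taxonomy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .records import ReferenceLibrary, SequenceRecord, is_strict_binomial

logger = logging.getLogger(__name__)

RANKS = ("species", "genus", "subfamily")
#: Default identity grid, percent.
DEFAULT_IDENTITY_GRID = tuple(range(85, 101))

DEFAULT_SCORING = {
    "match": 2.0,
    "mismatch": -3.0,
    "gap_open": -5.0,
    "gap_extend": -2.0,
}


@dataclass(frozen=True)
class TopHit:
    query_id: str
    hit_id: Optional[str]
    identity: float  # percent, 0..100
    aligned_columns: int
    hit_species: str = ""
    hit_genus: str = ""
    hit_subfamily: str = ""


def _make_aligner(scoring: Optional[dict] = None) -> Align.PairwiseAligner:
    s = dict(DEFAULT_SCORING)
    if scoring:
        s.update(scoring)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = s["match"]
    aligner.mismatch_score = s["mismatch"]
    aligner.open_gap_score = s["gap_open"]
    aligner.extend_gap_score = s["gap_extend"]
    # free terminal gaps on both sequences (overlap alignment)
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def overlap_align_identity(
    query_seq: str, ref_seq: str, scoring: Optional[dict] = None,
    aligner: Optional[Align.PairwiseAligner] = None,
) -> tuple[float, int]:
    """Percent identity and aligned-column count for one pair.

    Columns run from the first to the last position where both sequences
    are aligned (terminal overhangs excluded); internal gap columns count
    as mismatches.
    """
    if not query_seq or not ref_seq:
        raise ValueError("sequences must be non-empty")
    if aligner is None:
        aligner = _make_aligner(scoring)
    aln = aligner.align(query_seq.upper(), ref_seq.upper())[0]
    coords = aln.coordinates  # shape (2, k): target (query_seq) then query (ref_seq)
    t, q = coords[0], coords[1]
    segs = []
    for k in range(coords.shape[1] - 1):
        dt, dq = int(t[k + 1] - t[k]), int(q[k + 1] - q[k])
        segs.append((int(t[k]), int(q[k]), dt, dq))
    # drop terminal overhangs (segments where only one sequence advances)
    while segs and (segs[0][2] == 0 or segs[0][3] == 0):
        segs.pop(0)
    while segs and (segs[-1][2] == 0 or segs[-1][3] == 0):
        segs.pop()
    columns = 0
    matches = 0
    a, b = query_seq.upper(), ref_seq.upper()
    for t0, q0, dt, dq in segs:
        if dt and dq:  # aligned block
            columns += dt
            matches += sum(1 for x, y in zip(a[t0 : t0 + dt], b[q0 : q0 + dq]) if x == y)
        else:  # internal gap: columns, all mismatch
            columns += max(dt, dq)
    if columns == 0:
        return 0.0, 0
    return 100.0 * matches / columns, columns


def top_hit(
    query: SequenceRecord | tuple[str, str],
    reference: ReferenceLibrary,
    scoring: Optional[dict] = None,
    aligner: Optional[Align.PairwiseAligner] = None,
) -> TopHit:
    """Best reference hit for a query by percent identity.

    A reference record with the query's own record_id is skipped
    (self-match guard).  Ties are broken toward more aligned columns,
    then the lexicographically smaller hit id.
    """
    if isinstance(query, SequenceRecord):
        qid, qseq = query.record_id, query.ungapped
    else:
        qid, qseq = query
    if len(reference) == 0:
        raise ValueError("empty reference library")
    if aligner is None:
        aligner = _make_aligner(scoring)
    best: Optional[tuple[float, int, str, SequenceRecord]] = None
    for ref in reference:
        if ref.record_id == qid:
            continue
        ident, cols = overlap_align_identity(qseq, ref.ungapped, aligner=aligner)
        key = (-ident, -cols, ref.record_id)
        if best is None or key < best[0]:
            best = (key, ident, cols, ref)
    if best is None:
        raise ValueError("reference library holds only the query itself")
    _, ident, cols, ref = best
    return TopHit(
        query_id=qid,
        hit_id=ref.record_id,
        identity=ident,
        aligned_columns=cols,
        hit_species=ref.species_name.strip(),
        hit_genus=ref.genus.strip(),
        hit_subfamily=ref.subfamily.strip(),
    )


def _taxon_at(species: str, genus: str, subfamily: str, rank: str) -> str:
    if rank == "species":
        return species
    if rank == "genus":
        if genus:
            return genus
        # fall back to the leading token of a binomial or coded name
        head = species.split()[0] if species else ""
        return head if head[:1].isupper() and head.isalpha() else ""
    if rank == "subfamily":
        return subfamily
    raise ValueError(f"unknown rank {rank!r}")


def classify_outcome(
    hit: TopHit,
    truth: tuple[str, str, str],
    rank: str,
    threshold: float,
) -> str:
    """Score a top hit at one rank and identity threshold.

    ``truth`` is the query's (species, genus, subfamily).  Returns one of
    ``unmatched`` (identity below threshold), ``insufficient`` (hit lacks
    a usable name at the rank), ``correct`` or ``incorrect``.  At species
    rank only described binomials on the hit side count as usable names —
    a hit labelled with a coded or absent species name cannot identify a
    query to species level.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    if hit.hit_id is None or hit.identity < threshold:
        return "unmatched"
    hit_name = _taxon_at(hit.hit_species, hit.hit_genus, hit.hit_subfamily, rank)
    if rank == "species" and hit_name and not is_strict_binomial(hit_name):
        hit_name = ""
    if not hit_name:
        return "insufficient"
    true_name = _taxon_at(*truth, rank)
    if not true_name:
        return "insufficient"
    return "correct" if hit_name.lower() == true_name.lower() else "incorrect"


def threshold_sweep(
    queries: Sequence[SequenceRecord],
    reference: ReferenceLibrary,
    grid: Sequence[float] = DEFAULT_IDENTITY_GRID,
    ranks: Sequence[str] = RANKS,
    scoring: Optional[dict] = None,
) -> tuple[pd.DataFrame, list[TopHit]]:
    """Outcome curve over an identity-threshold grid at multiple ranks.

    Computes one top hit per query, then classifies it at every
    (threshold, rank).  Returns the curve table — per (threshold, rank):
    matched count, correct/incorrect/insufficient counts and their
    proportions of matched — together with the per-query hits.  Queries
    are typically haplotype representatives (one per unique sequence).
    """
    aligner = _make_aligner(scoring)
    hits = [top_hit(q, reference, aligner=aligner) for q in queries]
    truths = [
        (q.species_name.strip(), q.genus.strip(), q.subfamily.strip()) for q in queries
    ]
    rows = []
    for t in grid:
        for rank in ranks:
            cats = [classify_outcome(h, tr, rank, t) for h, tr in zip(hits, truths)]
            arr = np.asarray(cats, dtype=object)
            matched = int((arr != "unmatched").sum())
            row = {
                "threshold": float(t),
                "rank": rank,
                "n_queries": len(queries),
                "matched": matched,
            }
            for cat in ("correct", "incorrect", "insufficient"):
                c = int((arr == cat).sum())
                row[cat] = c
                row[f"prop_{cat}"] = c / matched if matched else np.nan
            rows.append(row)
    return pd.DataFrame(rows), hits


def hits_to_frame(hits: Sequence[TopHit]) -> pd.DataFrame:
    return pd.DataFrame([h.__dict__ for h in hits])
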