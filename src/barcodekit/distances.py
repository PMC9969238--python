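"""Kimura two-parameter (K2P/K80) distances and barcode-gap summaries.

The K2P model distinguishes transitions (A<->G, C<->T) from transversions.
With P and Q the observed proportions of transition and transversion
differences over compared sites, the distance estimate is

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

in substitutions per site.  Sites are compared under pairwise deletion:
only positions where both sequences carry an unambiguous base (A/C/G/T)
contribute.  Pairs with too few shared sites, or where the estimator
saturates (the logarithm argument is non-positive), carry an undefined
distance; undefined entries are masked, excluded from summaries, and
treated as infinitely distant in nearest-neighbor searches.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import ReferenceLibrary

logger = logging.getLogger(__name__)

# byte codes for vectorized comparison
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


@dataclass(frozen=True)
class PairwiseSiteCounts:
    """Shared-site, transition and transversion counts for one pair."""

    n_sites: int
    n_transitions: int
    n_transversions: int

    def __post_init__(self):
        if self.n_transitions + self.n_transversions > self.n_sites:
            raise ValueError("differing sites exceed compared sites")


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def count_site_patterns(seq_a: str, seq_b: str) -> PairwiseSiteCounts:
    """Count compared sites, transitions and transversions (pairwise deletion).

    Sequences must be equal length (positionally aligned); sites where
    either character is a gap or an ambiguity code are excluded.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"sequence lengths differ ({len(seq_a)} vs {len(seq_b)}); "
            "align sequences before computing distances"
        )
    a = _encode(seq_a.upper())
    b = _encode(seq_b.upper())
    both = (a != 255) & (b != 255)
    n = int(both.sum())
    diff = both & (a != b)
    # codes: A=0, C=1, G=2, T=3 -> transition iff both purine (0,2) or both
    # pyrimidine (1,3), i.e. same parity
    ts = int((diff & ((a % 2) == (b % 2))).sum())
    tv = int(diff.sum()) - ts
    return PairwiseSiteCounts(n_sites=n, n_transitions=ts, n_transversions=tv)


def k2p_from_counts(
    counts: PairwiseSiteCounts, min_overlap: int = 100
) -> Optional[float]:
    """K2P distance in substitutions/site, or None when undefined.

    Undefined when fewer than ``min_overlap`` sites were compared, or at
    saturation (1 - 2P - Q <= 0 or 1 - 2Q <= 0).
    """
    if counts.n_sites < min_overlap:
        return None
    p = counts.n_transitions / counts.n_sites
    q = counts.n_transversions / counts.n_sites
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return None
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise K2P distances with an undefined-entry mask.

    ``values`` holds substitutions/site (convert with :meth:`percent`);
    undefined entries hold NaN and are False in ``defined``.
    """

    labels: list[str]
    values: np.ndarray
    defined: np.ndarray
    min_overlap: int = 100
    #: per-pair count of compared (pairwise-deleted) sites; None when unknown
    overlap: Optional[np.ndarray] = None

    def __post_init__(self):
        n = len(self.labels)
        assert self.values.shape == (n, n) and self.defined.shape == (n, n)

    def __len__(self) -> int:
        return len(self.labels)

    def percent(self) -> np.ndarray:
        return self.values * 100.0

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(
            labels=list(labels),
            values=self.values[np.ix_(idx, idx)],
            defined=self.defined[np.ix_(idx, idx)],
            min_overlap=self.min_overlap,
            overlap=(
                self.overlap[np.ix_(idx, idx)] if self.overlap is not None else None
            ),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_square_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="record_id")

    def write_long_tsv(self, path) -> None:
        rows = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append(
                    {
                        "id1": self.labels[i],
                        "id2": self.labels[j],
                        "n_sites": (
                            int(self.overlap[i, j]) if self.overlap is not None else -1
                        ),
                        "distance": self.values[i, j],
                        "defined": bool(self.defined[i, j]),
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def distance_matrix(
    library: ReferenceLibrary, min_overlap: int = 100
) -> DistanceMatrix:
    """All-pairs K2P distance matrix for a library (pairwise deletion).

    Requires at least two records.  Sequences must share a common aligned
    length; COI barcodes are length-conserved, so trimmed barcodes compare
    positionally.  Ragged libraries are right-padded with gaps, which
    pairwise deletion then ignores.
    """
    if len(library) < 2:
        raise ValueError("distance matrix requires at least 2 records")
    seqs = [r.sequence for r in library]
    width = max(len(s) for s in seqs)
    enc = np.vstack([_encode(s.ljust(width, "-")) for s in seqs])
    n = len(seqs)
    values = np.zeros((n, n))
    defined = np.ones((n, n), dtype=bool)
    overlap = np.zeros((n, n), dtype=int)
    valid = enc != 255
    parity = enc % 2
    n_undefined = 0
    for i in range(n):
        vi, pi, ei = valid[i], parity[i], enc[i]
        for j in range(i + 1, n):
            both = vi & valid[j]
            m = int(both.sum())
            overlap[i, j] = overlap[j, i] = m
            d: Optional[float]
            if m < min_overlap:
                d = None
            else:
                diff = both & (ei != enc[j])
                ts = int((diff & (pi == parity[j])).sum())
                tv = int(diff.sum()) - ts
                p = ts / m
                q = tv / m
                w1 = 1.0 - 2.0 * p - q
                w2 = 1.0 - 2.0 * q
                d = None if (w1 <= 0 or w2 <= 0) else -0.5 * np.log(w1) - 0.25 * np.log(w2)
            if d is None:
                values[i, j] = values[j, i] = np.nan
                defined[i, j] = defined[j, i] = False
                n_undefined += 1
            else:
                values[i, j] = values[j, i] = d
    if n_undefined:
        logger.info("distance matrix: %d undefined pair(s) masked", n_undefined)
    overlap[np.diag_indices(n)] = [int(v.sum()) for v in valid]
    return DistanceMatrix(
        labels=library.record_ids, values=values, defined=defined,
        min_overlap=min_overlap, overlap=overlap,
    )


def species_distance_summary(
    matrix: DistanceMatrix, species_labels: Sequence[str]
) -> pd.DataFrame:
    """Per-species intraspecific spread and nearest-neighbor distance.

    Columns (percent K2P): ``max_intra_pct``, ``mean_intra_pct`` (NaN for
    singletons), ``nn_inter_pct`` (minimum defined distance to any record
    of another species) and the neighbor's species.  The comparison of
    maximum intraspecific distance with the nearest-neighbor distance per
    species is the per-species form of the barcode gap.
    """
    labels = np.asarray(species_labels, dtype=object)
    if len(labels) != len(matrix):
        raise ValueError("species labels must cover all matrix rows")
    pct = matrix.percent()
    rows = []
    for sp in pd.unique(labels):
        idx = np.flatnonzero(labels == sp)
        other = np.flatnonzero(labels != sp)
        intra_vals = []
        for ii, i in enumerate(idx):
            for j in idx[ii + 1 :]:
                if matrix.defined[i, j]:
                    intra_vals.append(pct[i, j])
        if len(idx) > 1 and not intra_vals:
            warnings.warn(
                f"species {sp!r}: all intraspecific pairs undefined", stacklevel=2
            )
        nn = np.nan
        nn_sp = ""
        if other.size:
            sub = pct[np.ix_(idx, other)]
            mask = matrix.defined[np.ix_(idx, other)]
            sub = np.where(mask, sub, np.inf)
            jmin = np.unravel_index(np.argmin(sub), sub.shape)
            if np.isfinite(sub[jmin]):
                nn = float(sub[jmin])
                nn_sp = str(labels[other[jmin[1]]])
        rows.append(
            {
                "species": sp,
                "n_records": int(len(idx)),
                "max_intra_pct": max(intra_vals) if intra_vals else np.nan,
                "mean_intra_pct": float(np.mean(intra_vals)) if intra_vals else np.nan,
                "nn_inter_pct": nn,
                "nearest_neighbor_species": nn_sp,
            }
        )
    return pd.DataFrame(rows)


def barcode_gap_table(
    matrix: DistanceMatrix,
    species_labels: Sequence[str],
    grouping_labels: Optional[Sequence[str]] = None,
) -> dict[str, dict[str, np.ndarray]]:
    """Pooled intra- and interspecific distance distributions per group.

    Each defined off-diagonal pair appears exactly once, classified as
    intraspecific (same species label) or interspecific.  With grouping
    labels (e.g. subfamily), a pair belongs to a group only when both
    members share that group; cross-group pairs appear only in the
    whole-library entry (key ``""``).  Values are percent K2P.
    """
    labels = np.asarray(species_labels, dtype=object)
    n = len(matrix)
    if len(labels) != n:
        raise ValueError("species labels must cover all matrix rows")
    groups = (
        np.asarray(grouping_labels, dtype=object)
        if grouping_labels is not None
        else None
    )
    pct = matrix.percent()
    out: dict[str, dict[str, list]] = {"": {"intra": [], "inter": []}}
    for i in range(n):
        for j in range(i + 1, n):
            if not matrix.defined[i, j]:
                continue
            kind = "intra" if labels[i] == labels[j] else "inter"
            out[""][kind].append(pct[i, j])
            if groups is not None and groups[i] == groups[j]:
                g = str(groups[i])
                out.setdefault(g, {"intra": [], "inter": []})[kind].append(pct[i, j])
    return {
        g: {k: np.asarray(v, dtype=float) for k, v in d.items()}
        for g, d in out.items()
    }
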