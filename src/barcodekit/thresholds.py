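"""Optimal identification threshold and Best Close Match.

The optimal threshold (OT) is the distance cutoff that minimizes
cumulative identification errors (false positives + false negatives)
when every sequence in the library is treated in turn as a query against
the rest.  Best Close Match (BCM) then assigns each sequence the species
of its closest defined match, provided that match lies within the
threshold, and scores the assignment as correct / incorrect / ambiguous /
no identification.  Barcoding efficiency (BE) is the percentage of
correctly identified sequences among those whose species has at least
two records — singletons cannot possibly match a conspecific and are
excluded from the denominator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .distances import DistanceMatrix

logger = logging.getLogger(__name__)

#: Default threshold grid: 0.1%..10.0% K2P in 0.1% steps.
DEFAULT_GRID = np.round(np.arange(0.1, 10.05, 0.1), 10)


@dataclass(frozen=True)
class OptimalThreshold:
    """A (possibly degenerate) plateau of thresholds attaining minimum error."""

    t_low: float
    t_high: float
    min_error: int


@dataclass(frozen=True)
class BCMOutcome:
    record_id: str
    category: str  # correct | incorrect | ambiguous | no_id
    best_distance_pct: Optional[float]
    closest_ids: tuple[str, ...]


@dataclass(frozen=True)
class EfficiencyReport:
    n_total: int
    n_non_singleton: int
    n_correct: int
    n_incorrect: int
    n_ambiguous: int
    n_no_id: int
    #: correct non-singletons / non-singletons, percent (None if no denominator)
    efficiency_percent: Optional[float]
    #: alternative: correct / (total - no_id), percent
    efficiency_identified_percent: Optional[float]

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _prepare(matrix: DistanceMatrix, species_labels: Sequence[str]):
    labels = np.asarray(species_labels, dtype=object)
    if len(labels) != len(matrix):
        raise ValueError("species labels must cover all matrix rows")
    d = matrix.percent().copy()
    d[~matrix.defined] = np.inf  # undefined = unusable for identification
    np.fill_diagonal(d, np.inf)  # self never a match
    same = labels[:, None] == labels[None, :]
    return labels, d, same


def threshold_scan(
    matrix: DistanceMatrix,
    species_labels: Sequence[str],
    grid: Sequence[float] = DEFAULT_GRID,
) -> pd.DataFrame:
    """Score every threshold on the grid by its identification outcomes.

    For sequence ``i`` at threshold ``t``, the match set ``M`` holds all
    other records at defined distance <= ``t``.  For a sequence whose
    species has other records: no conspecific in ``M`` -> false negative;
    any heterospecific in ``M`` -> false positive; otherwise (non-empty,
    all conspecific) -> true positive.  For a species singleton: ``M``
    empty -> true negative, else false positive.  Outcomes are exclusive,
    with the false-negative check taking precedence for non-singletons.
    Returns one row per threshold with the four counts and
    ``cumulative_error = false_pos + false_neg``.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("threshold grid must be strictly ascending")
    labels, d, same = _prepare(matrix, species_labels)
    n = len(labels)
    _, counts = np.unique(labels, return_counts=True)
    singleton = np.isin(labels, np.unique(labels)[counts == 1])

    # per sequence: nearest conspecific and nearest heterospecific distances
    d_con = np.where(same, d, np.inf).min(axis=1)
    d_het = np.where(~same, d, np.inf).min(axis=1)

    rows = []
    for t in grid:
        has_con = d_con <= t
        has_het = d_het <= t
        tn = int((singleton & ~has_het).sum())
        fp_s = int((singleton & has_het).sum())
        ns = ~singleton
        fn = int((ns & ~has_con).sum())
        fp = fp_s + int((ns & has_con & has_het).sum())
        tp = int((ns & has_con & ~has_het).sum())
        rows.append(
            {
                "threshold": float(t),
                "true_pos": tp,
                "true_neg": tn,
                "false_pos": fp,
                "false_neg": fn,
                "cumulative_error": fp + fn,
            }
        )
    out = pd.DataFrame(rows)
    assert (out[["true_pos", "true_neg", "false_pos", "false_neg"]].sum(axis=1) == n).all()
    return out


def optimal_threshold(scan: pd.DataFrame) -> OptimalThreshold:
    """Extract the lowest plateau of thresholds minimizing cumulative error.

    Returns the minimum and maximum grid values of the lowest contiguous
    run attaining the global minimum; a non-contiguous argmin set or an
    all-equal scan is reported with a warning.
    """
    if len(scan) == 0:
        raise ValueError("empty scan")
    err = scan["cumulative_error"].to_numpy()
    tvals = scan["threshold"].to_numpy()
    m = int(err.min())
    at_min = np.flatnonzero(err == m)
    runs = np.split(at_min, np.flatnonzero(np.diff(at_min) > 1) + 1)
    if len(runs) > 1:
        warnings.warn(
            "argmin set of cumulative error is non-contiguous; "
            "returning the lowest run",
            stacklevel=2,
        )
    if at_min.size == len(scan):
        warnings.warn("cumulative error constant across the whole grid", stacklevel=2)
    run = runs[0]
    return OptimalThreshold(
        t_low=float(tvals[run[0]]), t_high=float(tvals[run[-1]]), min_error=m
    )


def best_close_match(
    matrix: DistanceMatrix,
    species_labels: Sequence[str],
    threshold: float,
    rel_tol: float = 1e-9,
) -> list[BCMOutcome]:
    """Best-Close-Match identification of every sequence at a threshold (%).

    Each sequence is assigned from its closest defined match(es): farther
    than the threshold (or no defined match) -> ``no_id``; the full set of
    equally-closest matches all conspecific -> ``correct``; none
    conspecific -> ``incorrect``; mixed -> ``ambiguous``.  Near-exact
    distance ties (relative tolerance ``rel_tol``) count as ties, which is
    what makes the ambiguous category well-defined.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    labels, d, same = _prepare(matrix, species_labels)
    outcomes = []
    for i, rid in enumerate(matrix.labels):
        m = d[i].min()
        if not np.isfinite(m) or m > threshold:
            outcomes.append(
                BCMOutcome(
                    record_id=rid,
                    category="no_id",
                    best_distance_pct=float(m) if np.isfinite(m) else None,
                    closest_ids=(),
                )
            )
            continue
        ties = np.flatnonzero(d[i] <= m + rel_tol * max(m, 1.0))
        con = same[i, ties]
        if con.all():
            cat = "correct"
        elif not con.any():
            cat = "incorrect"
        else:
            cat = "ambiguous"
        outcomes.append(
            BCMOutcome(
                record_id=rid,
                category=cat,
                best_distance_pct=float(m),
                closest_ids=tuple(matrix.labels[j] for j in ties),
            )
        )
    return outcomes


def barcoding_efficiency(
    outcomes: Sequence[BCMOutcome], species_labels: Sequence[str]
) -> EfficiencyReport:
    """Summarize BCM outcomes into a barcoding-efficiency report.

    BE = 100 * (correct among non-singleton sequences) / (non-singleton
    sequences).  A second variant over all identified sequences
    (total - no_id) is reported alongside, since published BE figures do
    not always state which denominator was used.
    """
    labels = np.asarray(species_labels, dtype=object)
    if len(labels) != len(outcomes):
        raise ValueError("one species label per outcome required")
    _, counts = np.unique(labels, return_counts=True)
    non_singleton = np.isin(labels, np.unique(labels)[counts > 1])
    cats = np.asarray([o.category for o in outcomes], dtype=object)
    n_ns = int(non_singleton.sum())
    n_correct_ns = int(((cats == "correct") & non_singleton).sum())
    tally = {c: int((cats == c).sum()) for c in ("correct", "incorrect", "ambiguous", "no_id")}
    n_ident = len(outcomes) - tally["no_id"]
    return EfficiencyReport(
        n_total=len(outcomes),
        n_non_singleton=n_ns,
        n_correct=tally["correct"],
        n_incorrect=tally["incorrect"],
        n_ambiguous=tally["ambiguous"],
        n_no_id=tally["no_id"],
        efficiency_percent=100.0 * n_correct_ns / n_ns if n_ns else None,
        efficiency_identified_percent=(
            100.0 * tally["correct"] / n_ident if n_ident else None
        ),
    )
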