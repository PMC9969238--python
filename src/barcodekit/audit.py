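"""Library completeness, geography, habitat, and richness-scaling audits.

These operations summarize how well a reference library covers its
taxon: the fraction of records identified to genus and species level per
group, the contribution of each country to records / genera / BINs, the
split of species and clusters between lentic and lotic habitats, and the
log-log regression of cluster (BIN) richness on specimen count — a steep,
tight fit indicates that sampling, not biology, still limits recorded
richness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import Rank, ReferenceLibrary, identification_rank


def completeness_table(
    library: ReferenceLibrary,
    accepted_counts: Optional[Mapping[str, int]] = None,
    group_by: str = "subfamily",
) -> pd.DataFrame:
    """Identification-level completeness per group plus a family total.

    Percentages use strict (described-binomial) species semantics;
    ``n_species_recorded`` counts distinct strict binomials.  The
    optional ``accepted_counts`` supplies externally accepted species
    numbers per group for the recorded/accepted comparison.
    """
    groups: dict[str, list] = {}
    for r in library:
        g = getattr(r, group_by, "").strip() or "unassigned"
        groups.setdefault(g, []).append(r)
    if accepted_counts:
        unknown = set(accepted_counts) - set(groups)
        if unknown:
            warnings.warn(
                f"accepted counts for unknown group(s) {sorted(unknown)}", stacklevel=2
            )
    rows = []
    for g, recs in sorted(groups.items()):
        rows.append(_completeness_row(g, recs, accepted_counts))
    rows.append(_completeness_row("total", list(library), accepted_counts))
    return pd.DataFrame(rows)


def _completeness_row(group, recs, accepted_counts):
    n = len(recs)
    ranks = [identification_rank(r, "strict_public") for r in recs]
    n_genus_level = sum(1 for k in ranks if k >= Rank.GENUS)
    n_species_level = sum(1 for k in ranks if k >= Rank.SPECIES)
    genera = {r.genus.strip() for r in recs if r.genus.strip()}
    species = {
        r.species_name.strip().lower()
        for r, k in zip(recs, ranks)
        if k == Rank.SPECIES
    }
    bins = {r.bin_id for r in recs if r.bin_id.strip()}
    accepted = (accepted_counts or {}).get(group)
    return {
        "group": group,
        "n_specimens": n,
        "n_genera": len(genera),
        "pct_genus_level": 100.0 * n_genus_level / n if n else 0.0,
        "n_species_recorded": len(species),
        "n_species_accepted": accepted if accepted is not None else np.nan,
        "pct_species_level": 100.0 * n_species_level / n if n else 0.0,
        "n_bins": len(bins),
    }


def geographic_contribution(library: ReferenceLibrary) -> pd.DataFrame:
    """Records, genus and BIN richness per country, with cumulative share.

    Countries are ordered by descending record count (alphabetical
    tie-break); empty countries pool under ``unspecified``.  The
    ``cumulative_share`` of the top-k prefix quantifies how concentrated
    barcoding effort is geographically.
    """
    per: dict[str, list] = {}
    for r in library:
        c = r.country.strip() or "unspecified"
        per.setdefault(c, []).append(r)
    rows = []
    for c, recs in per.items():
        rows.append(
            {
                "country": c,
                "n_records": len(recs),
                "n_genera": len({r.genus.strip() for r in recs if r.genus.strip()}),
                "n_bins": len({r.bin_id for r in recs if r.bin_id.strip()}),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["n_records", "country"], ascending=[False, True], kind="mergesort"
    )
    total = df["n_records"].sum()
    df["cumulative_share"] = df["n_records"].cumsum() / total if total else 0.0
    return df.reset_index(drop=True)


def habitat_richness(
    library: ReferenceLibrary,
    cluster_labels: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Species and cluster richness per habitat class, with overlap.

    Species are counted under permissive (within-library) semantics so
    coded provisional names contribute.  ``cluster_labels`` maps
    record_id to a cluster/BIN id; when omitted, record BIN ids are used.
    The ``both`` row counts species (clusters) observed in lentic *and*
    lotic water bodies.
    """
    sp_by_hab: dict[str, set] = {"lentic": set(), "lotic": set(), "unknown": set()}
    cl_by_hab: dict[str, set] = {"lentic": set(), "lotic": set(), "unknown": set()}
    labels = library.species_labels("permissive_local")
    for r, sp in zip(library, labels):
        hab = r.habitat
        if sp:
            sp_by_hab[hab].add(sp.lower())
        cl = (
            cluster_labels.get(r.record_id, "")
            if cluster_labels is not None
            else r.bin_id
        )
        if cl:
            cl_by_hab[hab].add(cl)
    if not sp_by_hab["lentic"] and not sp_by_hab["lotic"]:
        warnings.warn("no records with known habitat", stacklevel=2)
    rows = []
    for hab in ("lentic", "lotic", "unknown"):
        rows.append(
            {
                "habitat": hab,
                "n_species": len(sp_by_hab[hab]),
                "n_clusters": len(cl_by_hab[hab]),
            }
        )
    rows.append(
        {
            "habitat": "both",
            "n_species": len(sp_by_hab["lentic"] & sp_by_hab["lotic"]),
            "n_clusters": len(cl_by_hab["lentic"] & cl_by_hab["lotic"]),
        }
    )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RichnessFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_points: int


def specimens_vs_richness_fit(
    pairs: Sequence[tuple[float, float]]
) -> RichnessFit:
    """Least-squares fit of log10(richness) on log10(specimens).

    ``pairs`` holds (n_specimens, n_clusters) per group; groups with a
    zero in either count are excluded (warned).  Requires >= 3 usable
    points.
    """
    arr = np.asarray(pairs, dtype=float)
    usable = (arr > 0).all(axis=1)
    if (~usable).any():
        warnings.warn(
            f"{int((~usable).sum())} group(s) with zero counts excluded from fit",
            stacklevel=2,
        )
    arr = arr[usable]
    if len(arr) < 3:
        raise ValueError("need at least 3 groups with positive counts")
    x = np.log10(arr[:, 0])
    y = np.log10(arr[:, 1])
    res = stats.linregress(x, y)
    return RichnessFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n_points=len(arr),
    )
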