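"""OTU clustering at a distance threshold and BIN–species concordance.

BOLD assigns barcodes to Barcode Index Numbers (BINs) with its internal
refined-single-linkage algorithm; this module audits any such partition.
Provided BIN ids are first-class; when none are available, a threshold
clustering (single or complete linkage, default single linkage at 2.2%
K2P — a conventional OTU cutoff for COI) stands in.  A cluster is
*singleton* when it holds one sequence, *discordant* when it mixes two or
more distinct species names, otherwise *concordant*.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .records import ReferenceLibrary

DEFAULT_OTU_THRESHOLD = 2.2  # percent K2P


@dataclass
class ClusterAssignment:
    assignment: dict[str, str]  # record_id -> cluster_id
    method: str  # provided_bins | single_linkage | complete_linkage
    threshold: Optional[float] = None  # percent, when clustered

    def clusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for rid, cid in self.assignment.items():
            out.setdefault(cid, []).append(rid)
        return {cid: sorted(ids) for cid, ids in out.items()}

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def write_tsv(self, path) -> None:
        pd.DataFrame(
            {"record_id": list(self.assignment), "cluster_id": list(self.assignment.values())}
        ).to_csv(path, sep="\t", index=False)


def from_provided_bins(library: ReferenceLibrary) -> ClusterAssignment:
    """Use the BIN ids already attached to the records as the partition.

    Records without a BIN each form their own cluster (labelled
    ``unbinned:<record_id>``)."""
    assignment = {}
    for r in library:
        assignment[r.record_id] = r.bin_id if r.bin_id else f"unbinned:{r.record_id}"
    return ClusterAssignment(assignment=assignment, method="provided_bins")


def cluster_otus(
    matrix: DistanceMatrix, threshold: float = DEFAULT_OTU_THRESHOLD,
    linkage: str = "single_linkage",
) -> ClusterAssignment:
    """Threshold clustering of a distance matrix into OTUs.

    ``single_linkage``: transitive closure of all pairs with defined
    distance <= threshold (%).  ``complete_linkage``: agglomerative
    merging, closest pair of clusters first, while the *maximum*
    inter-cluster distance stays <= threshold; ties are broken toward the
    pair containing the smallest lexicographic member id.  Undefined
    distances are treated as infinite.  Cluster ids are ``OTU0001``... in
    order of each cluster's smallest member id.
    """
    d = matrix.percent().copy()
    d[~matrix.defined] = np.inf
    np.fill_diagonal(d, 0.0)
    n = len(matrix)
    labels = matrix.labels

    if linkage == "single_linkage":
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(n):
            for j in range(i + 1, n):
                if d[i, j] <= threshold:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
        groups: dict[int, list[int]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(i)
        members = list(groups.values())
    elif linkage == "complete_linkage":
        clusters: list[list[int]] = [[i] for i in range(n)]
        while len(clusters) > 1:
            best = None  # (dist, min_member_id, a, b)
            for a in range(len(clusters)):
                for b in range(a + 1, len(clusters)):
                    dist = max(d[i, j] for i in clusters[a] for j in clusters[b])
                    if dist > threshold:
                        continue
                    tie_id = min(labels[i] for i in clusters[a] + clusters[b])
                    key = (dist, tie_id)
                    if best is None or key < best[0]:
                        best = (key, a, b)
            if best is None:
                break
            _, a, b = best
            clusters[a] = clusters[a] + clusters[b]
            del clusters[b]
        members = clusters
    else:
        raise ValueError(f"unknown linkage {linkage!r}")

    members.sort(key=lambda idxs: min(labels[i] for i in idxs))
    assignment = {}
    for k, idxs in enumerate(members, start=1):
        for i in idxs:
            assignment[labels[i]] = f"OTU{k:04d}"
    return ClusterAssignment(assignment=assignment, method=linkage, threshold=threshold)


@dataclass
class ConcordanceReport:
    """Per-cluster concordance category with summary counts."""

    category: dict[str, str]  # cluster_id -> concordant|discordant|singleton
    species_per_cluster: dict[str, int] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        out = {"concordant": 0, "discordant": 0, "singleton": 0}
        for c in self.category.values():
            out[c] += 1
        return out

    @property
    def percentages(self) -> dict[str, float]:
        total = len(self.category)
        return {k: 100.0 * v / total if total else 0.0 for k, v in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster_id": list(self.category),
                "category": list(self.category.values()),
                "n_species": [self.species_per_cluster.get(c, 0) for c in self.category],
            }
        )

    def write(self, tsv_path, json_path=None) -> None:
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            Path(json_path).write_text(
                json.dumps({"counts": self.counts, "percentages": self.percentages}, indent=2)
                + "\n"
            )


def classify_concordance(
    assignment: ClusterAssignment, species_labels: dict[str, str] | Sequence[str]
) -> ConcordanceReport:
    """Classify each cluster as concordant / discordant / singleton.

    ``species_labels`` maps record_id to species name (or is a sequence
    parallel to the assignment's insertion order).  Empty species names
    are uninformative: they never create discordance, but their records
    still count toward cluster size.
    """
    labels = _as_label_map(assignment, species_labels)
    category = {}
    species_per_cluster = {}
    for cid, ids in assignment.clusters().items():
        names = {labels[r] for r in ids if labels[r]}
        species_per_cluster[cid] = len(names)
        if len(ids) == 1:
            category[cid] = "singleton"
        elif len(names) >= 2:
            category[cid] = "discordant"
        else:
            category[cid] = "concordant"
    return ConcordanceReport(category=category, species_per_cluster=species_per_cluster)


def species_bin_mapping(
    assignment: ClusterAssignment, species_labels: dict[str, str] | Sequence[str]
) -> tuple[pd.Series, pd.Series]:
    """Count clusters per species and species per cluster.

    Returns ``(clusters_per_species, species_per_cluster)``; records with
    empty species names are excluded from the species-side tally.
    """
    labels = _as_label_map(assignment, species_labels)
    pairs = {
        (labels[r], cid)
        for r, cid in assignment.assignment.items()
        if labels[r]
    }
    df = pd.DataFrame(sorted(pairs), columns=["species", "cluster_id"])
    per_species = df.groupby("species")["cluster_id"].nunique()
    per_cluster = df.groupby("cluster_id")["species"].nunique()
    return per_species, per_cluster


def _as_label_map(
    assignment: ClusterAssignment, species_labels: dict[str, str] | Sequence[str]
) -> dict[str, str]:
    if isinstance(species_labels, dict):
        missing = set(assignment.assignment) - set(species_labels)
        if missing:
            raise ValueError(f"species labels missing for {sorted(missing)[:5]}")
        return {k: (v or "").strip() for k, v in species_labels.items()}
    ids = list(assignment.assignment)
    if len(species_labels) != len(ids):
        raise ValueError("species label sequence length mismatch")
    return {rid: (lab or "").strip() for rid, lab in zip(ids, species_labels)}
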