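"""Five-grade (A–E) quality ranking of species in a reference library.

Each described species retained after eligibility filtering is ranked by
how its barcodes relate to sequence clusters (BINs):

* **A** — consolidated concordance: one exclusive BIN, more than 10 barcodes;
* **B** — basal concordance: one exclusive BIN, 3–10 barcodes;
* **C** — multiple BINs: the species' barcodes fall in 2+ BINs, none shared;
* **D** — insufficient data: fewer than 3 barcodes, single exclusive BIN;
* **E** — discordant: the species shares a BIN with another species.

Precedence is E > C > D > (A|B): sharing a BIN marks a species E no
matter how many records or BINs it has, and a 2-record species split
across two exclusive BINs is C, not D.  Eligibility requires a described
(strict binomial) species name, a BIN id, and >= 500 bp of sequence;
BIN sharing is evaluated among eligible records only.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import pandas as pd

from .records import Rank, ReferenceLibrary, identification_rank

GRADES = ("A", "B", "C", "D", "E")


def eligible_records(
    library: ReferenceLibrary, min_length: int = 500
) -> ReferenceLibrary:
    """Records with a described species name, a BIN, and >= min_length bp."""
    keep = [
        r.record_id
        for r in library
        if identification_rank(r, "strict_public") == Rank.SPECIES
        and r.bin_id.strip()
        and len(r.ungapped) >= min_length
    ]
    return library.subset(keep)


def assign_grades(library: ReferenceLibrary) -> pd.DataFrame:
    """Grade every species in an (already eligibility-filtered) library.

    Species names are matched case-insensitively.  Returns one row per
    species: ``species, grade, n_records, n_bins, shares_bin``.
    """
    rows = []
    by_species: dict[str, dict] = {}
    bin_to_species: dict[str, set[str]] = {}
    display: dict[str, str] = {}
    for r in library:
        key = r.species_name.strip().lower()
        display.setdefault(key, r.species_name.strip())
        entry = by_species.setdefault(key, {"n": 0, "bins": set()})
        entry["n"] += 1
        entry["bins"].add(r.bin_id)
        bin_to_species.setdefault(r.bin_id, set()).add(key)

    for key in sorted(by_species):
        entry = by_species[key]
        n, bins = entry["n"], entry["bins"]
        shares = any(len(bin_to_species[b]) > 1 for b in bins)
        if shares:
            grade = "E"
        elif len(bins) >= 2:
            grade = "C"
        elif n < 3:
            grade = "D"
        elif n > 10:
            grade = "A"
        else:
            grade = "B"
        rows.append(
            {
                "species": display[key],
                "grade": grade,
                "n_records": n,
                "n_bins": len(bins),
                "shares_bin": shares,
            }
        )
    return pd.DataFrame(rows, columns=["species", "grade", "n_records", "n_bins", "shares_bin"])


def grade_summary(
    grades: pd.DataFrame, grouping_labels: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Per-group counts and percentages of species in each grade.

    ``grouping_labels`` is parallel to the rows of ``grades`` (e.g. the
    subfamily of each species); the ``overall`` row aggregates all
    species.  Empty groups are dropped with a warning.
    """
    df = grades.copy()
    df["group"] = (
        list(grouping_labels) if grouping_labels is not None else ["overall"] * len(df)
    )
    if grouping_labels is not None and len(df["group"]) != len(grades):
        raise ValueError("grouping labels must be parallel to the grade table")
    out_rows = []
    groups = list(dict.fromkeys(df["group"]))
    if grouping_labels is not None:
        groups.append("overall")
    for g in groups:
        sub = df if g == "overall" else df[df["group"] == g]
        if len(sub) == 0:
            warnings.warn(f"group {g!r} has no graded species; omitted", stacklevel=2)
            continue
        row = {"group": g, "n_species": len(sub)}
        for grade in GRADES:
            c = int((sub["grade"] == grade).sum())
            row[f"n_{grade}"] = c
            row[f"pct_{grade}"] = 100.0 * c / len(sub)
        out_rows.append(row)
    return pd.DataFrame(out_rows)
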