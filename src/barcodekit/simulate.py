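"""Synthetic barcode reference libraries with known ground truth.

Every analysis stage in this package is validated against libraries
generated here.  Sequences evolve on a star phylogeny under the K80
(Kimura two-parameter) substitution model: a root coding sequence gives
rise to one ancestor per species at branch length ``inter_branch``
(substitutions/site), and each record evolves from its species ancestor
at ``intra_branch``.  Expected intraspecific K2P distance is therefore
about ``2 * intra_branch`` and expected between-species distance about
``2 * inter_branch`` (plus intraspecific noise), giving an analytically
controlled barcode gap.  Label corruptions — misidentifications, blanked
names, coded provisional names — are applied last, at most one per
record, and logged so tests can score every downstream inference against
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .io import write_fasta
from .records import ReferenceLibrary, SequenceRecord

BASES = np.array(list("ACGT"))
#: Stop codons of the invertebrate mitochondrial code.
_STOPS = {"TAA", "TAG"}
_NONSTOP_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
)

_SYLLABLES = [
    "ba", "ce", "di", "fo", "gu", "la", "me", "ni", "po", "ru",
    "sa", "te", "vi", "xo", "zu", "ka", "lo", "mi", "ne", "ra",
]
_SUBFAMILIES = [
    "Chironominae", "Orthocladiinae", "Diamesinae",
    "Tanypodinae", "Prodiamesinae", "Podonominae",
]
_COUNTRIES = ["China", "Canada", "Germany", "Norway", "Japan", "Australia"]


@dataclass
class SplitMode:
    """Split the first ``n_species`` non-singleton species into ``k`` BINs,
    with extra ``divergence`` (substitutions/site) between sub-cluster
    ancestors."""

    k: int = 2
    divergence: float = 0.03
    n_species: int = 1


@dataclass
class MergeMode:
    """Make the listed pairs of species indices share a single BIN."""

    pairs: list[tuple[int, int]] = field(default_factory=list)


BinMode = Union[str, SplitMode, MergeMode]


@dataclass
class SimulationConfig:
    """Parameters of a simulated barcode library.

    Defaults emulate a curated regional COI library: 658-bp barcodes,
    transition/transversion ratio kappa=4, within-species divergence
    around 1% K2P (``intra_branch`` 0.005 per branch, two branches per
    pair) and between-species divergence around 8% (``inter_branch``
    0.04), with close to half of all species singletons — the singleton
    share observed in regional chironomid libraries.
    """

    n_species: int = 30
    records_per_species: Union[int, Sequence[int], dict] = field(
        default_factory=lambda: {"mean": 3.2, "singleton_fraction": 0.45}
    )
    seq_length: int = 658
    kappa: float = 4.0
    intra_branch: float = 0.005
    inter_branch: float = 0.04
    misid_rate: float = 0.0
    missing_name_rate: float = 0.0
    coded_name_rate: float = 0.0
    bin_mode: BinMode = "true_species"
    habitat_weights: dict = field(
        default_factory=lambda: {"lentic": 0.35, "lotic": 0.55, "unknown": 0.10}
    )
    country_weights: Optional[dict] = None
    seed: int = 0

    def __post_init__(self):
        for r in (self.misid_rate, self.missing_name_rate, self.coded_name_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("corruption rates must lie in [0, 1]")
        if self.misid_rate + self.missing_name_rate + self.coded_name_rate > 1.0:
            raise ValueError("corruption rates must sum to at most 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(self.bin_mode, SplitMode):
            d["bin_mode"] = {"split": asdict(self.bin_mode)}
        elif isinstance(self.bin_mode, MergeMode):
            d["bin_mode"] = {"merge": {"pairs": [list(p) for p in self.bin_mode.pairs]}}
        return d


@dataclass
class GroundTruth:
    """Per-record truth and the corruption log.

    ``table`` columns: record_id, true_species, true_bin, observed
    species name, corruption kind ('' | misid | blanked | coded) and the
    replaced name where applicable.
    """

    table: pd.DataFrame
    config: SimulationConfig

    def corrupted(self, kind: Optional[str] = None) -> pd.DataFrame:
        rows = self.table[self.table["corruption"] != ""]
        if kind is not None:
            rows = rows[rows["corruption"] == kind]
        return rows

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def random_coding_sequence(
    length: int, genetic_code: int = 5, rng: Optional[np.random.Generator] = None
) -> str:
    """Random sequence with no stop codons in frame 0.

    Codons are drawn uniformly from the 62 non-stop codons of the
    invertebrate mitochondrial code; a non-multiple-of-three tail is
    filled with random bases (it cannot complete a codon)."""
    if length < 3:
        raise ValueError("length must be >= 3")
    if genetic_code != 5:
        raise NotImplementedError("only genetic code 5 is supported")
    rng = np.random.default_rng() if rng is None else rng
    n_codons, tail = divmod(length, 3)
    idx = rng.integers(0, len(_NONSTOP_CODONS), size=n_codons)
    seq = "".join(_NONSTOP_CODONS[i] for i in idx)
    if tail:
        seq += "".join(rng.choice(BASES, size=tail))
    return seq


def _k80_transition_probs(branch_length: float, kappa: float) -> np.ndarray:
    """4x4 substitution-probability matrix (order ACGT) at a branch length.

    Rates are normalized so the expected number of substitutions per site
    equals ``branch_length``: with transition rate alpha and transversion
    rate beta per target, alpha + 2*beta = 1 and kappa = alpha/beta.
    """
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    t = branch_length
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1  # each of the two transversion targets
    # order A C G T; transitions A<->G, C<->T
    P = np.full((4, 4), p_tv)
    np.fill_diagonal(P, p_same)
    P[0, 2] = P[2, 0] = P[1, 3] = P[3, 1] = p_ts
    return P


def evolve_k80(
    sequence: str,
    branch_length: float,
    kappa: float = 4.0,
    rng: Optional[np.random.Generator] = None,
) -> str:
    """Evolve a sequence along one branch under the K80 model.

    Each A/C/G/T site substitutes independently with the exact
    transition-probability matrix; non-ACGT characters are carried
    through unchanged.  The expected K2P distance between input and
    output equals ``branch_length``.
    """
    if branch_length < 0:
        raise ValueError("branch length must be >= 0")
    rng = np.random.default_rng() if rng is None else rng
    if branch_length == 0:
        return sequence
    P = _k80_transition_probs(branch_length, kappa)
    cum = P.cumsum(axis=1)
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    u = rng.random(len(sequence))
    out = []
    for ch, x in zip(sequence, u):
        i = code.get(ch)
        if i is None:
            out.append(ch)
        else:
            out.append("ACGT"[int(np.searchsorted(cum[i], x, side="right"))])
    return "".join(out)


def _evolve_coding(
    sequence: str, branch_length: float, kappa: float, rng: np.random.Generator,
    max_tries: int = 200,
) -> str:
    """Evolve under K80 conditioned on the result staying stop-free.

    Functional COI is under purifying selection: substitutions creating an
    in-frame stop codon do not persist.  Realizations with a frame-0 stop
    are redrawn, which leaves the substitution process K80 up to a small
    truncation (expected pairwise distances remain ~= the branch lengths).
    """
    from .io import MITO_STOP_CODONS

    def has_stop(seq: str) -> bool:
        return any(
            seq[i : i + 3] in MITO_STOP_CODONS for i in range(0, len(seq) - 2, 3)
        )

    for _ in range(max_tries):
        out = evolve_k80(sequence, branch_length, kappa, rng)
        if not has_stop(out):
            return out
    raise RuntimeError("could not draw a stop-free sequence; branch length too large?")


def _species_name(rng: np.random.Generator, genus: str) -> str:
    epithet = "".join(rng.choice(_SYLLABLES, size=3)) + "a"
    return f"{genus} {epithet}"


def _genus_name(rng: np.random.Generator) -> str:
    return ("".join(rng.choice(_SYLLABLES, size=3)) + "us").capitalize()


def _records_per_species(config: SimulationConfig, rng: np.random.Generator) -> list[int]:
    spec = config.records_per_species
    if isinstance(spec, int):
        return [spec] * config.n_species
    if isinstance(spec, dict):
        mean = float(spec.get("mean", 3.2))
        f = float(spec.get("singleton_fraction", 0.45))
        out = []
        for _ in range(config.n_species):
            if rng.random() < f:
                out.append(1)
            else:
                k = 0
                while k < 2:  # non-singleton species need >= 2 records
                    k = int(rng.poisson(mean))
                out.append(k)
        return out
    sizes = list(spec)
    if len(sizes) != config.n_species:
        raise ValueError("explicit records_per_species must list one count per species")
    return sizes


def simulate_library(config: SimulationConfig) -> tuple[ReferenceLibrary, GroundTruth]:
    """Generate a library and its ground truth from a configuration.

    Star phylogeny: root -> species ancestors (``inter_branch``) ->
    individual haplotypes (``intra_branch``).  BIN assignment follows
    ``bin_mode``; label corruptions are applied after BIN assignment, so
    a misidentified record keeps the BIN of its true species — exactly
    how a real mislabel creates BIN discordance.  Identical
    configurations (including seed) reproduce identical libraries.
    """
    rng = np.random.default_rng(config.seed)
    if isinstance(config.bin_mode, MergeMode):
        for a, b in config.bin_mode.pairs:
            if not (0 <= a < config.n_species and 0 <= b < config.n_species):
                raise ValueError("merge pair indices exceed species count")

    sizes = _records_per_species(config, rng)
    genera: list[str] = []
    n_genera = max(1, config.n_species // 3)
    genus_pool = []
    seen = set()
    while len(genus_pool) < n_genera:
        g = _genus_name(rng)
        if g not in seen:
            seen.add(g)
            genus_pool.append(g)
    subfam_of_genus = {
        g: _SUBFAMILIES[i % len(_SUBFAMILIES)] for i, g in enumerate(genus_pool)
    }
    country_weights = config.country_weights or {
        c: w for c, w in zip(_COUNTRIES, [0.4, 0.25, 0.15, 0.1, 0.06, 0.04])
    }
    countries = list(country_weights)
    c_probs = np.array([country_weights[c] for c in countries], dtype=float)
    c_probs /= c_probs.sum()
    habitats = list(config.habitat_weights)
    h_probs = np.array([config.habitat_weights[h] for h in habitats], dtype=float)
    h_probs /= h_probs.sum()

    root = random_coding_sequence(config.seq_length, rng=rng)

    species_meta = []
    names_seen = set()
    for s in range(config.n_species):
        genus = genus_pool[s % len(genus_pool)]
        name = _species_name(rng, genus)
        while name in names_seen:
            name = _species_name(rng, genus)
        names_seen.add(name)
        ancestor = _evolve_coding(root, config.inter_branch, config.kappa, rng)
        species_meta.append({"name": name, "genus": genus, "ancestor": ancestor})

    # BIN structure
    split_species: dict[int, SplitMode] = {}
    if isinstance(config.bin_mode, SplitMode):
        chosen = [s for s in range(config.n_species) if sizes[s] >= 2][
            : config.bin_mode.n_species
        ]
        if len(chosen) < config.bin_mode.n_species:
            raise ValueError("not enough non-singleton species to split")
        split_species = {s: config.bin_mode for s in chosen}
    bin_of_species = {s: f"BOLD:SIM{s:04d}" for s in range(config.n_species)}
    if isinstance(config.bin_mode, MergeMode):
        for a, b in config.bin_mode.pairs:
            bin_of_species[b] = bin_of_species[a]

    records: list[SequenceRecord] = []
    truth_rows = []
    counter = 0
    for s, meta in enumerate(species_meta):
        sub_ancestors = [meta["ancestor"]]
        sub_bins = [bin_of_species[s]]
        if s in split_species:
            mode = split_species[s]
            sub_ancestors = [
                _evolve_coding(meta["ancestor"], mode.divergence, config.kappa, rng)
                for _ in range(mode.k)
            ]
            sub_bins = [f"{bin_of_species[s]}.{i}" for i in range(mode.k)]
        for r in range(sizes[s]):
            sub = r % len(sub_ancestors)
            seq = _evolve_coding(
                sub_ancestors[sub], config.intra_branch, config.kappa, rng
            )
            counter += 1
            rid = f"SIM{counter:05d}"
            records.append(
                SequenceRecord(
                    record_id=rid,
                    sequence=seq,
                    species_name=meta["name"],
                    genus=meta["genus"],
                    subfamily=subfam_of_genus[meta["genus"]],
                    family="Chironomidae",
                    bin_id=sub_bins[sub],
                    country=str(rng.choice(countries, p=c_probs)),
                    habitat=str(rng.choice(habitats, p=h_probs)),
                    latitude=float(np.round(rng.uniform(28, 38), 4)),
                    longitude=float(np.round(rng.uniform(80, 100), 4)),
                    life_stage=str(
                        rng.choice(["larva", "pupa", "adult_male", "adult_female"])
                    ),
                )
            )
            truth_rows.append(
                {
                    "record_id": rid,
                    "true_species": meta["name"],
                    "true_bin": sub_bins[sub],
                    "observed_species": meta["name"],
                    "corruption": "",
                    "replaced_with": "",
                }
            )

    library = ReferenceLibrary(records=records, source_label="simulated")
    truth = GroundTruth(table=pd.DataFrame(truth_rows), config=config)
    if config.misid_rate or config.missing_name_rate or config.coded_name_rate:
        library, truth = inject_label_errors(
            library,
            truth,
            misid_rate=config.misid_rate,
            missing_name_rate=config.missing_name_rate,
            coded_name_rate=config.coded_name_rate,
            rng=rng,
        )
    return library, truth


def inject_label_errors(
    library: ReferenceLibrary,
    truth: GroundTruth,
    misid_rate: float = 0.0,
    missing_name_rate: float = 0.0,
    coded_name_rate: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[ReferenceLibrary, GroundTruth]:
    """Corrupt species labels in place of field errors, one per record.

    ``misid``: the full identification (species, genus, subfamily) is
    replaced by another species' — a misidentified specimen is recorded
    under the wrong name wholesale; ``blanked``: the species name is
    emptied (genus kept); ``coded``: the name becomes "<Genus> sp. SIMn".
    Every corruption is logged in the truth table.
    """
    if misid_rate + missing_name_rate + coded_name_rate > 1.0:
        raise ValueError("corruption rates must sum to at most 1")
    rng = np.random.default_rng() if rng is None else rng
    taxonomy = {
        r.species_name: (r.genus, r.subfamily) for r in library if r.species_name
    }
    species_names = sorted(taxonomy)
    if misid_rate > 0 and len(species_names) < 2:
        raise ValueError("misidentification requires at least 2 species")
    table = truth.table.copy().set_index("record_id")
    new_records = []
    probs = np.array([misid_rate, missing_name_rate, coded_name_rate])
    cum = probs.cumsum()
    code_counter = 0
    for rec in library:
        u = rng.random()
        if u < cum[0]:
            others = [s for s in species_names if s != rec.species_name]
            new_name = others[int(rng.integers(len(others)))]
            genus, subfam = taxonomy[new_name]
            new_records.append(
                rec.copy(species_name=new_name, genus=genus, subfamily=subfam)
            )
            table.loc[rec.record_id, ["observed_species", "corruption", "replaced_with"]] = [
                new_name, "misid", new_name,
            ]
        elif u < cum[1]:
            new_records.append(rec.copy(species_name=""))
            table.loc[rec.record_id, ["observed_species", "corruption"]] = ["", "blanked"]
        elif u < cum[2]:
            code_counter += 1
            genus = rec.genus or "Genus"
            coded = f"{genus} sp. SIM{code_counter}"
            new_records.append(rec.copy(species_name=coded))
            table.loc[rec.record_id, ["observed_species", "corruption", "replaced_with"]] = [
                coded, "coded", coded,
            ]
        else:
            new_records.append(rec)
    out_lib = ReferenceLibrary(
        records=new_records, source_label=library.source_label
    )
    return out_lib, GroundTruth(table=table.reset_index(), config=truth.config)


def write_library(
    library: ReferenceLibrary,
    truth: Optional[GroundTruth],
    outdir,
    prefix: str = "library",
) -> dict[str, Path]:
    """Write FASTA + metadata TSV (+ truth TSV, config YAML) for a library.

    Output is deterministic for a given library, so identical simulation
    configs produce byte-identical files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    fasta = outdir / f"{prefix}.fasta"
    write_fasta(fasta, [(r.record_id, r.sequence) for r in library])
    paths["fasta"] = fasta
    meta = pd.DataFrame(
        {
            "processid": [r.record_id for r in library],
            "species_name": [r.species_name for r in library],
            "genus_name": [r.genus for r in library],
            "subfamily_name": [r.subfamily for r in library],
            "family_name": [r.family for r in library],
            "bin_uri": [r.bin_id for r in library],
            "country": [r.country for r in library],
            "lat": [r.latitude if r.latitude is not None else "" for r in library],
            "lon": [r.longitude if r.longitude is not None else "" for r in library],
            "habitat": [r.habitat for r in library],
            "life_stage": [r.life_stage for r in library],
        }
    )
    tsv = outdir / f"{prefix}_specimens.tsv"
    meta.to_csv(tsv, sep="\t", index=False)
    paths["specimens"] = tsv
    if truth is not None:
        tpath = outdir / f"{prefix}_truth.tsv"
        truth.write_tsv(tpath)
        paths["truth"] = tpath
        cpath = outdir / f"{prefix}_config.yaml"
        cpath.write_text(yaml.safe_dump(truth.config.to_dict(), sort_keys=True))
        paths["config"] = cpath
    return paths
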