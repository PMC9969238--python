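# Methods

This note documents the models, definitions, defaults and numerical
choices behind barcodekit, and what the synthetic validation does and
does not establish about real data.

## Distance model

Pairwise distances use the Kimura two-parameter estimator
*d* = −½·ln((1 − 2P − Q)·√(1 − 2Q)), where *P* and *Q* are the
proportions of transition (A↔G, C↔T) and transversion differences over
compared sites. Sites are compared under **pairwise deletion**: a
position contributes only when both sequences carry an unambiguous
A/C/G/T. This is the standard convention in barcoding software and is
robust to ragged sequence ends; complete deletion would discard sites
globally and couple every pair's distance to the worst sequence in the
library.

Two situations give an **undefined** distance, which is a value, not an
error:

- fewer than `min_overlap` shared sites (default **100**; guards
  against spurious distances from tiny overlaps between short
  fragments);
- saturation, when 1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0 and the logarithm has
  no real value.

Undefined entries are masked in the matrix, excluded from all
summaries, and treated as infinitely distant by nearest-neighbor
searches and clustering: a pair whose divergence cannot be estimated
cannot support an identification. Sequences are compared positionally;
COI barcodes are length-conserved (in-frame, indel-free in practice),
so equal-length trimmed barcodes are positionally homologous. Ragged
libraries are right-padded with gaps, which pairwise deletion ignores;
genuinely unaligned input must be aligned upstream.

Distances are held internally in substitutions/site and reported in
percent; every threshold parameter in the public API is in percent K2P.

## Quality control

Checks run in a fixed order — ungapped length (default minimum
**500 bp**, the conventional minimum for a barcode-compliant COI
record), ambiguous-base fraction (default maximum **0.01**; no
universal published cutoff exists, so this approximates
barcode-compliance norms and is configurable), then stop codons — and
the first failure is the recorded status, making the statuses a
partition of the library. The stop-codon screen translates the three
forward frames under the invertebrate mitochondrial code (table 5,
stops TAA and TAG), takes the frame with the fewest stops (ties to the
lowest frame index), and fails the record if that frame still contains
a stop. Only forward frames are screened because barcodes are
submitted in sense orientation. Codons containing gaps or ambiguity
characters are skipped rather than guessed.

Haplotype collapse is exact string identity of the gap-stripped,
uppercased sequence. No length-tolerant or ambiguity-aware collapsing
is attempted: exact identity is deterministic and order-independent,
at the cost of counting a truncated copy of a sequence as a separate
haplotype.

## Identification ranks and coded names

Regional libraries of poorly known groups carry many provisional
species — labels like "Cricotopus sp. TP1" that are stable hypotheses
within the library but not described species. Two rank semantics are
therefore exposed everywhere a species notion matters:

- **strict_public**: only a two-token Latin binomial with no
  open-nomenclature qualifier (sp., cf., nr., aff.) and no digits
  counts as species-level. Used for public-database audit metrics and
  grading eligibility.
- **permissive_local**: any non-empty species label counts. Used for
  within-library analyses (distances, BCM, habitat richness), where a
  coded name identifies a perfectly good species hypothesis.

## Threshold optimization and Best Close Match

For each sequence *i* at threshold *t*, the match set *M* holds all
other records at defined distance ≤ *t*. If *i*'s species has other
records: no conspecific in *M* → false negative; any heterospecific →
false positive; otherwise (non-empty, all conspecific) → true
positive. A species singleton is a true negative with *M* empty, else
a false positive. The three published rules overlap when *M* contains
heterospecifics but no conspecific; we resolve it false-negative-first,
which keeps the four outcomes an exact partition (their total is
constant across thresholds) and counts each sequence's failure once.
The cumulative error is FP + FN, and the **optimal threshold** is
reported as the lowest contiguous plateau of grid values attaining the
global minimum — on a library with a clean barcode gap the plateau
spans the gap; on a real library it narrows to an interval such as a
few tenths of a percent. The default grid is 0.1–10.0% in 0.1% steps,
bracketing optimal thresholds reported for this marker (0.7–2.8%
across regional chironomid libraries) at the resolution such studies
report.

**Best Close Match** considers, for each sequence, the full set of
equally closest defined matches (ties at relative tolerance 1e-9, so
analytically equal distances tie regardless of floating-point path):
farther than the threshold or undefined → no ID; all conspecific →
correct; none → incorrect; mixed → ambiguous. Considering the whole
tie set rather than an arbitrary winner is what makes "ambiguous"
well-defined.

**Barcoding efficiency** is 100 × correct / non-singleton sequences,
where a non-singleton sequence is one whose species has ≥2 records —
singletons cannot match a conspecific and are excluded from the
denominator. Published BE figures do not always state their
denominator, so the report also carries the variant over identified
(non-no-ID) sequences.

## OTU clustering and concordance

BOLD's BIN algorithm (refined single linkage) is proprietary
server-side machinery; the audit mathematics only needs *a* partition.
Provided BIN ids are therefore first-class inputs, and a threshold
clustering — single linkage (transitive closure of pairs within the
threshold) or complete linkage (agglomerative, closest pair first,
diameter capped at the threshold, ties to the smallest member id) —
stands in when no BINs exist. The default is single linkage at 2.2%,
a conventional OTU cutoff for COI. No stand-in threshold is expected
to reproduce BOLD's exact BIN counts. A cluster is *singleton* (one
sequence), *discordant* (≥2 distinct non-empty species names), or
*concordant*; empty names are uninformative and never create
discordance.

## Grading

Eligibility keeps records with a strict binomial, a BIN id and
≥500 bp. Grades follow discordance-first precedence E > C > D > A/B:
a species sharing any BIN with another species is E no matter its
record count; otherwise multiple BINs → C (even with <3 records);
otherwise <3 records → D; otherwise >10 records → A, else B. The
published grade definitions do not print a precedence for edge cases
(e.g. a 2-record species in 2 BINs); the discordance-first order
mirrors the grading tool's logic of surfacing taxonomic conflict
before sample-size concerns, and the fixtures in the test suite pin
it. BIN sharing is evaluated among eligible records only — an
ineligible record cannot create discordance, matching the stated
retention filter. Species names match case-insensitively; no synonym
resolution is attempted.

## Identity-threshold identification test

Instead of a live BLAST search against a remote database, queries are
aligned to every reference with a global aligner whose terminal gaps
are free (overlap alignment; match +2, mismatch −3, gap open −5,
extend −2, configurable), so partial barcodes align without penalty.
Identity is exact matches over alignment columns between the first and
last doubly-aligned position; internal gap columns count as
mismatches. This full-overlap identity is deterministic and
appropriate for full-length barcodes, but it is not numerically
identical to BLAST's per-HSP identity, so curves from this module are
comparable in shape, not digit-for-digit, with BLAST-based sweeps.
The top hit is the reference with the highest identity (ties: more
aligned columns, then smaller id; the query's own record id is
excluded). At each rank and threshold: identity below the threshold →
unmatched; hit lacking a usable name at the rank (at species rank,
a usable name is a strict binomial) → insufficient; otherwise correct
or incorrect against the query's own taxonomy. Proportions are
reported over matched queries, with absolute counts alongside. The
default grid is 85–100% in 1% steps.

## Synthetic libraries

The generator exists so that every stage can be validated against
known truth. Sequences evolve on a **star phylogeny** — root → species
ancestors at branch length `inter_branch` → records at `intra_branch` —
under K80 with transition/transversion rate ratio `kappa` (default 4,
typical for mitochondrial protein-coding genes). Rates are normalized
so a branch of length *t* yields an expected *t* substitutions/site;
the expected K2P distance is ~2×`intra_branch` within species (default
0.005 → ~1%) and ~2×`inter_branch` between (default 0.04 → ~8%),
matching the intraspecific (~1–3%) and interspecific (~5–15%) ranges
reported for this marker. A star tree is used instead of a birth–death
tree precisely because these expectations are exact and analytically
known, which is what the validation suite needs.

The root and all descendants are kept free of in-frame stop codons:
branch realizations creating a stop are redrawn (purifying selection —
a functional mitochondrial gene tolerates no internal stops). This
truncates the K80 process very slightly; `evolve_k80` itself remains
the pure model and its estimator-recovery tests use it directly.

Default library structure mirrors a curated regional library: ~45% of
species singletons, non-singleton sizes Poisson (truncated ≥2) around
a configurable mean, six subfamilies, weighted country and habitat
sampling. BIN truth is one BIN per species, with split mode (a species'
records partitioned over k sub-ancestors with extra divergence and
distinct BINs) and merge mode (chosen species pairs share a BIN) to
exercise grades C and E. Label corruptions are applied last, at most
one per record, and logged: **misid** replaces the full identification
(species, genus, subfamily) with another species' — the record's BIN
stays with its sequence, creating discordance exactly as a real
mislabel does; **blanked** empties the species name; **coded** turns it
into "Genus sp. SIMn". Identical configurations (including seed)
produce byte-identical output files.

What the simulations do *not* emulate: rate heterogeneity among sites
and lineages, indels, incomplete lineage sorting, geographically
structured intraspecific variation, and sequencing artifacts other
than uniform ambiguity. Passing the synthetic suite therefore shows
the pipeline's logic and estimators are correct under the stated
model, not that any particular real library has a barcode gap.

## Problem sizes in the validation suite

The test suite and the acceptance script run at desk scale by design:
random-triple checks at n = 1000; threshold-scan oracle equivalence on
50 libraries of ≤40 records; separation and misidentification-recovery
runs on 30-species and 1000-record libraries over 10–20 seeds; the
identification sweep on 60 queries of 350 bp (alignment cost grows
quadratically with length). The acceptance script simulates one
159-species / ~512-record library — the composition of the regional
library this pipeline is designed around — which takes seconds for the
distance stages and under a minute for the alignment sweep.

## Known limitations

- Positional comparison assumes aligned (length-conserved) barcodes;
  there is no built-in aligner for the distance stages.
- Single/complete-linkage OTUs approximate, but do not reproduce,
  BOLD's BIN partition.
- The misidentification-recovery analysis measures *detectable*
  mislabels: a swap affects both the swapped record and records whose
  nearest neighbor it is, so the affected fraction is larger than the
  injection rate (≈2r for small r); tests score recovery against the
  truth log rather than against r itself.
- Grading precedence (E > C > D) is a documented choice; other
  orderings exist in the wild and would shift C/D/E counts on
  borderline species.
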