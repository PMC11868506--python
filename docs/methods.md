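# Methods

This note documents the models and procedures implemented in `mycocurate`,
the parameters that matter, the design choices made where the design was
genuinely open, what the synthetic-data generator does and does not emulate,
and known limitations.

## Scope and assumptions

The toolkit starts from a *denoised* sample-by-ASV count matrix: upstream
read trimming, ITS extraction, quality filtering, per-library denoising and
chimera removal are assumed done.  Its job is what comes after — removing
residual artefacts (sequencing error, contamination, index switching),
assigning taxonomy conservatively, collapsing intraspecific/intragenomic ITS
variation into OTUs, and quantifying how well that worked.  The guiding
bias is deliberate: false positives are treated as more damaging than false
negatives, because downstream consumers (biodiversity platforms,
distribution models) are far more sensitive to spurious occurrences than to
missed ones.  The curation is therefore stringent and is expected to
underestimate diversity, particularly for rare and early-diverging taxa.

## The two-tier abundance filter

Index switching redistributes a small fraction of an abundant ASV's reads
into other samples of the same sequencing library.  Its signature is
therefore *library-relative*: a bled occurrence is small compared to the
ASV's library-wide total, regardless of how deep the recipient sample is.
Sequencing error and low-level contamination are *sample-relative*.  The
filter attacks both:

| step | rule (strict `<`) | default | targets |
|---|---|---|---|
| sample-wise | cell / sample total | 0.1% | errors, contamination |
| library-wise | cell / ASV's library total | 0.5% | index switching |

Design choices:

* **Single-pass thresholds.**  Denominators are computed once on each
  step's input; removals do not trigger recomputation.  Iterated filtering
  is a strictly harsher procedure; single-pass is reproducible, and
  idempotence is then a testable property (a second application with
  recomputed totals removes nothing on clean fixtures — verified in the
  suite).
* **Strict inequalities everywhere** (`< 0.1%`, `< 0.5%`, `< 5000` reads),
  so a cell sitting exactly on a threshold survives.  The boundary cases
  are hand-enumerated in the tests.
* **Sequential order, library-wise on the sample-wise output.**  The
  alternative (library denominators from the raw matrix) differs only
  marginally but is not what "two sequential filters" describes.
* **Controls are dropped after the filters**, so positive-control reads
  still contribute to library-wise denominators — dropping them first would
  silently change every denominator in libraries that carry controls (the
  suite contains a differential test for this).
* Plot replicates are resolved by keeping the sample with the lowest
  observed-richness / total-reads ratio (ties: higher depth, then smallest
  id) — the replicate least enriched in low-abundance artefact tails.

Rarefaction (exact multivariate-hypergeometric subsampling, seeded) to the
5,000-read floor is provided as an optional post-step and used for the
normalised output matrix; the absolute matrix remains the primary product.

Mould contamination from poor sample preservation is scored as the
cumulative relative abundance of designated mould taxa (default:
orders Mortierellales and Umbelopsidales plus genus *Trichoderma*) and
flagged where it strictly exceeds `mean + 3 SD` across samples (sample SD,
ddof = 1).  Flagging is advisory — no samples are removed automatically —
and the realised threshold is reported so users can instead apply the 35%
constant established on the original continental dataset; that constant is
dataset-specific, which is why the computed rule is the default.

## Adjusted similarity and the aligner backend

All internal scores are `identity × min(1, aln_len / min(qlen, slen))`,
identity passing through unchanged at full coverage.  This penalises short
partial alignments exactly where they mislead: a 50 bp perfect local match
between 200 bp sequences scores 0.25, not 1.0.  The formula is a package
decision (the adjustment is only qualitatively constrained by its purpose)
and is centralised in `pairwise_scoring` should a different down-weighting
be preferred.

The internal all-vs-all backend is a unit-cost global (Needleman–Wunsch)
alignment via edlib; identity is matched columns over total alignment
columns read from the extended CIGAR.  This is deterministic,
dependency-light and exact, and on the substitution-only synthetic fixtures
it reproduces Hamming identities precisely.  It deliberately does not
emulate heuristic seeded local search (word sizes, e-values); imported
12-column hit tables are the intended backend for real BLAST output, and
the suite checks that both routes agree within 0.005 on pairs with known
edit structure.

## Cut-off prediction

Thresholding pairwise similarity induces a binary classifier of "same taxon
at rank r" over all unordered sequence pairs in an evaluation set; the
predicted cut-off maximises F-measure over the grid 0.500–1.000 (step
0.001), with 0/0 ratios defined as 0.  Ties are broken toward the
**largest** threshold: on a clean fixture the F = 1 plateau spans the gap
between the largest between-taxon score and the smallest within-taxon
score, and the conservative end of that plateau is its top.  The best F is
reported as the entry's confidence.

Eligibility for a local (supertaxon-scoped) prediction: at least 10
distinct taxa **and** at least 30 sequences in total, with no single taxon
holding ≥50% of them.  The total-count reading was chosen over the
per-taxon-≥30 reading, which would disqualify nearly every local scope at
realistic database sizes; the strict reading remains available via
`min_seqs_per_taxon`.  Local predictions for each supertaxon–subrank
combination are computed across all higher ranks (species cut-offs for a
genus are predicted within the genus, its family, order, class and phylum),
and the retained entry per combination is the highest-confidence candidate,
ties resolved toward the most specific scope.  Where no local entry exists,
global entries per phylogenetic group (Dikarya; terrestrial early-diverging
fungi; zoosporic fungi) cover ranks class→species — a single all-fungi
global is dominated by Dikarya and misfits the early-diverging groups.
Phylum-level cut-offs are predicted over all fungi, and the kingdom-level
entry is derived from the all-fungi phylum entry by copying (the minimal
reading of "derived from").

For scopes above ~2,000 sequences the O(n²) pair set is subsampled
uniformly with a fixed seed (`max_pairs`, default 200,000).

## Consensus assignment

Per ASV, the top five hits (adjusted score descending; ties by coverage,
then subject id) are collected independently against the full reference
database and its species-only subset.  Rank by rank, kingdom→species:

1. hits are filtered by the most specific applicable cut-off entry for the
   *subject's* lineage (fallback: ancestors → phylogenetic-group global →
   all-fungi) and by coverage floors of 0.90 at genus and 0.95 at species;
2. the evaluation pool is the surviving species-only hits if any, else the
   surviving combined hits (per-rank preference — the species-only subset
   carries the curated names and should win whenever it can speak);
3. the modal name is accepted iff its share of the pool is **strictly
   greater than 2/3**.  "Over 66%" is read as a prose rounding of
   two-thirds; the strict reading makes 2-of-3 a boundary failure, the
   conservative direction.  The share denominator is the whole pool, so
   hits unidentified at the rank vote against consensus.

The first failing rank truncates the lineage there, guaranteeing monotone
lineages (never a species without its genus).  Raising any cut-off can only
remove assignments (anti-monotonicity; property-tested).

Trait annotation joins on genus against a FungalTraits-like table, with one
override: every Glomeromycota lineage is annotated arbuscular mycorrhizal
regardless of genus match, since most members of that phylum resist
genus-level ITS assignment yet the guild is phylum-wide.

## Nested clustering and pseudotaxa

Clustering runs kingdom→species; within each rank-(r−1) cluster, the
rank-r cut-off comes from the cut-off table looked up on the parent's
lineage, with coverage floors of 0.90/0.95 at genus/species and none above.

*Closed-reference pass*: ASVs named at r seed cores; each unassigned ASV
whose best qualifying score against **any current core member** clears the
cut-off joins that core.  All cores compete simultaneously within a pass
(batch update; ties: highest score, then larger core, then smallest taxon
name) and passes repeat to a fixpoint, so chains a–b–c form approximate
single-linkage clusters and the result is independent of update order.
Scoring against all members rather than only the original seeds is the
natural reading of single-linkage growth.

*De novo pass*: the residue is clustered as connected components of the
thresholded similarity graph (exact single linkage), each component named
`pseudo_<rank>_<anchor>_<serial>` where the anchor is the deepest named,
non-pseudo taxon of the parent lineage.  Serials are allocated per rank in
canonical order (clusters sorted by smallest member id), which makes names
stable under permutation of the input — the suite asserts full
order-invariance including names.

Species-level clusters become OTUs; the representative is the member with
the highest total count (ties: smallest id).  ASVs unidentified at kingdom
are clustered under a synthetic root so non-fungal residue can be
segregated and optionally dropped.  After every rank the partition property
(no orphan, no overlap) is asserted, and the rank-r partition refines
rank-(r−1) by construction.

## The synthetic-data generator

The generator emulates, at desk scale, exactly the structures the curation
method exists to handle:

* **Reference database** — a taxonomy tree with ancestor sequences per
  clade; each branch mutates `L·(R_parent − R_child)/2` positions so two
  sequences whose most recent common ancestor sits at rank r diverge by
  ≈ the planted radius `R_r` (defaults 0.005 / 0.03 / 0.08 / 0.12 / 0.16 /
  0.22 for species→phylum, 0.30 between phyla).  The default marker length
  is 800 bp — longer than real ITS1 (~177 bp) — so the smallest radius is
  exactly representable in whole substitutions (2 per branch); this is a
  fixture-resolution choice, not biology.  A fraction of entries per genus
  (default 10%, every 10th entry) is stripped to genus level to populate
  the full-database-only stratum that exercises the species-only
  preference.  The default shape includes a data-rich ectomycorrhizal genus
  (12 species × 3 sequences — locally eligible at species rank), a
  10-genus family (locally eligible at genus rank), the mould taxa, and
  representatives of all three phylogenetic groups.
* **Communities** — 4 libraries × 24 samples by default; specimen
  communities draw 25–40 taxa with log-normal (σ = 1) abundances,
  multinomially scaled to depths of 12,000–20,000 reads; each library
  carries two positive controls seeded with exactly 10 mock taxa at
  near-even abundance, and six "Antarctic" samples whose taxon pool
  excludes ectomycorrhizal genera entirely — so any ECM occurrence there is
  an index-switching artefact by construction.  One plot per library is
  sampled twice to exercise replicate resolution, and two samples receive a
  50% mould spike.
* **Bleed** — per library and ASV, `floor(rate·T/fanout)` reads (default
  rate 0.3%, fanout 10) are added to each of `fanout` uniformly chosen
  samples not truly containing the ASV, deducted from the dominant source
  cell; totals are conserved exactly and every bled cell is recorded in the
  ground truth (`SimTruth`), making filter recall/precision directly
  measurable.  ASVs too rare to yield at least one read per recipient do
  not bleed — matching the empirical pattern that tag-jumping is a
  phenomenon of abundant sequences.

All randomness flows from one seed; identical configs give byte-identical
matrices, FASTA and truth.  What the generator does **not** emulate:
read-level artefacts (quality scores, chimeras, PCR bias), indels (the
default mutation model is substitutions-only so identity arithmetic stays
exact; an ASV-level noise knob exists), within-species ASV radiation (one
ASV per species by default), or the taxonomic breadth and imbalance of a
real reference database.  Passing tests therefore demonstrate that the
*rules* behave exactly as specified and that the method recovers planted
structure under its own assumptions — not that real soil data are this
clean.

## Diagnostics

* Rarefaction curves: exact multivariate-hypergeometric subsampling,
  mean ± SD over seeded replicates; depths beyond the sample total are
  skipped with a warning.
* Depth–richness: ordinary least squares of richness on log10(depth) per
  region, reported as R² in percent.  Plain OLS, no covariates or mixed
  models; constant-depth groups are reported as undefined rather than 0.
* Mock-community check: observed richness per positive control against the
  seeded expectation (run before controls are dropped).
* Environmental-control check: the count of (sample, OTU) presence pairs of
  a guild (default ectomycorrhizal) in a host-free region (default
  `antarctica`).  Occurrence means presence (cell > 0).  On fully curated
  synthetic data this count is exactly 0 — the in-silico analogue of
  finding no ECM occurrences where no hosts exist.

## Numerical choices and degenerate inputs

* Percent identity is normalised to [0, 1] at parse time; one unit system
  throughout.
* F-measure 0/0 conventions: precision, recall and F are 0 when undefined.
* Zero-total samples pass through the sample-wise filter empty with a
  warning; ASVs with zero library totals are no-ops in the library-wise
  filter.
* Rarefaction refuses samples below the target depth (direct users are
  pointed at `drop_low_depth`); a sample at exactly the target depth is
  returned unchanged.
* `mean + 3 SD` uses sample SD; with one sample the SD term is 0 and
  nothing can exceed the threshold strictly.
* All tie-breaks (hit ranking, core competition, replicate resolution,
  representative choice, grid ties) are total orders, so every output is
  deterministic and order-invariant.

## Problem sizes

Tests and the acceptance script run the full study design (4 × 24 samples,
~165 reference sequences, ~65 ASVs) in seconds on one core; cut-off
parameter recovery uses 20 seeded replicate databases of a compact
single-phylum shape.  These sizes were chosen so the entire validation
battery stays interactive at the desk; all operations scale to larger
inputs, with `cutoffs.max_pairs` bounding the quadratic pair enumeration.

## Known limitations

* The adjusted-similarity formula and the internal aligner are reasonable,
  documented choices, not canonical definitions; imported hit tables are
  authoritative when available.
* Consensus counts hits, not unique reference taxa, so a species
  over-represented in the reference database carries more votes.
* The kingdom-level cut-off is a copy of the all-fungi phylum entry; no
  attempt is made to calibrate a true inter-kingdom threshold.
* Cut-off monotonicity across ranks (deeper ⇒ stricter) is checked as a
  sanity property on well-separated synthetic databases but is not
  guaranteed — and should not be assumed — on real references.
* OTU-level curation (re-running the filters on a clustered matrix) is
  supported but the primary order is curation at ASV level before
  clustering.
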