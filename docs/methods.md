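# Methods

This note documents the models and procedures implemented in mirevokit,
the assumptions behind them, the parameters that matter, and the
limitations of the synthetic test bed.

## Read preprocessing

Reads are normalized to uppercase DNA (U→T) on input; miRNA report
writers can render RNA again. Adapter removal uses leftmost
suffix(read)/prefix(adapter) matching: the first candidate position
(scanning 5'→3') where the overlap is at least `min_overlap` (default
6 nt) with a mismatch fraction at most `max_mismatch_frac` (default 0.1)
defines the insert; full internal adapter occurrences trigger trimming
the same way. Inserts shorter than `min_len` (default 18 nt, the usual
small-RNA lower bound) are discarded. Reads without an adapter match are
kept and flagged untrimmed by default (configurable): a read already at
insert length carries real signal, and the aligner's end-to-end contract
bounds the damage if residual adapter remains. Collapsing replaces
identical sequences by one tag `lib_<rank>_x<count>`, ranked by count
descending with lexicographic tie-break, so collapsed output is invariant
to input order. Quality scores are parsed for format validation only.

## Short-read alignment

The mapper is a contract re-implementation of the ungapped end-to-end
semantics used throughout small-RNA work: report **all** placements whose
mismatch count equals the minimum over every placement within
`max_mismatch` (best stratum, all hits), optionally sense-strand only.
`N` counts as a mismatch on either side, so N-containing reads can never
align exactly — the simplest consistent rule for keeping them in the data
without letting them match.

Candidates come from pigeonhole seeding: the query is split into
`max_mismatch + 1` evenly spread blocks; any placement within the bound
leaves at least one block mismatch-free, and the k-mer (k = 6) at that
block's start is then an exact hit in the target index. Queries shorter
than `(m+1)·k` fall back to scanning every offset. Every candidate is
verified by recounting mismatches, so seeding can only propose, never
decide. Reads of 18–26 nt against precursor- or ncRNA-scale references
make this exhaustive search cheap; the unit and acceptance suites check
exact agreement with a brute-force Hamming oracle over all offsets and
strands. Ties across targets are all reported; output order is
(target_id, start, strand) for determinism.

## Filtering and expression profiling

Filtering against the annotation database (rRNA, sc/sn/snoRNA, tRNA,
coding) discards a read iff it aligns on either strand within
`max_mismatch_db` (default 2, configurable 0–3). Profiling against known
precursors is sense-only with at most 1 mismatch. A read contributes its
full collapsed count to **every** best-stratum precursor it hits,
mirroring all-hit reporting; this over-counts multi-mapped families but
is deterministic and order-free (fractional allocation would require an
arbitrary tie policy and is left to downstream analysis). A read is
assigned to the 5p or 3p mature arm when at least 50% of its length
overlaps that arm's interval, else it counts as unassigned
(loop/star/offset reads). The 50% rule makes assignment unambiguous:
a read can reach 50% overlap with at most one arm of a valid annotation
(5p interval precedes 3p).

## MAF homolog extraction

Coordinates are 0-based half-open forward-strand everywhere internally;
MAF rows keep the native strand-relative convention and convert at the
boundary. MAF I/O goes through Biopython; block invariants (equal row
lengths, non-gap count = size, start+size ≤ srcSize) are validated after
parsing since the underlying parser does not enforce them.

Precursor placement replaces an external aligner with an internal
locator: exact substring search on both strands first, then a seeded
(k = 11) ungapped scan accepting ≥ 95% identity over the full precursor
length. Placement must be unique-best; ties raise an ambiguity error
listing all loci rather than silently picking one (paralogous clusters
need explicit curation, not a guess).

Region excision returns, per overlapping block, exactly the columns from
the first to the last column whose reference character is a non-gap base
inside the query interval; interior reference-gap columns (insertions in
other species) are retained. Stitching concatenates sliced blocks in
reference order, pads species missing from some blocks with gap columns
(flagged `partial`), and flags species in no block `absent`. Blocks are
assumed single-coverage on the reference (multiz-style); overlap is an
error, not silently resolved. Species names are the MAF `src` prefix
before the first dot.

Ortholog screening retains (precursor, species) pairs with identity
≥ 0.90 over coverage > 50 nt and ≥ 10 supporting reads — all three
thresholds configurable.

## K2P distances

Per column of a pairwise (gapped) alignment: both bases ACGT → match,
transition (A↔G, C↔T) or transversion; any gap → gap column; anything
else → ambiguous column. Gap and ambiguous columns are excluded from
numerator and denominator (pairwise complete deletion, the standard K2P
convention). With P and Q the transition/transversion proportions over
the n compared columns,

K = −½·ln((1−2P−Q)·√(1−2Q)).

When a log argument is non-positive the estimate is flagged saturated
and no numeric distance is reported. Identity is matches/n and n is
reported as coverage, so downstream screening can enforce the 50-nt
rule; distances on partial homologs are computed over covered columns
only. Regions: the full precursor, each annotated mature arm, and the
seed (mature positions 2–8, 1-based — the dominant convention; the slice
is configurable). Arm intervals live on the ungapped reference precursor
and are projected through the gapped reference row; region distances for
non-reference pairs are available behind an `all_pairs` flag.
K_mir/K_s takes K_s as user input; estimating synonymous divergence from
coding alignments is out of scope.

## Hairpin structure

Folding is a Nussinov-style dynamic programme maximizing total pair
weight (GC = 3, AU = 2, GU = 1) over non-crossing structures with a
minimum hairpin loop of 3 nt. This is a deliberate stand-in for
thermodynamic nearest-neighbour folding: it captures stem-loop topology
and relative pairing strength deterministically, with no parameter
tables, and an externally computed dot-bracket string can be supplied
anywhere a fold is accepted (`fold_from_bracket`). Traceback resolves
co-optimal structures deterministically (pair the interval ends first,
then partners in ascending order, then leave the left end unpaired).
Correctness is checked against exhaustive enumeration of all valid
structures for short sequences.

Projected structures re-insert `-` at each species' gap columns so
bracket strings align column-wise with the sequence alignment; per-base
read coverage over a precursor is the count-weighted sum of overlapping
reads.

The hairpin plausibility filter checks length bounds, score per
nucleotide (proxy for stability), terminal loop length, and the paired
fraction of annotated mature arms. Preset thresholds — animal: length
50–150, loop ≤ 30, score/nt ≥ 0.5, mature paired fraction ≥ 0.6; plant:
length 60–300, loop ≤ 150, otherwise equal — are provisional defaults
chosen from the typical size range of animal vs plant precursors, and
every threshold is exposed in configuration.

## Expression comparison

Each species' reads are mapped (sense-only, ≤ 1 mismatch, best stratum)
to that species' own homolog sequences; arm intervals are projected
through the alignment columns into species coordinates. The
normalization total N defaults to reads mapped to the homolog reference
set ("total mapped reads" in its narrowest reading); external totals
(e.g. genome-mapped) can be supplied instead. Note the compositional
caveat of any mapped-total normalization: strong changes in a few arms
shift the denominator and induce apparent opposite changes elsewhere.

The two-group Poisson LRT is computed in closed form — identical in
likelihood to a Poisson GLM with log offset and a group indicator, with
no iterative fitting: ê_i = N_i(x₁+x₂)/(N₁+N₂),
G = 2Σ x_i ln(x_i/ê_i) with 0·ln 0 ≡ 0, p from χ²₁. When x₁+x₂ = 0 the
test is undefined and returns p = 1 with a degenerate flag. 5p and 3p
arms are tested separately; Benjamini–Hochberg q-values are computed
over all tested arms and significance defaults to q < 0.05 (raw-p mode
available). Scatter output uses log₂ TPM with a one-read pseudocount so
zero counts remain plottable; the test itself always uses raw counts.
Overdispersion is not modelled (no biological replicates in the
two-library design); a negative-binomial extension is future work.

Method-comparison counts (how many orthologs each of two approaches
detects out of a common candidate set) are compared with Pearson's
chi-square with Yates continuity correction at 1 df.

## Novel-miRNA crosscheck

A candidate mature is reported against a known catalogue entry when the
7-nt seeds (positions 2–8) are identical **or** global mature identity
exceeds 0.8 — inclusive OR, with the fired rule recorded so stricter
post-filtering remains possible. Identity is matches over alignment
columns of the best global alignment (match 1 / mismatch 0 / gap −1,
used for alignment only); an option point left open — identity over the
shorter sequence — can be recovered by rescaling and was not taken,
because column-based identity penalizes indels symmetrically.

## Synthetic test bed

The generators emulate the pipeline's inputs at desk scale: a random
genome at configurable GC content with planted perfect stem-loop
precursors (stem 30 nt, loop 8 nt, mature arms 22 nt one base in from
each end); an ortholog genome mutated per site with transition
probability p* = 0.10 and transversion probability q* = 0.05 (the
canonical recovery setting over 10 kb), optional 1–3 nt indels that by
default avoid planted precursors so arm projection stays exact; a
reference-threaded MAF in blocks of ≤ 500 columns; and read libraries
whose per-arm counts are Poisson(rate·depth) with 0–2 nt end wobble,
appended 3' adapter, truncation to 36 nt, and optional contaminant reads
drawn from decoy ncRNA sequences. Default library depth is 2,000 with a
base arm rate of 0.02 and two 4-fold up-regulated 5p arms in the second
species — sizes chosen so a full two-species run completes in about a
second while every planted signal sits well clear of Poisson noise.

What the simulations do **not** contain: sequencing errors and quality
variation, expression-dependent length heterogeneity, repeat structure
and paralogous families, lineage-specific insertions near mature arms,
and realistic WGA artifacts (rearrangements, low-complexity
misalignment). Passing tests therefore demonstrate algorithmic
correctness against the stated contracts and statistical calibration
under the generative model — not robustness to every artifact of real
libraries and real whole-genome alignments.

## Numerical and design notes

- All randomness flows through seeded NumPy generators; pipeline stages
  derive independent streams from the run seed, and re-running a config
  reproduces byte-identical outputs (checksummed in the manifest).
- The LRT statistic is clamped at 0 against floating-point cancellation;
  k2p returns `None` (saturated) rather than NaN so table code must
  handle missing distances explicitly.
- Tie-breaks are deterministic everywhere: collapsed-read ranking,
  aligner output order, fold traceback, stage ordering.
- Degenerate inputs fail loudly: empty adapter, zero-margin contingency
  tables, empty libraries, ambiguous precursor placement, overlapping
  reference blocks.

## Known limitations

- Probabilistic novel-miRNA discovery is out of scope; leftover reads
  are exported for external predictors, and predictions are only
  crosschecked here.
- The folding DP is not a free-energy model; borderline hairpin-filter
  decisions should be re-run with imported MFE structures.
- Pairwise species comparison only; no joint multi-species test.
- Whole-genome alignment construction is consumed (MAF), never built.
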