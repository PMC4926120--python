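# Methods

`barcodiag` implements the computational side of a DNA-barcoding diagnostics
workflow for closely related insect pests: build a COI barcode reference
library, quantify its divergence structure, delimit candidate species from
the barcode gap, and design and screen species-specific PCR and TaqMan
assays against the library. This note records the models, the defaults and
the design choices, in the order the pipeline runs.

## Distances: the Kimura 2-parameter model

All pairwise comparisons use the K2P model, the de-facto standard for
animal barcodes. For two aligned sequences, sites where either carries a gap
or an IUPAC ambiguity code are excluded (pairwise deletion, the common
default of distance software; complete deletion is available via
`pairwise_matrix(..., deletion="complete")`). With transition proportion
`P` and transversion proportion `Q` over the `n` compared sites,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)   [substitutions/site]

When a log argument is non-positive (`1-2P-Q <= 0` or `1-2Q <= 0`) the
estimate is *saturated*: the pair is recorded as a missing value with a
warning rather than raising, so downstream summaries degrade gracefully on
extreme user data. Saturation cannot occur below roughly 40% divergence and
is never triggered in the regime this toolkit targets (< 23%).
Nearest-neighbour classification treats a saturated query-library distance
as infinitely far.

Divergence summaries report per-species intra- and inter-specific
average/min/max in percent. The per-species intra average is the plain mean
over that species' within-species pairs; values are kept at full precision
internally and rounded to two decimals only at the presentation layer.
Classification assigns a query its nearest neighbour's species when the
best distance is at most 2% (roughly an order of magnitude above typical
mean intraspecific COI variation), returns "ambiguous" when a second
species lies within 0.1 percentage points of the best, and "no-match"
otherwise; both thresholds are arguments.

## Haplotypes

Haplotype collapsing is a strict exact-sequence match over the full aligned
length, per species (identical sequences under two species labels are never
merged — labels are trusted input — but a warning is emitted). The
`exclude_ambiguous_columns` option first masks every column containing a
gap or ambiguity in any record, mirroring the "exclude sites with
gaps/missing data" behaviour of popular polymorphism software.

## Neighbour joining and bootstrap

Tree building is the classic Saitou–Nei agglomeration on the K2P matrix
with the standard Q-criterion. Ties in Q are broken deterministically by
the lowest (row, column) pair in the current matrix order, which follows
the input label order; because tie-breaking conventions differ between
implementations, topology equality with other software is only expected on
matrices without Q-ties. Negative branch-length estimates (a routine
artefact of NJ on noisy matrices) are clamped to zero with a warning.
Trees are unrooted (degree-3 seed node); an outgroup option re-roots a copy
for display only. Newick serialisation and parsing go through dendropy,
with bootstrap supports written as internal-node labels.

Bootstrap resamples alignment columns with replacement (seed mandatory),
rebuilds matrix and tree per replicate, and reports for each internal edge
of the original tree the percentage of successful replicates containing the
same leaf bipartition; replicates whose resampled matrix saturates are
skipped and excluded from the denominator.

## Barcode-gap discovery

Partitioning follows the automatic-barcode-gap idea: given a prior `P`
(maximum presumed intraspecific divergence, a proportion) the sorted
pairwise distances are scanned for the first interval `(d_i, d_{i+1})`
whose upper edge lies above `P` and whose width exceeds

    X * max(local mean spacing, min_slope)

where the local mean spacing is the average gap between distinct distances
at or below `d_i` (the global mean spacing is used before two distinct
values have accumulated), `X = 1.5` is the widely used relative-gap-width
default, and `min_slope = 0.01` substitutions/site floors the estimate so
that near-duplicate distances at the bottom of the distribution cannot
promote an arbitrarily narrow interval to a "gap". The reported gap's lower
edge is clamped up to `P`. Sequences are then linked single-linkage at the
gap's lower edge; connected components become groups, and the scan recurses
within each group (depth-capped at 10 to guarantee termination). Without an
initial gap the library is a single group.

The floor means gaps narrower than `X * min_slope` = 1.5% cannot be
detected. That is intentional: the method is meant for libraries whose
intraspecific distances sit below ~2% and interspecific distances above
~16%, where the gap is an order of magnitude wider than the floor and the
partition is insensitive to the exact slope statistic. Published
gap-discovery implementations use a more elaborate sliding slope estimate;
with a gap this wide all reasonable variants give identical partitions,
which the recovery property tests verify for priors across 0.1%–5%.

## Oligo thermodynamics

GC content, the Wallace rule (`2(A+T) + 4(G+C)`), and nearest-neighbour
melting temperatures. The NN model uses the unified DNA parameter set as
shipped with Biopython's melting-temperature module, the entropic salt
correction `dS += 0.368 (N-1) ln[Na+]`, and

    Tm = dH / (dS + R ln(C_T/4)) - 273.15

Defaults: 50 mM monovalent salt, total oligo concentration 250 nM
(`thermo.DEFAULT_PARAMS`). A second preset, `thermo.QPCR_PARAMS`
(0.25 M monovalent-equivalent, 0.2 uM primer), represents probe-qPCR
master-mix conditions: the Mg2+ contribution is folded into a single
monovalent-equivalent term (no separate divalent correction is modelled).
Published Tm columns from design software are treated as approximate
reference points: the package's test suite bounds the NN estimate within
+-6 C of each published value under that assay's own conditions, rather
than reproducing any proprietary formula exactly.

Secondary-structure screening (hairpins, self- and cross-dimers) is an
exhaustive ungapped register scan: every alignment register of one oligo
against the reverse of the other (or stem against downstream stem, loop
>= 3 nt) is scored by summing stack free energies at 37 C over contiguous
complementary runs of at least 3 bp, plus terminal initiation penalties.
Hits with |dG| >= 3 kcal/mol are reported, worst first. No
suboptimal-folding ensemble or partition function is computed; at primer
lengths (18–30 nt) the exhaustive register scan matches what interactive
design tools report.

## Assay design and the criterion reports

A column is *diagnostic* for a target species when the target is fixed for
one unambiguous base that no other species carries in that column. Primer
design enumerates windows whose 3'-terminal base is diagnostic (the
polymerase extension end is where a mismatch suppresses amplification),
evaluates every candidate, and pairs candidates within the product
(100–600 bp) and Tm-difference (5 C) windows.

Criteria are evaluated as explicit reports, not silent filters — published
assays violate individual rules, and the evaluator's job is to surface
that:

* **Endpoint primers (SP1–SP8):** length 18–30; worst structure
  |dG| < 9 kcal/mol; >= 1 diagnostic base within the 3'-terminal 5 nt;
  no hairpin with stem >= 4; GC 30–70%; footprint covers a diagnostic
  position; false-priming score < 100; Tm within 45–65 C.
* **Probes (PR1–PR7):** length 18–30; C count >= G count (else the report
  says to use the reverse complement); GC 30–80%; no 5' G (quenches the
  reporter); no GGGG run (hard; other 4-runs warn); probe 5' end within
  15 nt of the forward primer's 3' end; no probe–primer structure with
  |dG| >= 9.
* **qPCR pairs (QP1–QP6):** lengths within 4 nt of each other, each
  18–30; GC 40–60%; no 3'-terminal A; no GGGG; 3' end not closing with
  three G/C; no cross-dimer with |dG| >= 9.

The false-priming score is 100 x the best ungapped identity of the primer
against any same-orientation window of any library sequence outside its
intended site, counting only windows whose 3'-terminal 3 nt match exactly;
"< 100" therefore means no perfect unintended priming site. The intended
site is exempt only on target-species sequences: a perfect hit at the same
coordinates on another species is false priming. This deterministic score
captures the intent of the proprietary metrics interactive tools report.
All thresholds live in one `DesignConfig` block; the 5-nt 3' window and the
15-nt probe gap default were chosen so that all published designs are
accepted. Criteria that need library context (SP3, SP6, SP7) are reported
as "skipped" when an oligo is evaluated without one; a report's overall
verdict is the conjunction of its evaluated hard criteria. Among passing
designs the ranking key — criteria passed, then Tm balance — is a
convention; no canonical search order exists for this task.

Coordinates are 1-based, inclusive, on the plus strand of the reference
barcode throughout, matching the primer-name encoding
`<prefix><start><F|R><length>` (a name like `Tde25F20` binds 25–44 and the
product of a pair is `rev_start + rev_len - fwd_start`).

## In-silico PCR

A primer binds where a template window matches with at most 2 mismatches
and zero mismatches in the 3'-terminal 3 nt (both knobs exposed); IUPAC
codes in the primer match their base sets and never count as mismatches.
Site finding is mismatch-count only — no annealing thermodynamics; Tm
reasoning lives in the design module. Every plus-strand forward site paired
with a downstream minus-strand reverse site yields an amplicon (length
measured over the outermost primer bases, bounds 50–2000 bp). The
species x pair grid marks a pair *specific* when it amplifies at least one
sequence of its target and none of any other species; a plain-text
"virtual gel" renders the grid one lane per library member group.

## The simulator

`fixtures.simulate_library` generates aligned libraries that emulate the
divergence structure of a multi-species stored-product-pest barcode study:
six species x four sequences x 658 bp by default, intraspecific K2P <= ~1%
(target `intra = 0.01`), interspecific ~19% (target `inter = 0.19`),
AT-rich ancestral composition (A 30.0%, C 22.5%, G 16.2%, T 31.3% — the
composition of insect mitochondrial COI), transition:transversion odds
kappa = 2, and two 12-nt species-unique diagnostic windows per species with
recorded positions. Substitutions are placed by count, not per-site
Bernoulli draws, so realised divergences are controlled — the distances,
not the mutation process, are the object under test. The founder mutation
rate is calibrated analytically (a Jukes–Cantor-style inversion of the K2P
target minus the planted-window contribution, with a collision term), and
realised divergences are checked against the targets (+-20%-ish bands) with
up to 10 resampling attempts. Seeds are mandatory and the output is
byte-reproducible per seed.

What the simulator does *not* emulate: indels and alignment uncertainty,
rate heterogeneity along the sequence, shared polymorphism or
introgression between species, sequencing error, and chance similarity of
primer sites to off-target genomic sequence beyond the library itself.
Passing the end-to-end tests therefore demonstrates the machinery —
distances, gap partitioning, diagnostic-site detection, criterion
evaluation, in-silico screening — not the field performance of any primer
on real specimens. Note also that on simulated (as on real) data the
diagnostic-site detector legitimately finds more sites than were planted:
founder mutations create additional species-unique columns by chance; the
planted windows are guaranteed, not exhaustive.

## Problem sizes and reproducibility

Default test and acceptance runs use libraries of 6 species x 4 sequences
x 658 bp (24 sequences, 276 pairs), 100 bootstrap replicates, and recovery
checks over 2–8 clusters — sizes at which every stage completes in seconds
while exercising the same code paths as larger libraries. All randomness
flows through explicit integer seeds; identical seeds give byte-identical
FASTA, TSV and Newick outputs.

## Known limitations

* Distance models other than K2P (JC, K3P, GTR) are out of scope, as are
  likelihood/Bayesian trees and haplotype networks.
* The gap detector cannot find gaps narrower than 1.5% divergence (by the
  `min_slope` floor); it is not a general species-delimitation method.
* Structure screening has no folding ensemble; a strongly structured oligo
  could in principle score better than its true ensemble dG.
* In-silico PCR has no primer-efficiency or band-intensity model and does
  not simulate qPCR amplification curves or detection limits.
* Multiplex compatibility between assays is not optimised.
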