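# Methods

## The heuristic biosensor model

`tfbscreen` predicts transcription-factor-based biosensors from a purely
genomic signal: if a bacterium catabolizes a metabolite through a chain
of enzymatic steps, those enzymes are often co-transcribed as an operon,
and the transcription factor that senses the metabolite is often encoded
divergently at the operon's promoter side. The pipeline therefore never
inspects protein sequence or predicted binding sites; it ranks
regulator–operon pairs by gene-neighborhood geometry alone. This is a
heuristic: regulators encoded elsewhere (e.g. global regulators
controlling multiple transcription units), operons serving transport
rather than catabolism, and gaps in the reaction knowledge base all
produce misses, and a high score is a prioritization signal, not a
validation.

## Chain enumeration

Reactions are traversed strictly in their written left-to-right
direction. This is deliberate: a compound that the knowledge base lists
only as a product (as happens for one mandelate enantiomer, which
appears only as the racemase's product) yields no chains, reproducing
the behavior of direction-faithful mining. `--treat-reversible` adds the
right-to-left reading for callers who want it.

The expansion is depth-first with reactions and products visited in
lexicographic id order, so output order is deterministic. Each product
of a reaction spawns an independent continuation; co-products are
recorded on the step but not traversed within the same chain. A chain
never revisits a compound on its own consumed path (seed included),
which terminates trivial cycles. Cofactor-regeneration continuations
(e.g. a second step that only converts ADP back to ATP) are *not*
filtered by default, because no principled local rule distinguishes them
from genuine catabolic steps; callers can pass a currency-compound
exclusion list (`--exclude-compound`, default empty). Chains are
deduplicated by ordered EC sequence, keeping the first-found reaction
assignment; partial EC numbers (`1.1.1.-`) are retained in reaction
records but excluded from chain steps by default since they carry no
reliable gene linkage. Enumeration is capped at 10,000 chains (warning
on truncation) to bound combinatorial blowup on hub metabolites.

## Operon detection

Feature tables follow the NCBI Assembly dialect: tab-delimited, 1-based
inclusive coordinates, CDS rows only are used, rows without a locus tag
dropped. Genes are indexed densely per replicon after sorting by start,
and all distances are counted in gene-index space.

A chain's genes form an operon candidate when they share a replicon and
strand and no two genomic neighbors are separated by more than
`gap_tolerance` non-member genes. The default of 2 is a design choice:
tight enough to imply co-transcription, loose enough to tolerate small
unannotated ORFs or missed operon members. Intra-operon gene order is
*not* required to match chain step order (bacterial operons frequently
scramble pathway order); `--require-collinear` enables the stricter
rule. The operon's upstream gene is its 5′-most member (smallest start
on `+`, largest end on `-`) — the promoter side. Gene-copy combinatorics
(paralogs matching one step) are enumerated tightest-genomic-span first
and capped at 50 assignments per organism per chain.

Locus-tag matching between knowledge-base gene ids and feature-table
locus tags is case-insensitive exact string matching; mismatches are
logged per organism and simply drop that organism from the chain.

## Regulator search and proximity score

The search walks gene indices upstream of the operon's upstream member
only (the divergent-promoter side); `--search-both-sides` relaxes this,
with ties preferring the upstream side, then the lower start coordinate.
A gene counts as a regulator when its annotation contains any configured
keyword as a case-insensitive substring (default: "regulator",
"activator", "repressor"). Known limitation: prefixed annotations such
as "antirepressor" also match; the keyword list is configurable when
that matters.

The score for a pair is 0 minus 1 per intervening operon-strand gene
and minus 2 per intervening regulator-strand gene (operon-strand genes
are penalized less because they may simply be unrecognized operon
members), clamped at the floor of −500. The scan itself runs to the
replicon end — the clamp, not the scan, enforces the floor, so a
regulator behind 600 same-strand genes is still found and scored −500.
The mining pipeline drops a candidate whose *unclamped* deduction
exceeds the floor, so written reports contain scores in [−500, 0] with
raw deductions beyond the floor excluded. Only CDS features count as
intervening (RNA genes and pseudogenes are not loaded).

## Dose–response characterization

Raw readings are corrected by subtracting the cell-free medium blanks
from both fluorescence and OD600, then normalized as
`(F − F_blank)/(OD − OD_blank)`; points with non-positive corrected OD
are flagged invalid and excluded. Uninduced samples enter the fit at
concentration 0.

The Hill fit is nonlinear least squares over the 4-parameter model with
deterministic initialization: `b0 = min(y)`, `bmax = max(y)`, `Km` at
the log-interpolated dose of half-span response, `h = 1`; bounds
`h ∈ (0, 10]`, `Km ∈ (0, 10·max dose]`, and `b0`/`bmax` within one span
of the observed response range. At least 5 valid points are required;
constant responses and non-convergence raise an explicit fit failure
with diagnostics rather than returning garbage. The residual norm is
reported with the parameters.

The operational range uses the fractional response relative to the
`bmax − b0` span with `b0` subtracted, so
`I(f) = Km·(f/(1−f))^(1/h)`; with symmetric fractions the algebraic
identity `I(f)·I(1−f) = Km²` holds and is property-tested to 1e-9
relative. This span-relative convention reproduces the published bounds
(42–665 µM at h = 2.13, Km = 167 µM; 32–270 µM at h = 2.76, Km = 93 µM)
exactly after integer rounding, which validates the choice.

## Synthetic data

The simulators generate exactly what the screening logic consumes —
coordinates, strands, locus tags, annotations — and nothing it does not
(no nucleotide or protein sequence, no RNA features, single-replicon
genomes by default). Decoy annotations come from a keyword-free enzyme
vocabulary, so negative-control genomes cannot produce keyword hits by
construction; a separate adversarial pool with regulator-like decoys
exists for stress tests. Planted-operon truth scores are computed from
the planted arrangement by the same deduction formula, which is what
makes end-to-end recovery a meaningful check of the plumbing, not of the
formula itself. Consequences for interpretation: passing tests show the
pipeline recovers architectures it models, on annotations it can match
exactly; they say nothing about annotation noise, split/merged CDS
calls, multi-replicon paralogy or keyword vocabulary drift in real
assemblies.

Dose–response simulation applies mean-preserving multiplicative
log-normal noise (σ² = ln(1 + CV²), centered so the expected value lies
on the curve) to the normalized response and reconstructs raw
fluorescence so that blank correction and OD normalization invert it
exactly. The default assay emulates a 12-point log-spaced titration over
7.8125–2000 µM with basal output 50, maximal output 5000 (arbitrary
fluorescence units), 2 % CV and 3 replicates — a typical plate-reader
regime. Under those conditions the fitter recovers Km with a median
relative error well under 10 % across 20 seeds (measured in the test
suite, not asserted here).

Problem sizes throughout the suite are desk-scale by design: the
worked-example knowledge base has 4 reactions, simulated genomes have
20–650 genes, and the planted-truth study mines 5 genomes; these sizes
exercise every code path while keeping runs in seconds.

## Numerical and tie-break conventions

- Coordinates 1-based inclusive; strands `+`/`-` with the Unicode minus
  accepted on input.
- Traversal, assignment and output ordering are all lexicographic or
  span-based and therefore reproducible; reruns of `mine()` on the same
  inputs are byte-identical.
- Ranking: descending score, ties by organism code then regulator locus
  tag.
- Output file naming `<seed>_len<k>_<EC1>_<EC2>[...].csv` is
  collision-free because EC sequences are unique per chain.
- Random number use is confined to the simulators
  (`numpy.random.default_rng`, explicit seeds); the mining pipeline and
  the Hill fitter are deterministic.

## Known limitations

- Keyword-substring regulator detection inherits annotation vocabulary
  quirks (see above).
- No operator/binding-site prediction; divergent adjacency is a proxy
  for regulatory linkage.
- The knowledge-base provider contract admits a live REST-backed
  implementation, but only local flat-file snapshots are exercised.
- Generic/carrier compounds in the knowledge base are traversed like any
  other; curation happens via the exclusion list, not automatically.
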