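# Methods

This note documents the models and procedures `evescan` implements,
the parameters that matter, the design choices made where the design
was genuinely open, and what the synthetic-data tests do and do not
demonstrate about real screens.

## The screening model

An endogenous viral element (EVE) is detectable as a region of a host
assembly whose translation is significantly similar to a viral
protein.  The screen is deliberately conservative and proceeds in two
asymmetric steps:

1. a **forward translated search** (protein query vs six-frame
   translated genome) at a stringent threshold, E ≤ 1e-20, which
   nominates candidate loci; and
2. a **reciprocal search** of each candidate locus (translated) against
   a *mixed* database containing both viral and non-viral proteins at a
   permissive threshold, E ≤ 0.001.  A candidate is kept only when its
   single best reciprocal hit is (a) viral and (b) not annotated as a
   hypothetical/uncharacterized protein.  This is the reciprocal
   best-hit logic that protects against host genes, transposons and
   spuriously annotated proteins masquerading as EVEs.

Candidate loci are built by merging forward-search hits that lie
within `merge_gap = 10` bp on the same scaffold and strand, as the
transitive closure of that pairwise relation.  Merging is
**frame-agnostic within a strand**: an element degraded by indels
produces abutting hits in different frames, and requiring equal frames
would split genuinely single elements.  After classification,
fragments of one source protein that sit within `concat_max_gap` bp of
each other and cover *non-overlapping* protein intervals are
concatenated into a single call, ordered by protein coordinate.  The
original manual concatenation this codifies had no distance bound; the
default bound of 5 kb exists because an unbounded rule would join hits
across entire scaffolds, and it is configurable.

Classification provenance: a retained call's clade, protein class and
reference protein come from the *reciprocal* best hit, not from the
forward-search query.  The call's reported segments and peptide are
likewise trimmed to the extent of the reciprocal alignment.  Forward
local alignments occasionally overshoot a few residues into flanking
sequence (the query protein continues past the endogenized fragment,
and a lucky positive-scoring tail can bridge a flanking stop codon);
defining the element as the fragment homologous to its best protein
removes most of that noise and matches how translated protein
fragments are read in practice.

Best-hit ties are broken deterministically: ascending E-value, then
descending bit score, then lexical subject id.

## The search engine

The engine implements the standard seed-and-extend architecture over
amino-acid space:

- BLOSUM62 with affine gaps, open 11 / extend 1 (a gap of length k
  costs `11 + k`); these are the conventional protein-search defaults.
- word size 3 with neighborhood threshold 11 (a subject word seeds a
  query position when the word-pair score is ≥ 11);
- a **two-hit rule** (two seeds on one diagonal within 40 aa) plus an
  **ungapped X-drop extension** (drop 16) that must reach a trigger
  score (default 60) before gapped extension is attempted.  Without
  these two filters, neighborhood-11 seeding on megabase genomes
  produces an unusable density of candidate windows; with them, the
  engine screens a 2 Mb genome against ~16 proteins in ~20 s on one
  core.
- triggered windows are aligned by **exact affine-gap Smith–Waterman**
  (numba-compiled, full traceback).  Problems small enough
  (≤ 400 k cells) skip the heuristics entirely and run Smith–Waterman
  directly, so on small inputs the reported optimum is exact — this is
  the regime the oracle-equivalence tests check.
- each window is searched recursively (flanks left and right of each
  optimal alignment are re-searched), so multiple distinct matches in
  one window are all reported.

E-values follow the Karlin–Altschul formula `E = K·m·n·exp(−λS)` with
the conventional precomputed gapped pair (λ = 0.267, K = 0.041) for
BLOSUM62 11/1, `m` the query length and `n` the total translated
search-space length.  No composition-based statistics and no
edge-effect length correction are applied; E-values therefore differ
slightly from NCBI BLAST's, but the pipeline is self-consistent (the
same statistics are used throughout, and all quantitative tests use
the internal engine end-to-end).  The ungapped λ for BLOSUM62 under
Robinson–Robinson background frequencies is available by solving the
characteristic equation (`karlin_lambda_ungapped`, bisection to 1e-9).

The genetic code is the standard code; stop codons translate to `*`
(scored −4 against residues), ambiguous codons to `X`.
Selenocysteine/pyrrolysine are not supported.  No low-complexity
masking (SEG) is applied — synthetic genomes are not repetitive; on
real genomes an external engine can be used through the tabular
adapter.

## ORF intactness and potential functionality

Each retained call's peptide is the segment-wise translation of its
(frame-tagged) segments, in each segment's own frame, concatenated in
protein order.  Internal `*` characters are nonsense mutations; a stop
at the very end of the final segment is the natural terminator and is
not counted.  An intact (stop-free) element is **potentially
functional** when `|len(EVE) − len(reference)| ≤ 75` aa, inclusive —
the printed data motivating the rule cannot discriminate ≤ from <
(the largest qualifying gap is 73 aa), and "within" is read
inclusively.  The reference length is that of the reciprocal best-hit
protein.

## Genome-quality correlation

Pearson's product-moment correlation with the exact two-sided t-test
(`t = r√(n−2)/√(1−r²)`, df = n−2) between per-genome EVE counts and
five assembly-quality factors: total length, scaffold count, scaffold
N50, contig count, contig N50.  N50 is the length at which the
descending cumulative length first reaches half the total.  Contigs
are defined by splitting scaffolds at runs of ≥ 10 consecutive N (the
common assembler gap convention; the original analysis never states
its convention, and the run length is configurable).  On the packaged
19-genome survey, genome length vs EVE count gives r = +0.211,
p = 0.386.

## Association index

For a rooted tree whose tips carry host states, the index is

    AI = Σ over internal nodes i of (1 − f_i) / 2^(n_i − 1)

with `n_i` the number of descendant tips and `f_i` the relative
frequency of their most common state.  The `2^(n−1)` weighting makes
shallow nodes dominate: AI is essentially a measure of whether *recent*
relatives share hosts.  The source analysis names the index but not
its formula; this is the standard tip-trait association index, and the
two four-tip hand values (0.0625 host-structured, 0.5625 maximally
mixed) are derived in the tests directly from the formula.

The null permutes tip states without replacement; the **AI ratio** is
observed / null-mean (mean, not median — the source does not say
which; mean is implemented).  p-values are one-sided
(small-AI = structured) with the +1 correction,
`p = (1 + #{null ≤ obs}) / (n_perm + 1)`, so they are never 0.  With
1000 permutations (the default) the smallest attainable p is ≈ 0.001.
Because ties count toward the numerator, the reported p is
conservative on discrete data; the calibration test checks uniformity
of the tie-broken rank and validity (`P(p ≤ α) ≤ α`) of the reported
value.

## Event-cost reconciliation

The element tree is mapped onto the host tree by post-order dynamic
programming over (element node, host node) pairs with the event costs
co-divergence 0, duplication 1, host switch 1, loss 1 (per traversed
host edge).  For an internal element node placed on host branch `h`
with children `u, v`:

- **co-divergence**: `h` is internal and `u`, `v` descend into its two
  child subtrees (losses charged per edge walked below each child);
- **duplication**: both children stay within the subtree of `h`;
- **host switch**: one child stays within the subtree of `h`, the
  other jumps to any host branch *incomparable* to `h` (neither
  ancestor nor descendant), landing without loss charges.

`in(p,h)` (best placement of `p` within the subtree of `h`, plus
losses) is computed by one post-order pass per element node and
`out(p,h)` (best placement on a branch incomparable to `h`)
vectorizes over a precomputed comparability matrix, giving
`O(|P|·|H|)` cells with cheap updates.  Event counts come from one
optimal backtrace with fixed tie preference (co-divergence >
duplication > host switch, then lowest host index), so counts are
reproducible; the total cost equals Σ count(e)·cost(e) by
construction, which is asserted in the tests against an exhaustive
enumeration of all mappings on trees of ≤ 6 tips.

Two deliberate departures from genetic-algorithm event reconcilers:
the DP does not search host-timing orders, so a switch may target any
incomparable branch — it is a deterministic, testable lower-bound
event reconstruction with the same cost model; and **failure to
diverge** (host speciates, element persists on both daughters) is not
representable in a single-association mapping, so that counter is
always reported as 0 and flagged in the result.  Significance uses
`n_rand` (default 100) permutations of the tip→host map with the same
+1-corrected estimator.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of a real screen:

- genomes as multi-scaffold FASTA with log-normal scaffold lengths
  (default median 20 kb, log-sd 1.2, so a realistic share of
  sub-10 kb junk scaffolds that the pruning step removes), GC content
  0.38 (AT-rich, as in ant genomes);
- a viral database of `n_viral_clades × proteins_per_clade` proteins,
  clade members derived from a common ancestor at 15% per-residue
  divergence (within-clade identity exceeds between-clade identity, so
  reciprocal classification is non-trivial); decoy host proteins with
  30% labelled "hypothetical protein" to exercise the pruning rule;
- planted elements: a random fragment (default 60–300 aa) of a random
  viral protein, reverse-translated with uniformly drawn synonymous
  codons (no codon-usage model — codon bias is irrelevant to a
  protein-space search), optionally given one internal premature stop
  (probability `premature_stop_prob`), then degraded by per-site
  substitutions and 1-nt frameshifting indels, and written over a
  uniform position and strand of a scaffold that survives the length
  filter.  Plants never overlap and keep ≥ 3 kb apart (so each
  element is called separately).  Every plant is recorded in a truth
  row, enabling automatic sensitivity/precision scoring (a plant
  counts as recovered when a retained call overlaps it);
- host/element tree pairs: the host tree is grown as a Yule process;
  element lineages track host lineages, splitting with their host
  (co-divergence) and jumping to a uniformly chosen other host with
  probability `host_switch_prob` before each speciation; each
  surviving lineage finally becomes `eve_per_host` copies on its host
  (a terminal ladder of recent within-host duplications — the
  mechanism by which real elements occur as host-specific multi-copy
  clusters).

Two named regimes anchor the parameter-recovery tests: *pure
co-divergence* (12 hosts, 2 copies per host, no switching), which
yields AI ratios ≈ 0.1 and minimal reconciliation p-values, and *pure
host switch* (12 hosts, single copies, switch probability 1), which
yields AI ratios ≈ 1.  The standard planted-recovery conditions are
ten ~200 kb scaffolds with 30 plants: with undegraded plants the
screen attains sensitivity and precision 1.0; at 15% nucleotide
substitution (plus default indel and stop rates) sensitivity falls to
roughly 0.8–0.9 because short, heavily degraded plants drop below the
1e-20 threshold — which is the intended behavior of a conservative
screen, not a defect.

What passing these tests does **not** show: performance on repetitive
or low-complexity genomic sequence (no repeats are simulated and no
masking is implemented), robustness to nr-scale database heterogeneity
(the mixed database is tens of proteins, not millions), behavior on
multi-exon or spliced elements, and agreement with NCBI BLAST E-values
(statistics are self-consistent, not composition-adjusted).  The
published census numbers that depend on the 19 downloaded assemblies
and an nr-scale database (the 434-element census itself, per-genome
counts, the published AI ratios and reconciliation totals) are out of
reach at desk scale; the packaged tables reproduce the published
*statistics computed from printed values*, and the property-based
studies substitute for the rest.

## Numerical and procedural choices

- Coordinates are 0-based half-open internally; all emitted tables are
  1-based inclusive.
- "Under 10,000 bp" is read strictly: scaffolds of exactly 10 kb are
  retained.
- Duplicate FASTA ids are tolerated with a warning (real assemblies
  occasionally contain them).
- The flat key=value config file rejects unknown keys (typos in
  threshold names should fail loudly).
- All randomness flows from named `numpy` generators; the simulator
  derives per-stage substreams from one seed, so changing the number
  of plants does not perturb scaffold generation, and every CLI
  subcommand is byte-reproducible given its seed.
- Problem sizes in the test-suite studies (2 Mb genomes, 30 plants,
  20-seed tree studies, 99–200 permutations) are chosen so the whole
  suite completes in a few minutes on one core while keeping every
  statistical band at the 99% level or wider.
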