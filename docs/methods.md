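# Methods

This note records the models, conventions, parameter choices and known
limitations behind `viroscreen`. It documents how results are computed;
every number cited here is produced by the test suite or by
`scripts/acceptance.py`, not asserted independently.

## Coordinates and alphabets

All features use 0-based half-open intervals; minus-strand features store
forward-strand coordinates, and conversion to 1-based inclusive happens only
in the GFF3 writer. Viral RNA input is normalized to the DNA alphabet
(U→T, lowercase→uppercase, IUPAC ambiguity letters→N); terminal-motif
reports re-render T as U. One internal alphabet keeps codon logic and
alignment simple; the cost is that ambiguity finer than N is discarded.

## ORF discovery under alternate genetic codes

`find_orfs` scans all six frames under an arbitrary NCBI translation table
(tables 1 and 4 ship built in, via Biopython's codon-table registry; others
can be loaded from YAML). Conventions:

* A **complete** ORF runs from a start codon to the next in-frame stop. The
  default start set is {ATG} — the stricter, reportable choice; common ORF
  callers that take the longest open stretch regardless of start are
  emulated by the 5′-partial records plus a configurable start set.
* Intervals of stop-terminated ORFs include the stop codon; `length_aa`
  excludes it, matching the `-m <min aa>` semantics of common ORF callers
  (`min_len_aa` defaults to 100).
* Edge-open reading frames yield `5prime_partial` (frame edge to first
  stop), `3prime_partial` (last start to frame edge) or `internal` (frame
  with neither start nor stop) records, so no evidence is silently lost.
* Nested complete ORFs sharing a stop collapse to the earliest start (one
  ORF per stop per frame), configurable via `one_per_stop=False`.
* Codons containing N translate to X and are never starts or stops.
* Both strands are scanned: assembly orientation is arbitrary even for
  single-stranded viral genomes.

A property worth stating precisely: because table 4's stop set {TAA, TAG}
is a strict subset of table 1's {TAA, TAG, TGA}, every table-1 complete ORF
is matched or contained by a table-4 ORF of at least equal length starting
at the same or an earlier in-frame position — but that table-4 ORF is only
*complete* if an in-frame TAA/TAG exists downstream; otherwise it is
3′-partial. The test suite asserts this corrected form.

## Coding-system call (the mito-element signature)

`classify_coding_system` counts qualifying ORFs (complete, ≥ 100 aa by
default) under the nuclear and mitochondrial tables. Since every nuclear
ORF trivially reappears under table 4, *mito-specific* evidence requires a
table-4 ORF not reproduced at identical coordinates under table 1. Calls:
`noncoding` (none anywhere), `nuclear_coding` (table-1 ORFs, no
mito-specific extras), `mitochondrial_coding` (mito-specific ORFs only),
`dual_coding` (both — the source procedure does not define this case, so it
is flagged rather than resolved). `single_orf` records whether the calling
table has exactly one qualifying ORF; it is a defining property of
retroplasmids and mitoviruses.

## Triage

Categories are assigned with a fixed precedence (virus keyword → no ORF →
no hit → divergent non-host hit → host-like), mirroring the two-pass flow
of virome screening: keyword retention first, then follow-up analysis of
the three suspicious categories. Decisions:

* "Best hit" = lowest e-value, ties broken by bitscore, then identity, then
  subject id — deterministic for any row order.
* The 90% threshold applies to amino-acid identity of the best protein hit;
  the host comparison is an exact match on the configured organism label
  plus an optional list of closely related species.
* End contamination: an end is flagged when a nucleotide-level host hit
  with ≥ 90% identity covers ≥ 50% of the terminal window (20% of contig
  length) and does not extend past the contig midpoint. The window and
  thresholds are configuration, logged at run time; whole-contig host hits
  are a triage matter, not a trimming one. Flagged windows are reported so
  a trim step can excise them.

## Element classification

Domain evidence comes from a PROSITE-style pattern matcher
(fixed residues, `[classes]`, `{negations}`, bounded gaps `x(m,n)`) rather
than profile HMMs; patterns are configuration with shipped defaults: a
generalized reverse-transcriptase catalytic box `[YF]-[AGSTV]-D-D`, a
maturase placeholder `L-[AG]-x(2,4)-P-Q-G`, an HNH placeholder
`H-N-H-x(2,5)-H` and an RdRP core `[SG]-D-D`. Matching is non-overlapping
leftmost; a motif counts as present when its match count reaches
`min_score` (default 1). Precedence is total: group II intron (RT +
maturase/HNH) outranks retroplasmid (RT alone, single ORF) outranks
mitovirus-like (RdRP core). These short patterns have no claim to Pfam
fidelity — real analyses should replace them with curated patterns or keep
using external domain services; the flag `needs_external_confirmation` in
the report marks every non-host-like contig for exactly that reason.

## Redundancy clustering

`pairwise_stats` aligns with `Bio.Align.PairwiseAligner` (match +1,
mismatch −1; a gap of length k costs −2 −(k−1); terminal gaps free in the
default `global_overlap` mode). Identity is matches over aligned columns
excluding terminal overhangs; coverage is the aligned span on the shorter
sequence over its length, so fragments of a longer element are redundant
with it — the intent of the dedup. Inputs are canonically ordered before
aligning so the statistics are symmetric even under co-optimal alignments.
`greedy_cluster` visits sequences longest-first (ties by id) and joins the
first representative reaching both thresholds (≥ 95/≥ 95 defaults),
CD-HIT style: deterministic and order-stable, where exact clique
partitioning would be exponential. Representative count is monotone in the
thresholds on family-structured data, but greedy clustering offers no such
theorem in general.

## Terminal conservation

For a declared segment group, the longest prefix (suffix) of length
≤ 30 nt such that every segment matches within the substitution budget
(default 0 = strict consensus, i.e. the longest common prefix/suffix).
With a nonzero budget the candidate is the column-majority string, a
heuristic that minimizes total rather than per-segment mismatches; the
maximality guarantee is therefore exact only in the strict case. The
30-nt cap prevents a degenerate whole-sequence consensus for identical
inputs; `min_len` (default 3) suppresses trivially short motifs. At least
two segments are required.

## Synthetic data generator

`make_dataset(seed, n_per_class, mutation_rate)` emulates the statistical
structure the triage assumes — not read-level noise, assembly error or
realistic molecular evolution. Class designs (defaults chosen to resemble
the real elements' scale): host transcripts with 140–260-aa standard-code
ORFs and ~94–99% identity host hits; retroplasmid-like elements with a
single 300–420-aa mito-only ORF (Trp planted every 40–60 residues forces
in-frame TGA, truncating the standard-code reading below 100 aa) and
divergent 40–60% identity non-host hits; mitovirus-like elements with an
RdRP-motif ORF and virus-titled hits; group-II-intron-like elements with
RT + maturase + HNH in order; partitivirus-like trios sharing exact 7/5-nt
(or 9/4-nt) termini with forced disagreement immediately inside them;
host-end chimeras (host transcript + 300-nt host block + matching terminal
nucleotide hit); and 150–300-nt noncoding contigs. Hit tables are written
by the generator itself from ground truth, with organism labels and titles
drawn from small fixed vocabularies.

Every element is rejection-sampled until its class-defining invariants hold
— including a check that the planted protein matches *exactly* the intended
motif set, so short degenerate patterns cannot fire spuriously and blur the
zero-noise confusion matrix. Point mutations are applied after construction
and the invariants re-checked, regenerating the element (bounded retries)
when they break; the mutated datasets therefore measure the pipeline's
behavior under sequence noise *conditional on the elements remaining what
they are*, which is why recovery at 2% mutation remains near 100% rather
than degrading. All randomness flows from one seed through a single named
generator; regeneration is byte-identical.

`make_redundancy_set` builds 15 seed sequences (800–1600 nt) plus 109
copies, each trimmed a few nucleotides at the ends (strictly shorter than
its seed) and carrying at most 3% substitutions, applied as an exact count
so the divergence bound is never exceeded stochastically. Longest-first
greedy clustering then provably assigns every copy to its seed's cluster.

## Pipeline orchestration

Stage order: read → ORFs (tables 1 and 4) → triage → end flags →
coding-system calls → motif scan and element classification → clustering of
element proteins per class → terminal consensus per declared segment group
→ report. The coding-system call runs on virus candidates as well as
follow-ups, because mitovirus-like calls require it. The report joins all
evidence per contig, carries a config snapshot sufficient to re-run, and
derives an `inferred_class` in the generator's vocabulary (chimera flag
first, then segment-group membership, then element class, then triage
category) so recovery against planted labels is a dictionary comparison.
Output is deterministic for fixed inputs and configuration; the CLI exits
0 on success, 2 on configuration errors, 3 on data errors.

Configuration is YAML with explicit field-by-field validation (unknown
keys, ranges, table availability) rather than a JSON-schema engine.

## Problem sizes and defaults used in checks

The shipped checks run the pipeline at 50 elements per class (450 contigs)
at mutation rates 0 and 0.02, compare ORF discovery against an independent
brute-force enumerator on 200 random 600-nt contigs, cluster the
124-sequence redundancy set, and recover termini from three-segment sets —
sizes chosen so the whole suite completes in a few minutes on one CPU while
still exercising every stage at realistic contig lengths.

## Known limitations

* Motif patterns are stand-ins; no profile-HMM scoring or e-values.
* No taxonomy resolution: organism labels are exact strings.
* Greedy clustering can split a family whose members chain below the
  threshold pairwise; the generator avoids this by construction.
* The generator does not model indels, chimeric mis-joins beyond the
  single terminal block, coverage variation, or phylogenetic structure.
* Upstream steps (read trimming, assembly, similarity searches) and
  downstream confirmation (domain servers, phylogenetics, wet-lab
  validation) are out of scope; the pipeline consumes and produces their
  file formats instead.
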