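# viroscreen

Contig triage and mobile-genetic-element discovery for fungal viromes.

RNA-seq assemblies of fungi such as *Botrytis cinerea* contain, next to host
transcripts, the genomes of RNA viruses (mitoviruses, partitiviruses and
their RNA satellites) and of virus-adjacent mobile elements of the
perivirosphere: mitochondrial **retroplasmids** (which encode only a reverse
transcriptase) and **group II introns**. `viroscreen` implements the
screening and characterization steps that turn annotated contigs into
classified elements:

1. **Triage** — keep contigs whose best protein hit is virus-titled
   (case-insensitive keyword, matching inside words such as *mitovirus*);
   route the rest into follow-up categories (no ORF; ORF but no hit; best
   hit non-host with < 90% amino-acid identity) or call them host-like.
   Host sequence misassembled onto a contig end is flagged from terminal
   nucleotide-level host hits so it can be trimmed.
2. **Code-differential ORF analysis** — six-frame ORF discovery under
   arbitrary NCBI translation tables. The defining signature of
   mitochondrial elements is that complete ORFs ≥ 100 aa exist **only**
   under the mold/protozoan mitochondrial code (table 4, TGA = Trp) and not
   under the standard code (table 1, TGA = stop). A table-4 ORF that is
   reproduced at identical coordinates under table 1 is not mito-specific
   evidence.
3. **Domain-architecture classification** — a configurable PROSITE-style
   motif scanner assigns mitochondrially coded proteins to classes:
   reverse transcriptase + (maturase or HNH endonuclease) → group II
   intron; reverse transcriptase alone in a single-ORF element →
   retroplasmid; RdRP core → mitovirus-like.
4. **Redundancy clustering** — pairwise overlap alignment (match +1,
   mismatch −1, gap open −2, extend −1) with identity over aligned columns
   and coverage over the shorter sequence; greedy longest-first clustering
   at ≥ 95% identity / ≥ 95% coverage collapses database hits into
   distinct elements.
5. **Terminal conservation** — the longest 5′/3′ consensus shared by all
   segments of a multi-segment virus (strict by default, e.g. the
   partitivirus termini `GCGCAAA…AAUCC` and `GCGAAAUUU…AUAG`), rendered in
   the RNA alphabet.

A seeded synthetic-data generator (`viroscreen.synth`) produces labeled
contigs and matching hit tables for all of these element classes, so the
entire pipeline is testable end to end without downloads.

## Worked example

Generate a labeled dataset (4 elements per class; partitivirus-like
elements contribute a trio of segments each) and run the full pipeline:

```bash
$ mge synth --seed 11 --n-per-class 4 --out demo
wrote 36 contigs to demo/contigs.fasta

$ mge run --contigs demo/contigs.fasta --protein-hits demo/protein_hits.tsv \
      --nt-hits demo/nucleotide_hits.tsv --groups demo/segment_groups.tsv \
      --out demo/report.json
{"clusters": {"group_II_intron": 4, "mitovirus_like": 4, "retroplasmid": 4},
 "element_class": {"group_II_intron": 4, "mitovirus_like": 4, "not_applicable": 14,
                   "retroplasmid": 4, "unknown_mito_element": 2},
 "inferred_class": {"C": 4, "G2": 4, "H": 4, "M": 4, "N": 4, "P": 12, "R": 4},
 "n_contigs": 36, "n_segment_groups": 4,
 "triage": {"followup_divergent_hit": 8, "followup_no_orf": 4,
            "host_like": 8, "virus_candidate": 16}}
```

Reading the summary: the 16 virus-titled contigs (4 mitovirus-like + 12
partitivirus segments) were retained as virus candidates; the 8 divergent
follow-ups are the retroplasmid- and intron-like elements, whose best hits
are low-identity non-host proteins; 8 host-like contigs include the 4
chimeras, which are separated from clean host transcripts by their terminal
host hits (`inferred_class` C vs H). Each element class was deduplicated
into 4 clusters (all elements distinct here), and conserved termini were
recovered per segment group:

```bash
$ mge termini demo/contigs.fasta --groups demo/segment_groups.tsv --out demo/termini.tsv
4 segment groups
$ head -3 demo/termini.tsv
virus_id	five_prime	three_prime	n_segments
P000	GCGCAAA	AAUCC	3
P001	GCGCAAA	AAUCC	3
```

The same stages are available as library calls (`run_pipeline_data`,
`find_orfs`, `classify_coding_system`, `classify_element`,
`greedy_cluster`, `conserved_termini`) and as the subcommands `mge orfs`,
`mge triage`, `mge classify`, `mge cluster`, `mge termini`.

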