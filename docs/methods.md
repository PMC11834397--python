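# Methods

## The problem

Laboratory microbial strain collections drift. Every genetic manipulation
(marker deletion, knockout construction) and every inter-lab transfer passes
the population through a colony-level bottleneck at which mutations can fix;
over years of strain husbandry a collection accumulates second-site mutations
that differ between labs and between derivatives of the same parent. Whole
genome re-sequencing of each strain against the published reference, followed
by variant calling with a clonal microbial caller, yields one GenomeDiff (GD)
file of mutations per strain. `halotrace` takes those per-strain call sets
plus a *curated* strain lineage and answers: which mutations are shared by
everything (and therefore say more about the reference than about the
strains), which were acquired in a parental lineage, which arose during
knockout construction — and on which specific manipulation or transfer each
one most plausibly arose.

The package was built around the two model haloarchaea — *Halobacterium
salinarum* NRC-1 and *Haloferax volcanii* DS2, both polyploid, both carrying
megaplasmids and IS-element-rich repetitive regions — but nothing in the
pipeline is haloarchaea-specific beyond the defaults.

## Pipeline

Stages run strictly in order; each stage's contract is a module:

1. **gd_io** — parse GD text. Mutation records (SNP, SUB, DEL, INS, MOB,
   AMP, CON, INV) and evidence records (RA, MC, JC, UN) are typed; unknown
   record types are retained verbatim so files from newer callers load.
   Coordinates are 1-based inclusive everywhere in the package; BED input is
   converted on read.
2. **filters** — keep only high-confidence mutation records. Exclusions,
   each with an audit ledger entry: (i) records carrying a marginal marker
   (`reject`/`marginal` attributes, or a polymorphism frequency below 1 —
   the marker set is configuration, since caller dialects differ);
   (ii) unassigned missing-coverage/junction/unknown-base evidence, logged
   but never promoted to mutations — a large deletion counts only if the
   caller emitted an explicit DEL record; (iii) calls whose footprint lies
   entirely inside a user-supplied repeat interval. Containment, not mere
   overlap, is the repeat criterion: a point call inside repetitive sequence
   is unreliable with short reads, but a deletion that *spans* a repeat — up
   to a whole-replicon loss — is not itself a repeat artifact and is kept.
3. **annotation** — functional context from the reference FASTA + GFF3.
   SNP consequences by codon arithmetic on the coding strand (checked in the
   tests against an independent whole-CDS edit-and-translate oracle); indels
   by net length modulo 3; a DEL covering a whole CDS is a gene deletion and
   one covering ≥ 99% of a replicon is a replicon loss; everything outside
   CDS/pseudogene features is intergenic with distances to the flanking
   genes. Mobilome membership is a case-insensitive product/kind match on
   {`transposase`, `insertion sequence`, `IS<digit>`, `ISH`} — chosen to
   cover the IS families actually annotated in these genomes (ISH3, ISH8B,
   ISH11, ISH27, IS4-like, IS5-like) — and MOB records are mobilome by
   definition. Single-base indels inside a mononucleotide run of ≥ 6 bases
   (configurable) are flagged as homopolymer artifact candidates; the flag
   travels with the annotation and removes nothing.
4. **catalog** — cross-strain identity. Indels are left-aligned against the
   reference so the same homopolymer indel reported at different offsets
   collapses to one key; payloads are uppercased; matching across strains is
   exact on the normalized key. Fuzzy positional matching was deliberately
   rejected — coordinates against a shared reference are directly
   comparable, and tolerance would silently merge distinct events — but a
   near-miss report (distinct keys ≤ 10 bp apart) is emitted for review.
   The strain × mutation matrix has three-state cells: absent / present /
   present-and-intended, where intent is matched against the strain
   manifest's edits with transitive inheritance along the parent chain
   (every descendant of a uracil-auxotroph parent is intended-positive for
   that marker deletion).
5. **lineage** — the curated lineage is a rooted tree (root = published
   reference isolate; every non-root strain has exactly one parent) with
   `manipulation` and `transfer` edges and per-node sequenced flags.
   Classification of a presence pattern P over sequenced strains:
   * P = all sequenced strains → **Class I**, origin "pre-reference". Three
     explanations (mutation in the common ancestor, private to the reference
     isolate, reference assembly error) are observationally equivalent here,
     so the package records the sentinel and does not adjudicate.
   * otherwise an edge (u→v) is *consistent* iff the sequenced descendants
     of v are exactly P. Absence is evidence only at sequenced nodes, so
     consistent edges form a chain through unsequenced intermediates; the
     full chain is reported as the placement range and the root-most member
     is the origin ("earliest transition"). The deepest consistent node's
     role decides the class: parental/wild-type → **Class II**, knockout →
     **Class III** (this correctly puts a mutation shared by a knockout and
     its derived double knockout in Class III).
   * no consistent edge → homoplasy; left **unclassified** rather than
     force-fitted with multi-edge parsimony, because in a curated collection
     such patterns almost always indicate matrix errors or independently
     repeated marker edits that deserve eyes. One curated exception: a
     mutation private to a *sequenced internal* parental/wild-type node
     (absent in all its sequenced descendants) is Class II with a
     `colony_private` note — most simply explained as fixed only in the
     colony picked for re-sequencing.
   The origin edge's type gives the activity: parental generation, transfer,
   or knockout generation.
6. **summarize** — per-species counts and figure tables. Counting
   conventions: mutation counts are distinct keys (matrix columns), not
   strain incidences; Class I/II totals include intended columns (the
   expected marker deletions are part of the lineage-defining cohort) while
   the headline Class III count is unintended-only, which is what knockout
   verification cares about — both total and unintended counts are always
   reported. "Coding" means the effect alters a protein (nonsynonymous,
   start-loss, nonsense, frameshift, in-frame indel, gene deletion, replicon
   loss); synonymous and intergenic changes are not coding. Per-strain
   statistics (mean/max unexpected mutations per knockout, fraction of
   knockouts with ≥ 1, coding density) can exclude a configured strain set —
   used when one strain's calls are dominated by known construction
   artifacts of its parent — while class counts always cover everything.
   The heatmap export orders strains and mutations by average-linkage
   hierarchical clustering on binary Jaccard distance over presence/absence
   (intended and unintended both count as present); rows are canonically
   label-sorted before linkage so the ordering is deterministic and
   invariant to input order. The genome-plot table maps classes to
   concentric rings (outer I, middle II, inner III).

## Numerical and degenerate-input choices

* Start-codon SNPs: a change to any valid archaeal start (ATG/GTG/TTG) is
  treated as silent; any other change is `start_loss`, regardless of the
  in-frame amino acid. The whole-CDS oracle applies the same rule.
* A mutation overlapping several features reports all locus tags and takes
  the most severe category (replicon_loss > gene_deletion > frameshift >
  nonsense > start_loss > nonsynonymous > in_frame_indel > synonymous >
  pseudogene > intergenic). Pseudogene overlaps are always `pseudogene`.
* MOB insertions into a CDS are tagged frameshift (gene disruption); SUB/CON
  with net length 0 inside a CDS are tagged in-frame.
* The replicon-loss threshold (a DEL spanning ≥ 99% of a replicon) tolerates
  assembly-edge artifacts while catching whole-plasmid curing/loss events.
* Clustering ties are broken by the canonical label order; a single-row
  matrix is returned in identity order.
* Empty strain sets, presence patterns naming unsequenced strains,
  coordinates outside a replicon, and cyclic or multi-parent lineage graphs
  are rejected with explicit errors.

## Synthetic data generator

`synthetic_data` emulates the study conditions end to end: genomes with
annotated CDSs (valid starts/stops on either strand), IS-element features
carrying mobilome-matching products, pseudogenes, planted homopolymer tracts
and repeat intervals; random lineage trees (root reference isolate,
parental chains with optional transferred lab copies, all knockouts
sequenced, occasional derived double knockouts); and per-edge mutation
counts drawn Poisson. The per-edge mean is either type-specific
(manipulation 2.0, transfer 0.5 by default — construction steps involve
stronger bottlenecks and selection than passaging) or rate-derived as
ρ·L·G with ρ defaulting to the measured *Hfx.* background rate of
3.15 × 10⁻¹⁰ per site per generation. Mutation types follow a configurable
mix over SNP/INS/DEL/MOB/gene-deletion/replicon-loss; footprints are kept
disjoint so every planted event has a unique key and ground truth is exact.
Artifact channels are typed: marginal records and repeat-region calls are
exactly what the filters remove; homopolymer single-base indels survive
filtering and must instead be flagged by annotation; evidence records are
logged as evidence-only. The truth table records both the planted edge and
the earliest *recoverable* origin — with unsequenced intermediates the two
can differ, and recovery is scored against the latter because the planted
edge is not identifiable even in principle.

What the generator does **not** emulate: read-level error (no FASTQ),
within-population polymorphism (clonal post-bottleneck assumption),
polyploid heteroallelic states, and rearrangements beyond the GD record
vocabulary. Passing the synthetic suites therefore demonstrates the
correctness of the classification logic given a call set, not the
robustness of upstream variant calling.

## Curated species panels

`halotrace.study` reconstructs the two published strain panels as runnable
input: 22 sequenced *Hbt.* strains (a lab wild type, the 2014 and 2017
samplings of the Δura3 parental stock as distinct nodes, 19 knockouts) and
39 sequenced *Hfx.* strains (wild type DS2, four sequenced parentals, 34
knockouts from seven labs, two of them double knockouts), with the full
curated mutation catalog: 11 + 13 Class I mutations, 6 + 30 parental-lineage
mutations (including the intended ura3/pyrE2/pyrF/pHV2 and
H119/H555/H1209 edits), and 8 + 41 unexpected knockout mutations with their
documented effect composition. Coordinates are synthetic — the real
multi-megabase references cannot ship in a source tree — so each mutation is
re-embedded in a small generated replicon whose named genes carry the
documented products and planted codons (e.g. a CTG→CCG Leu→Pro site in the
50S ribosomal protein gene, an ATG→ATA start loss in *nadA*, poly-C tracts
for the homopolymer deletions). Planting codons rather than scanning random
sequence makes the panels reproducible for any seed. Nothing downstream
reads the curated class labels: classes, effects and all summary statistics
are recomputed by the ordinary pipeline from the emitted GD documents, which
is what makes the panels a genuine end-to-end check rather than a lookup.

The single H1209-derived knockout carries a six-mutation cluster in
HVO_1871 attributable to its parent's pitA replacement; it is excluded from
per-strain statistics (mean, max, fraction, coding density use the other 33
knockouts) but fully included in classification and class counts.

## Problem sizes

Synthetic suites use ~80 kb three-replicon genomes, lineages of ~12–18
strains, and 20 random lineages (> 500 planted mutations) for the recovery
property; the rate-calibration check uses a 2 Mb genome and 200 simulation
seeds. The curated panels are 22 and 39 strains with 55 and 123 matrix
columns respectively. The full test suite runs in a few seconds on one CPU.

## Known limitations

* Classification assumes the curated lineage is correct; the package never
  infers lineage from data, and a wrong parentage shows up only indirectly
  (as homoplasy flags).
* Exact-key matching will split a genuinely identical event if the upstream
  caller reports it with different endpoints in different strains; the
  near-miss report is the mitigation, merging is intentionally manual.
* Heteroallelic (polyploid) states are invisible: consensus calls are taken
  at face value, matching the upstream caller's clonal mode.
* Evidence-only records are never rescued, so rearrangements supported only
  by junction evidence are out of scope by design.
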