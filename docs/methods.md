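# Methods

This note documents the models, conventions and numerical choices behind
`mirseed`, in the order data flows through the pipeline.

## Sequence conventions

All sequences are held internally in a DNA alphabet (`ACGTN`; `U` → `T`
on input) so that tags, catalogs and genomes can never mismatch on
alphabet; RNA letters reappear only in reports. Genomic coordinates are
0-based, half-open, with explicit strand, asserted by one shared helper.
FASTQ qualities are Sanger/Phred+33; gzipped files are sniffed by
extension.

## Read cleaning

The 3' adapter is located as the earliest read position whose suffix
matches a prefix of the adapter with at most one substitution (minimum
overlap 5 nt) — i.e. the longest such match. Reads are discarded when the
adapter starts at position 0 (no insert), when no adapter is found in a
full-length read (no-insert or oversize insertion; reads shorter than a
supplied cycle count are treated as pre-trimmed), when the insert is
≥ 80 % A (poly-A artifact), contains `N`, or the mean Phred is below 20.
The quality threshold operationalizes "poor-quality" and is configurable;
each discard reason is counted so that kept + discarded = raw.

Unique-tag collapsing preserves per-library counts (the sum of tag totals
equals the read count — a conservation property the tests enforce), and
the putative-miRNA window keeps tags of 15–30 nt inclusive.

Class annotation replaces remote database searches with local matching
against user-supplied labeled reference sets: a tag belongs to a class if
it aligns ungapped, fully within any member, with ≤ 1 substitution;
classes are tried in the fixed priority order miRNA > rRNA > tRNA >
snRNA > snoRNA > other. Matching is an exact vectorized scan over every
window of every reference (NumPy byte comparison on a packed
sentinel-separated array) rather than a seeded heuristic: at these catalog
sizes exactness is affordable and it guarantees that raising any mismatch
budget can only grow the matched set.

## Conserved-miRNA calling

A length-filtered tag is conserved when it aligns ungapped and in full
within any catalog mature or precursor with ≤ 3 substitutions, sense
strand only (small-RNA library chemistry is stranded). Ties are broken by
fewest mismatches, then mature over precursor, then lexicographically
smallest reference id, and each tag is counted for exactly one reference
so expression is never double-counted; tags sharing a best reference merge
into one record with summed counts.

## RNA folding model

The folder computes the minimum-energy nested structure (no pseudoknots)
by dynamic programming over three tables (unconstrained, ≥ 1 pair, and
pair-closed subproblems). The energy model is deliberately simple and
fully specified by the packaged table:

* admissible pairs AU, GC, GU (wobble), minimum hairpin loop 3 nt;
* adjacent pairs stack with energies from a symmetrized table preserving
  the GC > AU > GU stability hierarchy (GC/GC −2.6 … GU/GU −0.8
  kcal/mol);
* each hairpin loop costs +3.0 kcal/mol; unpaired bases, bulges, internal
  loops and multiloops are free.

Energies are integer tenths of kcal/mol internally, so DP comparisons are
exact. Ties on energy are resolved toward the structure with the most
pairs, then by a fixed traceback order, making folding deterministic. The
test-suite and acceptance script verify the DP against exhaustive
enumeration of all nested structures on sequences up to 25 nt (hundreds of
thousands of structures), checking both the MFE and the optimality of the
returned structure.

Because the model omits loop-size terms, dangles and multiloop penalties,
its absolute energies are not comparable to full nearest-neighbor
implementations; every energy threshold in the pipeline (the −18 kcal/mol
precursor criterion, the −17 kcal/mol duplex cutoff) is therefore a
calibration to *this* model and exposed as configuration.

Hairpin geometry is measured from the pairs involving the placed mature:
arm assignment (5p/3p) requires all partners on one side and tolerates at
most 2 unpaired 3'-terminal mature bases — exactly the canonical Dicer
overhang — otherwise the mature is "spanning"; `max_bulge` is the largest
total unpaired gap between consecutive duplex pairs; the mature-side 3'
overhang is the distance from the last paired mature base to the mature
3' end.

## Novel-miRNA discovery

Unannotated tags are mapped to the genome ungapped on both strands (exact
by default; `str.find` for 0 mismatches, the vectorized scanner
otherwise). Tags with more than 10 genomic loci are dropped as repetitive
— an addition that guards against pathological candidates.

Around each hit, candidate precursors are excised at several flank
lengths (30/45/60/80/100 nt beyond the tag, tag at either window end,
reverse-complemented for minus-strand hits) and each window is folded.
Folding only the maximal window proved fragile: stray complementarity
between the far flank and the mature's outer bases can enclose the real
hairpin in a two-pair helix and inflate the apparent bulge size. Scanning
excisions and keeping the lowest-MFE window that satisfies the hairpin
geometry (else the lowest-MFE window overall) mirrors what
hairpin-prediction tools do internally when they cut the stem-loop out of
a larger region.

The six consensus criteria are then applied, each recorded as a named
pass/fail flag with a reason: (1) no sense-strand exon overlap (vacuously
true without an annotation; intergenic loci are admitted); (2) mature on
one arm; (3) mature-side 3' overhang exactly 2 nt (a ±1 relaxation exists
behind a flag); (4) largest bulge/internal loop ≤ 8 nt (the criterion's
"large" is not quantified in common usage; 8 nt is the declared default);
(5) MFE < −18 kcal/mol; (6) read support > 5, read literally as ≥ 6.
Overlapping passing candidates on a locus merge, keeping the lowest-MFE
precursor. Tightening any threshold provably shrinks the call set
(monotone filters; tested).

## Families, matrix, clustering

Family membership is conjunctive: identity > 98 % AND mismatches ≤ 1
("less than two") over an ungapped full-overlap alignment. On a 22-nt
mature a single mismatch already drops identity to 95.5 %, so the two
conditions can only jointly bind on precursors; the aligner therefore
prefers precursors and falls back to matures (still conjunctive), with
the basis recorded for audit. The species × family member-count matrix
binarizes at ≥ 1 member to yield Dollo characters. Species clustering
uses Euclidean distance on count rows with average linkage — both
unspecified upstream and declared here — and is invariant to family
(column) permutations. Lineage-specific families follow the strict rule:
present in every group member and absent from every non-member.

## Dollo parsimony

Each family is a binary character gained exactly once and never regained.
On a rooted tree, the gain sits at the MRCA of the presence leaves and the
character's length is 1 + the number of edges below the gain where the
minimal-loss reconstruction switches 1→0; absent characters cost 0, all
characters weigh 1. The implementation counts losses vectorized across
characters from subtree presence counts and is verified against brute
force over every gain placement and loss set on all 15 rooted 4-taxon
shapes.

Tree search is exact branch-and-bound by stepwise addition, rooting on a
user-declared outgroup (Dollo needs a root; requiring the user to name it
beats silent midpoint rooting). The Dollo length of a leaf subset never
exceeds that of any superset (deleting a leaf can only remove losses), so
a partial tree scoring above the incumbent is safely pruned while ties are
kept, and *all* minimum-length trees are returned. For ≤ 9 taxa the search
is exact; 6-taxon searches are verified against enumeration of all 105
outgroup-rooted topologies. Clade support is by character bootstrap: a
clade counts in a replicate only when it appears in every MP tree of that
replicate (conservative under ties), reported as a percentage on the best
tree — the package's stand-in for model-based posterior support.

## Expression profiling

Means are arithmetic over raw replicate counts (no normalization — a
single-condition design). Abundance bins complete the conventional
log-decades: `<10`, `10–100`, `100–1k`, `1k–10k`, `>10k`, lower-inclusive
at 10/100/1000 with the top bin strictly "more than 10,000". Replicate
agreement is Pearson correlation of log10(count+1). Composition profiles
are 5'-anchored; a miRNA contributes to a position only if long enough to
reach it, and the first-nucleotide breakdown is restricted to 20–24 nt,
where miRNA lengths concentrate.

## Target prediction

Seed classes follow the canonical definitions anchored on the 6mer core
(reverse complement of miRNA positions 2–7): an upstream match to
position 8 and/or an A facing position 1 upgrade to 7mer-m8 / 7mer-A1 /
8mer. Scoring is two-channel: a local affine-gap complementarity
alignment (+5 Watson–Crick, +2 GU, −3 mismatch, −8/−2 gaps, seed
positions 2–8 doubled — a perfect 22-mer scores 145) and the minimum
hybridization energy of the intermolecular duplex under the folding
model's stacking energies (monotone pairings, adjacent-pair stacks only;
an O(nm) prefix-minimum DP verified against pairing enumeration on ≤ 12 nt
strands). Default retention thresholds (score ≥ 90, energy ≤ −17
kcal/mol) are miRanda-spirited defaults calibrated to the in-house model.
Annotation reporting is a raw per-term tally of distinct target genes —
deliberately not an enrichment test, matching the upstream reporting
style; a gene with several terms counts toward each.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study conditions the pipeline targets: four
replicate libraries; 15–30 nt inserts with a 22-nt mode; a TruSeq-style
3' adapter; per-miRNA abundances log-normal across miRNAs (ln-scale mean
5.0, spread 1.2) with multiplicative replicate noise (ln-scale 0.1), so
replicate log-counts correlate at σ²/(σ²+σ²_rep) ≈ 0.99 — "high
replicate correlation" by construction; ~20 % contaminant tags drawn as
fragments of a packaged synthetic decoy set (random sequences labeled
rRNA/tRNA/snRNA/snoRNA/other — stand-ins, not database sequences); and
small admixtures of adapter-only, poly-A and low-quality reads to
exercise the cleaning counters.

Planted hairpins are built with canonical geometry: a GC-balanced
21–23 nt mature on the 5' arm, its reverse complement with 1–3 interior
non-pairing substitutions (small bulges) on the 3' arm, an 8–15 nt
homopolymeric-A apex loop, and 2-nt 3' overhangs at both duplex ends. The
A-loop and constrained mature ends keep the duplex register unambiguous
under the fold; each hairpin is additionally verified by folding at
construction time and resampled if the fold does not reproduce the
designed geometry, so planted positives are recoverable by design.
Planted novel tags are floored at 10 reads per replicate so the
read-support criterion is meaningful. All randomness flows from one seed
through named spawned streams; identical seeds give byte-identical
outputs, and adding a new generator cannot perturb existing ones.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: sequencing indels and quality-score decay;
isomiR 5'/3' heterogeneity; cross-mapping between paralogous loci;
RNA-edited or non-templated bases; genomic repeat structure (the
background is i.i.d. uniform); real contaminant taxonomies; and
expression differences across conditions. Recovery rates on synthetic
data are upper bounds, not field performance estimates.

## Problem sizes in tests and acceptance

The default synthetic run uses a 100 kb genome, 20 planted hairpins and
50 catalog miRNAs (~110 k reads over 4 replicates); folding oracles use
200 random sequences of 8–25 nt; Dollo oracles use all 4-taxon shapes ×
~100 characters and 20 random 6-taxon matrices against exhaustive search;
topology recovery uses 20 independent 9-taxon, 300-family simulations at
5 % per-branch loss. These sizes were chosen so the full suite and the
acceptance script each complete in about a minute on one CPU while still
exercising every engine at a scale where its search space is nontrivial.

## Known limitations

* The folding model's simplicity means MFE values are only internally
  comparable; criterion thresholds do not transfer to other folders.
* Exact MP search is factorial in taxa; the package targets ≤ ~12 taxa
  and offers no heuristic fallback.
* Conserved calling is substitution-only (no indels) and sense-only.
* Criterion 1 cannot distinguish intronic from intergenic loci without an
  annotation; intergenic loci are admitted and flagged.
* Family assignment ignores gapped homology and novel-family naming.
* The bootstrap support of a clade depends on the strict all-MP-trees
  rule; under extensive ties supports are conservative.
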