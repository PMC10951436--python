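# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `tylocus`. Coordinates are 0-based half-open internally
and 1-based closed in GFF3/SAM output.

## Synthetic data: what it emulates, and what it does not

The simulator builds a chromosome segment containing a tRNA-bracketed
locus with nested Ty insertions, evolves it along a strain tree, and
emits noisy long reads. It is the ground truth against which every
downstream stage is tested.

**Ty library.** Real consensus sequences are not part of this package;
the library is synthetic but structurally realistic: three Ty1
subfamilies (canonical, prime, 101) diverged from a common sequence at
~5% of sites, plus unrelated Ty2 and Ty3 entries; LTRs ~300 bp,
internal regions ~5 kb. The internal region carries a 1.8 kb
GAG-homologous ORF with an internal ATG 172 codons from its end — the
anchor for the domesticated-ORF logic. Subfamily mutations inside the
ORF are resampled if they would create an in-frame stop, so every
subfamily's ORF stays translatable.

**Locus blueprint.** The default layout is
flank — tRNA(+) — Ty2 solo LTR — truncated Ty1prime internal
(source interval 1100–3900 of the 5 kb internal, so ~1.2 kb of GAG
survives) — Ty1canonical solo LTR — Ty3 solo LTR(−) — tRNA(−) — flank,
with an engineered 1 bp deletion 300 bp into the fragment, upstream of
the internal ATG. The deletion frameshifts the 5′ GAG remnant
(premature stops appear in the shifted frame) while the downstream
ORF — internal ATG through the GAG stop, 172 codons — stays intact and
is recorded as truth.

**Strain evolution.** Point substitutions per branch under
Jukes–Cantor (K2P selectable, κ = 2), sampled from the exact
transition matrix for the branch length; substitutions creating
in-frame stops within the tracked ORF are reverted (the panel's ORF
must remain alignable for the codon-model stage — a deliberate
simulator choice, which also means the simulated ORF evolves almost
neutrally, ω ≈ 1, slightly depressed by stop rejection). Structural
events attached to a branch are applied after its substitutions and
inherited: `delete_locus_insertion` excises the truncated fragment,
`insert_ty` adds a solo LTR after a named feature, `gene_convert`
replaces the fragment's sequence with the same truncation of another
subfamily (same length by construction, so coordinates are unchanged).

**Default panel.** Twenty strains on a fixed binary tree (branch
lengths 0.004 substitutions/site — ordinary within-species divergence),
with two deletion events (clades of 3 and 2 strains) and two conversion
events (a 2-strain clade and one leaf): 12 present / 5 absent /
3 converted. The event branches are separated by insertion-bearing
lineages, so the engineered count (4) is also the Fitch parsimony
minimum. A 2-strain outgroup clade provides the rooting.

**Reads.** Lengths are log-normal (median ~8.1 kb, σ = 0.35, floor
1 kb — raised to 3 kb in assembly contexts), strands uniform, starts
uniform within the segment. Error profiles: PacBio-CLR-like
mismatch/insertion/deletion = 0.05/0.05/0.04, ONT-like 0.04/0.03/0.05,
or perfect. These are conventional figures for raw long reads, not
calibrated to any particular dataset. Not emulated: chimeric reads,
quality-value structure, diploid loci, basecalling artifacts — so
passing tests demonstrate algorithmic correctness under realistic error
rates, not robustness to every artifact of real sequencing runs.

## Mapping

Minimizer index (k = 15, w = 10, canonical hashes, leftmost-minimum
winnowing), O(n·window) colinear chaining DP (gap limit 5 kb,
predecessor window 60), per-chain base-level alignment: edit-distance
core over the chained interval plus score-trimmed tail extension
(match +2, mismatch −4, gap open −4, extend −2; the tail is cut at its
maximum-scoring prefix, an x-drop analog). Anchors inside an accepted
chain's bounding box are retired so parallel leftovers cannot surface
as duplicate chains. The best-scoring alignment is primary; chains
overlapping it by ≥ 50% on the read are secondary, others
supplementary. Mapping quality is a documented uniqueness score:
60 with no competing chain, else
`clamp(round(40·(1−s₂/s₁)·min(1, anchors/10)), 0, 60)` — an exact tie
gives 0. The default filter (mapq ≥ 30, drop secondary+supplementary)
matches the standard `-F 2304 -q 30` semantics. Locus reads are those
with a filtered alignment overlapping the locus by ≥ 1 bp that is not
fully contained in it; the ≥ 1 bp rule is a documented choice.

## Local assembly

Two independent algorithms assemble the extracted reads:

**OLC.** All-vs-all candidate overlaps from shared minimizers (offset =
median of position differences), confirmed by edit-distance alignment
of a ≤ 2 kb stretch of the overlap (min overlap 500 bp; min identity
0.75 noisy / applicable to perfect too); contained reads flagged.
Greedy best-overlap layout from the longest read (score =
identity × length; ties → longer overlap, then smaller read id), then
column-vote consensus and polishing (default 2 rounds).

**Consensus/polish columns.** Reads are realigned to the contig
(orientation cached after the first pass); each column takes the
depth-weighted plurality base. A deletion wins only with > 50% support.
An insertion wins with > 50%, or with > 35% when it out-votes every
competing insertion 3:1 — equivalent alignments scatter a true
insertion over neighbouring columns, so a strict majority
systematically misses real single-base insertions, while noise never
approaches the 35% floor at ≥ 20× depth. Single-base indel votes are
pooled at the start of their homopolymer run for the same reason.
Remaining ambiguous windows (indel support between 15% and 50%) are
re-voted as whole strings over spanning reads (pad 8 bp, window cap
32 bp, plurality ≥ 2). For noisy data the contig is finally trimmed to
its ≥ 4× core — below that a column vote is no better than a raw read;
the trim is skipped when the observed read-to-contig error rate is
< 1% so that perfect-read assemblies remain exactly the haplotype.
With these rules, 40× reads at the default error profile yield polished
identities of ~99.6–99.8%.

**Sparse-marker frame assembler.** An independent code path standing in
for a fast, non-polishing assembler: reads ≥ 3,000 bp are anchored onto
a growing coordinate frame by shared hash-thresholded k-mers (k = 17,
density 1/8 — selection by threshold, not windowing), the frame is cut
into 256 bp bins, the heaviest contiguous covered bin run is kept, and
a single majority consensus is taken. No polishing, so its contigs
carry measurably more base errors than the OLC path — mirroring the
polished-vs-unpolished contrast the dual-assembler design exists to
exploit. The column-vote consensus routine is shared infrastructure
between the two assemblers; layout, matching and read selection are
disjoint.

## QC

**Coverage discrepancy.** Reads are remapped to the contig; two depth
profiles are compared in 200 bp windows: all alignments vs the filtered
set (primary, mapq ≥ 30). A window fails with zero filtered coverage,
filtered < 0.25 × unfiltered, an all/filtered ratio > 1.3, or filtered
depth > 2 × its own median. Judging the low-support signal against the
unfiltered profile keeps natural end ramps (where both profiles taper
together) from failing clean assemblies; the ratio rule is the
collapsed-duplication detector — junction-spanning reads survive only
as supplementary alignments, and measured ratios are 1.0 on clean
panels vs ≥ 1.4 sustained over a collapsed region. The published
analysis made these calls by visual inspection of coverage tracks, so
there is no quantitative criterion to replicate; all thresholds are
parameters chosen to separate clean from corrupted simulations by a
wide margin.

**Collinearity.** Unique exact 21-mers between contig and
locus+flanks reference, longest strand-consistent chain (patience LIS);
pass iff the chain covers ≥ 80% of each 1 kb flank. Absence haplotypes
pass by construction (both flanks intact). The chain doubles as
dot-plot coordinates.

**Concordance and dedup.** Global edit-distance identity between the
two assemblers' contigs after orientation normalization (reported, not
gating); one record per canonical strain name, preferring QC pass, then
the newer dataset, then lexicographic order (deterministic ties).

## Annotation

tRNAs are found by direct alignment of the known flanking tRNA
references (call at ≥ 0.90 identity over the full reference; covariance
models are unnecessary when the genes are known a priori); the assembly
is reverse-complemented if the calls come out mirrored, so the 5′ tRNA
always precedes the 3′ tRNA. A missing flanking tRNA flags the strain
for exclusion rather than raising.

Ty fragments: exact 13-mer seeds per library entry/part/strand are
clustered by diagonal, boundaries refined by score-trimmed extension of
the query flanks (recovers diverged termini without smearing truncation
boundaries), co-oriented same-family hits within 50 bp merged, and each
fragment scored against every entry of its family (threshold 0.55 —
Ty families are ancient; minimum fragment 40 bp). The subfamily label
is assigned only when the best identity beats the runner-up by ≥ 0.5
percentage points; otherwise the call is family-only, which keeps
downstream gene-conversion calls conservative. LTR–internal–LTR runs
of one family, co-oriented and adjacent, are classed full-length;
internals without both LTRs truncated; lone LTRs solo.

ORF calls: longest ATG→stop ORF ≥ 50 codons over the three forward
frames. The fragment is related to a reference coding sequence through
a colinear exact-k-mer chain (end-to-end alignment would fabricate
indels where the fragment is truncated): clustered indels within 30 bp
are netted (compensating pairs cancel) and reported as frameshifts when
the net is not a multiple of 3; premature stops are scanned in the
frame set by the upstream reference-aligned region — the frame a
ribosome entering from 5′ would read — up to the ORF start.

## Phylogenetics

Progressive profile–profile MSA with affine gaps (DNA: match 2,
mismatch −2, open 6, extend 1; protein: BLOSUM62, 11/1), guide order
from shared-k-mer UPGMA. Distances with complete deletion of gapped
columns; JC correction errors on p ≥ 0.75. BioNJ agglomeration with
variance-weighted reduction recovers additive matrices exactly.
Bootstrap resamples alignment columns (plain site resampling; support =
replicates containing each point-tree bipartition). The ML tree uses
GTR with 4 mean-discretized Γ categories (α line-searched in
[0.05, 10], exchangeabilities by Nelder-Mead on the log scale), BioNJ
start, per-branch bounded line searches and NNI moves accepted while
the likelihood improves — a deliberately simple search whose contract
is topology recovery on well-separated data, not likelihood parity with
dedicated tree searchers. Branch lengths below 1e−5 are never pruned
from stored trees (display-only option).

The strain tree uses the concatenated 1 kb regions upstream of the 5′
tRNA and downstream of the 3′ tRNA — independent of locus content by
construction — rooted on the designated outgroup clade. The default
pipeline tree method is BioNJ + 100 bootstraps; the ML search is
config-selectable (`tree_method="ml"`).

## Classification

The structural signature of the locus insertion is a truncated
Ty1-family internal fragment in forward orientation between the tRNAs
(solo-LTR content is ignored — stricter matching is config-exposed).
All such fragments across strains, plus the reference/ancestral
fragment as anchor, enter a BioNJ+bootstrap phylogeny; the bona fide
clade is the maximal bipartition side containing the anchor and only
fragments whose best library hit is the canonical subfamily. Present =
qualifying fragment inside the clade; converted = qualifying fragment
outside it; absent = no qualifying fragment; excluded propagates
QC/tRNA flags. Clade membership is topological; the separating edge's
bootstrap support is reported, not thresholded. With < 3 fragments no
tree is built and membership falls back to the subfamily best hit
(logged). Loss/conversion events are counted by Fitch small parsimony
with presence forced at the root.

## Codon-model selection analysis

Codon alignment is protein-guided: translate (internal stops are
errors naming the sequence), align the proteins progressively, thread
codons back under each residue, so gaps are codon-sized. Optional
trimming drops all codon columns at/after a reference taxon's terminal
indel (recorded, no-op past the end).

The M0 (GY94) model: 61 sense codons (standard nuclear code),
`q_ij = π_j·κ^[transition]·ω^[nonsynonymous]` for single-position
changes, zero otherwise, Q scaled to one expected substitution per
codon at stationarity. Codon frequencies default to F3x4
(position-specific nucleotide products renormalized over sense codons;
F1x4 and uniform selectable). Likelihood by pruning with pattern
compression and spectral P(t) (reversibility-symmetrized
eigendecomposition); gap codons are missing data. Fitting is
coordinate ascent — per-branch line searches against cached
inside/outside partials, then bounded Brent in ω and κ — to 1e−6 in
logL (hard error after 200 iterations). dN and dS derive from the
fitted matrix: with tree length T and synonymous rate fraction ρS,
dS = T·ρS/(3·fS) where fS is the synonymous fraction of the ω = 1
matrix, dN analogous; dN/dS equals ω by construction. An alignment
with no variation raises (ω unidentifiable) instead of returning a
silent estimate. NG86 pathway counting (pairwise averages,
JC-corrected; saturated proportions fall back to the raw proportion)
serves as the independent counting estimate alongside the ML fit.

Recovery under the default test conditions (8 taxa, 500 codons, κ = 2):
estimates fall within ±20% of the true ω across 0.2–2.0 in ≳95% of
seeded replicates.

## Expression

TPM_i = 10⁶·(c_i/L_i)/Σ_j(c_j/L_j) per run; effective length is the
annotated length (no fragment-length correction — no model for one is
assumed). The focal percentile is floor(100·#{genes with mean TPM
strictly below}/(N−1)) over the mean of per-run TPMs; mid-rank ties and
TPM-of-pooled-counts are selectable alternatives, since the published
convention is not stated.

## Problem sizes and determinism

Default desk-scale sizes: ~14 kb segment, ~3.9 kb locus, 20 strains,
30× reads (≈ 50 reads/strain), 100 bootstrap replicates, 500-codon
alignments — chosen so the full pipeline runs in minutes on one CPU
while leaving unambiguous signal margins. Every stochastic step takes
an explicit seed; fixed seed + fixed input order + documented
tie-breaking (lexicographic throughout) make whole runs byte-identical.

## Known limitations

- The mapper, assemblers and annotators are compact reimplementations
  of their production counterparts; they target correctness at locus
  scale (≤ ~25 kb), not whole-genome throughput, and attempt no repeat
  resolution beyond greedy best overlap.
- QC thresholds replicate the *logic* of coverage-discrepancy and
  collinearity screening, not any published quantitative criterion
  (none exists); parity with manual calls on real data is not implied.
- The ML tree search explores NNI space only; for poorly separated data
  it can return a local optimum.
- Exact numeric parity of the M0 fit with other codon-model software
  depends on unstated settings there (frequency model, input branch
  lengths); the in-repo fit is validated by brute-force likelihood
  equality and simulation recovery instead.
- The expression stage starts from a count table; read alignment and
  counting are out of scope.
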