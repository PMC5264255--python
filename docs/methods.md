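# Methods

`minimeta` reconstructs near-complete bacterial genomes from a fragmented
metagenome assembly (meta-O) by exploiting a partial, high-purity view of
one target genome — typically contigs assembled from a flow-sorted,
MDA-amplified mini-metagenome (meta-S) — and then calls strain-level
variation de novo from bubbles in the assembly graph. This note records the
models, the defaults and why they hold, what the synthetic fixture does and
does not emulate, and the numerical choices.

## The contig connection graph

Contigs are nodes of a bidirected string graph; an edge records an exact
suffix/prefix overlap (>= `ccg.min_overlap`, default 40 bp = k-1 for a
k=41 de Bruijn assembly) between two oriented contigs, so every edge is
traversable from the reverse-complement direction. Candidate overlaps are
seeded by an index of 40 bp contig ends and verified exactly; for each
oriented pair only the longest overlap becomes an edge (parallel edges at
shorter lengths would create spurious walk multiplicity). Self-overlaps
are accepted only in the + to + orientation (circular contig) and flagged.

Long-range mate-pair links (Plinks) connect contigs bridged by >=
`ccg.plink_min_support` (default 3) read pairs. The gap estimate per pair
is the library insert mean minus the two mate tail lengths; the insert
distribution is a 1-D Gaussian mixture fitted by EM (below) on same-contig
innie pairs, the dominant component being the library insert. Plinks are
used only for scaffolding, never for partitioning.

**Partition.** Junction nodes whose outward edges cannot all reconverge
into a common node within `ccg.w_conv` (default 400) appended bases lose
those edges; repeating to a fixpoint splits the graph into components that
are, under the assumption that different species seldom share sequence,
genome-pure. Appended length counts node length minus overlap, so the
bound is in bases, not nodes. The trigger is out-degree >= 2 (a degree-2
junction is precisely the ambiguous case; `partition.strict_gt2` restores
the literal > 2 reading). Bubbles — walks that do reconverge — survive the
partition, which is what lets strain variation stay in the graph while
shared repeats are cut loose. All downstream traversal runs on the
partitioned graph.

## Binning (TNF clustering + graph merging)

Meta-S contigs >= `baf.min_len` (1 kb) are profiled by canonical
tetranucleotide frequency (136 features; reverse-complement pairs pooled)
and compared with the Spearman footrule distance — the L1 distance between
descending-frequency rank vectors, ties broken by canonical k-mer order.
Average-linkage hierarchical clustering is cut at `baf.cluster_cutoff`
(default 3500, calibrated on the default fixture where within-genome
distances sit below ~3100 at the 95th percentile and the nearest
between-genome bin averages exceed ~4500; the cut is deliberately on the
conservative side because oversplitting a genome is harmless while merging
two genomes is not). Shorter contigs are assigned to the nearest bin
centroid only within the same cut. Clustering input is sorted by contig
id, so input order never matters.

Bins are then located on the meta-O graph by exact 31-mer anchoring
(fraction of node bases covered by bin k-mers >= `baf.anchor_fraction`),
and merged when (1) two bins have >= `baf.end_overlap` (40 bp) end-to-end
overlaps with a common node, or (2) exactly one bounded path
(`baf.max_path_len`, 10 kb) joins them and no interior node is anchored to
a third bin. Merged bins are connected components of this bin-link graph.

Exact k-mer anchoring replaces an external whole-genome aligner because
both the simulator's contigs and real same-sample contigs are (near-)exact
substrings of their sources; k-mers are handled as rolling 2-bit packed
integers, vectorized with numpy.

## Recovery: increase, decrease, connection

**Increase.** Positives are the bin members; the negative set is every
meta-O contig whose mean footrule distance to the bin exceeds mu + 2 sigma
of the intra-bin distance distribution (computed over all members >= 300
bp, so short-contig rank noise keeps the cut realistic); the rest is the
test set. An RBF-kernel SVM (C = 1, gamma scale, balanced class weights,
standardized features) trained on codon-usage vectors predicts candidate
target contigs among the test set. The codon-usage feature is the
frame-free overlapping trinucleotide profile of the whole contig:
unannotated contigs carry no reliable reading frame, and a longest-ORF
frame (available via `mga.orf_frame`) samples only a few hundred bases,
which measurably degrades sensitivity. Contigs under `mga.min_contig`
(300 bp) are not classified.

**Decrease.** Seed contigs — meta-O contigs >= 90% covered by bin k-mers
(short contigs must be fully covered: on a 100 bp contig a single
unmatched window is a divergence signal, not an edge effect) — provide a
length-weighted depth sample. A Gaussian mixture (EM, BIC over K in
{1,2,3}) models it; the genome's intrinsic depth is taken as the
lowest-mean component among those with weight >= 0.25 rather than simply
the heaviest: sharing with other genomes or repeat collapse can only
inflate depth, so when the seed-depth distribution is multimodal the
lowest substantial mode is the target's own depth. Candidates whose depth
deviates more than `mga.depth_sd` (2) standard deviations are discarded;
landmarks are the survivors plus all seeds.

**Connection.** Bounded breadth-first maps (edge bound `mga.step_limit`
30, appended-span bound `mga.span_limit` 15 kb) are computed from each
landmark; a node is recovered when forward and backward bounds from two
distinct landmarks combine within both limits — the standard
meet-in-the-middle relaxation of "every node on any bounded
landmark-to-landmark path", whose exact form is exponential on
strain-variation tangles. Landmarks are always retained. All graph edges
between recovered nodes are kept.

**Simplification.** Tips (dead-end chains <= `mga.max_tip_nodes` nodes
and < `mga.max_tip_len` bp, attached to the graph on one side and
carrying no landmark) are removed to a fixpoint. Bubbles are detected
superbubble-style: from each branching state the nearest node reachable
from *all* out-branches is the candidate exit; the walk set is every
bounded simple path to it (DFS pruned to states that can still reach the
exit, with an expansion budget and a walk-count cap of
`mga.max_bubble_walks`); a bubble requires that no interior node connect
outside the walk set. Interior nodes on >= 2 walks are uniform, the rest
divergent. A bubble whose divergent sequences align pairwise at >=
`mga.identity` (0.95; global alignment, match +1 / mismatch -1 / gap -2,
identity = matches / columns) is a variant, not a repeat: the walk whose
depth is nearest the depth-model mean is kept and each other walk is
recorded in `removed_walks` and deleted — deletion removes the walk's
nodes that are not on the kept walk. The latter detail matters when
substitutions sit closer than k-1 apart: the arms of adjacent bubbles then
interconnect into "ladder" structures whose walks share all interior nodes
pairwise, leaving no walk-private node to delete.

Maximal unbranched chains of the simplified graph become scaffolds
(overlaps collapsed exactly); chain ends joined by an
orientation-consistent Plink are concatenated with max(10, estimated
distance) Ns. Total contig bases are conserved across scaffolds.

## Strain-level variation

Variant bubbles are the detected bubbles that pass the identity filter,
lose walks below `variation.min_walk_depth` (2-fold; error-like), still
have >= 2 walks, and have at most `variation.max_walks` (3) walks. Per
component of the target graph:

- bubble density = sum(LD) / (sum(LD) + sum(LU)), the divergent fraction
  of component bases (LD, LU: divergent / uniform node lengths);
- bubble identity = mean alignment identity over the component's variant
  bubbles, 1.0 (flagged) when there are none.

The per-genome summary m is the average component identity after a
single-pass removal of components outside +-3 sd. A logistic model on
X = (1, m, k) with k = ln(m / n), n the component count, is fitted by
batch gradient descent on cross-entropy (zero initialization, fixed
learning rate `variation.lr` = 0.5, `variation.gd_iters` = 5000
iterations — deterministic); label = probability >= 0.5.

Per-bubble variant abundances solve a weighted non-negative least squares
problem (scipy's active-set solver): one indicator row per walk with its
divergent-node depth, one all-ones row per uniform node with its depth,
row weights w = 1 - e^(-x * 0.5 / 100) for supporting contig length x
(short contigs carry noisy depth). Abundances are the normalized
solution; per-bubble alpha diversity is the Shannon entropy
H = -sum Pi ln Pi (natural log, 0 ln 0 = 0). The natural log is also used
in k = ln(m/n); both bases are conventions isolated in single functions.

Bubble distances delete all divergent nodes of a component and report the
accumulated lengths of the remaining maximal chains that were flanked by
bubbles on both sides; terminal chains are excluded.

## The Gaussian-mixture EM

One shared 1-D weighted EM serves insert sizes and depths: K in {1,2,3}
selected by BIC, deterministic initialization (means at weighted
quantiles, component sd = overall sd / 2K so well-separated modes are not
merged at the first E-step), sd floored (1 bp for inserts, 0.5-fold for
depths), 200-iteration cap, 1e-6 log-likelihood tolerance. Observation
weights are normalized to mean one so the BIC penalty stays on the
per-observation scale. It is hand-rolled because the environment's
mixture fitters do not accept per-observation weights.

## The synthetic community

The default fixture scales the 100-genome simulation design down to a
desk scale: 20 genomes x 200 kb, depths mapped from abundance rank
through a bounded power law d_i = 5 + 123 * ((n-i)/(n-1))^1.5 (rank 1 =
128x, rank n = 5x; a literal clamped d ~ rank^-1.5 would tie half the
community at exactly 5x, which the original design's 5-128x spread does
not exhibit), two strain pairs at ANI 0.98 (partners are founders with
i.i.d. point substitutions), and a shared-repeat library of 60 x 150 bp
sequences, each spliced into 2 positions of up to 3 genomes (~20
junction pairs per genome — enough contigs per genome for the 40%-seed
design and classifier training).

Genome sequences come from per-genome order-3 Markov models whose 64
context distributions are Dirichlet draws (total concentration 1.5)
rescaled so every context emits GC at exactly the genome's target (drawn
uniformly from [0.30, 0.65]); realized GC therefore lands within +-0.02 of
target, while genomes keep distinctive oligonucleotide signatures. The
concentration was set so between-genome footrule distances sit clearly
above within-genome ones on the fixture — the species-level separation
regime in which composition-based binning is informative, which is the
regime the original mock (real genomes of distinct species) occupies.
Weaker signatures make genomes *less* separable than real species and the
binning premise itself fails.

Contigs are unitigs of the compacted de Bruijn graph at k = 41 over all
genome sequences: genome walks are broken at every (k-1)-mer whose
bidirected in- or out-degree exceeds 1, segments overlap by exactly k-1,
and duplicates collapse canonically; the truth table maps every contig to
its (genome, position, strand) occurrences and per-contig depth is the sum
of its carriers' depths, Poisson-resampled. Concatenating a genome's
unitig walk reproduces the genome exactly, which anchors the whole fixture.

MDA-style mini-metagenome samples threshold a linearly interpolated
lognormal amplification field at the quantile matching the target covered
fraction; covered runs >= 500 bp become meta-S contigs (exact substrings).
Paired reads are drawn at each genome's depth with N(200, 20) inserts,
100 bp mates and uniform substitution errors (default rate 2%); truth
alignments place each mate on the unitig occurrence containing its 5'
start with the aligned length clipped at the unitig end (no split
records), which is adequate for the depth, insert-size and Plink round
trips.

**What the fixture does not emulate:** indels and chimeric reads (MDA
chimera formation in particular), assembler-induced misassemblies,
conserved genes shared across distant taxa, GC-dependent coverage bias,
and real taxonomic structure (the original mock used real genomes in
species/genus/family categories). Synthetic genomes are therefore cleaner
than real ones; passing the fixture shows the algorithms compose
correctly under the stated design, and the recovery/contamination bounds
should be read as one-sided.

**Evaluation.** Coverage is the fraction of reference bases covered by
exact 31-mers of the recovered scaffolds (inputs are error-free, so exact
matching suffices); contamination attributes each scaffold part to its
truth-table sources; NGA75 is the largest N such that co-linear
exact-match blocks of size >= N cover 75% of the reference. Step metrics
use candidate id sets against the truth table, with the sensitivity
denominator being true contigs >= 300 bp outside the seed bin. Genomes
whose seed bin covers < 30% of the genome are excluded from the report,
per the recommended-initial-coverage rule; genomes whose bin lacks 5
members >= 1 kb (the high-ANI strain partners fragment into sub-kb
contigs) skip the SVM and recover from seed landmarks alone — they count
in coverage/contamination but not in the step metrics, which describe the
classifier where it ran.

## Problem sizes

The default community (20 x 200 kb, ~11,000 unitigs of which ~2 x 3,500
belong to the strain tangles) runs the full pipeline plus binning in
roughly 2-4 minutes on one CPU; unit and property tests use 4-6 genome
communities of 15-60 kb. These sizes were chosen so the whole study is
re-runnable interactively while every stage still faces a non-trivial
graph (thousands of bubbles in the strain tangles, 16 separable clean
genomes, shared repeats in every genome).

## Known limitations

- Overlap detection reports one (longest) overlap per oriented contig
  pair; alternative shorter overlaps are not represented.
- The connection step's meet-in-the-middle bound can admit a node whose
  minimal-edge and minimal-span paths differ (a slight over-inclusion
  relative to exact bounded path enumeration).
- Bubble walks with no divergent sequence on one side (deletion alleles)
  align at identity 0 against a non-empty arm and are left unmerged; the
  simulator produces substitutions only, so indel alleles are untested.
- The strain classifier is trained on the mock community's labels; on
  real data its features (m, ln(m/n)) transfer but the weights should be
  refitted when a labeled set exists.
- No BAM/CRAM input, no gap filling with reads, at most 3 strains per
  bubble, no haplotype phasing across bubbles.
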