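# Methods

This note records the exact conventions, defaults and numerical choices
behind each stage of the pipeline, the rationale for decisions the
procedures leave open, and what the synthetic benchmarks do and do not
demonstrate.

## Trees, rooting and topological primitives

Trees are Newick files parsed with dendropy; internal node labels
(including IQ-TREE-style `aLRT/UFboot` dual supports) are carried as
opaque strings and never influence topology operations. A tree is
treated as rooted when its seed node has exactly two children.
Polytomies, zero-length and missing branch lengths are permitted.

Clade-based scoring requires a rooted traversal, but the upstream tools
that produce gene trees emit unrooted ones, so rooting is an explicit,
recorded policy rather than a hidden default: use the configured
outgroup if one is given; fall back to midpoint rooting when the
outgroup taxa are not a clan (with a warning); midpoint-root trees with
branch lengths; and root fully lengthless trees on the first leaf's
pendant edge so the choice is still deterministic. When the midpoint
falls exactly on a node, the remaining children are grouped under a
zero-length edge to restore a bifurcating root. Component
decompositions are insensitive to which edge *inside* an outgroup is
chosen, but sister sets near the root do depend on the root position —
hence the policy is part of a run's metadata, not an implementation
detail.

Bipartitions are reported one per internal edge of the tree as given
(for a rooted binary tree the two root edges induce the same
bipartition and are de-duplicated). A taxon set is a *clan* when it can
be separated from the rest by cutting one edge — the unrooted analog of
monophyly, used by the domain-violation screen.

## Split counting and marker ranking

The monophyletic components of a taxon set are the maximal clades of
the rooted gene tree whose leaves all belong to the set; one component
means the set is monophyletic. Unmapped taxa are transparent for the
decomposition (equivalent to pruning them first), so bacterial
sequences in an archaeal scoring run do not artificially split archaeal
clades; the sister-profiling stage deliberately uses the opposite
convention (see below).

Per bootstrap tree, a taxon counts as split when it lies outside its
clade's largest component. Size ties between components are broken
toward the component containing the lexicographically smallest taxon,
which makes the per-taxon attribution deterministic; the direction of
the tie-break is arbitrary but fixed. Clades with a single member
present can never be split. Both the clade-level and the taxon-level
totals are reported, since "how many times a taxon does not group with
its clade" can reasonably be counted either way.

Markers are scored over bootstrap replicates only — the ML tree serves
for validation and reporting. A clade counts toward
`percent_split_clades` when it is split in a strict majority (>50%) of
the replicates; the majority threshold is a parameter. The two ranking
criteria are combined lexicographically, percentage first, then the
normalized total, then the marker id, giving a total deterministic
order. Fraction selection takes `ceil(f·N)` markers from either end of
the ranking.

The domain screen excludes a marker when the union of its archaeal and
eukaryotic taxa is not a clan of the unrooted ML tree, i.e. when some
archaeal or eukaryotic sequence nests within Bacteria; markers with
fewer than three leaves are unusable and skipped with a warning.

## Sister profiling

For each clade label, each monophyletic component contributes exactly
one unit of observation weight at its parent node: the sister set is
the union of all other subtrees at that parent (multifurcations are
merged into one sister set), and the unit is divided among the labels
of the sister leaves proportionally to their counts. Unmapped leaves
are labeled by their domain (`domain:bacteria`, ...) when the taxon map
carries domains, else `unassigned`; they contribute sister weight but
are never focal. Components at the tree root yield no observation. The
component construction makes a monophyletic clade structurally unable
to be its own sister; self-weight can still arise from mixed sisters or
split clades and stays in the normalizing denominator but is excluded
from partner calls.

Weights are pooled over all (marker × bootstrap replicate) trees and
normalized once per focal label. Because the procedure's description —
averaging over trees and replicates — does not fix the order of
operations, a per-tree-average variant (normalize within each tree,
then average the distributions) is available behind a flag; on balanced
data the two agree. Partner calls require occurrence strictly above the
threshold (default 0.3). Sub-profiles keyed by component leaf set allow
profiling recurrent sub-clades of split focal groups separately.

## SR4 recoding and chi-square pruning

SR4 recoding maps `A,G,N,P,S,T→A; C,H,W,Y→C; D,E,K,Q,R→G; F,I,L,M,V→T`,
with `-` and `X` passing through; the scheme table is pluggable but
only SR4 ships.

The heterogeneity statistic is the classical contingency chi-square on
the taxon × state count table: gaps and `X` are excluded from the
counts (not treated as a 21st state), expectations come from row and
column marginals, and cells with zero expectation contribute zero.
Pruning removes `floor(f·L)` columns greedily: at each step the column
whose removal most decreases the total statistic goes first, the
statistic is recomputed after every removal, and ties go to the
leftmost column (which also makes the degenerate all-homogeneous case
deterministic: columns 1..k). Column indices are 0-based internally and
1-based in all reports. A one-shot variant ranks all columns once by
their removal effect on the full alignment; it is faster and, late in
a pruning run, can differ from the greedy order because the greedy
objective is pooled: as planted signal is depleted the marginal benefit
of the remaining biased columns shrinks linearly in their number, and
the last few can fall below chance fluctuations of unbiased columns.
Greedy removal is monotone non-increasing in the total chi-square by
construction.

## Co-proportionality screen

"Expected genome coverage" is interpreted as the Lander–Waterman
expected breadth `1 − e^(−depth)` with depth `r·l/g`; the ratio
function is pluggable since other expectations are defensible. The
three filters are strict inequalities exactly as specified: ratio
> 0.3, breadth > 0.1, reads > 10. Records with zero depth but positive
reported breadth are rejected as inconsistent rather than silently
filtered.

Normalized relative abundance is `Ar = (Nm/Ns)·(r·l/g)`. `Nm` is the
maximum read count over *all* input samples, computed before any
filtering or sample selection, so dropping a sample later does not
rescale the others. Sample inclusion requires the maximum focal-genome
Ar to be strictly above 1.0.

Zeros are replaced before the CLR transform by half the smallest
positive value in the table (configurable); a sample with no positive
abundance is an error. The proportionality statistic is
`ρ = 1 − var(x−y)/(var(x)+var(y))` on CLR rows with the n−1 sample
variance; it is symmetric, at most 1, and undefined when both vectors
are constant. "Proportional to more than three" focal genomes is read
strictly as ≥ 4, with both the ρ cutoff and the focal count exposed as
parameters.

## Synthetic benchmarks

The generators are pure functions of their seed and parameters; the
same call yields byte-identical output files.

*Species trees* are built by random sequential pairwise joins with
exponential branch lengths (a Yule-like shape), per clade and for the
backbone, so every clade label is monophyletic by construction and taxa
are split near-evenly over labels. The desk-scale preset — 32 taxa, 8
clades, 40 markers, K=50 bootstrap replicates — keeps the full test
suite in the minutes range on one core while leaving each stage's
signal clearly measurable.

*Transfers.* The default transfer model regrafts the whole recipient
clade onto an edge strictly inside the donor clan. This reproduces both
detection signatures at once: the recipient's sister becomes the donor
(the route the sister profile measures, with pooled occurrence equal to
the fraction of transferred markers), and the donor clade becomes
paraphyletic (what the split-counting rank penalizes). Moving a subset
of recipient leaves individually (`n_moved`) is also supported and
splits the recipient instead; note that with partial moves the pooled
sister occurrence of the donor is `f/(1+f)` rather than `f`, because
the left-behind component keeps reporting the original sister.
Benchmark donor/recipient pairs are chosen by `distant_pair`, which
requires the two clades not to be each other's species-tree sisters —
otherwise baseline and planted signal are confounded.

*Bootstrap noise* is modeled by independent random NNI moves per
internal edge (default probability 0.02), not by resampling alignment
columns: it is a topology-level stand-in that is cheap, seedable and
sufficient to exercise the aggregation logic. It does not reproduce the
correlation structure of real bootstrap replicates, so passing tests
say nothing about bootstrap support calibration on real data.

*Biased alignments* draw unbiased cells i.i.d. from one fixed global
composition and biased cells (chosen columns × chosen taxa) from the
mixture `(1−skew)·global + skew·target`, where the target concentrates
on four residues absent from the global background. Keeping the
background disjoint from the target makes the planted heterogeneity
compositionally unambiguous, so truth recovery is well-defined; the
benchmarks use skew 1.0, i.e. biased cells drawn fully from the skewed
composition. Real compositional bias is milder and phylogenetically
structured, so recall numbers here are an upper bound on what the
statistic can do in practice.

*Abundance tables* give every genome a lognormal latent abundance
(per-genome location ~ N(2, 0.3), per-sample deviation ~ N(0, 1));
linked partner/focal groups share one latent series with multiplicative
lognormal noise of s.d. `noise_sd` (benchmarks: 0.1). Latents are
converted to integer read counts, Lander–Waterman breadths with 2%
jitter, and per-sample read totals, so the full
filter → Ar → CLR → ρ path is exercised including rounding; with zero
noise, planted pairs reach ρ = 1 only up to read-count rounding. The
location constant keeps typical depths near 2× so records pass the
mapping filters; inactive samples shift the focal genomes down by e^6,
putting them below the Ar > 1 inclusion rule.

## Benchmark scales and what they show

The verification suite runs at desk scale: 1,000 random trees of ≤ 12
leaves for the oracle comparison, 40 markers × 50 replicates for
transfer recovery, 20 × 500 alignments with 10% planted sites for
pruning, and 27 samples × 50 genomes with five planted pairs for
proportionality. These sizes were chosen so each stage's planted signal
is comfortably above its sampling noise; they demonstrate correctness
of the implementations and recoverability of planted signal, not
statistical power on real datasets, which are one to two orders of
magnitude larger in taxa, markers and alignment length.

## Known limitations

- Sister profiles depend on the rooting policy for unrooted input
  trees; profiles from differently rooted runs are not comparable.
- The greedy chi-square objective is pooled, so its final removals can
  trade planted columns for chance-heterogeneous ones (see above);
  recall within the first 10% removed is typically 90–95% on the
  planted benchmark, not 100%.
- No duplication-transfer-loss reconciliation: sister frequencies
  detect recurrent routes, not individual transfer events, and cannot
  distinguish transfer from compositional attraction.
- The NNI bootstrap stand-in and the disjoint-alphabet bias plant are
  idealizations; see the generator section for what they do not model.
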