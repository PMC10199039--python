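# Methods

## Model

Two sister lineages (tagged `Sturgeon` and `Paddlefish`) share an
autopolyploidy event at time `t_wgd` before present and speciate at
`t_spec < t_wgd`.  Between the WGD and rediploidization a locus segregates
tetrasomically; its four copies resolve into two diverging ohnolog loci
only at the (block-wise) rediploidization time `r`.  For a gene family
retaining both ohnologs in both species, the rooted four-gene subtree is

- `((S1,P1),(S2,P2))` with one duplication node at `r` when `r > t_spec`
  (**PreSpec**, shared resolution), or
- `((S1,S2),(P1,P2))` with lineage-specific duplication nodes at
  `r_S, r_P < t_spec` (**PostSpec**, independent resolution).

Classification is purely topological.  Of the 15 rooted leaf-labelled
topologies on four tips, the three balanced shapes are PostSpec (two
same-species cherries) or PreSpec (two mixed cherries); the twelve
caterpillars are "Other".  We subdivide Other by the species composition
of the caterpillar's single cherry — same-species = PostSpec-like, mixed =
PreSpec-like — which is equivalent to classifying the unrooted central
split, and is the unique total rule under which every Other topology is
one branch move (one NNI) from its main topology.  This yields the census
1 PostSpec : 2 PreSpec : 4 PostSpec-like : 8 PreSpec-like.  Quartet
subtrees containing a polytomy are reported as `unresolved`, never forced
into a category.  With a single paddlefish gene (ohnolog lost or
collapsed) only three rooted triplets exist: the one whose cherry unites
the two sturgeon copies is PostSpec-type, the other two are PreSpec-type.

Topology identity is computed on leaf-label clusters, so it is invariant
to child order and Newick rotation.

## Tree processing

**Rooting.** Each gene tree is rooted on the branch of the single most
distantly related sequence, using a species rank derived from the fixed
13-species tree (depth of the LCA with the focal clade: chondrichthyans
before sarcopterygians before bichir before neopterygians).  Ties among
equally ranked species are broken by the lexicographically smallest gene
identifier — the rule is arbitrary but deterministic.

**Clans.** Monophyly is assessed in the unrooted sense: a leaf set is a
clan iff some edge bipartition isolates it exactly (the set or its
complement appears as a cluster).

**Reconciliation.** Strict LCA reconciliation labels an internal node a
duplication iff its child leaf-species sets intersect, and maps it to the
species-tree LCA of its leaf species.  No duplication-loss cost model is
used.

**PHOG quartet extraction.** Within a larger orthogroup, each ohnolog
quartet is extended to the highest ancestor whose subtree contains no
additional focal-species sequence, maximising retained outgroups; an
ancient duplication with both copies retaining 2+2 yields two disjoint
extracted families.

**Family filters.** Families are excluded when either species' ohnologs
share a chromosome, any focal gene sits on an unplaced scaffold (placed
chromosomes are a per-species configured list), no outgroup is available
for rooting, the focal four are not a clan, or the focal copy number is
not 2+2.  Reason codes are reported independently; a family passes iff
none fires.

**Support filtering.** The two UFBoot values checked are those of the two
non-root internal edges of the rooted quartet subtree — the only pair of
supports interior to it.  A family passes cutoff `c` iff
`min(s1, s2) >= c`.  Missing supports count as 0 under filtering
(conservative) and are flagged; `strict=True` raises instead.

**Fold deviation.** Against the uniform-topology null (each of the 15
rooted shapes equally likely: PostSpec 1/15, PreSpec 2/15, Other 12/15),
`fold = (count/total) / expectation`.  Unresolved quartets are excluded
from the totals and reported separately.

**Diagnostics.** Average pairwise identity excludes gap-gap columns per
pair and counts residue-vs-gap as mismatch (this convention can differ
slightly from other alignment-statistics tools, which is why it is stated
here).  A variable site has >= 2 distinct non-gap residues; parsimony
informative needs >= 2 residues each twice.  Evolutionary rate = tree
length / leaves; treeness = internal share of tree length; RCV = mean
absolute deviation of per-taxon residue counts from the mean composition
over taxa x length; saturation is the through-origin regression slope of
uncorrected on patristic distance (we report the slope itself: 1 =
unsaturated, smaller = saturated).  Branch-length rate comparisons use the
two-sided paired Wilcoxon test after removing pairs with either length
>= 0.15 (extreme-outlier rule); group comparisons elsewhere use Bonferroni
correction.

## AU test

Per-site log-likelihoods of the three unrooted quartet topologies are
computed by Felsenstein pruning under the JTT empirical exchangeability
matrix with its published stationary frequencies (observed frequencies are
available via the model object) and 4 equal-probability discrete-gamma
categories represented by conditional means.  The five branch lengths are
optimised per topology by bounded coordinate-wise scalar minimisation
(two sweeps, bounds `1e-6`–`10`, `xatol 1e-4`) — robust and ample for
four-taxon trees.  The gamma shape is estimated once by 1-D optimisation
(bounds 0.1–20) on the topology that fits best at shape 1, then reused for
all three topologies; branch lengths are re-optimised per candidate
topology (re-using estimates would bias against alternatives).  All-gap
columns are skipped and recorded.

The AU test resamples the per-site log-likelihoods (RELL) at ten scales
`r = 0.5 … 1.4`, 1000 replicates per scale by default.  A topology counts
as best in a replicate whenever it attains the resampled maximum, so
exactly tied topologies receive identical bootstrap proportions.  The
probit-transformed proportions are fitted by weighted least squares to
`z(r) = d*sqrt(r) + c/sqrt(r)` using only scales with proportions strictly
inside (0,1) (weights from the binomial delta method), and
`p_AU = 1 - Phi(d - c)`.  Fewer than two usable scales means the
proportions are degenerate and the p-value is set to 1 (proportions near
1) or 0 (near 0); indistinguishable topologies (identical site vectors
throughout) all receive p = 1.  An unrooted *type* (PreSpec-type has two
member topologies) is called rejected only when every member topology has
`p < alpha`.

## Ks

The estimator is NG86 with Jukes–Cantor correction: per-codon
synonymous-site fractions exclude changes to stop codons from the
counting; observed differences at multi-hit codons are averaged over all
minimal substitution pathways, discarding pathways through stops (falling
back to all pathways in the rare case none avoids them); codon pairs with
ambiguity, gaps, or stops are skipped pairwise; `d = -3/4 ln(1 - 4p/3)`;
`p >= 3/4` flags the pair non-computable.  The counting estimator was
chosen over a maximum-likelihood codon-model pipeline deliberately: the
claims being checked concern the *ordering* of category-wise
distributions, which counting preserves, while absolute values may differ
slightly from ML estimates.  Only the universal genetic code is supported.

Dataset bookkeeping: each classified family contributes one intra-sturgeon
and one intra-paddlefish ohnolog pair labelled by its category; each
PreSpec family additionally contributes exactly two cross-species ortholog
pairs read off the gene-tree cherries (their divergence is the speciation
itself); single-copy orthogroups form a separate ortholog set.  Flagged
pairs are dropped; records with `Ks >= 0.3` are kept but marked excluded
(summaries skip them by default).  Densities use a Gaussian kernel with
Silverman bandwidth on a fixed 512-point grid over [0, 0.3] for
reproducibility; quartiles use linear interpolation; mode counting uses
peak prominence above 10% of the density maximum.

## Synteny

Link anchors are gene midpoints.  Modes: `intra` (one within-species link
per species per family), `inter` (the two ortholog links of PreSpec
families), `combined` (PostSpec intra + PreSpec inter).  Blocks are
maximal same-category runs along a chromosome pair tolerating up to
`max_gap` interleaved other-category links, with at least `min_genes`
members; defaults `min_genes=3`, `max_gap=1` are package choices (no
standard calling threshold exists for this construction) and are exposed
in configuration.  Input order is irrelevant (internal sort).  The
clustering statistic is the number of adjacent same-category pairs in gene
order; the null is uniform label permutation;
`p = (1 + #{perm >= obs}) / (1 + n_perm)`.  A chromosome with a single
category present is degenerate (p = 1).  Circos link and karyotype writers
reproduce the >40 Mb macrochromosome / <20 Mb microchromosome labelling
conventions as options.

## Coverage

The single-copy reference depth is the kernel-density mode of the two-copy
ohnolog gene set (>= 10 values required).  A gene is called double-depth
iff its depth exceeds `threshold_factor` x reference; the default 1.5 is
the midpoint of the 1x and 2x peaks (no published cutoff exists; the
double peak is identified visually in practice).  The double fraction is
monotone non-increasing in the factor, and classification is exact for
noise-free 1x/2x depths for any factor in (1, 2).  Read mapping and depth
extraction are upstream of this package; input is a per-gene mean-depth
table.

## Supermatrix preparation

Dating families are PreSpec with both quartet supports exactly 100 and no
duplicate genes in any other species.  Per replicate and family a seeded
fair coin assigns one ohnolog pair as the "A" copy; rows are
SturgeonA/PaddlefishA/SturgeonB/PaddlefishB plus single-copy outgroups;
families missing any required sequence are dropped with a record (the coin
stream still advances, keeping assignments aligned across reruns).
Partitions tile the untrimmed matrix exactly.  No-gaps trimming removes
every column containing a gap or missing character and is applied
post-concatenation; entropy-based trimming (as performed by dedicated
external tools) is not implemented, so trimmed site counts are not
comparable to workflows that apply it.  The Bayesian dating itself is
external; relaxed PHYLIP and FASTA writers provide its input.

## Simulator

The generator realises the shared-WGD/asynchronous-rediploidization model
directly.  Times are in arbitrary units with defaults `t_root=3`,
`t_wgd=1`, `t_spec=0.5`; outgroup lineages hang off the focal quartet at
fixed node depths chosen to respect the accepted 13-species topology.  Per
block one candidate rediploidization time is drawn uniformly over
(0, `t_wgd`) by default (the true waiting-time law is unknown; uniform is
the least-informative choice); `u > t_spec` makes the block PreSpec with
shared time `u`, otherwise both lineages draw independent
Uniform(0, `t_spec`) times.  The expected PreSpec fraction is therefore
`(t_wgd - t_spec)/t_wgd`, and the fraction can be set by moving `t_spec`.
Genes inherit their block's category and are laid contiguously on
WGD-derived chromosome pairs (copy A/copy B on the two members), mirrored
across species.

Branch lengths are lineage rate x time span; defaults
`rate_sturgeon = rate_outgroup = 0.15` substitutions/site/time unit (root
to tip ~0.45) and paddlefish 1.2x faster, reflecting the faster paddlefish
substitution rate.  Amino-acid sequences evolve under JTT (+ optional
discrete gamma); codon sequences evolve by a jump process in which each
single-nucleotide change to a sense codon has rate `syn_rate/3` if
synonymous and `nonsyn_rate/3` otherwise (defaults 0.12 and 0.024), so
realised pairwise Ks tracks `2 x syn_rate x divergence time` and the
category Ks expectations are ~0.06 (PostSpec), 0.12 (orthologs) and
0.12–0.24 (PreSpec) — inside the analysis window, with the >= 0.3 filter
biting only the tail.

Supports are a heuristic stand-in for real ultrafast bootstrapping (which
would dominate runtime): a logistic function of the internal branch
length, `100 / (1 + exp(-(b - b50)/scale))` plus Gaussian noise (sd 2),
with `b50 = 5e-4` and `scale = 2e-4`.  These defaults emulate the strongly
saturating behaviour of ultrafast bootstrap proportions — near 100 for any
branch longer than a few thousandths of a substitution per site, dropping
steeply only below that — so that support filtering removes genuinely
uninformative subtrees rather than imposing a long quasi-linear penalty
that real UFBoot values do not show.  Topology noise applies one NNI
inside the quartet with probability `p_nni * exp(-b_min/0.005)`,
concentrating errors on families whose rediploidization time is near the
speciation (shortest internal branches), and depresses the affected
supports to 20–80; an NNI always converts a balanced shape into a
caterpillar, so noise inflates 'Other', never the opposite main category.

Ohnolog loss removes one paddlefish copy (family becomes a triplet at 1x
depth).  Assembly collapse — possible only for PostSpec families with
paddlefish rediploidization more recent than `collapse_recency` (default
`t_spec/2`) — merges the paddlefish copies into one gene at 2x depth.
Other genes draw Normal(30, 3) depths.  The simulator does not emulate:
incomplete lineage sorting or hybridisation, chromosome rearrangements,
gene conversion, alignment error (sequences are simulated already
aligned), or raw reads.  Passing tests on simulated data therefore
demonstrate correctness of the inference machinery under the model's
assumptions, not robustness to every artefact of real genome data.

## Orchestration and problem sizes

All randomness in a pipeline run derives from one master seed through
named per-stage substreams, so runs are bit-reproducible.  The expensive
stage is the AU likelihood optimisation, so the orchestrator runs it on a
seeded subsample of families (default 8) and simulates codon data for a
Ks subsample (default 120 families, 200 codons); all other stages use
every family.  Test-suite simulations use 10^3 families for
fraction-recovery checks, 200 replicates for AU calibration, and
10^3-replicate RELL bootstraps — sizes at which the Monte-Carlo error is
comfortably below the tolerances being asserted.

## Known limitations

- The PreSpec-like/PostSpec-like subdivision rule for unresolved edge
  cases is this package's own (split-based) definition; other
  implementations may treat polytomies differently.
- NG86 Ks values differ slightly from ML codon-model estimates; only
  orderings and distribution shapes should be compared across estimators.
- The heuristic support model is a stand-in; absolute support values carry
  no statistical meaning beyond their monotone relation to branch length.
- The saturation statistic is reported as the regression slope; some tools
  report `1 - slope`.
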