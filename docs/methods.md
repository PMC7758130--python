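# Methods notes

## Study model and contexts

The package analyses a four-group, two-assay (mRNA + miRNA) log2 expression
design: EC monoculture (A), cocultured ECs (B), NSPC monoculture (C),
cocultured NSPCs (D).  Context 1 is the contrast B vs A (NSPC-induced EC
alteration), context 2 is D vs C (EC-induced NSPC alteration); the control
group is always the monoculture.  All stages treat the two contexts
symmetrically and meet in the cross-context crosstalk scoring.

## Differential expression

Per contrast, the per-feature statistic is the empirical-Bayes moderated t:
pooled two-group variances s² on d = n₁+n₂−2 df are shrunk to
s²ₚₒₛₜ = (d₀s₀² + d·s²)/(d₀+d).  The hyperparameters are estimated by
method of moments on z = log s²: under s² ~ s₀²·F(d, d₀), var(z) exceeds the
sampling term trigamma(d/2) by trigamma(d₀/2); inverting the trigamma
(Newton iteration) gives d₀ and the corrected mean of z gives s₀².  When the
observed dispersion does not exceed the sampling term the prior is treated
as a point mass: d₀ = ∞, s₀² = mean(s²) (the unbiased estimate of a common
variance; this also makes the degenerate all-equal-variances input return
that common value exactly), P-values then come from the normal limit.
Otherwise P is two-sided on d₀+d df (capped at the pooled residual df), and
the B statistic is the log posterior odds with prior DE proportion 0.01 and
a fold-change prior variance estimated by quantile matching on the top |t|
values, bounded by coefficient sds [0.1, 4] rescaled by s₀².  The whole path
reproduces the reference R implementation (limma's lmFit/eBayes two-group
output) to ~1e-14 on all columns; that agreement is asserted in the test
suite with the R package used only as an independent oracle.

Calling rule: raw P < 0.05 and |log₂FC| ≥ 0.5, direction by the sign of
logFC.  Raw rather than adjusted P is deliberate: the report tables still
carry BH-adjusted values (computed via statsmodels), but the calling rule is
the raw-P threshold.  Ties in P-sorted reports break on feature id so output
files are stable.

## Overlap semantics

Genes "overlap" between contexts only when concordant (same direction in
both); discordant both-DE genes are kept as their own category.  miRNAs are
considered overlapped when DE in both contexts regardless of direction —
the direction-discordant miRNA pair is a real phenomenon in this design and
must stay eligible for crosstalk.  Both rules are exposed by one partition
object (`OverlapResult`).

## Hypergeometric machinery

pmf and upper tail are computed in log space with gammaln; out-of-support k
returns probability 0, k at or below the support minimum has tail 1.  The
engine is validated exhaustively against big-integer rational arithmetic for
every valid (N ≤ 40, M, n, k).  ORA intersects term sets and query with the
universe (all features of the expression matrix), tests only terms with
k ≥ 1, and reports BH adjustment within each analysis family (per
collection, per chemical screen); significance for downstream set
construction is raw p < 0.05.  The miRNA–chemical screen maps each pair to
(N = |gene universe|, M = |targets(miRNA)|, n = |genes(chemical)|,
k = overlap) — the only self-consistent reading with k ≤ M — and retains
pairs with p < 0.05 as chemical-network edges.

## Connectivity scoring

The KS statistic follows the two-sided running-maximum form (a/b terms over
ascending tag positions); an exact a = b tie resolves to the +a branch,
which matters only for measure-zero constructions and is pinned by a test.
S = 0 when KS_up and KS_down agree in sign, else KS_up − KS_down; outputs
also report S/2 so values are bounded by [−1, 1] (a fixed normalization
rather than a per-batch max-|S| rescaling, documented in the output header
semantics).  Signatures order features from most up- to most down-regulated;
tag sets and signatures must share one identifier namespace — any upstream
ortholog/probe conversion is out of scope and enforced as a precondition.

## Crosstalk scoring and the network

Meet/Min = |A∩B|/min(|A|,|B|) per dimension.  An empty set on either side is
*undefined* (sentinel "no common features", printed as NA), distinct from a
genuine zero overlap; the pair filter removes rows whose target dimension is
zero or undefined, or which have no positive dimension at all.  The five
per-(miRNA, context) sets are derived as: DE targets = merged
(validated ∪ predicted) targets ∩ that context's called DEGs; molecules =
drugs with nonzero integrated S in the context whose signature ranks the
miRNA in the top or bottom quartile (per-miRNA drug association; a purely
context-level set would be identical for every miRNA and make the dimension
uninformative); chemicals = association-screen pairs retained at p < 0.05;
pathways/BPs = terms with raw p < 0.05 in ORA of the miRNA's DE targets.
Network nodes are context-namespaced, so a miRNA active in both contexts
contributes one node per side and its self-pair is an ordinary edge;
bridging miRNAs are those appearing on both sides of retained edges, ranked
by summed target-dimension score.

## Topology metrics

All centralities are computed on the undirected simple-graph view
(directionality of TF/miRNA edges is annotation only).  Disconnected graphs
are handled per component: average shortest path length over the component,
closeness = 1/aspl, betweenness normalized by (m−1)(m−2)/2 with m the
component size; isolated nodes get 0 by convention.  The topological
coefficient of v averages J(v,m)/deg(v) over partners m (nodes adjacent to v
or sharing a neighbor), with J = shared neighbors plus 1 if adjacent, and is
0 for degree ≤ 1.  Top-k tables rank by descending degree with lexicographic
tie-break.

## Synthetic data: what it emulates and what it does not

The generator plants, per context, DE genes and DE miRNAs with an exact
±effect_size_log2 mean shift in the experimental group; shared-concordant
genes shift the same way in both contexts, shared-discordant genes
oppositely; miRNA up/down splits follow the emulated design (5/13 in context
1, 5/3 in context 2, scaled for other counts).  Noise is i.i.d. Gaussian
with sd = noise_sd_log2 (default 0.25), constant across features: a
heavy-tailed per-gene variance prior was considered and rejected because at
n = 3/group and effect 1.0 it makes recovery of individual planted features
intrinsically unreliable (the |logFC| ≥ 0.5 gate alone then misses several
percent of planted features), defeating the generator's role as a
ground-truth instrument.  The moderation estimator consequently sees a
near-degenerate variance distribution in synthetic runs; its ability to
recover a genuinely hierarchical prior is tested separately by simulating
s² ~ s₀²F(d, d₀) directly (d₀ = 4, s₀² = 0.04).

Annotations are built for identifiability: each one-context planted miRNA
regulates a disjoint module of its own context's exclusive DE genes, shared
miRNAs regulate (overlapping) draws from the shared DE genes, background
targets come from non-DE genes, each planted module is annotated to a
designated pathway and BP term, chemical gene sets for planted (miRNA,
chemical) pairs sample the miRNA's targets, and each drug signature places
the planted up/down tag miRNAs in the extreme 15% zones according to the
drug's planted sign per context.  Real data differ in ways the generator
does not model: probe-level artifacts, normalization and batch effects,
correlated noise, promiscuous and overlapping target annotations, and
incomplete/biased interaction databases.  Passing recovery tests therefore
demonstrates the pipeline's correctness and identifiability under the
stated statistical structure, not robustness to annotation noise.

Default scale: 2000 genes, 300 miRNAs, 3 replicates/group; 150/220 planted
DE genes with 20 concordant + 6 discordant shared (mirroring the ~2:3 ratio
and overlap proportion of the emulated study at desk scale), 18/8 DE miRNAs
with 3 shared, 20 drugs, 30 chemicals, 40 pathway and 60 BP terms.  These
sizes keep a full pipeline run at a few seconds while leaving BH and the
moment estimators enough features to behave asymptotically.

## Numerical and reporting conventions

Report tables print at 6 significant/decimal digits (crosstalk scores fixed
6 decimals); expression matrices round-trip at full double precision (%.17g)
so file-based runs reproduce in-memory runs bit-identically.  Logs contain
no timestamps, making whole output directories byte-reproducible for a
fixed seed.  All randomness flows from a single integer seed
(numpy default_rng; annotations use seed+1 so study and annotations can be
generated independently).

## Known limitations

No statistical null model for Meet/Min scores (none is defined for the
method); GO term ancestry is ignored (flat GMT sets); multi-factor designs,
missing values and weighted networks are out of scope; the drug screen
requires both an up and a down tag set per context and reports an empty
table otherwise.
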