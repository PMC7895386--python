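# Methods

This note documents the models, the numerical choices, and the design
decisions behind `phylotrait`, and states what the synthetic benchmark
does and does not demonstrate about real data.

## Problem setting

The pipeline asks which gene families (EC numbers and Pfam domains,
measured as per-genome copy numbers) are associated with the gain or
presence of a binary genomic trait — in the motivating application, the
Calvin cycle, called positive when a genome carries both of its unique
markers (Rubisco large subunit and phosphoribulokinase). Because genomes
are related by descent, naive cross-genome comparisons confound trait
association with phylogeny; the design counters this in two ways: a
phylogenetically matched case–control set (closest-relative pairing) and
an explicitly phylogenetic analysis (ancestral character estimation on
subtrees).

## Trait calling

A genome is trait-positive iff it retains ≥1 filtered homology hit for
*every* required marker. Hits are filtered by full-sequence E-value
(default < 0.01) and, for Rubisco, by the presence of the catalytic
lysine at a fixed column of a supplied reference alignment; form-IV
Rubisco-like proteins lack this residue and must not count. Marker
identity is established by a model-id whitelist on the hit table rather
than re-annotation, keeping the stage deterministic. Genomes whose
taxonomy contains an excluded label (e.g. Cyanobacteria, whose deep
divergence would dominate any contrast) are dropped entirely; this is
the only path by which a genome leaves the dataset at this stage.

## Pairing

Greedy global-minimum matching: repeatedly select the smallest remaining
(positive, negative) distance, remove both genomes, until every positive
is paired. This is deliberately the greedy loop, not optimal assignment:
the greedy order is part of the method being reproduced. Ties are broken
lexicographically by (positive accession, negative accession) so results
are permutation-invariant and reproducible. Distances are consumed, not
computed — the pipeline derives them as patristic distances on the input
tree; any externally computed matrix with the same axes works.

## Enrichment

Two-sided Wilcoxon rank-sum per feature. Copy-number data is massively
tied, so the dominant code path is the tie-corrected normal
approximation with continuity correction (via `scipy.stats.mannwhitneyu`,
matching R's `wilcox.test`); the exact null is used only for pooled
samples of ≤ 20 tie-free observations. Benjamini–Hochberg adjustment is
applied jointly across both feature types. Features with all-zero counts
in both groups are removed from the testing pool (they carry no
information and would dilute the correction with p = 1 entries); the
trait markers themselves are excluded because their enrichment is
circular. The ≥ 95% completeness filter applies to this stage only; the
ACE and forest stages receive all paired genomes.

When one group mean is zero the log2 ratio is reported as a ±inf
sentinel and excluded from any range summary.

## Ancestral character estimation

**Subtree choice.** Candidate subtrees are internal nodes with 50–300
leaves (bounds configurable; 20–100 is used for the 200-genome
benchmark, where the default bounds would leave almost no candidates).
Each candidate B is scored against a reference tree A by

    s = exp(−(|ln(P_B/P_A)| + |ln(N_B/N_A)| + |ln(c_v,B/c_v,A)| + |ln(h_B/h_A)|))

with P/N the trait-positive/negative leaf counts, c_v the coefficient of
variation of all edge lengths in the (sub)tree, and h the maximum
root-to-tip height; s ∈ (0, 1], s = 1 iff all four statistics match, and
s is symmetric in A and B. Selection is greedy by descending s, skipping
candidates whose node set overlaps an already accepted subtree.
Candidates that cannot be scored (a zero statistic, e.g. a one-class
subtree) are skipped. Two structural rules: the full tree is never a
candidate for itself (whole-tree reconstruction is exactly the regime in
which ancestral trait signal washes out — the reason subtrees exist),
and the reference is a held-out clade. On real data the reference is a
separate domain (e.g. the archaeal tree, analysed as subtree 0); on
synthetic data the smaller root child plays this role when it has ≥ 8
leaves and both trait classes, otherwise whole-tree statistics serve as
reference and nothing is held out.

**Discrete reconstruction.** 2-state Mk model with equal rates (the
conventional default when the rate model is unstated). The likelihood is
computed by Felsenstein pruning with per-node scaling; the single rate is
fitted by a 40-point log-grid scan on [1e-8, 1e3] followed by bounded
scalar refinement between the flanking grid points. Marginal ancestral
likelihoods use the standard two-pass (re-rooting) algorithm with a
uniform root prior, appropriate for a symmetric model. All-one-state
input short-circuits to certainty for that state: the ML rate sits at
the boundary and every reconstruction is degenerate. Likelihoods sum to
one per node and swap under relabeling of the two states (both are
tested).

**Continuous reconstruction.** Ancestral copy numbers under Brownian
motion, computed by Gaussian message passing: each adjacent direction
(child clades, rest of tree) contributes a Gaussian estimate whose
variance grows linearly with path length, and the node estimate is their
precision-weighted mean. This equals the GLS/BM conditional expectation
obtained by re-rooting at each node (tested against the explicit
covariance-matrix oracle) and is linear in the leaf values, so all
features are reconstructed in one vectorised pass. Zero-length edges are
floored at 1e-9 to keep precisions finite.

**Per-feature statistics.** Spearman correlation (average-rank ties)
between trait likelihood and ancestral count across a subtree's internal
nodes, plus a Wilcoxon test between nodes classified positive
(likelihood strictly > 0.5; ties go to the negative class) and negative.
BH adjustment is per subtree and per test type — each subtree is its own
testing universe. The per-feature summary is

    Σ|r_w| = Σ_n |r_n| · w(q_c,n; q̃_c) · w(q_W,n; q̃_W),
    w(q; q̃) = ln(q + q̃) / ln(q̃)

with q̃ the median q across all subtrees and features. The raw weight is
1 at q = 0, decreasing in q, but turns negative as q → 1 (the log of a
value above 1 divided by a negative log); it is therefore clamped to
[0, 1], preserving the intended monotone down-weighting while keeping
the statistic non-negative. A subtree entry with an undefined r or an
undefined Wilcoxon q (an empty node class) contributes nothing; a
feature absent from every subtree scores 0 and shares the bottom rank.
Significance is flagged when both q-values are < 0.001.

## Random forest

EC and Pfam universes are processed entirely separately — impurity
importances are only comparable within a type. Constant columns are
dropped, then recursive feature elimination under L2-penalised logistic
regression (liblinear, raw counts — the coefficients feed only a
rank-based elimination) removes 10 features per round down to 600 per
type. Each of 100 repetitions draws an unstratified random ¾/¼ split
(resampled if a class goes missing), fits a 500-tree forest, and records
held-out accuracy and importances; per-repetition seeds are
`master*10000 + repetition` so any single repetition is re-runnable.

One caveat established empirically: recursive elimination with a
ridge-penalised linear model handles *mutually redundant* informative
features poorly in its final rounds — when only a handful of features
remain, the coefficients collapse onto one representative of a
correlated group. With the keep-rates the pipeline actually uses
(hundreds kept out of thousands), planted informative features survive
reliably; eliminating down to exactly the number of planted redundant
features does not, and the test suite checks the former regime.

## Consensus

Each method contributes average-tie ranks: enrichment q ascending,
Σ|r_w| descending, forest importance descending (within type, so one EC
and one Pfam share each forest rank). The consensus is the rank of the
sum; a feature absent from a method (e.g. eliminated before forest
training) carries that method's maximum rank + 1. Consensus depends only
on ranks and is invariant to monotone transforms of any method's scores.

## Gene-neighborhood proximity

In trait-positive genomes, distances between feature-bearing ORFs and
marker ORFs are absolute differences of ordinal positions on the same
contig, in ORF counts. Contigs are treated as linear even when the
molecule is a known-circular chromosome — most assemblies are unplaced
scaffolds, and a uniform convention avoids a mixed metric at the cost of
over-stating some distances. Every feature copy is measured against
every marker copy ("all copies"); a marker measured against itself on
the same ORF is excluded by default (a flag restores it), while
marker-to-marker distances between distinct ORFs are kept so the mutual
proximity of the markers is reported. Summaries are per (feature,
marker, strand relation), with counts split by molecule type and the
plasmid fraction computed over placed (chromosome/plasmid) occurrences
only, NaN when none are placed.

## Synthetic data generator

The generator emulates the pipeline's real inputs under controlled
conditions:

* **Tree** — pure-birth (Yule) process, default rate 1.0, forward
  simulation to n leaves plus one final waiting time, so trees are
  ultrametric. Pure-birth rather than birth–death keeps one parameter
  and suffices for method testing.
* **Trait** — 2-state continuous-time Markov chain along branches, root
  drawn from the stationary distribution. Defaults q01 = 0.2,
  q10 = 0.4: the trait is the minority state (stationary fraction 1/3),
  mirroring the minority prevalence of real trait datasets and
  guaranteeing the negative pool is large enough for pairing.
* **Counts** — each feature's log-mean evolves by Brownian motion
  (default variance rate 0.1) from a base log-mean of 0; a fixed random
  10% of features are trait-linked and receive +1.5 on the log scale
  (≈ 4.5-fold) in trait-positive leaves; observed counts are Poisson.
  The trait effect is multiplicative on expected copies, matching the
  log2-ratio scale on which enrichment is interpreted.
* **ORFs** — 1–3 contigs per genome; positive genomes carry a marker
  operon (both markers adjacent, same strand) at the start of the first
  contig, and copies of linked features are placed immediately
  downstream with probability 0.8 (configurable), emulating operon-like
  clustering; all other copies land on random ORFs, one copy per ORF,
  so the per-genome ORF feature multiset equals the matrix row exactly.

Ground truth (internal trait states, linked-feature identities, latent
log-means) is kept on the dataset object and written to sidecar files.

**What the benchmark shows — and does not.** The recovery benchmark
(200 genomes × 300 features, 10% linked, effect 1.5, subtree bounds
20–100, 20 forests × 200 trees) demonstrates that the full pipeline
concentrates planted trait-linked features into the top decile of the
consensus ranking (≥ 80% capture at the benchmark seed) and that the
enrichment and forest stages are calibrated under the null (type-I rate
near 0.05 with no effect; permuted-label accuracy near 0.5 on the
balanced paired set, averaged over 10 permutations — a single
permutation of ~100 genomes is itself noisy at the ±0.1 level). The
generator does **not** simulate horizontal transfer as a process,
annotation error, assembly incompleteness, correlated features beyond
shared phylogeny, or rate variation across lineages; passing these tests
therefore validates the statistical machinery and its implementation,
not robustness to every failure mode of real comparative-genomics data.
Recovery also degrades when the realized trait prevalence in a simulated
tree is unusually low (few positives ⇒ less power in every stage), which
is expected behaviour, not a defect.

## Numerical and edge-case choices

* Branch lengths are floored at 1e-9 wherever reconstruction needs
  positive lengths.
* Mk rate search bounds [1e-8, 1e3]; degenerate (one-state) input
  bypasses the search.
* Wilcoxon: exact only for pooled n ≤ 20 without ties; otherwise
  tie-corrected normal approximation with continuity correction.
* The Σ|r_w| median q-values are clipped into (0, 1) before taking
  logs; weights clamped to [0, 1].
* Average-tie ranking everywhere a rank is produced.
* Greedy ties (pairing, subtree selection) break lexicographically.
* Forest ¾ sampling is unstratified simple random sampling; splits that
  lose a class are resampled and logged.
* The benchmark pipeline scales are stated above; the full-scale
  defaults (subtree bounds 50–300, 100 forests × 500 trees, keep 600 per
  type) remain the package defaults.

## Known limitations

* The equal-rates Mk assumption is fixed; asymmetric-rate or covarion
  models are out of scope.
* The weight clamp is a documented deviation from the literal weight
  formula, which is unbounded below.
* Proximity treats every contig as linear; distances on genuinely
  circular molecules can be overstated by up to half the contig length.
* The consensus penalty (max + 1) makes absent-from-forest features
  comparable but slightly favours methods that rank everything.
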