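# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Domain profiles and scanning

A profile is a position-specific scoring model built from a seed alignment:
columns with more than 50% gaps are dropped from the match states, and each
match state scores residue *r* as `log2((n_r + 1)/(n + 20) / 0.05)` —
observed frequency with pseudocount 1 against a uniform 5% background, in
bits.  Scanning is local alignment (Smith–Waterman) of the profile against
the protein with affine gaps (defaults: open 10 bits, extend 1 bit);
sub-optimal non-overlapping hits are found by recursing into the sequence
segments flanking each accepted hit.

Significance is calibrated empirically: the profile is scored against ≥200
random sequences of its own length drawn from the uniform background, a
Gumbel distribution is fitted to the resulting maxima, and a hit's e-value is
the Gumbel tail probability scaled by search space — `(protein length /
calibration length) × search_space`, where `search_space` (default 1000)
plays the role of the database size in a proteome scan.  The candidate
threshold is e < 1, so on a scan of a thousand random proteins about one hit
this good is expected by chance; the suite verifies that random sequences
yield e < 1 hits in ≤10% of trials.

A hit is flagged **degenerate** when its bit score falls below a fraction
(default 0.6) of the profile's trusted self-score (the consensus scored
against the profile).  Degeneracy of A domains is a qualitative notion in the
literature; 0.6 cleanly separates half-length degenerate domains (score
ratio ≈ 0.5) from full domains at the divergences the generator produces
(ratio ≈ 0.8 at 15% divergence), with several standard deviations of margin
at domain length 480.

This scanner is a calibrated position-specific scoring model, not a full
profile HMM: the screening logic downstream (threshold, architecture calling,
module counting) is the object of interest, and the scanner's contract —
local hits with calibrated e-values — is all it requires.  HMMER2 ASCII
profiles can be imported through `read_hmmer2_profile` (match emissions only,
recalibrated natively) when real published profiles are to be used.

Architecture calling resolves overlaps greedily by bit score.  Two hits
conflict when their overlap exceeds 30% of the shorter hit; score ties break
by earlier start, then by the canonical domain order A < T < C < R, making
the call deterministic.  Degenerate A domains render as `dA`;
`module_count` counts A plus dA.  Split gene models must be merged in the
input FASTA — no gene-level rescanning of genomic DNA is attempted.

## A-domain sets and masking

Phylogenies are built from individual A domains (id `protein|m<k>`, k the
1-based module index), not whole proteins, so multimodular synthetases
contribute one leaf per module; degenerate domains are excluded by default
and domains shorter than 150 residues are dropped as partial.  When hits
carry profile coordinates and contain no indels, extracted domains are
gap-padded onto the profile coordinate system, which yields an alignment
directly; otherwise an external aligner adapter (mafft) is used.  Column
masking removes a column iff its gap fraction strictly exceeds the threshold
(0.30 for full datasets, 0.50 for reduced ones) — a column at exactly the
threshold survives.  Masking is idempotent and preserves row order.

## Distances, trees, supports, rooting

Pairwise distances are maximum-likelihood under WAG exchangeabilities and
stationary frequencies with discrete-gamma rate heterogeneity (4 categories,
category rate = mean of its equal-probability quantile bin; shape α defaults
to 1.0 and is configurable — observed-frequency `+F` mode is a flag).  Sites
where either sequence has a gap or a non-canonical residue are ignored.  The
likelihood is maximized by bounded scalar search on [1e-6, 10] to tolerance
1e-6; saturated pairs cap at 10.  The rate matrix is normalized to one
expected substitution per site per unit distance, so distances are in
substitutions/site.

Neighbor joining follows the standard Q-criterion agglomeration with two
documented choices: Q-ties (within 1e-12) pick the lexicographically
smallest label pair, and negative intermediate branch lengths are clamped to
zero with the deficit moved to the sister edge (their sum is preserved).
Output is unrooted with a trifurcating root node.  Bootstrap supports
resample columns with replacement to the original length; an internal edge's
support is the percentage of replicate trees containing the identical
leaf-set bipartition, rounded to the nearest integer.  Supports are invariant
to row order (rows are sorted by label before the distance pass).

Rooting places the root at the midpoint of the edge subtending the smallest
clade containing all outgroup labels; supports are re-attached by unrooted
bipartition, which is invariant to the root position.  The three-tree
consensus requirement is met by three configurable builders — by default NJ
under three gamma shapes (0.5, 1.0, 2.0); external ML programs can be
substituted through newick files, since the subfamily extractor consumes
trees, not alignments.

## Consensus subfamilies

A subfamily is promoted during a preorder walk of tree 1 when (i) its
subtending edge has support ≥ cutoff (70 by default, per-tree configurable),
(ii) a clade with the identical leaf set exists with support ≥ cutoff in
trees 2 and 3, and (iii) it contains at least one reference synthetase.
Once promoted, the subtree is not descended — "most internal branch from the
root" — which makes calls maximal and pairwise disjoint (asserted on every
run).  The clade whose complement is the outgroup is never promoted: its
subtending edge is the rooting edge itself, so it is the trivial
"all synthetases" group rather than a subfamily.  Clades failing the support
test are rescued when the same composition exists in all three full trees and
is supported at ≥ rescue cutoff (80) in every reduced-dataset tree,
intersecting compositions with the reduced leaf set.  Leaves in no promoted
clade are reported unplaced.

Gene assignment is by majority vote over a gene's A-domain leaves; ties take
the N-terminal-most module's subfamily and any gene whose modules split
across subfamilies is flagged recombinant (the tie rule is this package's
choice; published tables do not state one).  Genes with all modules unplaced
go to `Other`.

## Fisher tests

Association between a subfamily and a taxonomic group is tested on the 2×2
table (genes in subfamily ∧ group, in subfamily ∧ not group, other genes in
group, other genes outside).  The default alternative is one-sided
"greater" (overrepresentation); the comparison universe defaults to all
species and can be restricted (e.g. the two Dikarya groups).  The exact test
is scipy's; the test suite verifies it against exhaustive integer
hypergeometric enumeration for all margins ≤ 30.  Odds ratios use the
Haldane–Anscombe +0.5 correction on zero cells.  No multiple-testing
correction is applied by default; Benjamini–Hochberg is available across the
subfamily × group scan.  An empty margin yields p = 1 with a warning rather
than an error.

## Birth–death gene-family model

Each gene duplicates and dies at the same rate λ (per gene per time unit of
the species tree; My for dated trees); 0 genes is absorbing.  With
α = λt/(1+λt) the transition probability is evaluated in the all-positive
form `P(c|s,t) = Σ_k C(s,k) C(c−1,k−1) α^{s+c−2k} (1−α)^{2k}`,
`P(0|s,t) = α^s` — each of the s ancestral lineages either goes extinct
(probability α) or leaves a geometric number of descendants.  The
alternating-sign form usually quoted is algebraically identical but
numerically unstable for α > ½ at realistic family sizes; the tests assert
the equality where both are stable and also check a matrix-exponential and a
Gillespie-simulation oracle.  The state space is truncated at
`c_max = 2·max(tip count) + 10` with rows renormalized; the likelihood's
truncation error is checked by a plateau test.

The family likelihood is computed by pruning (vectorized across families),
requiring the tree to be ultrametric within relative tolerance 1e-6.  A
single global λ̂ maximizes the summed log-likelihood over families (bounded
search on [1e-8, 10/height], tolerance 1e-8); at the stated simulation
design (100 families, 10 taxa, height 1000 My, λ = 0.002) the median
relative error over 20 replicates is well under 30%.

Family significance is Monte-Carlo: n families (default 1000) are simulated
under λ̂ on the same tree and the p-value is the fraction with
log-likelihood ≤ the observed one, add-one corrected so p ∈ [1/(n+1), 1].
The root prior is uniform over 1..c_max by default (root 0 excluded,
consistent with the parsimony filter below).  `analyze_families` instead
conditions each family on its **parsimony root count** by default (point
prior; null families simulated from the same root state): with an uninformed
uniform prior, low-copy families all look alike and p-values are driven by
the prior rather than the data.  The conditioning is modestly anticonservative
(the null false-positive rate in the demo runs near 0.1 at nominal 0.05)
because it ignores root uncertainty; branch-level calls are unaffected.

Branch significance uses the most probable joint ancestral reconstruction
(max-product dynamic programming, ties to the smaller state): for an edge
with reconstructed parent s and child c over time t, the p-value is the total
probability of transitions from s no more probable than the observed one —
a two-sided exact tail by probability ordering (the cited tool's precise
definition is not published; this one is declared, documented behavior).
Direction is expansion if c > s, contraction if c < s.  Families whose
Sankoff parsimony root count (absolute-difference edge costs, smallest state
on ties) is zero are excluded from fitting and scoring, mirroring the
exclusion of lineage-restricted families that violate the model's
root-presence assumption.

## Synthetic data: what it emulates, and what it does not

The generator provides ground truth for every stage.  Proteins are built
from per-domain-type consensus sequences (A 480, T 80, C 430, R 340
residues — realistic sizes so coordinates are meaningful) joined by random
linkers of 10–50 residues; non-NRPS tokens in hybrid templates (KS, AT, ACP,
…) become inert 300-residue segments.  Each subfamily's A consensus
substitutes a *disjoint* block of the shared consensus's sites (the offset
fraction, default 0.3, capped at 1/n_subfamilies so blocks never overlap);
each gene's domains are the subfamily consensus mutated independently at the
requested divergence.  Disjoint blocks make between-subfamily distance exceed
within-subfamily divergence while leaving the deep between-subfamily splits a
hard polytomy — no two subfamilies share derived residues, so no intermediate
grouping carries bootstrap signal, and the planted subfamilies really are the
maximal clades the consensus rule should find (mirroring the unresolved deep
relationships of real A-domain radiations).  Degenerate A domains are the
N-terminal half of the subfamily consensus.
Seed alignments (10 copies at ≤2% divergence, first copy exact) are emitted
per subfamily for A and per type for T/C/R, so profiles can be built from
generator output alone.

Mutations are uniform across sites and residues — there is no site-rate
variation, no indels within domains, no amino-acid exchangeability structure,
and no compositional bias.  Passing tests on this material therefore
demonstrate the correctness of the screening logic, coordinates, consensus
rules and statistics, not scanner sensitivity on remote real homologs, where
alignment quality and profile curation dominate.

Method-tree triplets plant disjoint clades that are identical (composition
and per-tree supports) in all three trees; elsewhere the trees differ by
random NNI moves that swap complete subtrees only, so planted clades can
never be broken.  Background internal edges carry supports drawn uniformly
from [5, 65] — below the 70% cutoff by construction, which is what makes the
planted clades the unique ground truth; an outgroup clade is kept intact at
support 99.  Birth–death counts are simulated event-by-event (Gillespie),
making the generator an independent oracle for the closed-form transition
probabilities; ultrametric species trees are pure-birth trees rescaled to a
fixed height with pendant edges pinned exactly.

## Pipeline and problem sizes

The pipeline runs scan → architectures → A-domain set (+ outgroup, masking)
→ three bootstrap NJ trees → subfamilies → counts → Fisher → birth–death
from one config; every stage reads and writes files in the working
directory, so stages re-run from stored intermediates, and all outputs carry
the config hash and seed (identical config + seed ⇒ byte-identical outputs;
the output directory itself is excluded from the hash).  Stage errors halt
the run with the stage named; partial outputs are retained.

The shipped demo uses 6 species in two groups, four planted subfamilies
(≈30 A-domain leaves with the outgroup), 40 bootstrap replicates per tree,
and 20–30 birth–death families with one planted eight-fold expansion below a
short internal branch (about a tenth of the tree height, so the jump cannot
be smeared across edges by the joint reconstruction).  These sizes keep a
full run in the low minutes on one core while leaving the planted signals
several standard deviations clear of their thresholds; production runs on
real proteomes would raise the bootstrap replicates (the classic choice is
200 for NJ) and the resampling count, both plain config fields.

## Known limitations

- The scanner has no insert states; domains with long internal insertions
  relative to the profile will fragment or truncate (affine gaps mitigate
  short ones).
- One global λ for birth and death, across lineages and families; no
  separate birth vs death rates, no among-family rate variation.
- Subfamily extraction requires exact leaf-label identity across the three
  trees — labels must be normalized upstream.
- Fisher tests treat genes as independent draws; no phylogenetic correction.
- The parsimony-conditioned family p-values ignore root-state uncertainty
  (see above); treat marginal family-level calls with care and prefer the
  branch-level tests for localization.
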