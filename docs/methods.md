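# Methods

`cladetrace` implements the computational core of a parsimony-based
character-tracing analysis on a molecular phylogeny: discrete characters
(here, maximum occurrence depth and habitat type of deep-sea
chemosymbiotic clams) are mapped onto a fixed tree, the minimum number of
state changes is computed, and the correlation between character and
phylogeny is tested against a null distribution of parsimony lengths on
random trees.  Around that core sit the supporting computations such a
study needs: pairwise sequence divergence, neighbor joining for fixture
trees, and GTR+I+G likelihood evaluation on a fixed topology.

## Parsimony reconstruction

For one character with state alphabet of size k on one rooted tree, the
engine is the Sankoff dynamic programme over an arbitrary k x k step
matrix C (zero diagonal, nonnegative costs).  Bottom-up, each node v
carries a cost vector S_v(s) = minimal cost of v's subtree given v in
state s; each child contributes `min_t [C(s,t) + S_c(t)]` and
contributions sum over children, so polytomies need no special handling.
The parsimony length is `min_s S_root(s)`.

A second, top-down pass computes for each node the cost A_v(s) of the
rest of the tree given v in state s; a state s belongs to the MPR
(most-parsimonious-reconstruction) set of v exactly when
A_v(s) + S_v(s) equals the global minimum, i.e. when some globally
minimal reconstruction assigns s to v.  Nodes whose MPR set has more
than one state are flagged *equivocal* — these are the grey branches of
classic character-tracing plots.  Ties are never broken silently; the
single-reconstruction export picks the lowest state index and is
documented as one-of-many.

Two step matrices are built in: *unordered* (every change costs 1 step —
"unweighted" parsimony, the default, matching how depth and habitat are
traced in the motivating analysis) and *ordered* (cost |i - j|, natural
for ranked depth intervals).  A bitmask Fitch pass provides a fast path
for unit costs on binary trees; the test suite verifies Fitch, Sankoff
and an exhaustive enumeration oracle against one another, including MPR
sets and the minimal-transition count (for general costs, the minimal
number of *changed branches* among minimal-cost reconstructions is found
by a lexicographic (cost, changes) variant of the same DP).

Missing states: taxa without a state for the analysed character are
pruned from the tree for that character (wildcard treatment would make
step counts indeterminate).  Parsimony length under a symmetric step
matrix is invariant to rerooting (tested); MPR sets are reported for the
rooting given.

## The randomisation signal test

Phylogenetic signal is operationalised as: the observed parsimony length
is smaller than lengths of the same character on random trees.  The null
distribution is built from N randomised trees (default N = 1000) by one
of two methods:

- `random_topology` (default): a fresh topology drawn uniformly from all
  labelled rooted binary topologies over the same tip set, by sequential
  random addition — each next tip is inserted on a branch chosen
  uniformly, including the branch above the root, which makes every one
  of the (2n-3)!! topologies equally likely (chi-square-tested for n = 4
  and 5).  This matches the equiprobable-random-trees convention of
  classic character-tracing software.
- `shuffle_tips`: the observed topology is kept and tip labels are
  permuted uniformly.

Significance is the one-tailed rank p-value with the add-one correction,
p = (1 + #{null lengths <= observed}) / (N + 1), so p is never 0 and the
test is exact (never anti-conservative) under exchangeability.  The
z-like descriptive (observed - null mean) / null s.d. is reported
alongside, mirroring the mean-of-null comparison older software
emphasised.

A caveat the test suite documents: parsimony lengths are small integers,
so the null distribution is heavily tied on small trees with few states.
Because tied null values count against rejection, the realised size of
the test at nominal alpha = 0.05 is slightly below 0.05 (around 0.03 for
24 tips and 4 balanced states with N = 199); the add-one rank rule is
kept because it is standard and safe, and the conservatism vanishes as
the length support widens.

## Monophyly classification

On a rooted tree, a named group is *monophyletic* when the smallest
clade spanning its members contains no other tips; *paraphyletic* when
the non-member tips inside that spanning clade themselves form a single
clade (removing one nested clade leaves the group exclusive);
*polyphyletic* otherwise.  Members absent from the tree are dropped with
a report; fewer than two members present makes the group
*not assessable*.  The classification is rooted-tree dependent and
reported as such.

## Depth and habitat coding

Depth in metres is discretised into 13 half-open intervals
[lower, upper); a depth exactly on a boundary belongs to the deeper
interval, and the deepest interval is open above.  The default edges —
200, 500, 1000, 1500, 2000, 2500, 3000, 3500, 4000, 4500, 5000, 6000 m —
place the first boundary at the shelf break and slice the bathyal and
abyssal zones; they are a documented, fully configurable default, and
every analysis here is agnostic to the exact edges.  Habitat is a
4-category unordered character in the fixed order Seeps, Vents, Seeps
and Vents, Coastal (case-folded, with a small synonym map; unknown
labels are an error, never coerced).  The depth character defaults to
*unordered* costs to match unweighted-parsimony tracing, with the
ordered mode one flag away.

## Molecular computations

*Divergence* is the uncorrected p-distance — mismatches over columns
where both sequences have a plain A/C/G/T (pairwise deletion) — which is
what percent-divergence statements in COI barcoding practice refer to;
Kimura 2-parameter correction is available behind a flag.  Intra-group
divergence maxima are exhaustive over pairs.

*Neighbor joining* (Q-criterion, Studier–Keppler branch lengths) is
provided as a fixture-tree builder, not a phylogenetic-inference claim:
on exactly additive matrices it provably recovers the generating
unrooted topology with branch lengths to 1e-9 (tested on 200 random
trees), and negative branch-length estimates on non-additive input are
clamped to zero with a warning.

*GTR+I+G likelihood*: Felsenstein pruning with the general
time-reversible rate matrix built from 6 exchangeabilities and 4
stationary frequencies, scaled to one expected substitution per site per
unit branch length (so branch lengths are comparable with standard ML
software).  Among-site rate variation uses Yang's discrete-gamma
construction: ncat equal-probability categories (default 4) represented
by their conditional means under Gamma(alpha, alpha), renormalised to
mean 1.  With a proportion p_inv of invariable sites, the site
likelihood is

    L = p_inv * L_inv + (1 - p_inv) * mean_c L_c

where L_inv sums the stationary frequencies of every state compatible
with all tips at the site (gaps and ambiguities are compatible with
everything) and L_c is the pruned likelihood with branch lengths
multiplied by the category rate.  Gaps/ambiguities enter the pruning as
all-ones partial likelihoods.  The evaluator is verified against a
closed-form Jukes–Cantor two-taxon expression and against brute-force
summation over all internal-state assignments and categories; by
reversibility the value is invariant to rerooting (tested to 1e-8).
There is deliberately no optimisation of parameters, branch lengths or
topology — model parameters are inputs, as in a study where tree search
and model fitting are done by dedicated ML software.

## Synthetic data generator

The generator emulates the *shape* of the motivating dataset: 87 taxa, a
630 bp COI-like alignment simulated under GTR+I+G with the published
heterogeneity estimates for that marker (p_inv = 0.39, alpha = 0.54),
transition-rich exchangeabilities (AG = CT = 6) and AT-rich base
composition (0.28/0.16/0.18/0.38), plus a 13-state depth character and a
4-state habitat character evolved under the Mk model on a 53-taxon
ingroup subset.  Ground truth (generating tree, all ancestral states,
parameters) is written alongside, and every output is byte-deterministic
per seed.

Scale choices, with reasoning:

- **Tree prior**: pure-birth (Yule), the simplest process with a
  closed-form height expectation `sum_{k=2..n} 1/(lambda k)` usable as a
  test oracle.  Default birth rate 0.28 per unit time.  With 53 taxa
  this gives an expected total tree length of ~190 time units, so the
  default character rate below produces on the order of ten character
  changes across the tree — comparable to the number of transitions a
  depth or habitat reconstruction shows at this taxon scale, and far
  from the degenerate regime where a character is constant and carries
  no testable signal.
- **Mk characters**: symmetric k-state model; `rate` is the total rate
  of leaving the current state (each alternative gained at
  rate/(k-1)), so a two-state character changes on a branch of length t
  with probability (1 - e^(-2 rate t))/2 and characters with different
  k share one change budget.  Default rate 0.05 per unit time = strong
  signal; raising it weakens signal monotonically (tested).  Root state
  uniform.
- **Sequences**: Yule branch lengths are multiplied by 0.03
  substitutions/site per time unit, giving a root height of ~0.4
  substitutions/site at 87 taxa — family-level COI divergence.
- **Root-state recovery** is scored as: the true simulated root state is
  contained in the root's MPR set (the standard notion of a
  reconstruction recovering the truth when ties are reported as sets).

What the generator does *not* emulate: real COI base composition beyond
a crude AT bias, codon structure, among-lineage rate variation,
alignment error, or any ecological correlation between depth and habitat
(characters are independent given the tree).  Passing tests on this
synthetic data therefore show the *algorithms* are correct and the test
is calibrated and powerful under the model — they do not validate the
biological conclusions one would draw from real data.

## Numerical and interface choices

- Newick round trips preserve topology and labels exactly and branch
  lengths to better than 1e-9 (10 significant digits written).
- Rerooting subdivides the chosen branch at its midpoint, preserving all
  tip-to-tip path lengths; an old root left with a single child is
  spliced out with lengths summed.
- Step-matrix DP uses float costs with a 1e-9 tie tolerance; unit-cost
  lengths are returned as exact integers.
- NEXUS export is a restricted CHARACTERS dialect (SYMBOLS line,
  MISSING=?) that classic character-tracing programs and dendropy both
  read.
- CLI exit codes: 0 ok, 2 input/parse, 3 validation, 4 internal; every
  stochastic subcommand requires an explicit `--seed` and is then
  byte-reproducible.

## Problem sizes used in the checks

The test suite exercises the engines at the scales the analyses actually
run at: oracle equivalences on hundreds of random instances up to 12
tips (enumeration oracles up to 7 tips / 4 states, where exhaustive
labelings are cheap); calibration with 1000 replicate datasets of 24
tips and N = 199 randomisations; power and root-state recovery with 200
replicate 53-taxon datasets and N = 1000; simulator fidelity with
2000-replicate height checks and a 50 kb pairwise alignment; and the
full 87-taxon / 630 bp end-to-end pipeline, run twice to confirm
byte-level reproducibility.

## Known limitations

- Parsimony only: no likelihood (Mk) ancestral-state estimation, no
  Dollo or weighted variants beyond the step matrix.
- The signal test conditions on the observed tree being correct; tree
  uncertainty is not propagated.
- The likelihood evaluator does not optimise anything; it is an
  evaluator for fixed topologies and parameters.
- Monophyly classification is rooted-tree dependent by design; callers
  working with unrooted trees must root deliberately (e.g. on an
  outgroup) first.
- p-distances are not additive; NJ on them is a visual/fixture device,
  not inference.
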