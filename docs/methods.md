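# Methods

## Model overview

`rnagvae` treats an RNA molecule as a (sequence, nested secondary
structure) pair and represents it by the unique derivation of an
unambiguous context-free grammar. The derivation's production rules
are written into an L x 17 binary matrix; a variational autoencoder
learns the distribution of these matrices; and generation inverts the
encoding by maximum-score dynamic programming over rule scores
computed from a reconstructed (real-valued) matrix. The pipeline is
strictly modular: grammar <-> matrix <-> VAE, so each stage is testable
in isolation.

## Grammar and parsing

The grammar uses non-terminals S (leftmost unpaired emission), T
(right-end trimming, pair closure, bifurcation) and U (one base pair),
with spans indexed 1-based and inclusive:

```
ss: S[i,j] -> n S[i+1,j]     (terminal: S[i,i] -> n)
st: S[i,j] -> T[i,j]
tt: T[i,j] -> T[i,j-1] n
tu: T[i,j] -> U[i,j]
tb: T[i,j] -> T[i,k] U[k+1,j]
us: U[i,j] -> n S[i+1,j-1] n'
```

Assumptions and constraints:

* structures are nested (pseudoknot layers in input annotations are
  opened to unpaired with a warning — a CFG cannot represent them);
* every pair is canonical (au, ua, cg, gc, gu, ug); the data pipeline
  opens all others before parsing;
* a pair needs a non-empty interior (`us` requires j >= i+2), so the
  adjacent pair `()` is a hard parse error;
* gap `-` and padding `x` are ordinary terminals but may only occupy
  unpaired positions.

Because the grammar is unambiguous, `parse` is a deterministic O(L)
walk guided by the bracket-matching table, and `realize` is its exact
inverse (`realize(parse(x)) == x` is property-tested).

## Binary encoding

Columns 1-6 (Bn) one-hot the character at each position (a, c, g, u,
-, x). Columns 7-17 (Bg) receive rule flags: `ss`, `st`, `tt`, `tu`
write row i of columns 7, 9, 11, 13 and row j of the following column;
`tb` writes rows i, j, k of columns 15, 16, 17. Two choices the
layout forces or leaves open:

* the terminal `S[i,i] -> n` is encoded as a degenerate `ss` with
  j = i (columns 7 and 8 both at row i), which matches the DP base
  case below;
* `us` writes no grammar columns — the 17-column budget (6 + 2x4 + 3)
  has no room, and its decoding score uses only the nucleotide
  columns of the two partners;
* collisions (e.g. chained `ss` rules sharing j) are OR-resolved, so
  the matrix stays binary.

Flattening is row-major; the model's I/O contract is the length-17L
vector.

## Maximum-score decoding

Given `B_hat` in [0,1]^{L x 17}, each rule scores as the product of
its cells, e.g. `pi(ss[i,j,n]) = B[i,7] B[j,8] B[i,I_n]` and
`pi(us[i,j,n,n']) = B[i,I_n] B[j,I_n']`. Three L x L tables M_S, M_T,
M_U are filled by the natural recurrences (maximizing over characters
N and pairs P inside each rule), and the optimal tree is recovered by
traceback from M_S[1,L]. Numerical and tie-breaking choices:

* infeasible spans (T/U shorter than 3) carry a distinguished
  "impossible" marker (-1), not score 0, so a zero-score feasible
  parse still beats an illegal one;
* ties break deterministically: at S, `ss` before `st`; at T, `tt`
  before `tu` before `tb` with splits in increasing k; characters in
  alphabet order; pairs in the order au, ua, cg, gc, gu, ug; the
  first maximum wins. The brute-force oracle enumerates skeletons in
  the same preference order, so both sides agree on ties;
* the plain O(L^3) recursion is used throughout; products are plain
  float64 (at the sequence lengths this package targets, L up to a
  few hundred, underflow of [0,1] products is not reachable in
  practice; extremely long sequences with near-zero scores would
  need a log-space variant, which is a known limitation);
* the traceback recomputes candidate values with exactly the same
  floating-point association as the fill, so exact equality
  identifies the argmax;
* decoded sequences may contain `-`/`x`; downstream generation strips
  them (they are always unpaired).

Guarantees verified by tests: the exact encoding of any tree decodes
to score exactly 1 and reproduces the sequence (the one-hot Bn factors
force each emission); single-hairpin structures are recovered exactly,
while multi-stem inputs can admit alternative score-1 structures
because flank columns are encoded independently; and the DP equals
exhaustive enumeration on all random instances up to L = 7.

## VAE

Encoder: flattened matrix -> 4096 -> 2048 -> 516 -> (mu, log sigma^2)
with ReLU activations; decoder mirrors the encoder; the output layer
applies a row-wise softmax over the six Bn columns and elementwise
sigmoids over the eleven Bg columns, so every reconstructed value lies
in [0,1]. The latent space is 8-dimensional. `scale_factor` shrinks
all hidden widths proportionally (1/16 to 1/64 for the reduced models;
the "516" width is as configured, not rounded to a power of two).

Loss, for one matrix:

```
loss = alpha * CE(Bn, Bn_hat) + beta * BC(Bg, Bg_hat)
       + lambda * KL(q(Z|B) || N(0,I))  [+ w * (a_hat - a)^2]
alpha = 1/L,  beta = 1/(11 L),  lambda = 0.001,  w = 1
```

CE and BC are summed over elements before scaling, which makes
`alpha*CE` the mean per-position cross-entropy (ln 6 = 1.7918 under a
uniform prediction — a closed form the tests pin). The KL is the
closed form for a diagonal Gaussian against the standard normal. The
activity head (latent -> 32 -> 1, sigmoid) is optional; activities
must be min-max normalized to [0,1].

Training uses Adam (lr 0.001), batch size 100, default 2000 epochs
(loss typically plateaus far earlier; an early-stop knob exists but is
off by default), a seeded 70/30 train/test split when requested, and
the standard reparameterization trick; evaluation-time encoding and
reconstruction use the posterior mean, so they are deterministic.
Training is bitwise reproducible for a fixed seed.

Two initialization choices matter at small step budgets and are part
of this package's design:

* the decoder's output bias is set to the training set's marginal
  log-odds before the first step, so optimization is spent on
  per-item differences rather than on re-deriving the family
  consensus;
* the log-variance head's bias starts at -8 (posterior sigma ~ 0.02),
  so early reconstruction gradients are not drowned in
  reparameterization noise; with the small KL weight used here the
  variance re-inflates as far as the objective wants.

Everything — forward passes, backpropagation, Adam — is NumPy; the
analytic gradients are checked against central finite differences
(max relative error ~ 2e-5 on a small model, asserted at 1e-4).

## Data pipeline

Unaligned mode strips gaps (their always-unpaired structure columns
drop with them) and pads with `x` at the 3' end to the family maximum
L. Aligned mode keeps `-` and requires equal lengths. Records are
excluded, and counted per reason, when the sequence contains letters
other than a/c/g/u (after lowercasing and t->u mapping), when the
grammar cannot derive the structure, or when the exact sequence was
already seen. Stockholm consensus structures (WUSS brackets of any
nested layer) are projected per sequence, opening pairs broken by
non-canonical characters or gaps. Activity tables are min-max
normalized per dataset ((x - min)/(max - min)); a constant column has
no defined normalization and is an error.

## Generation and analysis

Generation samples standard-normal latent points, decodes each
(`decode_latent` then `decode_max`), strips `-`/`x`, and filters
duplicates and exact training matches. `region_sample` draws uniform
points in a latent ball around a center to compare localized regions
(e.g. high- vs low-activity clusters); it keeps duplicates by default
since the local decode distribution is the object of interest.

Moran's I uses a binary, directed k-nearest-neighbor graph (Euclidean,
row weights 1), `I = (n/W) sum_ij w_ij d_i d_j / sum_i d_i^2`;
symmetrization is an option. The permutation null has mean -1/(n-1),
which the tests verify empirically.

Noise injection flips each Bg bit independently with the given rate,
leaving Bn untouched; robustness is summarized as the median structure
F1 (on base pairs) of decoding the perturbed encodings. Raw encodings
are brittle to this perturbation — the median F1 drops from 1.0 at
rate 0 to ~0 by rate 0.1 — because a single lost `us`-adjacent flag
can reroute the whole traceback; the tests assert the monotone
degradation, not a particular rate.

Sequence identities come from Biopython global alignment (match 1,
mismatch 0, gap -1), counting only columns where both sequences have a
base. This stands in for profile-based alignment against a family
model, which needs external tools and is out of scope.

## Synthetic families

`make_family` draws one consensus sequence for the family (random
canonical pairs on the consensus structure, random bases elsewhere),
then varies members two ways: with probability
`structure_perturb_prob` (default 0.3) one whole stem is opened —
stem-scale variation, emulating libraries where a local mutation
rearranges a full helix — and unpaired positions mutate independently
at `mutation_rate` (default 0.1). Families are therefore high-identity
(like natural seed alignments or mutant libraries), always
grammar-valid, and unique by bounded retry (a degenerate zero-rate
"family of clones" is available with `unique=False`). The default
family used across the tests has n = 50 members at L = 40.

Activity is a noisy deterministic function of structure: the fraction
of a target pair set present in a member's structure plus Gaussian
noise (sd 0.05), clipped to [0,1]. By default the target set is the
full consensus pairing, so opening any stem lowers activity in
proportion to the stem's size and the family shows a spread of
activity levels tied to its structural variants.

What the generator does *not* emulate: thermodynamic plausibility of
sequences, covariation between paired columns beyond canonical
complementarity, indel variation within a family (unaligned-mode
length variation enters only through padding), and measurement
artifacts of real activity assays. Tests passing on these fixtures
show the machinery is correct and that the latent space organizes
structure-determined signals; they do not certify generation quality
on natural families, which the identity statistics and (externally)
covariance-model scores would have to assess.

## Problem sizes used in the checks

The automated checks run deliberately scaled-down studies: round trips
on 500 inputs with L <= 60; decoder-vs-enumeration agreement on 100
random matrices at each L in 3..7; training runs with hidden widths at
1/64 of full size for 300 epochs (reconstruction) or 1000 epochs
(latent organization, 5 seeds x 2 models) on the 50-member family.
With these sizes the whole suite completes in well under an hour on a
single CPU. Full-scale widths (4096-2048-516) and 2000 epochs remain
the configured defaults for real use.

## Known limitations

* Multi-stem structure recovery from exact encodings is not unique
  (flank columns are independent), so structure identity is only
  guaranteed for single-hairpin inputs.
* The grammar cannot represent pseudoknots; annotations containing
  them are silently (with a warning) reduced to their nested layer.
* Covariance-model bit scores and profile alignments (the
  field-standard external quality measures) are not computed here;
  identity statistics use plain global alignment.
* The plain-float DP would underflow for extremely long, low-score
  inputs; a log-space variant is the natural extension.
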