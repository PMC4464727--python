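# Methods

## The alignment-set objective

The package treats pairwise genome alignment as a set-selection problem:
given candidate local alignments between a query genome and a reference
genome, report the set of disjoint candidate pieces maximizing
Σ(score − f).  The existence cost f plays the role of a per-alignment
prior: in the underlying generative picture, an unaligned background
emits letters until an alignment starts (probability mass α of starting,
γ of continuing), and taking logs turns the start/stop probabilities
into a constant cost per reported alignment.  Two consequences shape the
output:

* no reported alignment contains an internal contiguous segment with
  score < −f (otherwise splitting around the segment would raise the
  objective), so pathological interior regions of individual candidates
  are cut out rather than tolerated;
* overlapping candidates compete, and the dynamic program places the
  breakpoint between them optimally instead of keeping both.

One pass over the query yields many-to-one alignments ("1-split").  A
second pass with the roles of query and reference swapped, using the
same f, yields one-to-one alignments ("2-split").  Probabilities are
computed in the final pass, so the reported mismaps reflect the
competition actually present in that pass.

## Scores as scaled log odds

An integer substitution matrix S is read as t-scaled log odds: there is
a unique scale λ = 1/t > 0 and background vectors p, q with

    π_xy = p_x q_y e^{λ S(x,y)},  Σπ = 1,  row sums = p,  column sums = q,

whenever the matrix is a valid local-alignment matrix.  Writing
Y = exp(λS), the marginal conditions collapse to Y q = 1 and Yᵀ p = 1,
so λ solves 1ᵀY(λ)⁻¹1 = 1.  That function is not monotone near λ = 0
(Y approaches the singular all-ones matrix), so `compute_scale` scans a
logarithmic grid for the last positive-to-negative sign change and
polishes the root with Brent's method; residuals of all three constraint
families come out at machine precision (≪ 1e-10).  Matrices admitting no
such decomposition (e.g. no negative expectation) are rejected.

Gap cost inversion assumes the background-continue probability ω = 1
(the model takes the alignment-start probability γ ≈ ω², making the
γ/ω² factor in the substitution scores equal to 1):

    β = e^{−gap_extend/t},   α = β e^{−gap_open/t}/(1 − β).

This convention reproduces every published probability block of the
three shipped schemes (human-chimp.v2, HoxD70, HoxD55) at printed
precision, which is the strongest available evidence that it is the
intended reading.  The reverse direction rounds t·log odds to integers
and floors probabilities at 1e-12 before logs, so zero counts map to
large-but-finite penalties.

## Profiles and the dynamic program

Candidates are first oriented to the forward strand of the query
(MAF convention: a strand flip maps start to srcSize − start − size and
reverse-complements both rows together).  Each candidate i is reduced to
two integer arrays over its query span:

* A[i][j] — the score at query letter j: the substitution score for a
  match/mismatch column, or the affine charge for an inserted letter
  (−gap_extend each, plus −gap_open on the run's first letter);
* D[i][j] — the deletion charge between letters j−1 and j:
  −(gap_open + L·gap_extend) for a run of L deleted reference letters.

The per-letter attribution of an insertion run's open cost is a
convention (only run totals are determined); it can shift an optimal
breakpoint by one column inside a gap, which is why oracle tests compare
fragment totals rather than attributions.  Candidates must begin and end
with aligned-letter columns; ΣA + ΣD then reproduces the candidate's
score exactly, which is asserted at build time.

The recurrence (V for "last column lies in candidate i", W for the
running optimum) walks query positions once, visiting only candidates
whose span covers the position; W carries unchanged across uncovered
stretches.  Tie-breaks are fixed for determinism: continuation beats
restart at equality (so a dip of exactly −f does not split), the carried
W beats an equal V, and the lowest candidate index wins among equal V's.

## Forward–Backward and mismap probabilities

The probabilistic pass replaces max with sums of exponentiated scores
A' = e^{A/t}, D' = e^{D/t}, f' = e^{f/t}.  The forward quantity G
accumulates the partition function over all disjoint fragment sets
ending by position j (the empty set contributes 1, so z > 1 whenever any
candidate exists); the backward pass mirrors it.  The column posterior

    P[i][j] = (F[i][j+1] B[i][j] / A'[i][j]) / z

is the exact marginal probability that the column at query letter j of
candidate i belongs to the (model-random) reported set, and
F·B·D'/z gives the analogous probability for a deletion event between
two letters.  Error = 1 − P.

Numerics: F and G are divided by the running G at every position (the
standard HMM rescaling) and the log scale is accumulated, likewise B and
C against C; every reported ratio is formed in log space from the scaled
values, so probabilities are exact to floating-point rounding at any
span.  The forward and backward totals are required to agree to 1e-9
relative; disagreement raises rather than warns.  Scaling makes
overflow unreachable for per-column scores of ordinary magnitude; this
is property-tested at spans of 10⁴.

A fragment's mismap is the minimum error probability over its columns
that contain a query letter (a deletion column is not a query position;
its error is still reported on the p-line at the following query
letter).  The default filter keeps a fragment iff mismap ≤ 1e-5, i.e.
iff at least one of its positions is essentially unambiguous.

## Event counting and parameter fitting

`count_events` tallies substitution pairs over match columns and gap
runs in either row (one existence event per run, one extension per
additional column).  The gap extension probability is fitted by least
squares to log frequencies of gap lengths 1–10 (configurable): real gap
length distributions have heavy tails, so the geometric model is fitted
where it holds.  When fewer than two short gap lengths were observed
(closely related genomes at moderate sequence length), the fit falls
back to the geometric maximum-likelihood estimate
extensions/(extensions + runs).  The gap open probability is runs per
opening opportunity, with two opportunities (insertion, deletion) per
match column — the same convention the simulator uses, so
simulate-then-count recovers the generating parameters.  φ and ψ for
score reconstruction are the row/column marginals of π over substitution
columns only; reconstruction of published count-derived tables agrees
within ±3 score units, the precision supported by 2-significant-figure
probabilities.

## Culling and post-masking

`cull_gapless` discards a gapless alignment whose query interval is
fully contained in those of ≥ 2 alignments with strictly greater
score-per-length (whole-alignment density; ties never count, making the
survivor set order-independent).  `postmask` implements gentle masking:
every column touching a lowercase (soft-masked) letter has its score
capped at min(score, 0), gap costs are left unchanged, and the fragment
survives iff its maximum-scoring contiguous column segment still reaches
the reporting threshold e.  Capping at 0 is the weakest intervention
under which an entirely masked alignment cannot reach any positive e;
the filter's decisions therefore depend only on the unmasked portion.

## Synthetic data

`simulate_pair` emulates the generative alignment model itself: aligned
pairs from π; from each match, a deletion or insertion opens with
probability α each and extends geometrically with β; emission stops on
the match column that consumes the requested number of query letters.
Defaults are taken from the calibrated schemes (e.g. the
human-chimp.v2-implied model: ~93 % identity, α ≈ 2.1e-5, β ≈ 0.11), so
simulated data represents the divergence regime those schemes model.
What it deliberately lacks: CpG-elevated substitution, tandem-repeat
indel clustering, heavy-tailed gap lengths, regional rate variation, and
repeat families.  Passing recovery tests therefore show estimator
correctness under the model, not robustness to real genome structure —
the gap-length fit exists precisely because real data deviates.

`make_rearranged_query` applies inversions, deletions, and tandem or
dispersed duplications to a reference and records the surviving
one-to-one orthology (duplicate copies flagged many-to-one).
`exhaustive_local_alignments` is a full Smith–Waterman–Gotoh search (both
query strands) that reports successively weaker local alignments by
banning previously aligned letter pairs — a deliberately slow, complete
stand-in for seed-and-extend candidate generation at test scale
(capped at |query|·|ref| ≤ 10⁶).

`enumerate_fragment_sets` is the independent oracle for the split
machinery: it enumerates every set of disjoint contiguous candidate
fragments via prefix/suffix partition sums over fragment end positions,
returning the exact optimum, partition function, and column marginals;
a plain recursive enumerator cross-validates it at spans ≤ 14.  Oracle
agreement is asserted over hundreds of seeded random instances (spans to
~30 for the optimum, ~12 for marginals — sizes chosen to keep the whole
suite under half a minute).

## Defaults

| parameter | default | meaning |
|---|---|---|
| f | e − 1 | alignment existence cost, score units; just below the reporting threshold e |
| e | 40 (CLI) | reporting score threshold for toy-scale use; genome-scale runs should set the aligner's own threshold |
| t | from calibration | score units per nat |
| mismap threshold | 1e-5 | keep fragments with ≥ 1 position this unambiguous |
| gap-fit cutoff | 10 | longest gap length entering the extension-probability fit |
| window | 200 | window size for substitution-rate summaries (gap columns removed) |

## Known limitations

* One-to-one selection ignores phylogeny and many-to-many orthology;
  reciprocal gene loss will be aligned confidently and wrongly.
* The probability model inherits the classic alignment model's blind
  spots (uniform rates, geometric gaps).
* The MAF dialect is two-row blocks only; the p-line probability
  encoding (phred+33, floored at error 1e-9) is this package's
  convention.
* Candidate generation is out of scope: quality depends on the seeds of
  the upstream aligner, and x-drop artifacts in candidates cannot be
  repaired downstream.
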