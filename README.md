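# splitalign

Split-alignment of genomes: find an optimal **set** of one-to-one local
alignments between two genomes, instead of optimal individual alignments,
and attach a mismap (error) probability to every aligned column.

## Who this is for

Comparative genomicists who need *orthologous* pairwise genome
alignments — e.g. as input to substitution-rate scans, rearrangement
surveys, or read-to-genome mapping — and who want a per-column measure
of alignment ambiguity rather than a single hard assignment.  The input
is a set of candidate local alignments (MAF) from any seed-and-extend
aligner; the output is a non-overlapping subset of their pieces, also in
MAF, annotated with error probabilities.

## The method

Given candidate local alignments of one query sequence against a
reference genome, the tool maximizes

    sum over reported alignments of (alignment score − f)

where *f* is an **alignment existence cost**.  Subtracting *f* per
alignment prevents trivial solutions made of many length-1 alignments,
and guarantees that no reported alignment contains an internal segment
scoring below −*f*.  With *A[i][j]* the score of candidate *i* at query
letter *j* (match, mismatch, or insertion) and *D[i][j]* the deletion
score between letters *j−1* and *j*, the optimum is found by dynamic
programming:

    V[i][j+1] = max(V[i][j] + D[i][j],  W[j] − f) + A[i][j]
    W[j+1]    = max(W[j],  max_i V[i][j+1])

with `V[i][beg(i)] = −∞` and `W[beg] = 0`; the optimal total is
`W[end]`, and traceback recovers the reported pieces.  Running the
procedure a second time with query and reference roles swapped
("2-split") makes the output one-to-one in both genomes.

Scores are related to probabilities through the scale factor *t* (score
units per nat): `prob ∝ exp(score/t)`.  *t* and the background/pair
frequencies implied by a substitution matrix are recovered by solving
the valid log-odds decomposition `π_xy = p_x q_y e^{S(x,y)/t}` (the
implicit-frequencies method), and the affine gap costs convert to gap
open/extend probabilities via

    gap existence cost = −t ln(α(1−β)/β),   gap extension cost = −t ln(β).

A Forward–Backward pass over the same *A/D* layout replaces `max` with
sums of `exp(score/t)`, yielding the posterior probability that each
column belongs to the reported set; `1 − P` is the column's error
probability and a fragment's **mismap** is its minimum column error.
Fragments lacking any position with error ≤ 10⁻⁵ are filtered by
default.

Supporting procedures: event counting and model fitting from existing
alignments, gapless-alignment culling (discard a gapless alignment whose
query segment lies inside ≥ 2 denser ones), and post-masking (discard
alignments that lack any segment scoring ≥ *e* once soft-masked columns
are capped at 0).

## Worked example

Calibrate a built-in scoring scheme:

```
$ splitalign calibrate --matrix human-chimp.v2
# matrix	human-chimp.v2
t	69.0042
lambda	0.0144919
letter	p(ref)	q(query)
a	0.2684	0.2684
c	0.2316	0.2316
g	0.2316	0.2316
t	0.2684	0.2684
pi	a	c	g	t
a	0.27	0.00052	0.002	0.00041
c	0.00052	0.23	0.00053	0.002
g	0.002	0.00053	0.23	0.00052
t	0.00041	0.002	0.00052	0.27
gap_existence_probability	2.1e-05
gap_extension_probability	0.11
```

The scale factor t = 69.0042 means one score unit is 1/69 nats: a score
margin of `ceil(t ln 10^5) = 795` between two alignments of the same
query segment corresponds to a 10⁵-fold ratio of model probabilities.
The π block says this scheme models ~93 % identity (0.27+0.23 ≈ 0.50 per
matching diagonal pair), and gaps are rare (open probability 2.1×10⁻⁵).

Split a set of candidate alignments and keep unambiguous pieces:

```sh
splitalign split    --matrix HoxD70 -e 4000 candidates.maf > 1.maf   # many-to-one
splitalign onetoone --matrix HoxD70 -e 4000 candidates.maf > 2.maf   # one-to-one
```

Each output block carries `mismap=` (minimum column error probability)
on its `a` line and a phred+33-encoded `p` line of per-column error
probabilities.  `-f` (alignment existence cost) defaults to `e − 1`.

Simulate a sequence pair from a scheme's implied model and check the
round trip:

```sh
splitalign simulate --matrix human-chimp.v2 -n 100000 --seed 1 -o sim
splitalign count sim.maf
```

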